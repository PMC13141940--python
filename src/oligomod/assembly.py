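"""Model building by coordinate splicing and filament propagation.

The workflow mirrors how full-length oligomerization-domain models are
assembled from two partial crystal forms:

1. *Splice*: a chimeric monomer is built by superposing the N-terminal donor
   onto the C-terminal donor over a shared helical segment (CA atoms of
   ``fit_range``) and concatenating the ``n_range`` residues of the first
   with the ``c_range`` residues of the second.
2. *Central dimer*: two chimeras built from the A/B chains of the same donor
   dimer are combined without further fitting — the dimer geometry is
   inherited from the C-terminal donor's crystal frame.
3. *Filament propagation*: copies of the dimer are appended through the
   crystal's terminal-dimerization template — at each junction the copy's
   terminal helix is superposed onto the partner-chain position of the
   template dimer, alternating between the two template pairs.

Junction covalent geometry is not regularized (no force-field step); instead
the C(i)–N(i+1) distance across each splice junction is reported and flagged
when outside the peptide-bond range [1.0, 2.0] A, and steric clashes between
adjacent dimers (heavy-atom pairs closer than the clash cutoff) are counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import PairingError, SpecError
from .structio import Chain, StructureModel, select
from .superpose import RigidTransform, apply_transform, kabsch_fit

CLASH_CUTOFF = 2.4  # A, heavy-atom van der Waals overlap between dimers
PEPTIDE_BOND_RANGE = (1.0, 2.0)  # A, acceptable C(i)-N(i+1) junction span

#: default residue intervals: terminal-site propagation and splice fitting
DEFAULT_PROPAGATION_FIT_RANGE = (2, 27)
DEFAULT_SPLICE_FIT_RANGE = (32, 49)


@dataclass
class SpliceSpec:
    """Recipe for a chimeric monomer.

    ``n_donor``/``c_donor`` supply the N- and C-terminal parts; ``fit_range``
    is the inclusive residue interval whose CA atoms drive the superposition;
    ``n_range``/``c_range`` are the inclusive residue intervals taken from
    each donor. The junction must be contiguous in author numbering.
    """

    n_donor: StructureModel
    n_chain: str
    c_donor: StructureModel
    c_chain: str
    fit_range: tuple[int, int] = DEFAULT_SPLICE_FIT_RANGE
    n_range: tuple[int, int] = (2, 32)
    c_range: tuple[int, int] = (33, 58)

    def validate(self) -> None:
        if self.n_range[0] > self.n_range[1] or self.c_range[0] > self.c_range[1]:
            raise SpecError("residue ranges must be increasing")
        if self.n_range[1] + 1 != self.c_range[0]:
            raise SpecError(
                f"junction not contiguous: n_range ends at {self.n_range[1]}, "
                f"c_range starts at {self.c_range[0]}"
            )


@dataclass
class JunctionMetrics:
    fit_rmsd: float
    n_fit_atoms: int
    junction_cn_distance: Optional[float] = None
    junction_ok: Optional[bool] = None
    clash_count: int = 0

    def as_dict(self) -> dict:
        return {
            "fit_rmsd": self.fit_rmsd,
            "n_fit_atoms": self.n_fit_atoms,
            "junction_cn_distance": self.junction_cn_distance,
            "junction_ok": self.junction_ok,
            "clash_count": self.clash_count,
        }


@dataclass
class FilamentModel:
    structure: StructureModel
    n_dimers: int
    junction_report: list[JunctionMetrics] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)


def _fit_ca(model: StructureModel, chain: str, fit_range: Sequence[int]) -> np.ndarray:
    numbers = range(fit_range[0], fit_range[1] + 1)
    coords = model.ca_coords(chain, numbers)
    if len(coords) < 3:
        raise PairingError(
            f"chain {chain}: only {len(coords)} CA atoms in fit range {tuple(fit_range)}"
        )
    return coords


def _paired_fit_ca(
    mobile_model: StructureModel, mobile_chain: str,
    target_model: StructureModel, target_chain: str,
    fit_range: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """CA coordinates paired on residue numbers present in both chains."""
    mc = mobile_model.chain(mobile_chain)
    tc = target_model.chain(target_chain)
    if mc is None or tc is None:
        raise PairingError(f"fit chains {mobile_chain!r}/{target_chain!r} missing")
    lo, hi = fit_range
    m_nums = {r.number for r in mc.residues if lo <= r.number <= hi and r.atom("CA")}
    t_nums = {r.number for r in tc.residues if lo <= r.number <= hi and r.atom("CA")}
    common = sorted(m_nums & t_nums)
    if len(common) < 3:
        raise PairingError(
            f"only {len(common)} shared CA residues in fit range {tuple(fit_range)}"
        )
    return (
        mobile_model.ca_coords(mobile_chain, common),
        target_model.ca_coords(target_chain, common),
    )


def splice_chimera(spec: SpliceSpec, out_chain_id: str = "A") -> tuple[StructureModel, JunctionMetrics]:
    """Build a single-chain chimera per the SpliceSpec.

    The N-terminal donor is superposed onto the C-terminal donor over the CA
    atoms of ``fit_range``; the output chain is the transformed ``n_range``
    residues followed by the C-donor's ``c_range`` residues, keeping author
    numbering. Returns the chimera and junction metrics (fit rmsd and the
    C(i)-N(i+1) distance across the junction).
    """
    spec.validate()
    mob, tgt = _paired_fit_ca(
        spec.n_donor, spec.n_chain, spec.c_donor, spec.c_chain, spec.fit_range
    )
    fit = kabsch_fit(mob, tgt)
    n_part = apply_transform(
        select(spec.n_donor, {spec.n_chain}, spec.n_range), fit.transform
    )
    c_part = select(spec.c_donor, {spec.c_chain}, spec.c_range)
    if not n_part.chains or not c_part.chains:
        raise SpecError("a donor supplied no residues in its range")

    chain = Chain(id=out_chain_id)
    chain.residues = n_part.chains[0].residues + c_part.chains[0].residues
    chimera = StructureModel(
        identifier=f"chimera_{spec.n_donor.identifier}_{spec.c_donor.identifier}",
        chains=[chain],
    )

    metrics = JunctionMetrics(fit_rmsd=fit.rmsd, n_fit_atoms=fit.n_pairs)
    last_n = chain.residues and _residue_by_number(chain, spec.n_range[1])
    first_c = chain.residues and _residue_by_number(chain, spec.c_range[0])
    c_atom = last_n.atom("C") if last_n else None
    n_atom = first_c.atom("N") if first_c else None
    if c_atom is not None and n_atom is not None:
        d = float(np.linalg.norm(c_atom.position - n_atom.position))
        metrics.junction_cn_distance = d
        metrics.junction_ok = PEPTIDE_BOND_RANGE[0] <= d <= PEPTIDE_BOND_RANGE[1]
    return chimera, metrics


def _residue_by_number(chain: Chain, number: int):
    for r in chain.residues:
        if r.number == number:
            return r
    return None


def count_clashes(model_a: StructureModel, model_b: StructureModel,
                  cutoff: float = CLASH_CUTOFF) -> int:
    """Heavy-atom pairs between two models closer than the clash cutoff."""
    a, b = model_a.coords(), model_b.coords()
    if not a.size or not b.size:
        return 0
    tree = cKDTree(b)
    return int(sum(len(hits) for hits in tree.query_ball_point(a, cutoff)))


def build_central_dimer(
    chimera1: StructureModel, chimera2: StructureModel
) -> tuple[StructureModel, JunctionMetrics]:
    """Combine two chimeric monomers into the central-site dimer.

    No fitting is performed: both chimeras keep the C-terminal donor's
    coordinates, so the dimer geometry is inherited from that crystal frame.
    Chain-id collisions are resolved by renaming the second chain.
    """
    c1 = chimera1.copy().chains[0]
    c2 = chimera2.copy().chains[0]
    if c1.id == c2.id:
        c2.id = "B" if c1.id != "B" else "C"
    dimer = StructureModel(identifier="central_dimer", chains=[c1, c2])
    m1 = StructureModel(chains=[c1])
    m2 = StructureModel(chains=[c2])
    if m1.coords().shape == m2.coords().shape and np.allclose(m1.coords(), m2.coords()):
        raise SpecError("both chimeras occupy identical coordinates (exact duplication)")
    clashes = count_clashes(m1, m2)
    return dimer, JunctionMetrics(fit_rmsd=0.0, n_fit_atoms=0, clash_count=clashes)


def propagate_filament(
    dimer: StructureModel,
    template: StructureModel,
    template_pairs: Sequence[tuple[str, str]],
    fit_range: Sequence[int] = DEFAULT_PROPAGATION_FIT_RANGE,
    n_dimers: int = 4,
) -> FilamentModel:
    """Grow a filament by repeated terminal-site superposition.

    At each step the template's terminal dimer (pair ``(ref, partner)``,
    alternating through ``template_pairs``) is brought into the frame of the
    filament's current end chain by superposing the template ``ref`` chain
    onto the end chain over the CA atoms of ``fit_range``. A fresh copy of
    the input dimer is then superposed (first chain, same fit range) onto
    the transformed template ``partner`` chain. The copy's second chain
    becomes the new growing end.

    Returns a FilamentModel with ``2 * n_dimers`` chains renamed
    sequentially (A, B, C, ...), a per-junction report (fit rmsd, clash
    count against the previous dimer) and a provenance map.
    """
    if n_dimers < 1:
        raise SpecError("n_dimers must be >= 1")
    if len(dimer.chains) != 2:
        raise SpecError("input dimer must have exactly 2 chains")
    if not template_pairs:
        raise SpecError("at least one template chain pair is required")

    alphabet = [chr(ord("A") + i) for i in range(26)] + [
        chr(ord("a") + i) for i in range(26)
    ] + [str(i) for i in range(10)]

    placed: list[StructureModel] = [dimer.copy()]
    report: list[JunctionMetrics] = []
    provenance: list[dict] = [
        {"copy_index": 0, "source_chain": c.id} for c in dimer.chains
    ]

    end_model = placed[0]
    end_chain = dimer.chains[1].id  # second chain exposes the free terminal site
    first_chain = dimer.chains[0].id

    for k in range(1, n_dimers):
        ref_id, partner_id = template_pairs[(k - 1) % len(template_pairs)]
        # bring the template terminal dimer into the frame of the growing end
        mob, tgt = _paired_fit_ca(template, ref_id, end_model, end_chain, fit_range)
        to_end = kabsch_fit(mob, tgt)
        template_in_frame = apply_transform(select(template, {partner_id}), to_end.transform)
        # superpose a fresh copy onto the transformed partner chain
        mob2, tgt2 = _paired_fit_ca(dimer, first_chain, template_in_frame, partner_id, fit_range)
        place = kabsch_fit(mob2, tgt2)
        copy = apply_transform(dimer, place.transform)
        clashes = count_clashes(placed[-1], copy)
        report.append(
            JunctionMetrics(fit_rmsd=place.rmsd, n_fit_atoms=place.n_pairs,
                            clash_count=clashes)
        )
        placed.append(copy)
        provenance.extend(
            {"copy_index": k, "source_chain": c.id} for c in dimer.chains
        )
        end_model = copy
        end_chain = dimer.chains[1].id

    structure = StructureModel(identifier=f"filament_{n_dimers}x")
    idx = 0
    for copy in placed:
        for chain in copy.chains:
            chain.id = alphabet[idx]
            structure.chains.append(chain)
            idx += 1
    for entry, chain in zip(provenance, structure.chains):
        entry["placed_chain"] = chain.id
    return FilamentModel(
        structure=structure, n_dimers=n_dimers,
        junction_report=report, provenance=provenance,
    )


def junction_report_jsonl(filament: FilamentModel) -> str:
    """Serialize the junction report as JSON lines (one record per junction)."""
    import json

    return "\n".join(json.dumps(m.as_dict()) for m in filament.junction_report)
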