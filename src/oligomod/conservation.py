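"""Map structurally identified interaction residues onto a multiple
sequence alignment of homologs and classify their conservation.

A reference sequence (e.g. the crystallized protein) anchors the mapping:
ungapped reference positions, counted from 1, are mapped to alignment
columns, and each homolog's residue in that column is classified as
identical, similar (same physicochemical group), different, or gap. The
similarity grouping is configuration; the default groups small/aliphatic,
aromatic, basic, acidic, polar, and conformationally special residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import AlignIO

from .errors import FormatError, SpecError

#: default similarity grouping (one-letter codes); the classification is
#: configuration, not a fixed biological truth
DEFAULT_SIMILARITY_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("ILVMA"),
    frozenset("FWY"),
    frozenset("KRH"),
    frozenset("DE"),
    frozenset("STNQ"),
    frozenset("GP"),
    frozenset("C"),
)

GAP_CHARS = frozenset("-.")


@dataclass
class Alignment:
    """Aligned sequences with gaps preserved; ids unique."""

    ids: list[str]
    sequences: dict[str, str]

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))


@dataclass
class AlignmentColumnMap:
    reference_id: str
    alignment: Alignment
    column_of_residue: dict[int, int]  # reference residue number -> column (0-based)

    def residue_at(self, sequence_id: str, column: int) -> str:
        return self.alignment.sequences[sequence_id][column].upper()


@dataclass
class ConservationReport:
    residue_number: int
    reference_aa: str
    status: dict[str, str] = field(default_factory=dict)  # homolog -> classification


def load_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Load a FASTA or Clustal alignment (all sequences equal length)."""
    fmt = format.lower()
    if fmt not in ("fasta", "clustal"):
        raise FormatError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        # AlignIO rejects ragged records; surface the offender when possible
        raise FormatError(f"{path}: {exc}") from exc
    ids, seqs = [], {}
    for rec in aln:
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        ids.append(rec.id)
        seqs[rec.id] = str(rec.seq)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        offender = next(i for i in ids if len(seqs[i]) != len(seqs[ids[0]]))
        raise FormatError(f"{path}: ragged alignment (sequence {offender!r})")
    if not ids:
        raise FormatError(f"{path}: empty alignment")
    return Alignment(ids=ids, sequences=seqs)


def map_reference(alignment: Alignment, reference_id: str) -> AlignmentColumnMap:
    """Map reference residue numbers (ungapped, from 1) to alignment columns."""
    if reference_id not in alignment.sequences:
        raise SpecError(f"reference id {reference_id!r} not in alignment")
    seq = alignment.sequences[reference_id]
    column_of_residue = {}
    resnum = 0
    for col, ch in enumerate(seq):
        if ch not in GAP_CHARS:
            resnum += 1
            column_of_residue[resnum] = col
    if not column_of_residue:
        raise SpecError(f"reference {reference_id!r} is all gaps")
    return AlignmentColumnMap(reference_id, alignment, column_of_residue)


def _group_of(aa: str, groups: Sequence[frozenset[str]]) -> Optional[frozenset[str]]:
    for g in groups:
        if aa in g:
            return g
    return None


def conservation_report(
    column_map: AlignmentColumnMap,
    residues: Iterable[int],
    similarity_groups: Sequence[frozenset[str]] = DEFAULT_SIMILARITY_GROUPS,
) -> list[ConservationReport]:
    """Classify each requested reference residue across all homologs.

    Statuses: ``identical`` (same amino acid), ``similar`` (same similarity
    group), ``different``, ``gap``. Case-insensitive.
    """
    reports = []
    homologs = [i for i in column_map.alignment.ids if i != column_map.reference_id]
    for resnum in sorted(residues):
        if resnum not in column_map.column_of_residue:
            raise SpecError(
                f"residue {resnum} outside reference {column_map.reference_id!r}"
            )
        col = column_map.column_of_residue[resnum]
        ref_aa = column_map.residue_at(column_map.reference_id, col)
        report = ConservationReport(residue_number=resnum, reference_aa=ref_aa)
        for hid in homologs:
            aa = column_map.residue_at(hid, col)
            if aa in GAP_CHARS:
                status = "gap"
            elif aa == ref_aa:
                status = "identical"
            elif _group_of(aa, similarity_groups) is not None and _group_of(
                aa, similarity_groups
            ) == _group_of(ref_aa, similarity_groups):
                status = "similar"
            else:
                status = "different"
            report.status[hid] = status
        reports.append(report)
    return reports


def conserved_or_similar_counts(
    reports: Sequence[ConservationReport],
) -> dict[str, dict[str, int]]:
    """Per homolog: how many of the queried residues are identical, and how
    many are identical-or-similar."""
    out: dict[str, dict[str, int]] = {}
    for rep in reports:
        for hid, status in rep.status.items():
            entry = out.setdefault(hid, {"identical": 0, "conserved_or_similar": 0})
            if status == "identical":
                entry["identical"] += 1
            if status in ("identical", "similar"):
                entry["conserved_or_similar"] += 1
    return out


def report_to_tsv(reports: Sequence[ConservationReport]) -> str:
    if not reports:
        return "residue\treference_aa"
    homologs = list(reports[0].status)
    header = "\t".join(["residue", "reference_aa", *homologs])
    lines = [header]
    for rep in reports:
        lines.append(
            "\t".join(
                [str(rep.residue_number), rep.reference_aa]
                + [rep.status[h] for h in homologs]
            )
        )
    return "\n".join(lines)
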