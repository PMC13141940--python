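# Methods

This note records the models, conventions and numerical choices behind
`oligomod`, and what the synthetic test data do and do not establish.

## Coordinate model and file handling

Structures are a plain chain → residue → atom hierarchy in ångström, using
**author residue numbering** throughout (the numbering used in the
structural literature on these proteins; for mmCIF the `auth_` identifiers
are taken). Parsing and serialization go through gemmi. Policy on reading:

* only amino-acid polymer residues are kept — waters, ligands and ions are
  excluded; a file containing no protein atoms is an error, not an empty
  model;
* hydrogens are always dropped: the crystal structures of interest contain
  none, and every distance cutoff in the package is heavy-atom based;
* alternate locations resolve to altloc "A" when present, otherwise the
  highest-occupancy conformer, ties broken by file order — deterministic and
  in line with common practice;
* insertion codes are carried in the model but expected to be absent in the
  target structures; a warning is logged when one is seen;
* multi-model (NMR-style) files contribute only their first model.

Writing emits standard PDB records; residue numbers above 9999 or more than
62 chains are rejected rather than silently truncated. Round trips preserve
identifiers exactly and coordinates to the PDB's three decimals.

## Rigid-body superposition

`kabsch_fit` is the closed-form least-squares superposition: SVD of the
3×3 covariance of the centered point sets with a determinant sign
correction, guaranteeing a proper rotation (det = +1, never a reflection).
Reported RMSD is always the post-superposition minimum. Point sets whose
second covariance singular value falls below 1e-10 of the largest are
rejected as collinear (the rotation is not unique there). An independent
quaternion characteristic-polynomial implementation exists in the test
suite only, as an oracle; the two agree to better than 1e-9 Å on random
noisy instances.

`chain_pair_rmsd` pairs Cα atoms by the intersection of author residue
numbers — "common Cα pairs" read literally — and fits each chain pair
independently. No sequence alignment, fragment weighting or B-factor
weighting is performed.

## Chimeric splicing and filament propagation

The model-building procedure reproduces how a full oligomerization-domain
monomer is assembled from two partial crystal forms: the N-terminal donor is
superposed onto the C-terminal donor over the Cα atoms of a shared helical
interval (default 32–49), and the chimera takes residues 2–32 from the
first donor and 33–58 from the second, keeping the C-donor frame fixed so
that a central-site dimer is inherited rather than refit. Filaments grow by
repeatedly superposing a fresh dimer copy onto the partner-chain position of
the crystal's terminal-dimer template (default fit interval 2–27),
alternating template pairs along the filament; chains are renamed
sequentially with a recorded provenance map.

Junction covalent geometry is deliberately **not** regularized — no force
field is involved. Instead each junction reports its fit RMSD, the
C(i)–N(i+1) distance (flagged outside 1.0–2.0 Å, the plausible peptide-bond
span), and the count of inter-dimer heavy-atom pairs closer than 2.4 Å (a
conservative van der Waals overlap criterion). No atoms are discarded when
copies overlap; clashes are counted and reported instead.

## Interface analysis

SASA is Shrake–Rupley with a fixed golden-section (Fibonacci) spiral
lattice — 960 points per atom by default, probe radius 1.4 Å — so results
are bit-reproducible run to run. Van der Waals radii are a Bondi-type set
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å) shipped in `_tables.py` and used
for both SASA and clash checks; an atom without a tabulated radius is an
error naming the offenders. Buried interface area follows the convention
area = (SASA(A) + SASA(B) − SASA(AB)) / 2, computed both over a stated
residue interval (e.g. the terminal-site region 2–37) and over whole chains,
since published interface figures do not always say which was used. No
solvation free energy or interface "significance" is estimated — area only.

Salt bridges: inter-chain basic side-chain nitrogen (Arg NE/NH1/NH2,
Lys NZ; His ND1/NE2 optional, off by default) within 4.0 Å of an acidic
side-chain oxygen (Asp OD1/OD2, Glu OE1/OE2), one record per residue pair at
the minimum distance. The 4.0 Å N–O default is the common convention; the
cutoff is an explicit parameter because published contact lists rarely state
one. Hydrophobic contacts: inter-chain side-chain carbon pairs of Ala, Val,
Leu, Ile, Met, Phe, Trp, Pro within 4.5 Å; glycine participates through its
Cα, since it has no side chain yet can contribute to apolar packing.

## SEC-SAXS analysis

Frame reduction averages the stated buffer frames (arithmetic mean),
averages the sample frames, subtracts, and propagates uncertainties in
quadrature divided by the frame counts. Absolute-scale calibration is out
of scope.

Guinier analysis fits ln I against q² by (weighted, when σ is present)
linear regression over the largest contiguous low-q window satisfying
q·R_g ≤ `q_rg_max`, iterating window and R_g to convergence (tolerance
1e-6, ≤ 50 iterations); R_g = √(−3·slope), I(0) = exp(intercept). The
default bound 1.3 is the standard validity limit for globular particles.
Note a known property of the estimator: for a *noise-free* compact body the
neglected quartic term of the form-factor expansion biases the log-space
slope — about +2% in R_g for a uniform sphere fit to q·R_g = 1.3 — so
internal consistency checks against coordinate R_g use a stricter window
(q·R_g ≤ 0.8), where the bias is well under 1%. This is a property of the
Guinier approximation itself, not of the implementation.

Theoretical scattering uses the Debye double sum with q = 0 handled by the
sinc limit. Atomic scattering weights are q-independent electron counts by
default; an optional reduced-excess mode subtracts displaced-solvent
electrons (0.334 e/Å³ × Fraser-type atomic volumes). **No hydration shell
is modelled**: hydration typically inflates the apparent R_g of a
solution-scattering curve by several percent relative to the bare
coordinates, so comparisons against shell-modelling programs carry that
known systematic gap. Pairwise cost is bounded two ways: structures above
20,000 atoms are coarse-grained to one bead per residue (weighted centroid,
summed weight), and point sets with more than ~4M ordered pairs are
evaluated through a fine pair-distance histogram (bin width ≤ 0.05 Å,
quadrature error (q·Δr)²/24, each bin at its weighted centroid distance) —
both documented approximations with sub-percent effect on the q ranges
used. Theory-to-experiment fitting is linear least squares in scale and
constant offset, weighted by experimental σ, reporting χ²/(N−2).

The dimensionless Kratky transform (qR_g)²·I/I(0) against qR_g is provided
for shape classification: globular particles peak at 3/e ≈ 1.10 near
qR_g = √3; extended or flexible chains rise toward a plateau.

## Conservation mapping

A reference sequence anchors residue numbers (ungapped positions counted
from 1) to alignment columns; each homolog's residue in a column is
classified identical / similar / different / gap. "Similar" is a
configurable partition of the amino acids, defaulting to
{ILVMA} {FWY} {KRH} {DE} {STNQ} {GP} {C} — published figures rarely define
their shading rule, so the grouping is explicit configuration, not a
claim. Alignment-column equivalence (not position-number identity) is the
convention. Alignments are consumed, never computed; homolog sequences are
user input and only small fictional demo alignments ship with the package.

## Synthetic data: what it emulates, and what passing tests show

The generators are all deterministic under a seed:

* `make_helix` — ideal α-helix (rise 1.5 Å, twist 100°, Cα radius 2.3 Å,
  textbook values) with backbone N/CA/C/O on companion helical paths and an
  optional axis bend at a chosen residue, emulating the bent two-helix
  monomer fold; side chains are not generated (interaction fixtures place
  explicit side-chain atoms at specified geometry instead).
* `make_antiparallel_dimer` — the terminal-site antiparallel coiled-coil
  topology, by a 180° flip plus translation.
* `make_bead_sphere` — uniform beads in a ball (rejection sampling), the
  analytic oracle body for scattering: R_g = √(3/5)·R exactly in the
  continuum limit. A single random realization carries Monte-Carlo structure
  noise (amplified near form-factor minima) and a flat 1/N incoherent floor,
  so form-factor comparisons ensemble-average several independent
  realizations.
* `simulate_sec_series` — Gaussian elution peak over a constant buffer with
  relative Gaussian noise; defaults (303 frames, peak near frame 139, 15
  pre-peak buffer frames, 11 peak frames) mirror a continuous-collection
  SEC-SAXS acquisition.

These fixtures have exact ground truth but are idealized: no side-chain
packing, no solvent, no detector artifacts, no inter-frame drift. Passing
tests therefore establish the correctness of the algorithms and their
numerical contracts, not the field-specific systematics of real data
(hydration, capillary fouling, beam-profile smearing), which are out of
scope.

## Reproduction against deposited data

The crystal structures (wwPDB 8H8H — eight chains forming four terminal-site
dimers; 5B52 — the straight-helix variant) and the solution profile (SASBDB
SASDUP4) are consumed as user-supplied files under `data/accessions/`; the
package does not redistribute or download them. The reproduction tests
assert the published statistics (fragment superposition RMSD 0.46 Å,
chain-A-vs-rest RMSD range 0.926–2.645 Å, eight chains, maximum terminal
interface 941.8 Å² over residues 2–37, dimer coordinate R_g 24.2 Å,
solution R_g 28.8 ± 1.9 Å, and exact recovery of the eleven published salt
bridges at some N–O cutoff in 3.5–4.5 Å). Documented systematics: the SASA
value depends mildly on the radius set and point count, and the coordinate
R_g excludes the hydration contribution present in shell-modelling tools.

## Problem sizes

Default test and acceptance runs use bead counts of 2,000–12,000 (with six
realizations for ensemble-averaged form-factor checks), 1,000 random
superposition instances, 303-frame simulated elutions and helices of 20–58
residues — sizes at which every closed-form oracle is sharp while the whole
suite stays fast on a single CPU.

## Known limitations

No crystallographic phasing/refinement, no energy minimization, no p(r)
inversion or ab initio shape reconstruction, no molecular-weight estimation
from Porod volume, no hydration-shell scattering, no sequence-alignment
computation, no symmetry expansion from crystallographic operators.
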