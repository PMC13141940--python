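"""Small-angle X-ray scattering analysis.

Covers the solution-structure workflow around an in-line size-exclusion
chromatography SAXS experiment:

* frame reduction — averaging pre-peak buffer frames, averaging peak frames,
  buffer subtraction with quadrature error propagation;
* Guinier analysis — iterative low-q window selection under the
  q·Rg <= 1.3 validity bound, weighted regression of ln I on q²,
  Rg = sqrt(-3·slope), I(0) = exp(intercept);
* dimensionless (normalized) Kratky transform (qRg)²·I/I(0) vs qRg —
  globular particles peak near sqrt(3) at height 3/e, extended or flexible
  chains rise toward a plateau;
* theoretical scattering from coordinates via the Debye double sum
  I(q) = sum_ij f_i f_j sinc(q r_ij), with either constant per-element
  electron counts or reduced excess scattering factors (electrons minus
  displaced-solvent electrons); no explicit hydration shell is modelled;
* least-squares scale/offset fitting of a theoretical curve to an
  experimental profile with reduced chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from ._tables import DISPLACED_VOLUMES, ELECTRON_COUNTS, WATER_ELECTRON_DENSITY
from .errors import SpecError
from .structio import StructureModel

DEFAULT_Q_RG_MAX = 1.3


@dataclass
class ScatteringProfile:
    """A 1-D scattering curve: q (A^-1), intensity, optional uncertainty."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have equal length")
        if self.sigma is not None and self.sigma.shape != self.q.shape:
            raise ValueError("sigma must match q in length")
        if np.any(self.q < 0) or np.any(np.diff(self.q) < 0):
            raise ValueError("q must be non-negative and non-decreasing")
        if self.sigma is not None and np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive where present")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class GuinierResult:
    rg: float
    i0: float
    fit_range: tuple[int, int]  # [first, last] q index used, inclusive
    q_rg_max: float
    r_squared: float


@dataclass
class FrameSeries:
    """Ordered scattering frames on a shared q grid (an elution series)."""

    frames: list[ScatteringProfile]
    elution_index: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.elution_index:
            self.elution_index = list(range(len(self.frames)))
        q0 = self.frames[0].q
        for f in self.frames[1:]:
            if f.q.shape != q0.shape or not np.array_equal(f.q, q0):
                raise ValueError("all frames must share an identical q grid")


# ---------------------------------------------------------------------------
# profile I/O (3-column whitespace text, the de facto .dat convention)

def read_profile(path: str | Path) -> ScatteringProfile:
    """Read a 3-column (q, I, sigma) or 2-column (q, I) text profile.

    Comment lines (#) and non-numeric header/footer lines are skipped.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            continue
        try:
            vals = [float(p) for p in parts[:3]]
        except ValueError:
            continue
        rows.append(vals)
    if not rows:
        raise SpecError(f"{path}: no numeric data rows found")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows])
    sigma = arr[:, 2] if ncol >= 3 and np.all(arr[:, 2] > 0) else None
    return ScatteringProfile(arr[:, 0], arr[:, 1], sigma)


def write_profile(profile: ScatteringProfile, path: str | Path) -> None:
    cols = [profile.q, profile.intensity]
    if profile.sigma is not None:
        cols.append(profile.sigma)
    np.savetxt(path, np.column_stack(cols), fmt="%.8e")


# ---------------------------------------------------------------------------
# SEC-SAXS reduction

def subtract_background(
    series: FrameSeries,
    buffer_frames: Iterable[int],
    sample_frames: Iterable[int],
) -> ScatteringProfile:
    """Average sample frames minus averaged buffer frames.

    ``buffer_frames``/``sample_frames`` index into ``series.elution_index``.
    Sigmas are propagated in quadrature, divided by the frame counts.
    """
    buf = set(buffer_frames)
    sam = set(sample_frames)
    if not buf or not sam:
        raise SpecError("buffer and sample frame sets must be non-empty")
    if buf & sam:
        raise SpecError(f"buffer/sample frame sets overlap: {sorted(buf & sam)}")
    index = {e: i for i, e in enumerate(series.elution_index)}
    missing = (buf | sam) - set(index)
    if missing:
        raise SpecError(f"frames not in series: {sorted(missing)}")

    def _mean(frames: set[int]) -> tuple[np.ndarray, Optional[np.ndarray]]:
        profs = [series.frames[index[e]] for e in sorted(frames)]
        inten = np.mean([p.intensity for p in profs], axis=0)
        if all(p.sigma is not None for p in profs):
            var = np.sum([p.sigma**2 for p in profs], axis=0) / len(profs) ** 2
            return inten, np.sqrt(var)
        return inten, None

    b_i, b_s = _mean(buf)
    s_i, s_s = _mean(sam)
    sigma = None
    if b_s is not None and s_s is not None:
        sigma = np.sqrt(b_s**2 + s_s**2)
    return ScatteringProfile(series.frames[0].q.copy(), s_i - b_i, sigma)


# ---------------------------------------------------------------------------
# theoretical scattering from coordinates

def _atom_weights(model: StructureModel, form_factor: str) -> np.ndarray:
    elements = [a.element.upper() for _, _, a in model.iter_atoms()]
    if form_factor == "constant_electrons":
        return np.array([ELECTRON_COUNTS.get(e, 6.0) for e in elements])
    if form_factor == "reduced_excess":
        return np.array(
            [
                ELECTRON_COUNTS.get(e, 6.0)
                - WATER_ELECTRON_DENSITY * DISPLACED_VOLUMES.get(e, 16.44)
                for e in elements
            ]
        )
    raise SpecError(f"unknown form_factor {form_factor!r}")


def rg_from_coords(model: StructureModel, weighting: str = "electron_count") -> float:
    """Radius of gyration (A) of the coordinates.

    Weighted root-mean-square distance from the weighted centroid;
    ``weighting`` is ``"uniform"`` or ``"electron_count"``.
    """
    coords = model.coords()
    if coords.shape[0] == 0:
        raise SpecError("model has no atoms")
    if weighting == "uniform":
        w = np.ones(len(coords))
    elif weighting == "electron_count":
        w = _atom_weights(model, "constant_electrons")
    else:
        raise SpecError(f"unknown weighting {weighting!r}")
    centroid = (coords * w[:, None]).sum(axis=0) / w.sum()
    d2 = ((coords - centroid) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def debye_profile(
    model: StructureModel,
    q_grid: Sequence[float],
    form_factor: str = "constant_electrons",
    coarse_grain_threshold: int = 20000,
) -> ScatteringProfile:
    """Orientationally averaged scattering intensity via the Debye sum.

    I(q) = sum_i sum_j f_i f_j sin(q r_ij)/(q r_ij); q = 0 is evaluated by
    the sinc limit. Structures above ``coarse_grain_threshold`` atoms are
    coarse-grained to one bead per residue (at the residue centroid, weighted
    by the residue's summed scattering factor) to bound the pairwise cost.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or len(q) == 0 or np.any(np.diff(q) <= 0) or np.any(q < 0):
        raise SpecError("q_grid must be non-empty, non-negative, strictly increasing")
    coords = model.coords()
    if coords.shape[0] == 0:
        raise SpecError("model has no atoms")
    weights = _atom_weights(model, form_factor)

    if len(coords) > coarse_grain_threshold:
        beads, bw, start = [], [], 0
        for chain in model.chains:
            for res in chain.residues:
                n = len(res.atoms)
                xyz = coords[start : start + n]
                rw = weights[start : start + n]
                beads.append((xyz * rw[:, None]).sum(axis=0) / rw.sum())
                bw.append(rw.sum())
                start += n
        coords = np.array(beads)
        weights = np.array(bw)

    n = len(coords)
    intensity = np.empty_like(q)
    if n * n > 4_000_000:
        # pair-distance histogram evaluation, accumulated in row blocks to
        # bound memory: bins fine enough that the quadrature error
        # (q*dr)^2/24 is negligible at the largest q; each occupied bin
        # contributes at its weighted centroid distance. All ordered pairs
        # (including i == j, at r = 0) enter once, so no separate self term.
        from scipy.spatial.distance import cdist

        dr = min(0.05, 0.02 / max(q[-1], 1e-6))
        span = coords.max(axis=0) - coords.min(axis=0)
        nbins = int(np.ceil(np.linalg.norm(span) / dr)) + 2
        w_hist = np.zeros(nbins)
        wr_hist = np.zeros(nbins)
        block = max(1, int(1e7 // n))
        for i0 in range(0, n, block):
            d = cdist(coords[i0 : i0 + block], coords).ravel()
            ww = (weights[i0 : i0 + block, None] * weights[None, :]).ravel()
            idx = np.minimum((d / dr).astype(np.int64), nbins - 1)
            w_hist += np.bincount(idx, weights=ww, minlength=nbins)
            wr_hist += np.bincount(idx, weights=ww * d, minlength=nbins)
        occupied = w_hist > 0
        w_b = w_hist[occupied]
        r_b = wr_hist[occupied] / w_b
        for k, qk in enumerate(q):
            intensity[k] = (w_b * np.sinc(qk * r_b / np.pi)).sum()
    else:
        # exact condensed-form double sum
        from scipy.spatial.distance import pdist

        rij = pdist(coords)
        iu = np.triu_indices(n, k=1)
        wij = weights[iu[0]] * weights[iu[1]]
        self_term = float((weights**2).sum())
        chunk = max(1, int(2e7 // max(len(rij), 1)))
        for start in range(0, len(q), chunk):
            qs = q[start : start + chunk]
            x = qs[:, None] * rij[None, :]
            intensity[start : start + chunk] = (
                self_term + 2.0 * (wij * np.sinc(x / np.pi)).sum(axis=1)
            )
    return ScatteringProfile(q, intensity)


# ---------------------------------------------------------------------------
# Guinier analysis

def guinier_fit(
    profile: ScatteringProfile,
    q_rg_max: float = DEFAULT_Q_RG_MAX,
    min_points: int = 5,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> GuinierResult:
    """Guinier regression with iterative range selection.

    Fits ln I = ln I(0) - (Rg² / 3) q² over the largest contiguous low-q
    window satisfying q_max·Rg <= ``q_rg_max``, iterating the window until
    the Rg estimate converges. Points with non-positive intensity are
    excluded from the low-q end consideration.
    """
    q, inten = profile.q, profile.intensity
    positive = inten > 0
    first = int(np.argmax(positive))
    if not positive.any():
        raise SpecError("no positive intensities: cannot take logarithms")
    run_end = first
    while run_end < len(q) and positive[run_end]:
        run_end += 1
    if run_end - first < min_points:
        raise SpecError(f"fewer than {min_points} positive low-q points")

    w = None
    if profile.sigma is not None:
        w = (inten / profile.sigma) ** 2  # weights for ln I: (I/sigma)^2

    def _fit(i0_idx: int, i1_idx: int) -> tuple[float, float, float]:
        sl = slice(i0_idx, i1_idx + 1)
        x = q[sl] ** 2
        y = np.log(inten[sl])
        ww = None if w is None else np.sqrt(w[sl])
        slope, intercept = np.polyfit(x, y, 1, w=ww)
        yhat = slope * x + intercept
        ss_res = float(((y - yhat) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return slope, intercept, r2

    hi = run_end - 1
    rg_prev = None
    for _ in range(max_iter):
        slope, intercept, r2 = _fit(first, hi)
        if slope >= 0:
            raise SpecError("non-negative Guinier slope: profile is not Guinier-like")
        rg = float(np.sqrt(-3.0 * slope))
        # largest index with q*Rg <= bound
        valid = np.searchsorted(q * rg, q_rg_max, side="right") - 1
        new_hi = max(min(valid, run_end - 1), first + min_points - 1)
        if rg_prev is not None and abs(rg - rg_prev) <= tol * rg and new_hi == hi:
            break
        rg_prev, hi = rg, new_hi
    slope, intercept, r2 = _fit(first, hi)
    if slope >= 0:
        raise SpecError("non-negative Guinier slope after range selection")
    rg = float(np.sqrt(-3.0 * slope))
    return GuinierResult(
        rg=rg,
        i0=float(np.exp(intercept)),
        fit_range=(int(first), int(hi)),
        q_rg_max=q_rg_max,
        r_squared=r2,
    )


def normalized_kratky(
    profile: ScatteringProfile, g: GuinierResult
) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless Kratky transform: (qRg, (qRg)²·I/I(0))."""
    x = profile.q * g.rg
    y = x**2 * profile.intensity / g.i0
    return x, y


# ---------------------------------------------------------------------------
# theory-vs-experiment fitting

@dataclass
class ProfileFit:
    scale: float
    offset: float
    chi2_reduced: float
    fitted: ScatteringProfile  # scale * theory + offset on the experiment grid


def fit_theoretical(
    theory: ScatteringProfile, experiment: ScatteringProfile
) -> ProfileFit:
    """Least-squares scale + constant offset fit of theory to experiment.

    Minimizes sum(((I_exp - c·I_th - b)/sigma)²); the reduced chi-square
    divides by N - 2. Without experimental sigmas an unweighted fit is
    performed (with a warning).
    """
    th = np.interp(experiment.q, theory.q, theory.intensity)
    if experiment.sigma is None:
        warnings.warn("experiment has no sigma; performing unweighted fit")
        sig = np.ones_like(experiment.intensity)
    else:
        sig = experiment.sigma
    A = np.column_stack([th / sig, 1.0 / sig])
    y = experiment.intensity / sig
    (c, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = (experiment.intensity - c * th - b) / sig
    ndof = max(len(y) - 2, 1)
    return ProfileFit(
        scale=float(c),
        offset=float(b),
        chi2_reduced=float((resid**2).sum() / ndof),
        fitted=ScatteringProfile(experiment.q.copy(), c * th + b),
    )
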