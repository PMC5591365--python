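"""Synthetic inputs: geometric phantoms and simulated validation cohorts.

Two families of test data stand in for patient imaging and records, which
the original study could not share:

* **Phantoms** — axis-aligned ellipsoid "tumours" with an oedema shell of
  commanded thickness, a ventricle slab at a commanded surface gap,
  optional overlapping corpus-callosum / eloquent boxes, and commanded
  laterality relative to the midsagittal plane. Every commanded quantity
  is the analytic ground truth the geometry module must recover (lengths
  to within one voxel diagonal, booleans exactly).

* **Simulated cohorts** — per-patient binary feature flags drawn at the
  prevalences observed in the validation cohort (68/88, 29/88, 38/88,
  62/88, 61/88), graded with the scoring rules, and given class-conditional
  resection / major-complication outcomes (7/14, 7/45, 1/29 and 0/14,
  1/45, 2/29). A noisy second rater flips each flag independently with
  probability ``epsilon``, which makes chance-corrected agreement a
  one-parameter calibration problem.

Flags are independent Bernoulli by default; the published tables give only
marginals, so any joint structure (optional Gaussian copula) is explicitly
synthetic. All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grading import FLAG_NAMES, classify_scores
from .cohort_stats import cohens_kappa, rater_crosstab
from .geometry import TumorFeatures
from .masks import MaskVolume, Plane, RegionAtlas

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "random_phantom_spec",
    "CohortSimParams",
    "simulate_cohort",
    "simulate_second_rater",
    "calibrate_rater_noise",
    "enumerate_class_distribution",
    "cohort_from_prevalence_counts",
    "cohort_from_outcome_counts",
]

_SLAB_THICKNESS_MM = 8.0
_BOX_HALF_MM = 4.0
_CLEARANCE_MM = 5.0  # tumour-to-box gap for non-involved regions
_MARGIN_MM = 3.0


@dataclass(frozen=True)
class PhantomSpec:
    """Commanded geometry of one phantom subject.

    ``ventricle_gap_mm`` is the gap between the tumour surface and the
    ventricle slab face (negative values command overlap). ``grid_shape``
    of None auto-sizes the grid to contain everything with a margin.
    """

    semi_axes_mm: tuple[float, float, float] = (25.0, 15.0, 10.0)
    oedema_thickness_mm: float = 15.0
    ventricle_gap_mm: float = 12.0
    callosum_overlap: bool = False
    eloquent_overlap: bool = False
    span_midline: bool = False
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_shape: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(s > 0 for s in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")
        if not all(s > 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.oedema_thickness_mm < 0:
            raise ValueError("oedema thickness must be >= 0")
        # bilaterality needs at least one voxel centre on each side
        if self.span_midline and self.semi_axes_mm[0] <= self.spacing[0]:
            raise ValueError("span_midline requires semi_axes_mm[0] > spacing[0]")

    @property
    def ground_truth(self) -> TumorFeatures:
        """Features implied analytically by the commanded geometry."""
        return TumorFeatures(
            ventricle_distance_mm=max(self.ventricle_gap_mm, 0.0),
            corpus_callosum_involved=self.callosum_overlap,
            bilateral=self.span_midline,
            eloquent_involved=self.eloquent_overlap,
            max_diameter_mm=2.0 * max(self.semi_axes_mm),
            oedema_extension_mm=self.oedema_thickness_mm,
        )


@dataclass(frozen=True)
class Phantom:
    tumour: MaskVolume
    oedema: MaskVolume
    atlas: RegionAtlas
    ground_truth: TumorFeatures
    spec: PhantomSpec = field(repr=False, default=None)


def _required_bounds(spec: PhantomSpec, centre: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b, c = spec.semi_axes_mm
    th = spec.oedema_thickness_mm
    lo = centre - np.array([a, b, c]) - th - _MARGIN_MM
    hi = centre + np.array([a, b, c]) + th + _MARGIN_MM
    # ventricle slab sits below the tumour along y
    slab_top = centre[1] - b - spec.ventricle_gap_mm
    lo[1] = min(lo[1], slab_top - _SLAB_THICKNESS_MM - _MARGIN_MM)
    # non-overlapping region boxes sit beyond the tumour along +y / +z
    hi[1] = max(hi[1], centre[1] + b + _CLEARANCE_MM + 2 * _BOX_HALF_MM + _MARGIN_MM)
    hi[2] = max(hi[2], centre[2] + c + _CLEARANCE_MM + 2 * _BOX_HALF_MM + _MARGIN_MM)
    if spec.span_midline:
        lo[0] = min(lo[0], -_MARGIN_MM)
        hi[0] = max(hi[0], _MARGIN_MM)
    return lo, hi


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterise a phantom subject and return masks, atlas and ground truth.

    The midsagittal plane is x = 0 of the scanner frame; voxel centres are
    laid on half-spacing offsets so no centre falls exactly on the plane.
    """
    sp = np.asarray(spec.spacing, dtype=float)
    a, b, c = spec.semi_axes_mm
    # tumour centre: on the midline when spanning, otherwise fully right of it
    cx = 0.0 if spec.span_midline else a + spec.oedema_thickness_mm + 2 * _MARGIN_MM
    centre = np.array([cx, 0.0, 0.0])
    lo, hi = _required_bounds(spec, centre)
    # half-spacing origin offset keeps voxel centres off the x=0 plane
    origin = np.floor(lo / sp) * sp - 0.5 * sp
    if spec.grid_shape is None:
        shape = tuple(int(math.ceil((hi[i] - origin[i]) / sp[i])) + 1 for i in range(3))
    else:
        shape = tuple(spec.grid_shape)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(sp)
    affine[:3, 3] = origin
    ext_hi = origin + (np.array(shape) - 1) * sp
    if (origin > lo + 1e-9).any() or (ext_hi < hi - 1e-9).any():
        raise ValueError(
            f"grid {shape} at spacing {tuple(sp)} cannot contain the phantom "
            f"(needs mm extent {lo} .. {hi})"
        )

    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij", sparse=True)
    X = origin[0] + ii * sp[0]
    Y = origin[1] + jj * sp[1]
    Z = origin[2] + kk * sp[2]

    tum = ((X - centre[0]) / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    tumour = MaskVolume(tum, affine)
    if tumour.is_empty:
        raise ValueError("tumour ellipsoid rasterised to an empty mask")

    if spec.oedema_thickness_mm > 0:
        from scipy.ndimage import distance_transform_edt

        dist = distance_transform_edt(~tum, sampling=sp)
        oedema = MaskVolume((dist > 0) & (dist <= spec.oedema_thickness_mm), affine)
    else:
        oedema = MaskVolume(np.zeros(shape, dtype=bool), affine)

    # snap the slab face onto the voxel-centre lattice so the commanded gap
    # is realised between centres to within half a voxel
    slab_top = centre[1] - b - spec.ventricle_gap_mm
    slab_top = origin[1] + round((slab_top - origin[1]) / sp[1]) * sp[1]
    vent = (Y <= slab_top + 1e-9) & (Y >= slab_top - _SLAB_THICKNESS_MM) & np.ones(shape, bool)
    if not vent.any():
        raise ValueError("ventricle slab fell outside the grid")

    def box(center_mm: np.ndarray) -> np.ndarray:
        return (
            (np.abs(X - center_mm[0]) <= _BOX_HALF_MM)
            & (np.abs(Y - center_mm[1]) <= _BOX_HALF_MM)
            & (np.abs(Z - center_mm[2]) <= _BOX_HALF_MM)
        )

    cc_centre = (
        centre
        if spec.callosum_overlap
        else centre + np.array([0.0, b + _CLEARANCE_MM + _BOX_HALF_MM, 0.0])
    )
    el_centre = (
        centre
        if spec.eloquent_overlap
        else centre + np.array([0.0, 0.0, c + _CLEARANCE_MM + _BOX_HALF_MM])
    )
    callosum = box(cc_centre)
    eloquent = box(el_centre)
    for name, region, want in (("callosum", callosum, spec.callosum_overlap),
                               ("eloquent", eloquent, spec.eloquent_overlap)):
        if not region.any():
            raise ValueError(f"{name} box fell outside the grid")
        if bool((region & tum).any()) != want:
            raise ValueError(f"{name} box overlap does not match the commanded value")

    atlas = RegionAtlas(
        ventricles=MaskVolume(vent, affine),
        corpus_callosum=MaskVolume(callosum, affine),
        eloquent=MaskVolume(eloquent, affine),
        midline=Plane.midsagittal(),
    )
    return Phantom(tumour=tumour, oedema=oedema, atlas=atlas,
                   ground_truth=spec.ground_truth, spec=spec)


def random_phantom_spec(rng: np.random.Generator, spacing=(1.0, 1.0, 1.0)) -> PhantomSpec:
    """Draw a random but always-valid phantom spec (for property suites)."""
    semi = (
        float(rng.uniform(8, 24)),
        float(rng.uniform(6, 18)),
        float(rng.uniform(5, 14)),
    )
    gap = float(rng.uniform(-5, 18)) if rng.random() < 0.8 else 0.0
    thickness = float(rng.uniform(4, 16)) if rng.random() < 0.8 else 0.0
    return PhantomSpec(
        semi_axes_mm=semi,
        oedema_thickness_mm=thickness,
        ventricle_gap_mm=gap,
        callosum_overlap=bool(rng.random() < 0.5),
        eloquent_overlap=bool(rng.random() < 0.5),
        span_midline=bool(rng.random() < 0.5),
        spacing=tuple(spacing),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: marginal feature prevalences of the 88-patient validation cohort
DEFAULT_PREVALENCES = (68 / 88, 29 / 88, 38 / 88, 62 / 88, 61 / 88)
#: complete-resection probability per complexity class (7/14, 7/45, 1/29)
DEFAULT_RESECTION = {"low": 7 / 14, "moderate": 7 / 45, "high": 1 / 29}
#: major-complication probability per complexity class (0/14, 1/45, 2/29)
DEFAULT_COMPLICATION = {"low": 0 / 14, "moderate": 1 / 45, "high": 2 / 29}

_MAJOR_CLAVIEN = np.array(["3b", "4a", "4b", "5"])


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the cohort generator; defaults are the study's rates."""

    n: int = 88
    feature_prevalences: tuple[float, ...] = DEFAULT_PREVALENCES
    resection_prob_by_class: dict = field(default_factory=lambda: dict(DEFAULT_RESECTION))
    complication_prob_by_class: dict = field(default_factory=lambda: dict(DEFAULT_COMPLICATION))
    dependence: np.ndarray | None = None  # latent Gaussian correlation, 5x5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        p = np.asarray(self.feature_prevalences, dtype=float)
        if p.shape != (5,) or (p < 0).any() or (p > 1).any():
            raise ValueError("feature_prevalences must be five probabilities in [0,1]")
        for d in (self.resection_prob_by_class, self.complication_prob_by_class):
            if set(d) != {"low", "moderate", "high"}:
                raise ValueError("class-conditional probabilities need keys low/moderate/high")
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ValueError("probabilities must lie in [0,1]")
        if self.dependence is not None:
            m = np.asarray(self.dependence, dtype=float)
            if m.shape != (5, 5) or not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1):
                raise ValueError("dependence must be a symmetric 5x5 matrix with unit diagonal")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError("dependence matrix must be positive semi-definite")
            object.__setattr__(self, "dependence", m)


def _draw_flags(params: CohortSimParams, rng: np.random.Generator) -> np.ndarray:
    p = np.asarray(params.feature_prevalences)
    if params.dependence is None:
        return rng.random((params.n, 5)) < p
    # Gaussian copula: threshold correlated latent normals at the marginal quantile
    latent = rng.multivariate_normal(np.zeros(5), params.dependence, size=params.n)
    return latent < stats.norm.ppf(p)


def _grade_flags(flags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    score = flags.sum(axis=1).astype(int)
    return score, classify_scores(score)


def simulate_cohort(params: CohortSimParams | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate a validation cohort in the standard cohort-CSV schema.

    Per patient: five binary flags at the commanded prevalences, the
    resulting score and complexity class, and class-conditional complete
    resection and major complication; a fired complication is assigned a
    Clavien-Dindo grade drawn uniformly from {3b, 4a, 4b, 5}, otherwise
    'none'. Bit-reproducible for a fixed seed.
    """
    params = params or CohortSimParams()
    rng = np.random.default_rng(seed)
    flags = _draw_flags(params, rng).astype(int)
    score, complexity = _grade_flags(flags)
    p_res = np.array([params.resection_prob_by_class[c] for c in complexity])
    p_cmp = np.array([params.complication_prob_by_class[c] for c in complexity])
    resected = rng.random(params.n) < p_res
    complic = rng.random(params.n) < p_cmp
    clavien = np.where(complic, rng.choice(_MAJOR_CLAVIEN, size=params.n), "none")
    df = pd.DataFrame(flags, columns=list(FLAG_NAMES))
    df.insert(0, "subject_id", [f"S{i + 1:05d}" for i in range(params.n)])
    df["score"] = score
    df["complexity"] = complexity
    df["complete_resection"] = resected.astype(int)
    df["clavien_dindo"] = clavien
    df.attrs["provenance"] = {"source": "simulated", "seed": seed, "n": params.n}
    return df


def simulate_second_rater(cohort: pd.DataFrame, epsilon: float, seed: int | None = None) -> pd.DataFrame:
    """Attach a noisy second rater: each flag flips independently with
    probability ``epsilon`` (0 <= epsilon <= 0.5); the second rater's score
    and class are recomputed from the flipped flags."""
    if not 0 <= epsilon <= 0.5:
        raise ValueError("flip probability must lie in [0, 0.5]")
    missing = [f for f in FLAG_NAMES if f not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks flag columns: {missing}")
    rng = np.random.default_rng(seed)
    flags = cohort[list(FLAG_NAMES)].to_numpy(dtype=int)
    flips = rng.random(flags.shape) < epsilon
    flags2 = flags ^ flips
    score2, class2 = _grade_flags(flags2)
    out = cohort.copy()
    out["score_rater2"] = score2
    out["grade_rater2"] = class2
    return out


def simulated_kappa(epsilon: float, n: int = 10_000, seed: int | None = None,
                    params: CohortSimParams | None = None, scale: str = "class") -> float:
    """Agreement produced by flag-level noise ``epsilon`` on a fresh cohort."""
    base = params or CohortSimParams()
    cohort = simulate_cohort(CohortSimParams(
        n=n,
        feature_prevalences=base.feature_prevalences,
        resection_prob_by_class=base.resection_prob_by_class,
        complication_prob_by_class=base.complication_prob_by_class,
        dependence=base.dependence,
    ), seed=seed)
    rated = simulate_second_rater(cohort, epsilon, seed=None if seed is None else seed + 1)
    return cohens_kappa(rater_crosstab(rated, scale=scale)).kappa


def calibrate_rater_noise(
    target_kappa: float,
    n: int = 10_000,
    seed: int | None = None,
    tol: float = 1e-3,
    max_iter: int = 25,
    params: CohortSimParams | None = None,
) -> tuple[float, float]:
    """Find the flip probability whose simulated class-scale kappa matches a
    target, by bisection on [0, 0.5] (kappa is monotone decreasing in the
    flip probability). Returns ``(epsilon, achieved_kappa)``."""
    lo, hi = 0.0, 0.5
    k_lo = simulated_kappa(lo, n=n, seed=seed, params=params)
    k_hi = simulated_kappa(hi, n=n, seed=seed, params=params)
    if not k_hi <= target_kappa <= k_lo:
        raise ValueError(
            f"target kappa {target_kappa} outside achievable range [{k_hi:.3f}, {k_lo:.3f}]"
        )
    eps, k = 0.25, np.nan
    for _ in range(max_iter):
        eps = 0.5 * (lo + hi)
        k = simulated_kappa(eps, n=n, seed=seed, params=params)
        if abs(hi - lo) < tol:
            break
        if k > target_kappa:
            lo = eps
        else:
            hi = eps
    return eps, float(k)


def enumerate_class_distribution(prevalences=DEFAULT_PREVALENCES) -> dict[str, float]:
    """Exact class distribution of independent flags, by enumerating all
    2^5 flag outcomes weighted by their Bernoulli probabilities."""
    p = np.asarray(prevalences, dtype=float)
    probs = {"low": 0.0, "moderate": 0.0, "high": 0.0}
    for code in range(32):
        bits = np.array([(code >> i) & 1 for i in range(5)])
        w = float(np.prod(np.where(bits, p, 1 - p)))
        score = int(bits.sum())
        probs[str(classify_scores([score])[0])] += w
    return probs


# ---------------------------------------------------------------------------
# reconstruction of published summary tables as explicit cohorts
# ---------------------------------------------------------------------------

def cohort_from_prevalence_counts(n: int = 88, counts=(68, 29, 38, 62, 61)) -> pd.DataFrame:
    """Deterministic cohort whose per-feature marginal counts are exact.

    Each feature is set to 1 for its first ``count`` patients, so only the
    marginals (not the joint structure) reproduce a published prevalence
    table. Intended for prevalence summaries, not outcome analyses.
    """
    if any(c > n or c < 0 for c in counts):
        raise ValueError("counts must lie in [0, n]")
    flags = np.zeros((n, 5), dtype=int)
    for j, c in enumerate(counts):
        flags[:c, j] = 1
    score, complexity = _grade_flags(flags)
    df = pd.DataFrame(flags, columns=list(FLAG_NAMES))
    df.insert(0, "subject_id", [f"R{i + 1:04d}" for i in range(n)])
    df["score"] = score
    df["complexity"] = complexity
    df.attrs["provenance"] = {"source": "reconstructed-prevalence-table"}
    return df


def cohort_from_outcome_counts(
    class_sizes={"low": 14, "moderate": 45, "high": 29},
    resection_counts={"low": 7, "moderate": 7, "high": 1},
    complication_counts={"low": 0, "moderate": 1, "high": 2},
) -> pd.DataFrame:
    """Deterministic cohort realising a published grade-by-outcome table.

    Flags are assigned a representative pattern consistent with each class
    (score 1, 3 and 5 for low, moderate, high); complications are recorded
    as Clavien-Dindo 3b. Exactly reproduces the commanded counts.
    """
    rows = []
    rep_score = {"low": 1, "moderate": 3, "high": 5}
    i = 0
    for cls in ("low", "moderate", "high"):
        size = class_sizes[cls]
        if resection_counts[cls] > size or complication_counts[cls] > size:
            raise ValueError(f"outcome counts exceed class size for {cls!r}")
        flags = [1] * rep_score[cls] + [0] * (5 - rep_score[cls])
        for j in range(size):
            rows.append(
                {
                    "subject_id": f"T{i + 1:04d}",
                    **dict(zip(FLAG_NAMES, flags)),
                    "score": rep_score[cls],
                    "complexity": cls,
                    "complete_resection": int(j < resection_counts[cls]),
                    "clavien_dindo": "3b" if j < complication_counts[cls] else "none",
                }
            )
            i += 1
    df = pd.DataFrame(rows)
    df.attrs["provenance"] = {"source": "reconstructed-outcome-table"}
    return df
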