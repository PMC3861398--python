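"""Seeded synthetic data: core images with known nest ground truth, and
survival cohorts with known feature-hazard structure.

Two generators make every downstream stage testable without any download:

* :func:`generate_core_image` renders non-overlapping DAB-brown nest blobs
  (circles, ellipses or sinusoidally perturbed "blobs") on a pale
  hematoxylin-like background, with optional additive Gaussian noise and
  unstained vessel/nerve-like distractor shapes.  The returned
  :class:`GroundTruth` carries the exact label mask plus analytic areas and
  perimeters, which serve as the oracle for segmentation and feature tests.

* :func:`generate_cohort` draws per-patient integer grades, sums them into a
  score, and samples exponential event times whose hazard is log-linear in
  the score and in any configured clinical covariates, with independent
  exponential censoring and administrative censoring at the follow-up
  horizon.

* :func:`generate_study` ties both together into the full study bundle
  (default 202 patients x 2 cores): a per-patient latent aggressiveness
  u ~ U(0, 1) drives both the nest morphology (more, blobbier nests for
  higher u) and the hazard, so the downstream pipeline can rediscover the
  morphology-survival link from the images alone.

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call; identical spec and seed give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import CoreImage

__all__ = [
    "SyntheticImageSpec",
    "GroundTruth",
    "SyntheticCohortSpec",
    "StudySpec",
    "PlacementError",
    "generate_core_image",
    "generate_cohort",
    "generate_study",
    "write_core_image",
]

# Default stain colors: DAB-brown foreground, pale hematoxylin background.
DEFAULT_FG_RGB = (120, 70, 40)
DEFAULT_BG_RGB = (225, 220, 235)
# Blue-grey tint for distractor shapes (vessels/nerves): hematoxylin-like,
# with a DAB deconvolution response at or below the background's, so
# distractors are never mistaken for stained nests.
_DISTRACTOR_SHIFT = (-35, -25, -5)

_MAX_PLACEMENT_ATTEMPTS = 10_000
_MIN_GAP_PX = 4.0  # clearance between shapes so opening never has to split them


class PlacementError(RuntimeError):
    """Raised when non-overlapping shape placement fails; nests are never
    silently dropped."""


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of one synthetic core image.

    ``blob_irregularity`` is the total relative amplitude of the low-order
    sinusoidal radial perturbation of the ``blob`` family; 0 reduces blobs
    to circles, larger values lower circularity.  Shapes are placed fully
    inside the raster without overlap by rejection sampling.
    """

    width_px: int = 512
    height_px: int = 512
    n_nests: int = 12
    shape_family: str = "blob"  # {"circle", "ellipse", "blob"}
    size_range_px: tuple[float, float] = (8.0, 28.0)
    stain_fg_rgb: tuple[int, int, int] = DEFAULT_FG_RGB
    stain_bg_rgb: tuple[int, int, int] = DEFAULT_BG_RGB
    noise_sd: float = 6.0
    n_distractors: int = 3
    blob_irregularity: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.width_px < 32 or self.height_px < 32:
            raise ValueError("raster must be at least 32 x 32")
        if self.n_nests < 0 or self.n_distractors < 0:
            raise ValueError("counts must be non-negative")
        if self.shape_family not in ("circle", "ellipse", "blob"):
            raise ValueError(f"unknown shape_family {self.shape_family!r}")
        lo, hi = self.size_range_px
        if lo < 2 or hi < lo:
            raise ValueError("size_range_px must satisfy 2 <= min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.blob_irregularity < 0.5:
            raise ValueError("blob_irregularity must be in [0, 0.5)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticImageSpec":
        d = json.loads(text)
        for k in ("size_range_px", "stain_fg_rgb", "stain_bg_rgb"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact geometry of the rendered nests (test oracle)."""

    label_mask: np.ndarray  # uint16, 0 background, k = nest k
    areas: np.ndarray  # analytic area per nest
    perimeters: np.ndarray  # analytic perimeter per nest
    centroids: np.ndarray  # (n, 2) (row, col)

    @property
    def n_nests(self) -> int:
        return len(self.areas)


# ---------------------------------------------------------------------------
# shape sampling and rasterization
# ---------------------------------------------------------------------------

@dataclass
class _Shape:
    family: str
    cy: float
    cx: float
    r: float  # base radius
    aspect: float = 1.0  # ellipse minor = r / aspect
    theta: float = 0.0  # orientation (ellipse)
    amps: tuple[float, ...] = ()
    ks: tuple[int, ...] = ()
    phases: tuple[float, ...] = ()

    @property
    def bound(self) -> float:
        if self.family == "blob":
            return self.r * (1.0 + sum(abs(a) for a in self.amps))
        return self.r

    def rasterize(self, height: int, width: int) -> np.ndarray:
        b = int(np.ceil(self.bound)) + 2
        r0 = max(int(np.floor(self.cy)) - b, 0)
        r1 = min(int(np.ceil(self.cy)) + b + 1, height)
        c0 = max(int(np.floor(self.cx)) - b, 0)
        c1 = min(int(np.ceil(self.cx)) + b + 1, width)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dy = yy - self.cy
        dx = xx - self.cx
        if self.family == "circle":
            inside = dy * dy + dx * dx <= self.r * self.r
        elif self.family == "ellipse":
            ct, st = np.cos(self.theta), np.sin(self.theta)
            u = dx * ct + dy * st
            v = -dx * st + dy * ct
            a, bb = self.r, self.r / self.aspect
            inside = (u / a) ** 2 + (v / bb) ** 2 <= 1.0
        else:  # blob: star-convex radial perturbation
            d = np.hypot(dx, dy)
            ang = np.arctan2(dy, dx)
            rad = self.r * (1.0 + sum(
                a * np.sin(k * ang + p)
                for a, k, p in zip(self.amps, self.ks, self.phases)))
            inside = d <= rad
        out = np.zeros((height, width), bool)
        out[r0:r1, c0:c1] = inside
        return out

    def analytic_area_perimeter(self) -> tuple[float, float]:
        if self.family == "circle":
            return np.pi * self.r ** 2, 2.0 * np.pi * self.r
        if self.family == "ellipse":
            a, b = self.r, self.r / self.aspect
            area = np.pi * a * b
            # Ramanujan's approximation
            per = np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b)))
            return area, per
        # blob: dense polygon from the analytic radial function
        th = np.linspace(0.0, 2.0 * np.pi, 4097)
        rad = self.r * (1.0 + sum(
            a * np.sin(k * th + p)
            for a, k, p in zip(self.amps, self.ks, self.phases)))
        x = rad * np.cos(th)
        y = rad * np.sin(th)
        area = 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
        per = float(np.sum(np.hypot(np.diff(x), np.diff(y))))
        return float(area), per


def _sample_shape(rng: np.random.Generator, spec: SyntheticImageSpec,
                  cy: float, cx: float) -> _Shape:
    lo, hi = spec.size_range_px
    r = float(rng.uniform(lo, hi))
    if spec.shape_family == "circle":
        return _Shape("circle", cy, cx, r)
    if spec.shape_family == "ellipse":
        return _Shape("ellipse", cy, cx, r,
                      aspect=float(rng.uniform(1.2, 1.8)),
                      theta=float(rng.uniform(0.0, np.pi)))
    total = spec.blob_irregularity
    w = rng.dirichlet([1.0, 1.0])
    amps = tuple(float(total * wi) for wi in w)
    ks = tuple(int(k) for k in rng.integers(2, 7, size=2))
    phases = tuple(float(p) for p in rng.uniform(0.0, 2.0 * np.pi, size=2))
    return _Shape("blob", cy, cx, r, amps=amps, ks=ks, phases=phases)


def _place_shapes(rng: np.random.Generator, spec: SyntheticImageSpec,
                  n: int, occupied: list[_Shape], kind: str) -> list[_Shape]:
    """Rejection-sample n non-overlapping shapes fully inside the raster."""
    placed: list[_Shape] = []
    attempts = 0
    H, W = spec.height_px, spec.width_px
    while len(placed) < n:
        if attempts >= _MAX_PLACEMENT_ATTEMPTS:
            raise PlacementError(
                f"could not place {kind} {len(placed) + 1}/{n} after "
                f"{attempts} attempts: raster too crowded"
            )
        attempts += 1
        lo, hi = spec.size_range_px
        margin = hi * (1.5 if spec.shape_family == "blob" else 1.0) + 3
        if 2 * margin >= min(H, W):
            margin = min(H, W) / 2.0 - 1
        cy = float(rng.uniform(margin, H - margin))
        cx = float(rng.uniform(margin, W - margin))
        cand = _sample_shape(rng, spec, cy, cx)
        b = cand.bound
        if not (b + 1 <= cy <= H - b - 2 and b + 1 <= cx <= W - b - 2):
            continue
        ok = True
        for other in occupied + placed:
            d = np.hypot(cand.cy - other.cy, cand.cx - other.cx)
            if d < cand.bound + other.bound + _MIN_GAP_PX:
                ok = False
                break
        if ok:
            placed.append(cand)
    return placed


def generate_core_image(spec: SyntheticImageSpec) -> tuple[CoreImage, GroundTruth]:
    """Render one synthetic core image plus its exact ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px

    nests = _place_shapes(rng, spec, spec.n_nests, [], "nest")
    distractors = _place_shapes(rng, spec, spec.n_distractors, nests, "distractor")

    label = np.zeros((H, W), dtype=np.uint16)
    img = np.empty((H, W, 3), dtype=float)
    img[:] = spec.stain_bg_rgb
    dist_color = np.clip(
        np.asarray(spec.stain_bg_rgb, float) + _DISTRACTOR_SHIFT, 0, 255)
    for sh in distractors:
        # thin, elongated unstained structures (vessel/nerve-like)
        sh.family = "ellipse"
        sh.aspect = float(rng.uniform(3.0, 5.0))
        sh.theta = float(rng.uniform(0.0, np.pi))
        img[sh.rasterize(H, W)] = dist_color
    areas, perims, cents = [], [], []
    for k, sh in enumerate(nests, start=1):
        m = sh.rasterize(H, W)
        label[m] = k
        img[m] = spec.stain_fg_rgb
        a, p = sh.analytic_area_perimeter()
        areas.append(a)
        perims.append(p)
        cents.append((sh.cy, sh.cx))
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        label_mask=label,
        areas=np.asarray(areas, float),
        perimeters=np.asarray(perims, float),
        centroids=np.asarray(cents, float).reshape(-1, 2),
    )
    return CoreImage(pixels=pixels, core_id=f"seed{spec.seed}"), truth


def write_core_image(path: str | Path, image: CoreImage) -> None:
    """Write an 8-bit RGB core image as PNG or BMP (by extension)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), image.pixels)


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

# grade distribution for directly drawn cohorts: most patients mid/low grade
_GRADE_PROBS = (0.4, 0.4, 0.2)

# default generators for clinical covariates (value set, probabilities),
# loosely shaped like a breast-carcinoma TMA cohort
_COVARIATE_CATALOG: dict[str, tuple[tuple[int, ...], tuple[float, ...]]] = {
    "t_stage": ((1, 2, 3), (0.13, 0.69, 0.18)),
    "n_status": ((0, 1), (0.44, 0.56)),
    "histological_grade": ((1, 2, 3), (0.14, 0.62, 0.24)),
    "hormone_receptor": ((0, 1), (0.4, 0.6)),
    "her2": ((0, 1), (0.7, 0.3)),
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a directly drawn synthetic survival cohort.

    Event times are exponential with per-patient hazard
    ``baseline_hazard * exp(log_hr_per_score_unit * score + sum(beta_c * x_c))``;
    censoring is the minimum of an independent exponential time at
    ``censoring_rate`` and the administrative ``followup_horizon`` (months).
    """

    n_patients: int = 202
    baseline_hazard: float = 0.0017
    log_hr_per_score_unit: float = 0.30
    censoring_rate: float = 0.003
    followup_horizon: float = 60.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValueError("rates must be positive")
        if self.followup_horizon <= 0:
            raise ValueError("followup_horizon must be positive")
        for k in self.covariate_effects:
            if k not in _COVARIATE_CATALOG:
                raise ValueError(f"unknown covariate {k!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticCohortSpec":
        return cls(**json.loads(text))


def _draw_covariates(rng: np.random.Generator, names: Sequence[str],
                     n: int) -> dict[str, np.ndarray]:
    out = {}
    for name in names:
        vals, probs = _COVARIATE_CATALOG[name]
        out[name] = rng.choice(vals, size=n, p=probs)
    return out


def generate_cohort(cspec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table with known score-hazard structure.

    Columns: ``patient_id``, three per-parameter grades (1/2/3), their sum
    ``score``, any configured covariates, observed ``time`` (months) and
    ``event`` (1 = event observed before censoring and horizon).
    """
    cspec.validate()
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_patients
    grades = rng.choice((1, 2, 3), size=(n, 3), p=_GRADE_PROBS)
    score = grades.sum(axis=1)
    covs = _draw_covariates(rng, list(cspec.covariate_effects), n)
    log_hazard = np.log(cspec.baseline_hazard) + cspec.log_hr_per_score_unit * score
    for name, beta in cspec.covariate_effects.items():
        log_hazard = log_hazard + beta * covs[name]
    event_time = rng.exponential(1.0 / np.exp(log_hazard))
    cens_time = rng.exponential(1.0 / cspec.censoring_rate, size=n)
    observed = np.minimum.reduce([event_time, cens_time,
                                  np.full(n, cspec.followup_horizon)])
    event = (event_time <= cens_time) & (event_time <= cspec.followup_horizon)
    df = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(1, n + 1)],
        "grade_a": grades[:, 0],
        "grade_b": grades[:, 1],
        "grade_c": grades[:, 2],
        "score": score,
        "time": observed,
        "event": event.astype(int),
    })
    for name in covs:
        df[name] = covs[name]
    return df


# ---------------------------------------------------------------------------
# full study bundle: images wired to survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySpec:
    """The default synthetic study: per-patient latent aggressiveness drives
    both nest morphology and hazard.

    For patient latent ``u ~ U(0, 1)``: each core gets
    ``n_nests ~ 5 + Binomial(25, u)`` blob nests; with rising u the nests
    become smaller (size range scaled by 1.3 - 0.6 u) and rounder (radial
    irregularity 0.35 - 0.30 u).  An aggressive core is therefore a field
    of many small round nests — nest number, circularity and total
    perimeter rise with u while the average-size parameters (average area,
    average perimeter, total-area/total-perimeter, average area/perimeter)
    fall, matching the direction structure of the prognostic sets.  The
    event hazard is
    ``baseline_hazard * exp(latent_log_hr * (u - 0.5) + sum(beta_c x_c))``.
    Defaults give roughly half the cohort an event within the 60-month
    horizon.
    """

    n_patients: int = 202
    cores_per_patient: int = 2
    width_px: int = 512
    height_px: int = 512
    size_range_px: tuple[float, float] = (8.0, 26.0)
    noise_sd: float = 6.0
    n_distractors: int = 3
    baseline_hazard: float = 0.0115
    latent_log_hr: float = 1.8
    censoring_rate: float = 0.004
    followup_horizon: float = 60.0
    covariate_effects: dict[str, float] = field(default_factory=lambda: {
        "t_stage": 0.30,
        "n_status": 0.35,
        "histological_grade": 0.45,
        "hormone_receptor": -0.40,
        "her2": 0.10,
    })
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.cores_per_patient < 1:
            raise ValueError("cores_per_patient must be >= 1")
        for k in self.covariate_effects:
            if k not in _COVARIATE_CATALOG:
                raise ValueError(f"unknown covariate {k!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudySpec":
        d = json.loads(text)
        if "size_range_px" in d:
            d["size_range_px"] = tuple(d["size_range_px"])
        return cls(**d)


def generate_study(sspec: StudySpec):
    """Generate the full synthetic study bundle.

    Yields per-core ``(CoreImage, GroundTruth)`` lazily via the returned
    iterator factory, plus the clinical table.  Returns ``(cores, clinical)``
    where ``cores`` is a list of ``(core_id, SyntheticImageSpec)`` to render
    on demand with :func:`generate_core_image`, and ``clinical`` is a
    DataFrame with survival and covariates per patient (including the latent
    ``u`` for diagnostics; downstream stages ignore it).
    """
    sspec.validate()
    rng = np.random.default_rng(sspec.seed)
    n = sspec.n_patients
    u = rng.uniform(0.0, 1.0, size=n)
    covs = _draw_covariates(rng, list(sspec.covariate_effects), n)
    log_hazard = np.log(sspec.baseline_hazard) + sspec.latent_log_hr * (u - 0.5)
    for name, beta in sspec.covariate_effects.items():
        x = covs[name].astype(float)
        log_hazard = log_hazard + beta * (x - x.mean())
    event_time = rng.exponential(1.0 / np.exp(log_hazard))
    cens_time = rng.exponential(1.0 / sspec.censoring_rate, size=n)
    observed = np.minimum.reduce([event_time, cens_time,
                                  np.full(n, sspec.followup_horizon)])
    event = (event_time <= cens_time) & (event_time <= sspec.followup_horizon)

    clinical = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(1, n + 1)],
        "time": observed,
        "event": event.astype(int),
        "latent_u": u,
    })
    for name in covs:
        clinical[name] = covs[name]

    cores: list[tuple[str, str, SyntheticImageSpec]] = []
    for i in range(n):
        pid = f"P{i + 1:04d}"
        n_extra = rng.binomial(25, u[i], size=sspec.cores_per_patient)
        core_seeds = rng.integers(0, 2**31 - 1, size=sspec.cores_per_patient)
        size_scale = 1.3 - 0.6 * u[i]
        lo, hi = sspec.size_range_px
        for c in range(sspec.cores_per_patient):
            ispec = SyntheticImageSpec(
                width_px=sspec.width_px,
                height_px=sspec.height_px,
                n_nests=int(5 + n_extra[c]),
                shape_family="blob",
                size_range_px=(lo * size_scale, hi * size_scale),
                noise_sd=sspec.noise_sd,
                n_distractors=sspec.n_distractors,
                blob_irregularity=float(0.35 - 0.30 * u[i]),
                seed=int(core_seeds[c]),
            )
            cores.append((f"{pid}_core{c + 1}", pid, ispec))
    return cores, clinical
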