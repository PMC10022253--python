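"""Synthetic data: capsule phantoms, patient cohorts, and rater tables.

The phantoms stand in for CT-arthrogram acquisitions: a bright, contrast-like
shape on a noisy background, with the three scapular landmarks placed so that
the derived scapular frame has a prescribed origin and axes, and with
analytically known total and quadrant volumes.  The cohort simulator draws a
Gaussian-copula multivariate sample whose margins default to the published
means and SDs of the four quadrant volumes and the four passive motions, with
a configurable cross-correlation structure; the rater simulator produces
ratings with a variance-component structure whose implied ICC is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geometry import ScapularFrame, ScapularLandmarks, build_frame
from .image import SegmentationMask, VolumeImage
from .volumetry import QuadrantVolumes

__all__ = ["PhantomSpec", "Phantom", "make_phantom",
           "CohortSimConfig", "simulate_cohort", "default_correlation_matrix",
           "RaterSimConfig", "simulate_raters", "validate_injection_protocol",
           "PUBLISHED_COHORT_MARGINS", "VOL_TJ_REFERENCE", "INJECTION_COMPONENTS_ML",
           "SIM_VARIABLES"]

# ---------------------------------------------------------------------------
# published cohort margins (mean, SD) used as simulation defaults
# ---------------------------------------------------------------------------

PUBLISHED_COHORT_MARGINS: dict[str, tuple[float, float]] = {
    "Vol.AIQ": (2.17, 1.10),
    "Vol.ASQ": (2.28, 0.85),
    "Vol.PSQ": (2.60, 1.23),
    "Vol.PIQ": (3.14, 1.34),
    "Sc": (159.71, 25.23),
    "ERs": (47.21, 17.35),
    "ER90": (76.58, 16.14),
    "IRb": (7.07, 3.67),
}

#: published total joint volume (mean, SD); the simulator reports, but does not
#: enforce, these moments — the total is always the sum of the four quadrants
VOL_TJ_REFERENCE = (10.38, 3.14)

#: arthrography injectate components in mL: saline, iopromide contrast, mepivacaine
INJECTION_COMPONENTS_ML = (12.5, 6.0, 1.5)

#: total injectate used as the standardized-filling inclusion threshold
INJECTION_TOTAL_ML = 20.0

SIM_VARIABLES = ("Vol.AIQ", "Vol.ASQ", "Vol.PSQ", "Vol.PIQ", "Sc", "ERs", "ER90", "IRb")

# published quadrant-volume x motion correlations (motions x quadrants)
_CROSS_R = np.array([
    [0.26, 0.00, 0.24, 0.30],   # Sc
    [0.23, 0.09, 0.18, 0.16],   # ERs
    [0.25, 0.03, 0.29, 0.29],   # ER90
    [0.26, -0.07, 0.22, 0.18],  # IRb
])


def default_correlation_matrix(within_volumes: float = 0.3,
                               within_motions: float = 0.3) -> np.ndarray:
    """8x8 target correlation matrix over ``SIM_VARIABLES``.

    The volume x motion block carries the published pairwise correlations;
    within-block correlations (quadrant-quadrant and motion-motion) default
    to 0.3, a mild positive dependence consistent with compartments of one
    joint and motions of one shoulder.  The default is positive definite.
    """
    C = np.eye(8)
    C[:4, :4][~np.eye(4, dtype=bool)] = within_volumes
    C[4:, 4:][~np.eye(4, dtype=bool)] = within_motions
    C[4:, :4] = _CROSS_R
    C[:4, 4:] = _CROSS_R.T
    return C


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

_SHAPES = ("solid_sphere", "spherical_shell", "offset_sphere", "two_blob")


@dataclass
class PhantomSpec:
    """Geometry and imaging parameters of a synthetic capsule phantom.

    The shape is defined in scapular-frame coordinates (a, s, l) relative to
    the glenoid center; ``offset_mm`` shifts the primary sphere's center.
    Landmarks are placed so that :func:`~glenovol.geometry.build_frame`
    reproduces ``frame_origin`` / ``frame_axes`` exactly.
    """

    shape: str = "solid_sphere"
    radius_mm: float = 20.0
    inner_radius_mm: float = 0.0
    offset_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spacing_mm: float | tuple[float, float, float] = 1.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    contrast: float = 300.0
    background: float = 0.0
    noise_sd: float = 0.0
    side: str = "right"
    frame_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    # rows: a, s, l axes in LPS; default is the axis-aligned anatomical frame
    frame_axes: np.ndarray = field(default_factory=lambda: np.array(
        [[0.0, -1.0, 0.0], [0.0, 0.0, 1.0], [-1.0, 0.0, 0.0]]))
    blob2_center_mm: np.ndarray = field(default_factory=lambda: np.array([0.0, 45.0, 0.0]))
    blob2_radius_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ConfigError(f"unknown phantom shape {self.shape!r}; choose from {_SHAPES}")
        self.offset_mm = np.asarray(self.offset_mm, dtype=float)
        self.frame_origin = np.asarray(self.frame_origin, dtype=float)
        self.frame_axes = np.asarray(self.frame_axes, dtype=float)
        self.blob2_center_mm = np.asarray(self.blob2_center_mm, dtype=float)
        sp = np.asarray(self.spacing_mm, dtype=float)
        self.spacing_mm = np.full(3, float(sp)) if sp.ndim == 0 else sp
        if self.radius_mm <= self.inner_radius_mm or self.inner_radius_mm < 0:
            raise ConfigError("need outer radius > inner radius >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise SD must be >= 0")

    @property
    def mid_contrast(self) -> float:
        """Default region-growing threshold: halfway between background and contrast."""
        return 0.5 * (self.background + self.contrast)


@dataclass
class Phantom:
    """A generated phantom with its ground truth."""

    volume: VolumeImage
    mask: SegmentationMask
    landmarks: ScapularLandmarks
    frame: ScapularFrame
    analytic: QuadrantVolumes
    seed_point_mm: np.ndarray
    spec: PhantomSpec


def _landmarks_for_frame(origin: np.ndarray, axes: np.ndarray,
                         side: str) -> ScapularLandmarks:
    """Place the three fiducials so build_frame reproduces (origin, axes).

    The angulus inferior sits 80 mm inferior and 60 mm medial to the glenoid
    center, the trigonum scapulae 100 mm superior to the angulus along the
    medial border — schematic but scapula-scaled distances; all three lie in
    the plane normal to the anterior axis by construction.
    """
    a, s, l = axes
    medial = -l  # any in-plane offset works; the sign is cosmetic for the frame
    ai = origin + 60.0 * medial - 80.0 * s
    ts = ai + 100.0 * s
    return ScapularLandmarks(ai, ts, origin.copy(), side=side)


def _sphere_halves_ml(R: float, d: float) -> tuple[float, float]:
    """(positive-side, negative-side) volumes in mL of a radius-R sphere whose
    center sits at signed distance d from a cutting plane (|d| < R)."""
    h = R + d
    pos = np.pi * h * h * (3.0 * R - h) / 3.0
    tot = 4.0 / 3.0 * np.pi * R ** 3
    return pos / 1000.0, (tot - pos) / 1000.0


def _membership(spec: PhantomSpec, coords: np.ndarray) -> np.ndarray:
    """Shape membership for points given in frame coordinates, shape (..., 3)."""
    rel = coords - spec.offset_mm
    r2 = np.einsum("...i,...i->...", rel, rel)
    R2 = spec.radius_mm ** 2
    if spec.shape in ("solid_sphere", "offset_sphere"):
        return r2 <= R2
    if spec.shape == "spherical_shell":
        return (r2 <= R2) & (r2 > spec.inner_radius_mm ** 2)
    rel2 = coords - spec.blob2_center_mm
    in2 = np.einsum("...i,...i->...", rel2, rel2) <= spec.blob2_radius_mm ** 2
    return (r2 <= R2) | in2


def _analytic_quadrants(spec: PhantomSpec) -> QuadrantVolumes:
    R, r = spec.radius_mm, spec.inner_radius_mm
    da, ds = float(spec.offset_mm[0]), float(spec.offset_mm[1])
    sphere_ml = 4.0 / 3.0 * np.pi * R ** 3 / 1000.0
    shell_ml = sphere_ml - 4.0 / 3.0 * np.pi * r ** 3 / 1000.0

    if spec.shape == "spherical_shell" and da == 0.0 and ds == 0.0:
        q = shell_ml / 4.0
        return QuadrantVolumes(shell_ml, q, q, q, q)
    if spec.shape in ("solid_sphere", "offset_sphere"):
        if da == 0.0 and ds == 0.0:
            q = sphere_ml / 4.0
            return QuadrantVolumes(sphere_ml, q, q, q, q)
        if ds == 0.0 and abs(da) < R:
            ant, post = _sphere_halves_ml(R, da)
            return QuadrantVolumes(sphere_ml, ant / 2, ant / 2, post / 2, post / 2)
        if da == 0.0 and abs(ds) < R:
            sup, inf = _sphere_halves_ml(R, ds)
            return QuadrantVolumes(sphere_ml, inf / 2, sup / 2, sup / 2, inf / 2)
    return _brute_force_quadrants(spec)


def _brute_force_quadrants(spec: PhantomSpec, spacing: float = 0.25) -> QuadrantVolumes:
    """High-resolution voxel-count oracle for shapes with no closed form."""
    centers = [spec.offset_mm]
    radii = [spec.radius_mm]
    if spec.shape == "two_blob":
        centers.append(spec.blob2_center_mm)
        radii.append(spec.blob2_radius_mm)
    lo = np.min([c - rad for c, rad in zip(centers, radii)], axis=0) - spacing
    hi = np.max([c + rad for c, rad in zip(centers, radii)], axis=0) + spacing
    axes = [np.arange(lo[i] + spacing / 2, hi[i], spacing) for i in range(3)]
    counts = np.zeros(4)
    total = 0
    # slab-wise over the a axis to bound memory
    ss, ll = np.meshgrid(axes[1], axes[2], indexing="ij")
    for a_val in axes[0]:
        pts = np.stack([np.full(ss.shape, a_val), ss, ll], axis=-1)
        inside = _membership(spec, pts)
        total += int(inside.sum())
        # quadrant codes per the half-open clock convention
        aiq = inside & (a_val >= 0) & (ss < 0)
        asq = inside & (a_val > 0) & (ss >= 0)
        psq = inside & (a_val <= 0) & (ss >= 0) & ~((a_val < 0) & (ss == 0))
        piq = inside & (a_val < 0) & (ss <= 0)
        counts += [aiq.sum(), asq.sum(), psq.sum(), piq.sum()]
    vv_ml = spacing ** 3 / 1000.0
    return QuadrantVolumes(total * vv_ml, *(counts * vv_ml))


def make_phantom(spec: PhantomSpec, rng: np.random.Generator | int | None = None) -> Phantom:
    """Generate a capsule phantom with ground-truth mask and analytic volumes.

    The grid is centered on the glenoid center with an axis-aligned voxel
    lattice; the shape lives in scapular-frame coordinates.  The intensity
    volume is ``background + contrast * membership + N(0, noise_sd)`` with the
    noise drawn from ``rng``.  The ground-truth mask is exact voxel-center
    membership.  Analytic quadrant volumes use closed forms (sphere, shell,
    spherical caps) where symmetry permits and a 0.25 mm brute-force voxel
    count otherwise.
    """
    rng = np.random.default_rng(rng)
    frame = ScapularFrame(spec.frame_origin, *spec.frame_axes, side=spec.side)
    if frame.a_axis[1] >= 0 or frame.s_axis[2] <= 0:
        raise ConfigError("frame_axes must satisfy the anatomical sign conventions "
                          "(anterior axis with negative LPS-y, superior axis with positive z) "
                          "so the landmark-derived frame reproduces them")
    landmarks = _landmarks_for_frame(spec.frame_origin, spec.frame_axes, spec.side)

    dims = np.array(spec.grid_shape)
    sp = np.asarray(spec.spacing_mm, dtype=float)
    origin = spec.frame_origin - (dims - 1) / 2.0 * sp
    idx = np.stack(np.meshgrid(*(np.arange(d) for d in dims), indexing="ij"), axis=-1)
    centers = origin + idx * sp  # identity direction: grid axes = LPS axes
    coords = frame.to_coords(centers.reshape(-1, 3)).reshape(*dims, 3)

    # containment: shape extent must stay >= 2 voxels inside the grid
    extent = np.abs(spec.offset_mm) + spec.radius_mm
    if spec.shape == "two_blob":
        extent = np.maximum(extent, np.abs(spec.blob2_center_mm) + spec.blob2_radius_mm)
    half = (dims - 1) / 2.0 * sp - 2.0 * sp
    if np.any(extent > half):
        raise ConfigError(f"shape extent {extent} mm escapes the grid "
                          f"(usable half-size {half} mm); enlarge grid_shape")

    inside = _membership(spec, coords)
    voxels = np.full(tuple(dims), float(spec.background))
    voxels[inside] = spec.contrast
    if spec.noise_sd > 0:
        voxels = voxels + rng.normal(0.0, spec.noise_sd, size=voxels.shape)

    volume = VolumeImage(voxels=voxels, spacing=sp, origin=origin, direction=np.eye(3))
    mask = SegmentationMask(voxels=inside.astype(np.uint8), spacing=sp.copy(),
                            origin=origin.copy(), direction=np.eye(3))

    if spec.shape == "spherical_shell":
        seed_f = spec.offset_mm + np.array([0.0, (spec.radius_mm + spec.inner_radius_mm) / 2.0, 0.0])
    else:
        seed_f = spec.offset_mm.copy()
    seed_point = frame.from_coords(seed_f)

    return Phantom(volume=volume, mask=mask, landmarks=landmarks, frame=frame,
                   analytic=_analytic_quadrants(spec), seed_point_mm=seed_point, spec=spec)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Configuration for the Gaussian-copula cohort simulator.

    Margins are (mean, SD) per variable in ``SIM_VARIABLES`` order; the
    correlation matrix is 8x8 over the same order.  Volumes are truncated at
    a small positive floor, angles clamped to physiologic bounds, and the IRb
    latent value rounded and clamped to the ordinal 1..18 scale.
    """

    n: int = 83
    margins: dict = field(default_factory=lambda: dict(PUBLISHED_COHORT_MARGINS))
    correlation: np.ndarray = field(default_factory=default_correlation_matrix)
    volume_floor_ml: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.n < 3:
            raise ConfigError(f"cohort size must be >= 3, got {self.n}")
        missing = [v for v in SIM_VARIABLES if v not in self.margins]
        if missing:
            raise ConfigError(f"margins missing for {missing}")
        for v, (_, sd) in self.margins.items():
            if sd <= 0:
                raise ConfigError(f"SD for {v} must be positive")
        C = self.correlation
        if C.shape != (8, 8) or not np.allclose(C, C.T, atol=1e-12) \
                or not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise ConfigError("correlation must be a symmetric 8x8 matrix with unit diagonal")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-8:
            raise ConfigError(f"correlation matrix is not positive semidefinite "
                              f"(smallest eigenvalue {w.min():.3g})")


def simulate_cohort(config: CohortSimConfig,
                    rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Simulate a cohort table with the configured margins and correlations.

    A latent multivariate normal with the target correlation matrix is scaled
    to each variable's mean/SD (Gaussian copula with normal margins).  The
    total joint volume is the sum of the four quadrant volumes, keeping the
    table consistent with the volumetry partition invariant; its moments are
    therefore emergent, not enforced.  Deterministic given ``config.seed`` (or
    an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    else:
        rng = np.random.default_rng(rng)
    w, V = np.linalg.eigh(config.correlation)
    A = V * np.sqrt(np.clip(w, 0.0, None))
    Z = rng.standard_normal((config.n, 8)) @ A.T

    data = {}
    for j, var in enumerate(SIM_VARIABLES):
        mean, sd = config.margins[var]
        data[var] = mean + sd * Z[:, j]
    for var in ("Vol.AIQ", "Vol.ASQ", "Vol.PSQ", "Vol.PIQ"):
        data[var] = np.maximum(data[var], config.volume_floor_ml)
    data["Sc"] = np.clip(data["Sc"], 0.0, 180.0)
    data["ERs"] = np.clip(data["ERs"], 0.0, 120.0)
    data["ER90"] = np.clip(data["ER90"], 0.0, 120.0)
    data["IRb"] = np.clip(np.rint(data["IRb"]), 1, 18).astype(int)

    df = pd.DataFrame(data)
    df.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(config.n)])
    df.insert(1, "Vol.TJ", df[["Vol.AIQ", "Vol.ASQ", "Vol.PSQ", "Vol.PIQ"]].sum(axis=1))
    from .stats import score_to_irb
    df["IRb_label"] = df["IRb"].map(score_to_irb)
    return df


# ---------------------------------------------------------------------------
# rater simulation
# ---------------------------------------------------------------------------

@dataclass
class RaterSimConfig:
    """Variance-component model for repeated measurements of one quantity.

    ``rating[i, j] = true_score[i] + bias[j] + noise[i, j]`` with
    ``true_score ~ N(true_mean, true_sd^2)`` and ``noise ~ N(0, error_sd^2)``.
    With zero bias the implied ICC(2,1) is ``true_sd^2 / (true_sd^2 + error_sd^2)``.
    """

    n_subjects: int = 83
    n_raters: int = 2
    true_mean: float = VOL_TJ_REFERENCE[0]
    true_sd: float = VOL_TJ_REFERENCE[1]
    error_sd: float = 1.0
    rater_bias: tuple[float, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_sd < 0 or self.error_sd < 0:
            raise ConfigError("SDs must be >= 0")
        if self.rater_bias is not None and len(self.rater_bias) != self.n_raters:
            raise ConfigError("rater_bias length must equal n_raters")

    @property
    def implied_icc(self) -> float:
        """Expected ICC(2,1) in the unbiased-rater case."""
        denom = self.true_sd ** 2 + self.error_sd ** 2
        return 1.0 if denom == 0 else self.true_sd ** 2 / denom


def simulate_raters(config: RaterSimConfig,
                    rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Simulate the subjects x raters ratings table; seeded and reproducible."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    else:
        rng = np.random.default_rng(rng)
    true = rng.normal(config.true_mean, config.true_sd, size=config.n_subjects)
    bias = np.zeros(config.n_raters) if config.rater_bias is None \
        else np.asarray(config.rater_bias, dtype=float)
    noise = rng.normal(0.0, config.error_sd, size=(config.n_subjects, config.n_raters))
    ratings = true[:, None] + bias[None, :] + noise
    return pd.DataFrame(ratings, columns=[f"rater{j + 1}" for j in range(config.n_raters)])


def validate_injection_protocol(components_ml) -> float:
    """Sum the injectate components (mL), validating each is positive.

    The standardized arthrography protocol injects 12.5 mL saline + 6 mL
    iopromide + 1.5 mL mepivacaine = 20 mL; receiving the full 20 mL is the
    inclusion criterion that equalizes capsule filling across patients.
    """
    components = list(components_ml)
    if not components:
        raise ConfigError("injection protocol needs at least one component")
    for c in components:
        if not np.isfinite(c) or c <= 0:
            raise ConfigError(f"injection components must be positive volumes, got {c}")
    return float(sum(components))
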