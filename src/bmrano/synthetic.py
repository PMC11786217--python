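"""Seeded synthetic longitudinal lesion cohorts.

The study data this pipeline targets — per-lesion 3D contours of brain
metastases followed over serial MRI after stereotactic radiosurgery — are
not public, so every analysis here runs on synthetic cohorts built to carry
the statistical structure the analyses assume:

* a cohort on the order of tens of patients, hundreds of lesions, with a
  baseline scan at treatment plus a handful of follow-ups per patient;
* paired "manual" and "automatic" contours of the same underlying lesion
  with high volume agreement, differing in their noise character — manual
  contours are drawn slice by slice and show a sawtooth profile along the
  inferior-superior axis, automatic contours have smooth 3D boundary
  jitter;
* manually measured diameters systematically smaller than contour-derived
  ones (multiplicative bias, default 0.75);
* a fraction of lesions (default 10.9%) labelled radio-necrosis by the
  reading radiologists;
* a mix of monotone (shrinking, growing, stable), pseudo-progressing and
  completely responding size trajectories.

All randomness flows from a single master seed through a
``numpy.random.SeedSequence`` spawn tree (patient -> lesion -> observation),
so the same configuration and seed reproduce a cohort bit for bit and
sub-streams can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .mask_ops import Mask3D, longest_axial_diameter, volume_mm3
from .response import classify_clinician_style
from .response import SizeSeries

TRAJECTORY_KINDS = ("shrink", "grow", "stable", "pseudo_progression", "complete_response")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ShapeConfig:
    """Ellipsoid shape sampling: base radius (lognormal) and axis ratios."""

    mean_radius_mm: float = 6.0
    radius_log_sd: float = 0.35
    axis_ratio_range: tuple[float, float] = (0.6, 1.0)
    surface_noise: float = 0.05  # relative radial amplitude of SH perturbation


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults emulate the target study scale.

    49 patients with 4-14 lesions each give roughly 450 lesions; follow-up
    intervals of ~75 +/- 25 days over 1-6 follow-ups span a few hundred
    days. ``manual_diam_bias`` (default 0.75) makes manually read diameters
    systematically smaller than contour-derived ones, and
    ``radionecrosis_fraction`` (default 0.109) sets the per-lesion
    probability of a radio-necrosis label. Where the emulated study reports
    only means, the distributions here are order-of-magnitude choices and
    documented as such.
    """

    n_patients: int = 49
    lesions_per_patient: tuple[int, int] = (4, 14)  # inclusive uniform range
    followup_interval_days: tuple[float, float] = (75.0, 25.0)  # mean, jitter sd
    n_followups: tuple[int, int] = (1, 6)  # inclusive uniform range
    grid_spacing: float = 1.0
    shape: ShapeConfig = field(default_factory=ShapeConfig)
    trajectory_mix: dict[str, float] = field(
        default_factory=lambda: {
            "shrink": 0.35,
            "grow": 0.15,
            "stable": 0.25,
            "pseudo_progression": 0.10,
            "complete_response": 0.15,
        }
    )
    volume_noise_sd: float = 0.05  # multiplicative lognormal sd per observation
    manual_contour_noise: float = 1.0  # mm, per-slice sawtooth amplitude
    auto_contour_noise: float = 0.6  # mm, smooth 3D jitter amplitude
    manual_diam_bias: float = 0.75
    manual_diam_noise_sd: float = 0.5  # mm
    manual_reading_fraction: float = 0.8  # lesions carrying man-diam + labels
    radionecrosis_fraction: float = 0.109
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.grid_spacing <= 0:
            raise ConfigurationError("grid_spacing must be positive")
        mix = self.trajectory_mix
        if set(mix) - set(TRAJECTORY_KINDS):
            raise ConfigurationError(f"unknown trajectory kinds: {set(mix) - set(TRAJECTORY_KINDS)}")
        if any(not 0 <= p <= 1 for p in mix.values()) or abs(sum(mix.values()) - 1) > 1e-9:
            raise ConfigurationError("trajectory_mix must be proportions summing to 1")
        for name in ("manual_reading_fraction", "radionecrosis_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        lo, hi = self.lesions_per_patient
        if lo < 1 or hi < lo:
            raise ConfigurationError("lesions_per_patient range invalid")
        lo, hi = self.n_followups
        if lo < 1 or hi < lo:
            raise ConfigurationError("n_followups range invalid")
        if self.manual_contour_noise < 0 or self.auto_contour_noise < 0:
            raise ConfigurationError("contour noise amplitudes must be >= 0")


@dataclass(frozen=True)
class TrueLesionState:
    """Ground-truth ellipsoid at one time point."""

    center: tuple[float, float, float]  # mm
    semi_axes: tuple[float, float, float]  # mm
    orientation: tuple[float, float, float]  # Euler angles (deg, xyz intrinsic)
    true_volume: float  # mm^3 (0 after complete response)
    time_days: float

    def __post_init__(self) -> None:
        if self.true_volume < 0:
            raise ValueError("true_volume must be >= 0")
        if self.true_volume > 0 and any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive for an existing lesion")


@dataclass
class Observation:
    """One imaging time point of one lesion."""

    time_days: float
    state: TrueLesionState
    masks: dict[str, Mask3D]  # keys: "manual", "automatic"; empty dict if CR
    manual_diameter_mm: float | None = None
    t1t2_match: bool | None = None
    radiologist_label: str | None = None

    @property
    def is_cr(self) -> bool:
        return self.state.true_volume == 0


@dataclass
class LesionTrajectory:
    """Ordered observations of one lesion across the follow-up schedule."""

    patient_id: str
    lesion_id: str
    kind: str
    radionecrosis: bool
    has_manual_reading: bool
    observations: list[Observation]

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(o.time_days for o in self.observations)

    def size_series(self, method: str) -> SizeSeries:
        """Measured sizes along the trajectory for one of the five methods.

        Methods: vol-manseg, vol-autoseg, diam-manseg, diam-autoseg,
        man-diam. CR time points contribute 0.
        """
        values = []
        for obs in self.observations:
            if obs.is_cr:
                values.append(0.0)
                continue
            if method == "man-diam":
                if obs.manual_diameter_mm is None:
                    raise ValueError(f"lesion {self.lesion_id} has no manual diameter reading")
                values.append(obs.manual_diameter_mm)
            else:
                meas, source = method.split("-")
                mask = obs.masks["manual" if source == "manseg" else "automatic"]
                values.append(
                    volume_mm3(mask) if meas == "vol" else longest_axial_diameter(mask)
                )
        return SizeSeries(self.lesion_id, method, self.times, tuple(values))


@dataclass
class Cohort:
    config: CohortConfig
    trajectories: list[LesionTrajectory]

    @property
    def n_lesions(self) -> int:
        return len(self.trajectories)

    def table(self) -> pd.DataFrame:
        """Long-format cohort table, one row per lesion x time x contour source."""
        rows = []
        for traj in self.trajectories:
            for obs in traj.observations:
                sources = sorted(obs.masks) if obs.masks else [None]
                for src in sources:
                    rows.append(
                        {
                            "patient_id": traj.patient_id,
                            "lesion_id": traj.lesion_id,
                            "time_days": obs.time_days,
                            "contour_source": src,
                            "manual_diameter_mm": obs.manual_diameter_mm,
                            "radiologist_label": obs.radiologist_label,
                            "excluded_radionecrosis": traj.radionecrosis,
                        }
                    )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectory simulation


def simulate_trajectory(
    initial_volume: float,
    kind: str,
    times: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """True lesion volumes (mm^3) along a follow-up schedule.

    ``kind`` selects the expected shape: exponential ``shrink``/``grow``
    (monotone in expectation; strictly monotone at ``noise_sd=0``),
    ``stable``, ``pseudo_progression`` (a transient rise peaking at an
    interior follow-up, then regression below baseline), or
    ``complete_response`` (shrinkage, then exactly 0 from a sampled
    follow-up onward). Multiplicative lognormal noise of fractional sd
    ``noise_sd`` applies to every post-baseline, nonzero volume.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise ValueError("need a baseline plus at least one follow-up time")
    if times[0] != 0:
        raise ValueError("times must start at 0 (baseline at treatment)")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if kind not in TRAJECTORY_KINDS:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    if initial_volume <= 0:
        raise ValueError("initial_volume must be positive")

    span = times[-1]
    if kind == "stable":
        profile = np.ones_like(times)
    elif kind == "shrink":
        half_life = rng.uniform(100, 250)
        profile = np.exp(-np.log(2) / half_life * times)
    elif kind == "grow":
        doubling = rng.uniform(150, 400)
        profile = np.exp(np.log(2) / doubling * times)
    elif kind == "pseudo_progression":
        if len(times) < 3:  # cannot show rise-then-fall with one follow-up
            doubling = rng.uniform(150, 400)
            profile = np.exp(np.log(2) / doubling * times)
        else:
            peak_idx = int(rng.integers(1, len(times) - 1))
            peak = rng.uniform(1.3, 2.0)
            final = rng.uniform(0.3, 0.7)
            t_peak = times[peak_idx]
            profile = np.where(
                times <= t_peak,
                np.exp(np.log(peak) * times / t_peak),
                np.exp(
                    np.log(peak)
                    + (np.log(final) - np.log(peak)) * (times - t_peak) / (span - t_peak)
                ),
            )
    else:  # complete_response
        gone_idx = int(rng.integers(1, len(times)))
        half_life = rng.uniform(40, 120)
        profile = np.exp(-np.log(2) / half_life * times)
        profile[gone_idx:] = 0.0

    volumes = initial_volume * profile
    if noise_sd > 0:
        noise = np.exp(rng.normal(0.0, noise_sd, size=len(times)))
        noise[0] = 1.0
        volumes = volumes * noise
    volumes[profile == 0] = 0.0
    return volumes


# ---------------------------------------------------------------------------
# geometry rendering


def _real_sh_perturbation(u: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Low-order real-spherical-harmonic radial modulation for directions u.

    Uses degree-2 and degree-3 bands (7 + 5 = 12 real terms built from
    simple Cartesian polynomials on the unit sphere), zero-mean by
    construction, normalised so the modulation has unit rms for unit-variance
    coefficients.
    """
    x, y, z = u[..., 0], u[..., 1], u[..., 2]
    basis = np.stack(
        [
            x * y, y * z, x * z, x * x - y * y, 3 * z * z - 1,
            x * (5 * z * z - 1), y * (5 * z * z - 1), z * (5 * z * z - 3),
            x * (x * x - 3 * y * y), y * (3 * x * x - y * y), x * y * z,
            z * (x * x - y * y),
        ],
        axis=-1,
    )
    basis = basis / np.sqrt((basis**2).mean(axis=tuple(range(basis.ndim - 1)), keepdims=True) + 1e-12)
    field = basis @ coeffs
    return field / np.sqrt(len(coeffs))


def render_lesion_mask(
    state: TrueLesionState,
    spacing: float = 1.0,
    margin_voxels: int = 3,
    surface_noise: float = 0.0,
    rng: np.random.Generator | None = None,
    extent_mm: float | None = None,
) -> Mask3D:
    """Voxelize a (possibly surface-perturbed) ellipsoid on an isotropic grid.

    A voxel is occupied when its centre lies inside the ellipsoid, optionally
    radially modulated by a low-order spherical-harmonic perturbation of
    relative amplitude ``surface_noise``. The grid is sized from the largest
    semi-axis plus ``margin_voxels``; pass ``extent_mm`` to force a half-extent,
    which raises if the lesion would not fit with the required margin.
    The measured voxel volume converges to the analytic ellipsoid volume
    (4/3 pi abc) as the spacing shrinks.
    """
    if state.true_volume == 0:
        return Mask3D(np.zeros((1, 1, 1), dtype=bool), (spacing,) * 3)
    a = np.array(state.semi_axes, dtype=float)
    r_out = a.max() * (1 + 2.5 * surface_noise)
    half = r_out + margin_voxels * spacing
    if extent_mm is not None:
        if extent_mm < r_out + margin_voxels * spacing:
            raise ValueError(
                f"lesion at t={state.time_days:g}d (semi-axes {tuple(a)}) exceeds "
                f"grid half-extent {extent_mm} mm with {margin_voxels}-voxel margin"
            )
        half = extent_mm
    n = int(np.ceil(2 * half / spacing)) + 1
    coords = (np.arange(n) - (n - 1) / 2) * spacing
    gx, gy, gz = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)

    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("xyz", state.orientation, degrees=True).as_matrix()
    local = pts @ rot  # world -> lesion frame (rot columns are lesion axes)
    rho = np.sqrt(((local / a) ** 2).sum(axis=-1))
    if surface_noise > 0:
        if rng is None:
            raise ValueError("surface_noise > 0 requires an rng")
        rad = np.sqrt((local**2).sum(axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.where(rad[..., None] > 0, local / (rad[..., None] + 1e-12), 0.0)
        coeffs = rng.normal(size=12)
        occ = rho <= 1 + surface_noise * _real_sh_perturbation(u, coeffs)
    else:
        occ = rho <= 1
    origin = tuple(float(c + coords[0]) for c in state.center)
    return Mask3D(occ, (spacing,) * 3, origin)


# ---------------------------------------------------------------------------
# contour perturbation


def _signed_distance(mask: Mask3D) -> np.ndarray:
    """mm distance to the mask surface: positive inside, negative outside.

    EDT measures centre-to-centre distance to the nearest opposite-phase
    voxel; subtracting half a voxel places the implied surface midway
    between voxel centres, so boundary-adjacent voxels sit at +-0.5 voxel
    rather than +-1.
    """
    occ = mask.occupancy
    h = 0.5 * min(mask.spacing)
    inside = ndimage.distance_transform_edt(occ, sampling=mask.spacing)
    outside = ndimage.distance_transform_edt(~occ, sampling=mask.spacing)
    return np.where(occ, inside - h, -(outside - h))


def perturb_contour(
    mask: Mask3D,
    style: str,
    amplitude: float,
    rng: np.random.Generator,
) -> Mask3D:
    """Emulate contouring noise on a ground-truth mask.

    ``style="manual"`` draws an independent in-plane dilation/erosion offset
    per axial slice (uniform in [-amplitude, amplitude] mm), reproducing the
    sawtooth profile along the inferior-superior axis that slice-by-slice
    manual contouring leaves behind. ``style="automatic"`` applies a smooth,
    spatially correlated 3D boundary jitter of the same maximum amplitude.
    Either way every changed voxel lies within ``amplitude`` mm of the
    original boundary (signed-distance thresholding guarantees the
    morphological envelope), and ``amplitude=0`` returns the input
    unchanged. If the perturbation would empty the mask, the deepest voxel
    is retained so a present lesion never vanishes by noise alone.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if mask.is_empty:
        raise ValueError("cannot perturb an empty mask")
    if amplitude == 0:
        return Mask3D(mask.occupancy.copy(), mask.spacing, mask.origin)

    sdist = _signed_distance(mask)
    if style == "manual":
        nz = mask.occupancy.shape[2]
        offsets = rng.uniform(-amplitude, amplitude, size=nz)
        threshold = -offsets[np.newaxis, np.newaxis, :]
    elif style == "automatic":
        raw = rng.normal(size=mask.occupancy.shape)
        smooth = ndimage.gaussian_filter(raw, sigma=2.0)
        sd = smooth.std()
        if sd == 0:  # pragma: no cover - degenerate single-voxel grid
            smooth = np.zeros_like(smooth)
        else:
            smooth = np.clip(amplitude * smooth / (1.2 * sd), -amplitude, amplitude)
        threshold = -smooth
    else:
        raise ValueError(f"style must be 'manual' or 'automatic', got {style!r}")

    occ = sdist > threshold
    if not occ.any():
        occ = sdist == sdist.max()
    return Mask3D(occ, mask.spacing, mask.origin)


def simulate_manual_diameter(
    mask: Mask3D,
    bias: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> float:
    """A radiologist's caliper reading of the longest axial diameter.

    Modelled as ``bias x longest_axial_diameter + N(0, noise_sd)``, floored
    at 0. The default bias of 0.75 makes manual readings systematically
    smaller than contour-derived diameters, matching the reading style the
    cohort emulates. Raises on an empty mask — disappeared lesions carry no
    manual diameter.
    """
    if mask.is_empty:
        raise ValueError("cannot read a diameter off an empty mask")
    d = bias * longest_axial_diameter(mask)
    if noise_sd > 0:
        d += rng.normal(0.0, noise_sd)
    return max(0.0, float(d))


# ---------------------------------------------------------------------------
# cohort assembly


def _sample_schedule(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    n_fu = int(rng.integers(cfg.n_followups[0], cfg.n_followups[1] + 1))
    mean, jitter = cfg.followup_interval_days
    intervals = np.maximum(14.0, rng.normal(mean, jitter, size=n_fu))
    return np.concatenate([[0.0], np.cumsum(intervals)])


def _simulate_lesion(
    cfg: CohortConfig,
    patient_id: str,
    lesion_id: str,
    times: np.ndarray,
    rng: np.random.Generator,
) -> LesionTrajectory:
    kinds = list(cfg.trajectory_mix)
    kind = rng.choice(kinds, p=[cfg.trajectory_mix[k] for k in kinds])
    radionecrosis = bool(rng.random() < cfg.radionecrosis_fraction)
    if radionecrosis:
        kind = "grow"  # radio-necrosis presents as an enlarging lesion

    shape = cfg.shape
    radius = shape.mean_radius_mm * np.exp(rng.normal(0.0, shape.radius_log_sd))
    ratios = rng.uniform(*shape.axis_ratio_range, size=2)
    semi = np.array([radius, radius * ratios[0], radius * ratios[1]])
    rng.shuffle(semi)
    orientation = tuple(rng.uniform(-90, 90, size=3))
    v0 = 4 / 3 * np.pi * np.prod(semi)

    volumes = simulate_trajectory(v0, kind, times, cfg.volume_noise_sd, rng)
    has_reading = bool(rng.random() < cfg.manual_reading_fraction)

    observations: list[Observation] = []
    for t, v in zip(times, volumes):
        if v == 0:
            state = TrueLesionState((0, 0, 0), (0, 0, 0), orientation, 0.0, float(t))
            observations.append(Observation(float(t), state, {}))
            continue
        scale = (v / v0) ** (1 / 3)
        state = TrueLesionState(
            center=(0.0, 0.0, 0.0),
            semi_axes=tuple(semi * scale),
            orientation=orientation,
            true_volume=float(v),
            time_days=float(t),
        )
        margin = int(np.ceil(3 + max(cfg.manual_contour_noise, cfg.auto_contour_noise)))
        truth = render_lesion_mask(
            state,
            spacing=cfg.grid_spacing,
            margin_voxels=margin,
            surface_noise=shape.surface_noise,
            rng=rng,
        )
        masks = {
            "manual": perturb_contour(truth, "manual", cfg.manual_contour_noise, rng),
            "automatic": perturb_contour(truth, "automatic", cfg.auto_contour_noise, rng),
        }
        obs = Observation(float(t), state, masks)
        if has_reading:
            obs.manual_diameter_mm = simulate_manual_diameter(
                masks["manual"], cfg.manual_diam_bias, cfg.manual_diam_noise_sd, rng
            )
        observations.append(obs)

    traj = LesionTrajectory(
        patient_id=patient_id,
        lesion_id=lesion_id,
        kind=kind,
        radionecrosis=radionecrosis,
        has_manual_reading=has_reading,
        observations=observations,
    )
    if has_reading:
        _attach_radiologist_labels(traj)
    return traj


def _attach_radiologist_labels(traj: LesionTrajectory) -> None:
    """Clinician-style categories from the manual diameter readings.

    Radio-necrosis lesions carry gado-T1/T2 mismatch (flag False); all other
    lesions match. A baseline reading of 0 (possible for a tiny lesion under
    reading noise) leaves the trajectory unlabelled.
    """
    diams = [0.0 if o.is_cr else (o.manual_diameter_mm or 0.0) for o in traj.observations]
    if diams[0] <= 0:
        return
    series = SizeSeries(traj.lesion_id, "man-diam", traj.times, tuple(diams))
    match = tuple(not traj.radionecrosis for _ in range(series.n_followups))
    seq = classify_clinician_style(series, match)
    for obs, cat in zip(traj.observations[1:], seq.categories):
        obs.radiologist_label = cat.value
        obs.t1t2_match = not traj.radionecrosis


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort from one master seed.

    Follow-up schedules are sampled per patient and shared across that
    patient's lesions (imaging sessions image the whole head); each lesion
    then gets its own shape, trajectory kind, contour pair per time point
    and — for a configurable subset — manual diameter readings with
    clinician-style labels. Identical (config, seed) pairs reproduce the
    cohort exactly.
    """
    master = np.random.SeedSequence(config.seed)
    patient_seqs = master.spawn(config.n_patients)
    trajectories: list[LesionTrajectory] = []
    for p, pseq in enumerate(patient_seqs):
        patient_id = f"P{p:03d}"
        prng = np.random.default_rng(pseq)
        times = _sample_schedule(config, prng)
        n_lesions = int(prng.integers(config.lesions_per_patient[0], config.lesions_per_patient[1] + 1))
        for lseq in pseq.spawn(n_lesions):
            lrng = np.random.default_rng(lseq)
            lesion_id = f"{patient_id}-L{len(trajectories):04d}"
            trajectories.append(_simulate_lesion(config, patient_id, lesion_id, times, lrng))
    return Cohort(config=config, trajectories=trajectories)


def default_analysis_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default cohort for the stability/agreement analyses: ~200 lesions.

    25 patients at 6-10 lesions each; all other parameters at their
    study-scale defaults.
    """
    cfg = CohortConfig(n_patients=25, lesions_per_patient=(6, 10), seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
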