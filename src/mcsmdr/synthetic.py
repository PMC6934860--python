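"""Seeded synthetic inputs with known ground truth.

Generates the three input kinds the pipeline consumes, with the
statistical structure each downstream stage assumes:

* spheroid / monolayer time-lapse stacks (phase + green channels) whose
  green signal follows saturating uptake-efflux kinetics, with
  phenotype-dependent penetration depth, low-frequency intensity
  inhomogeneity over the spheroid and soft boundaries — the two
  features that defeat classical threshold segmentation;
* MTS microplate absorbance tables (A490/A650) drawn from a
  four-parameter-logistic viability curve;
* flow-cytometry event tables with log-normal green intensities,
  bimodal live/dead PI and inhibitor-dependent median shifts.

Every generator is a pure function of its spec and an integer seed.

Kinetics model
--------------
Intracellular dye concentration follows uptake at constant rate ``u``
opposed by first-order efflux at rate ``e``::

    C(t) = u * t                      if e == 0
    C(t) = (u / e) * (1 - exp(-e*t))  otherwise

so a sensitive line (low efflux) accumulates dye roughly linearly
while a resistant line plateaus early at the low level ``u/e``.
Penetration into the spheroid is phenomenological: the dye reaches a
normalized depth ``delta(t) = delta_max * (1 - exp(-k_p * t))`` from
the boundary; deeper voxels are attenuated exponentially with length
scale 0.05 spheroid radii, which produces rim-only fluorescence for
resistant spheroids and full-core penetration for sensitive ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SegMask, TimeLapseStack

PENETRATION_TAIL = 0.05  # exp length scale beyond the penetration front, in radii

INHIBITOR_TUBES = ("control", "MDR1_verapamil", "MRP1_MK571", "BCRP_novobiocin")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticPhenotype:
    """Kinetic ground truth for one cell line.

    u        : uptake rate, fluorescence a.u. per hour
    e        : efflux rate, 1/h (0 = no efflux)
    delta_max: maximal dye penetration depth, fraction of radius
    k_p      : penetration-front rate, 1/h
    ros_init : initial ROS-reporter fluorescence, a.u.
    ros_decay: first-order ROS signal decay, 1/h
    """

    name: str
    u: float
    e: float
    delta_max: float
    k_p: float
    ros_init: float
    ros_decay: float

    def __post_init__(self):
        if self.u <= 0:
            raise ValueError("uptake rate u must be > 0")
        if self.e < 0 or self.k_p < 0 or self.ros_init < 0 or self.ros_decay < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.delta_max <= 1.0:
            raise ValueError("delta_max must lie in [0, 1]")


#: Default study phenotypes.  Chosen so that 12-hour accumulated calcein
#: orders sensitive > moderate > resistant with the moderate line
#: mid-range, ROS decay occurs only in the sensitive line, and the
#: resistant line shows rim-only penetration.
PHENOTYPES: dict[str, SyntheticPhenotype] = {
    "sensitive": SyntheticPhenotype("sensitive", u=1500.0, e=0.05, delta_max=1.0,
                                    k_p=0.5, ros_init=800.0, ros_decay=1.0),
    "moderate": SyntheticPhenotype("moderate", u=1400.0, e=0.12, delta_max=0.7,
                                   k_p=0.3, ros_init=0.0, ros_decay=0.0),
    "resistant": SyntheticPhenotype("resistant", u=1000.0, e=1.5, delta_max=0.15,
                                    k_p=0.3, ros_init=0.0, ros_decay=0.0),
}


@dataclass(frozen=True)
class SpheroidGeometry:
    """Rendered spheroid disk: center/radius in pixels, soft boundary,
    multiplicative low-frequency inhomogeneity and background noise."""

    center: tuple[float, float] = (128.0, 128.0)
    radius: float = 60.0
    boundary_softness: float = 4.0
    inhomogeneity_amplitude: float = 0.3
    background_noise_sd: float = 60.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.boundary_softness < 0:
            raise ValueError("boundary_softness must be >= 0")
        if not 0.0 <= self.inhomogeneity_amplitude < 1.0:
            raise ValueError("inhomogeneity_amplitude must be in [0, 1)")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")


@dataclass(frozen=True)
class PlateSpec:
    """One drug / one culture mode MTS plate."""

    drug: str
    concentrations: tuple[float, ...]
    true_ic50: float
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    replicates: int = 3
    noise_sd: float = 0.0          # absorbance units on each well
    control_signal: float = 1.2    # corrected A490-A650 of untreated wells
    blank_abs: float = 0.05        # corrected A490-A650 of blank wells
    a650_level: float = 0.04       # reference-wavelength baseline

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if c.size < 1 or np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and strictly ascending")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.bottom >= self.top:
            raise ValueError("bottom must be < top")
        if self.true_ic50 <= 0 or self.hill <= 0:
            raise ValueError("true_ic50 and hill must be > 0")


@dataclass(frozen=True)
class FlowSpec:
    """One sample's four-tube efflux assay (control + three inhibitors)."""

    n_events: int = 10_000
    dead_fraction: float = 0.05
    baseline_mfi: float = 500.0
    retention_ratio: dict = field(default_factory=lambda: {
        "MDR1_verapamil": 1.5, "MRP1_MK571": 2.0, "BCRP_novobiocin": 3.0,
        "control": 1.0,
    })
    log_sd: float = 0.35           # sd of log10 green intensity
    live_pi_median: float = 100.0
    dead_pi_median: float = 10_000.0
    pi_log_sd: float = 0.15

    def __post_init__(self):
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must lie in [0, 1]")
        if self.retention_ratio.get("control", 1.0) != 1.0:
            raise ValueError("control retention ratio must equal 1")
        if any(r < 1.0 for r in self.retention_ratio.values()):
            raise ValueError("retention ratios must be >= 1")


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def uptake_curve(phenotype: SyntheticPhenotype, times_h) -> np.ndarray:
    """Closed-form intracellular dye concentration C(t) at the given hours."""
    t = np.asarray(times_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    if phenotype.e == 0:
        return phenotype.u * t
    return (phenotype.u / phenotype.e) * (1.0 - np.exp(-phenotype.e * t))


def penetration_factor(depth_norm: np.ndarray, delta: float) -> np.ndarray:
    """Radial attenuation: 1 inside the penetration front, exponential tail
    (length scale 0.05 radii) beyond it.  depth_norm is the distance from
    the spheroid boundary in units of the radius."""
    depth_norm = np.asarray(depth_norm, dtype=float)
    beyond = np.clip(depth_norm - delta, 0.0, None)
    return np.exp(-beyond / PENETRATION_TAIL)


def _times(frame_interval_min: float, duration_h: float) -> np.ndarray:
    if frame_interval_min <= 0 or duration_h < 0:
        raise ValueError("frame interval must be > 0 and duration >= 0")
    n = int(np.floor(duration_h * 60.0 / frame_interval_min)) + 1
    return np.arange(n) * frame_interval_min / 60.0


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  octaves: int = 2) -> np.ndarray:
    """2-octave smoothed noise in [-1, 1], used as multiplicative
    low-frequency inhomogeneity over the spheroid."""
    h, w = shape
    field = np.zeros(shape)
    for octave in range(octaves):
        n = 4 * 2**octave
        coarse = rng.standard_normal((n, n))
        from skimage.transform import resize

        field += resize(coarse, shape, order=3, anti_aliasing=False,
                        mode="reflect") / 2**octave
    field -= field.mean()
    m = np.max(np.abs(field))
    return field / m if m > 0 else field


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

PHASE_BACKGROUND = 1000.0
PHASE_FOREGROUND = 2000.0


def make_spheroid_stack(
    phenotype: SyntheticPhenotype,
    geometry: SpheroidGeometry,
    frame_interval_min: float = 20.0,
    duration_h: float = 12.0,
    seed: int = 0,
    image_size: int = 256,
) -> tuple[TimeLapseStack, list[SegMask]]:
    """Render a spheroid time-lapse plus exact ground-truth masks.

    Phase channel: bright disk with a soft boundary and multiplicative
    low-frequency inhomogeneity (static over time) on additive Gaussian
    background noise.  Green channel: ``uptake_curve(t)`` modulated by
    the radial penetration factor, same inhomogeneity field, plus noise.
    Ground-truth masks are the exact geometric disk (distance <= radius).
    """
    cy, cx = geometry.center
    if (cy - geometry.radius < 0 or cx - geometry.radius < 0
            or cy + geometry.radius >= image_size or cx + geometry.radius >= image_size):
        raise ValueError("spheroid does not fit inside the frame")

    rng = np.random.default_rng(seed)
    times = _times(frame_interval_min, duration_h)
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    dist = np.hypot(yy - cy, xx - cx)
    disk = dist <= geometry.radius

    # soft foreground profile in [0,1]
    if geometry.boundary_softness > 0:
        profile = 1.0 / (1.0 + np.exp((dist - geometry.radius) / geometry.boundary_softness))
    else:
        profile = disk.astype(float)
    inhom = 1.0 + geometry.inhomogeneity_amplitude * _smooth_field(
        (image_size, image_size), rng
    )
    depth_norm = np.clip((geometry.radius - dist) / geometry.radius, 0.0, None)

    conc = uptake_curve(phenotype, times)
    delta_t = phenotype.delta_max * (1.0 - np.exp(-phenotype.k_p * times))

    phase = np.empty((len(times), image_size, image_size), dtype=np.float32)
    green = np.empty_like(phase)
    for k in range(len(times)):
        noise_p = rng.normal(0.0, geometry.background_noise_sd, (image_size, image_size))
        noise_g = rng.normal(0.0, geometry.background_noise_sd, (image_size, image_size))
        # illumination inhomogeneity multiplies the whole field, so at high
        # amplitude bright background can outshine dim spheroid regions —
        # exactly the failure mode global thresholding cannot handle
        phase[k] = (PHASE_BACKGROUND
                    + (PHASE_FOREGROUND - PHASE_BACKGROUND) * profile) * inhom + noise_p
        g = conc[k] * penetration_factor(depth_norm, delta_t[k]) * profile * inhom
        green[k] = g + noise_g
    np.clip(phase, 0, None, out=phase)
    np.clip(green, 0, None, out=green)

    stack = TimeLapseStack(
        phase=phase, green=green, times_h=times,
        meta={"phenotype": phenotype.name, "frame_interval_min": frame_interval_min,
              "radius_px": geometry.radius, "seed": seed, "kind": "spheroid"},
    )
    masks = [SegMask(disk.astype(np.uint8), frame_index=k, source="ground_truth")
             for k in range(len(times))]
    return stack, masks


def make_ros_stack(
    phenotype: SyntheticPhenotype,
    geometry: SpheroidGeometry,
    frame_interval_min: float = 20.0,
    duration_h: float = 1.0,
    seed: int = 0,
    image_size: int = 256,
) -> tuple[TimeLapseStack, list[SegMask]]:
    """DCFDA/ROS variant: green follows ``ros_init * exp(-ros_decay * t)``
    over the whole spheroid instead of the uptake kinetics."""
    stack, masks = make_spheroid_stack(
        phenotype, geometry, frame_interval_min, duration_h, seed, image_size
    )
    rng = np.random.default_rng(seed + 7)
    cy, cx = geometry.center
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    dist = np.hypot(yy - cy, xx - cx)
    if geometry.boundary_softness > 0:
        profile = 1.0 / (1.0 + np.exp((dist - geometry.radius) / geometry.boundary_softness))
    else:
        profile = (dist <= geometry.radius).astype(float)
    level = phenotype.ros_init * np.exp(-phenotype.ros_decay * stack.times_h)
    green = np.empty_like(stack.green)
    for k in range(stack.n_frames):
        noise = rng.normal(0.0, geometry.background_noise_sd, profile.shape)
        green[k] = np.clip(level[k] * profile + noise, 0, None)
    stack.green = green
    stack.meta["kind"] = "ros"
    return stack, masks


def make_monolayer_stack(
    phenotype: SyntheticPhenotype,
    n_cells: int = 150,
    frame_interval_min: float = 20.0,
    duration_h: float = 12.0,
    seed: int = 0,
    image_size: int = 256,
) -> TimeLapseStack:
    """2-D culture arm: scattered cell-sized Gaussian blobs whose green
    amplitude follows the uptake curve (no penetration limit in 2-D)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    times = _times(frame_interval_min, duration_h)
    centers = rng.uniform(8, image_size - 8, size=(n_cells, 2))
    sigmas = rng.uniform(2.0, 4.0, size=n_cells)
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    blobs = np.zeros((image_size, image_size))
    for (cy, cx), s in zip(centers, sigmas):
        blobs += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
    blobs = np.clip(blobs, 0, 1)

    conc = uptake_curve(phenotype, times)
    phase = np.empty((len(times), image_size, image_size), dtype=np.float32)
    green = np.empty_like(phase)
    for k in range(len(times)):
        phase[k] = np.clip(
            PHASE_BACKGROUND + (PHASE_FOREGROUND - PHASE_BACKGROUND) * blobs
            + rng.normal(0, 40.0, blobs.shape), 0, None)
        green[k] = np.clip(conc[k] * blobs + rng.normal(0, 40.0, blobs.shape), 0, None)
    return TimeLapseStack(
        phase=phase, green=green, times_h=times,
        meta={"phenotype": phenotype.name, "frame_interval_min": frame_interval_min,
              "n_cells": n_cells, "seed": seed, "kind": "monolayer"},
    )


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------

def four_pl(conc, top, bottom, ic50, hill):
    """4-parameter logistic viability: V(c) = bottom + (top-bottom)/(1+(c/ic50)^hill)."""
    c = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def make_plate(spec: PlateSpec, seed: int = 0, mode: str = "2D",
               n_controls: int = 6, n_blanks: int = 3) -> pd.DataFrame:
    """Simulate an MTS plate as a tidy well table.

    Columns: well, drug, conc_uM, mode, replicate, role
    (treated/control/blank), a490, a650.  The corrected signal
    A490-A650 of a treated well is blank + viability/100 * (control -
    blank) plus Gaussian noise of sd ``spec.noise_sd`` (added to A490).
    """
    rng = np.random.default_rng(seed)
    rows = []
    well = 0

    def _emit(role, conc, rep, corrected):
        nonlocal well
        a650 = spec.a650_level
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        rows.append({
            "well": f"W{well:03d}", "drug": spec.drug,
            "conc_uM": conc, "mode": mode, "replicate": rep, "role": role,
            "a490": corrected + a650 + noise, "a650": a650,
        })
        well += 1

    for rep in range(spec.replicates):
        for c in spec.concentrations:
            v = four_pl(c, spec.top, spec.bottom, spec.true_ic50, spec.hill)
            corrected = spec.blank_abs + (v / 100.0) * (spec.control_signal - spec.blank_abs)
            _emit("treated", c, rep, corrected)
    for rep in range(n_controls):
        _emit("control", np.nan, rep, spec.blank_abs
              + (spec.top / 100.0) * (spec.control_signal - spec.blank_abs))
    for rep in range(n_blanks):
        _emit("blank", np.nan, rep, spec.blank_abs)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------

def make_flow_events(spec: FlowSpec, seed: int = 0, replicate: int = 0) -> pd.DataFrame:
    """Simulate the four-tube efflux assay as a tidy event table.

    Green intensity per tube is log-normal with median = baseline_mfi *
    retention_ratio[tube]; PI is a live/dead log-normal mixture with
    ``dead_fraction`` dead events.  Dead events lose the green signal
    (median scaled to 20%), which is why gating matters.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for tube in INHIBITOR_TUBES:
        ratio = spec.retention_ratio.get(tube, 1.0)
        n_dead = int(round(spec.n_events * spec.dead_fraction))
        n_live = spec.n_events - n_dead
        med = spec.baseline_mfi * ratio
        green_live = 10 ** rng.normal(np.log10(med), spec.log_sd, n_live)
        green_dead = 10 ** rng.normal(np.log10(max(med * 0.2, 1e-6)), spec.log_sd, n_dead)
        pi_live = 10 ** rng.normal(np.log10(spec.live_pi_median), spec.pi_log_sd, n_live)
        pi_dead = 10 ** rng.normal(np.log10(spec.dead_pi_median), spec.pi_log_sd, n_dead)
        frames.append(pd.DataFrame({
            "event_id": np.arange(spec.n_events),
            "tube": tube,
            "replicate": replicate,
            "green": np.concatenate([green_live, green_dead]),
            "pi": np.concatenate([pi_live, pi_dead]),
            "is_dead_truth": np.r_[np.zeros(n_live, bool), np.ones(n_dead, bool)],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# study-condition presets (cell lines x drugs)
# ---------------------------------------------------------------------------

#: Synthetic true IC50 tables (uM) following the published qualitative
#: pattern: the resistant line highest for every drug, the sensitive
#: line lowest, 2-D methotrexate indistinguishable across lines, and
#: spheroids at least as resistant as monolayers.
TRUE_IC50: dict[str, dict[str, dict[str, float]]] = {
    "sensitive": {
        "doxorubicin": {"2D": 400.0, "MCS": 800.0},
        "cisplatin": {"2D": 15.0, "MCS": 30.0},
        "methotrexate": {"2D": 20.0, "MCS": 30.0},
    },
    "moderate": {
        "doxorubicin": {"2D": 900.0, "MCS": 2000.0},
        "cisplatin": {"2D": 40.0, "MCS": 80.0},
        "methotrexate": {"2D": 20.0, "MCS": 60.0},
    },
    "resistant": {
        "doxorubicin": {"2D": 2500.0, "MCS": 8000.0},
        "cisplatin": {"2D": 120.0, "MCS": 280.0},
        "methotrexate": {"2D": 20.0, "MCS": 150.0},
    },
}

#: Drug dose ranges (uM) used on both culture modes.
DOSE_RANGES: dict[str, tuple[float, float]] = {
    "cisplatin": (3.33, 333.0),
    "doxorubicin": (170.0, 17000.0),
    "methotrexate": (2.2, 220.0),
}

#: Per-phenotype inhibitor retention ratios: the sensitive line shows a
#: BCRP-dominant strong response, the moderate line MDR1/MRP1-dominant,
#: the resistant line barely responds to any inhibitor.
RETENTION_RATIOS: dict[str, dict[str, float]] = {
    "sensitive": {"control": 1.0, "MDR1_verapamil": 1.5, "MRP1_MK571": 2.0,
                  "BCRP_novobiocin": 3.0},
    "moderate": {"control": 1.0, "MDR1_verapamil": 2.2, "MRP1_MK571": 2.1,
                 "BCRP_novobiocin": 1.4},
    "resistant": {"control": 1.0, "MDR1_verapamil": 1.2, "MRP1_MK571": 1.1,
                  "BCRP_novobiocin": 1.3},
}


def dose_grid(drug: str, n: int = 8) -> tuple[float, ...]:
    """Log-spaced doses spanning the assay range for a drug."""
    lo, hi = DOSE_RANGES[drug]
    return tuple(np.geomspace(lo, hi, n))


def plate_spec_for(phenotype_name: str, drug: str, mode: str,
                   noise_sd: float = 0.0, n_doses: int = 8,
                   replicates: int = 3) -> PlateSpec:
    return PlateSpec(
        drug=drug, concentrations=dose_grid(drug, n_doses),
        true_ic50=TRUE_IC50[phenotype_name][drug][mode],
        hill=1.0, replicates=replicates, noise_sd=noise_sd,
    )


def flow_spec_for(phenotype_name: str, n_events: int = 10_000,
                  dead_fraction: float = 0.05) -> FlowSpec:
    return FlowSpec(n_events=n_events, dead_fraction=dead_fraction,
                    retention_ratio=dict(RETENTION_RATIOS[phenotype_name]))


def make_segmentation_dataset(
    n_frames: int,
    seed: int = 0,
    image_size: int = 128,
    amplitudes: tuple[float, ...] = (0.0, 0.3, 0.6),
    boundary_softness: float = 3.0,
) -> tuple[list[np.ndarray], list[SegMask], list[float]]:
    """Sample single phase-contrast frames + ground-truth masks for
    segmenter training/evaluation, cycling through the given
    inhomogeneity amplitudes.  Returns (frames, masks, amplitudes)."""
    rng = np.random.default_rng(seed)
    frames, masks, amps = [], [], []
    for i in range(n_frames):
        amp = amplitudes[i % len(amplitudes)]
        radius = rng.uniform(0.22, 0.38) * image_size
        lo = radius + 4
        hi = image_size - radius - 4
        cy, cx = rng.uniform(lo, hi, 2)
        geo = SpheroidGeometry(center=(cy, cx), radius=radius,
                               boundary_softness=boundary_softness,
                               inhomogeneity_amplitude=amp)
        stack, gt = make_spheroid_stack(
            PHENOTYPES["sensitive"], geo, duration_h=0.0,
            seed=int(rng.integers(2**31)), image_size=image_size,
        )
        frames.append(stack.phase[0])
        masks.append(gt[0])
        amps.append(amp)
    return frames, masks, amps


def geometry_for_density(cells_per_well: float, base_radius: float = 60.0,
                         image_size: int = 256, **kwargs) -> SpheroidGeometry:
    """Map a seeding density to a spheroid radius (volume ~ cell count).

    Boundary softness scales with the radius so the rendered rim is the
    same *fraction* of every spheroid; per-pixel mean fluorescence is
    then size-free, matching the biology the density study probes.
    """
    radius = base_radius * (cells_per_well / 1.5e4) ** (1.0 / 3.0)
    radius = min(radius, image_size / 2.0 - 8.0)
    kwargs.setdefault("boundary_softness", 0.1 * radius)
    return SpheroidGeometry(center=(image_size / 2, image_size / 2),
                            radius=radius, **kwargs)
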