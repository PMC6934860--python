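"""Fluorescence kinetics from segmented stacks, plus group statistics.

Spheroid mode averages the green channel over the segmented spheroid
mask frame by frame; monolayer mode averages over Laplacian-of-Gaussian
edge pixels, which track the perimeters of the cell regions.  A series
is summarised by its "accumulated" fluorescence — the trapezoidal time
integral of the per-frame mean over the acquisition window, in
a.u.·hours — with the final-frame value kept as an alternative
endpoint summary.  Group comparisons use one-way ANOVA with Tukey's
HSD for the pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_laplace

from .containers import SegMask, TimeLapseStack


class EmptyMaskError(ValueError):
    """Raised when a mean is requested over an empty mask."""


# ---------------------------------------------------------------------------
# per-frame means
# ---------------------------------------------------------------------------

def mean_channel_over_mask(frame: np.ndarray, mask: SegMask | np.ndarray) -> float:
    """Arithmetic mean of channel pixels where the mask is 1."""
    m = mask.pixels if isinstance(mask, SegMask) else np.asarray(mask)
    frame = np.asarray(frame)
    if frame.shape != m.shape:
        raise ValueError("frame and mask shapes differ")
    sel = m.astype(bool)
    if not sel.any():
        raise EmptyMaskError("mask selects no pixels")
    return float(frame[sel].mean())


def log_edge_map(frame: np.ndarray, sigma: float = 2.0,
                 magnitude_percentile: float = 90.0) -> np.ndarray:
    """Laplacian-of-Gaussian edge mask.

    Edge pixels are those whose |LoG response| exceeds the given
    percentile of the nonzero responses.  A uniform frame has no
    nonzero response and yields an empty mask.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    frame = np.asarray(frame, dtype=np.float64)
    resp = np.abs(gaussian_laplace(frame, sigma=sigma))
    nz = resp[resp > 0]
    if nz.size == 0:
        return np.zeros(frame.shape, dtype=np.uint8)
    thr = np.percentile(nz, magnitude_percentile)
    return (resp > thr).astype(np.uint8)


def mean_over_edges(frame: np.ndarray, edges: np.ndarray) -> float:
    """Mean of the channel over edge pixels (definitionally
    ``mean_channel_over_mask`` with the edge map as the mask)."""
    return mean_channel_over_mask(frame, edges)


# ---------------------------------------------------------------------------
# kinetic series
# ---------------------------------------------------------------------------

@dataclass
class KineticSeries:
    """Per-frame mean fluorescence with its accumulated summary."""

    times_h: np.ndarray
    mean_fluorescence: np.ndarray
    channel: str = "green"
    culture_mode: str = "MCS"          # "2D" or "MCS"
    subject: str = ""
    accumulated: float = 0.0           # trapezoidal integral, a.u. * hours
    final_value: float = 0.0           # endpoint alternative summary
    dropped_frames: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.mean_fluorescence = np.asarray(self.mean_fluorescence, dtype=float)
        if len(self.times_h) != len(self.mean_fluorescence):
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times_h) < 0):
            raise ValueError("times must be ascending")


def accumulated_fluorescence(times_h, values) -> float:
    """Trapezoidal time-integral of a mean-fluorescence series."""
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        return 0.0
    return float(np.trapezoid(v, t))


def uptake_timeseries(
    stack: TimeLapseStack,
    masks: list[SegMask] | None = None,
    mode: str = "spheroid",
    channel: str = "green",
    sigma: float = 2.0,
    magnitude_percentile: float = 90.0,
) -> KineticSeries:
    """Per-frame mean fluorescence of a stack.

    mode="spheroid" needs one mask per frame; mode="monolayer-edges"
    derives a LoG edge map from each phase frame instead.  Frames with
    an empty mask/edge map are dropped from the series (and recorded),
    not interpolated.
    """
    img = stack.green if channel == "green" else stack.phase
    if mode == "spheroid":
        if masks is None or len(masks) != stack.n_frames:
            raise ValueError("one mask per frame required in spheroid mode")
        sels = [m.pixels.astype(bool) for m in masks]
    elif mode == "monolayer-edges":
        sels = [log_edge_map(stack.phase[k], sigma, magnitude_percentile).astype(bool)
                for k in range(stack.n_frames)]
    else:
        raise ValueError("mode must be 'spheroid' or 'monolayer-edges'")

    times, values, dropped = [], [], []
    for k in range(stack.n_frames):
        if not sels[k].any():
            dropped.append(k)
            continue
        times.append(stack.times_h[k])
        values.append(float(img[k][sels[k]].mean()))
    series = KineticSeries(
        times_h=np.asarray(times), mean_fluorescence=np.asarray(values),
        channel=channel,
        culture_mode="2D" if mode == "monolayer-edges" else "MCS",
        subject=str(stack.meta.get("phenotype", "")),
        dropped_frames=dropped,
    )
    series.accumulated = accumulated_fluorescence(series.times_h, series.mean_fluorescence)
    series.final_value = float(series.mean_fluorescence[-1]) if len(values) else float("nan")
    return series


def ros_timeseries(
    stack: TimeLapseStack,
    masks: list[SegMask] | None = None,
    mode: str = "spheroid",
    alpha: float = 0.05,
) -> tuple[KineticSeries, bool]:
    """ROS (DCFDA) series plus a monotone-decay flag.

    The flag is True when the fitted linear slope of mean fluorescence
    against time is negative with p < alpha.
    """
    series = uptake_timeseries(stack, masks, mode=mode)
    if len(series.times_h) < 2:
        raise ValueError("ROS series needs at least two frames")
    res = stats.linregress(series.times_h, series.mean_fluorescence)
    decay = bool(res.slope < 0 and res.pvalue < alpha)
    return series, decay


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    labels: list[str]
    f_statistic: float
    p_value: float
    tukey_p: dict[tuple[str, str], float]

    def stars(self, pair: tuple[str, str]) -> str:
        """Conventional significance tiers: * <0.05, ** <0.01, *** <0.001."""
        p = self.tukey_p[pair]
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return "ns"


def anova_tukey(groups: dict[str, np.ndarray | list]) -> GroupComparison:
    """One-way ANOVA F/p plus Tukey-HSD adjusted pairwise p values."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")

    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:  # all values identical: no variance anywhere
        tk = {(a, b): 1.0 for i, a in enumerate(labels) for b in labels[i + 1:]}
        return GroupComparison(labels, 0.0, 1.0, tk)

    f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):  # zero within-group variance, groups differ
        f, p = float("inf"), 0.0
    res = stats.tukey_hsd(*arrays)
    tk = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            tk[(a, labels[j])] = float(res.pvalue[i, j])
    return GroupComparison(labels, float(f), float(p), tk)


def density_independence_check(
    accumulated_by_density: dict[float, np.ndarray | list],
    alpha: float = 0.05,
) -> tuple[GroupComparison, str]:
    """Test whether accumulated calcein depends on seeding density.

    Takes per-density replicate accumulated values (one per seed) and
    returns the ANOVA comparison plus the verdict: "independent" when
    p >= alpha, else "dependent".
    """
    if len(accumulated_by_density) < 2:
        raise ValueError("need at least two densities")
    comp = anova_tukey({str(k): v for k, v in accumulated_by_density.items()})
    verdict = "independent" if comp.p_value >= alpha else "dependent"
    return comp, verdict
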