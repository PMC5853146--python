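"""CE-LIF electropherogram processing.

The processing chain mirrors routine IgG-Fc glycan CE-LIF practice:

1. :func:`detect_peaks` -- baseline-correct the trace (rolling minimum plus
   smoothing), find local maxima above a signal-to-noise threshold, and
   integrate each peak over an apex-centred window clipped at neighbouring
   apexes.
2. :func:`normalize_migration_time` -- rescale apex times so the co-injected
   APTS-maltose internal standard lands at its reference migration time,
   removing run-to-run mobility drift.
3. :func:`fit_gu_calibration` -- fit a monotone piecewise-linear mapping from
   normalized migration time to glucose units (GU) through the APTS-dextran
   ladder peaks (degree of polymerization = GU).
4. :func:`annotate_peaks` -- assign each detected peak to the nearest
   reference peak within the GU tolerance; for comigrating structures the
   dominant structure defines the peak's galactosylation type.
5. :func:`relative_intensities` -- express assigned peak areas as fractions of
   the total assigned area.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import minimum_filter1d, uniform_filter1d

from .reference import ReferenceTable
from .traits import GlycoProfile, ProfileError

__all__ = [
    "Electropherogram",
    "DetectedPeak",
    "CalibrationModel",
    "CalibrationError",
    "detect_peaks",
    "estimate_baseline",
    "normalize_migration_time",
    "fit_gu_calibration",
    "annotate_peaks",
    "relative_intensities",
    "read_electropherogram",
    "write_electropherogram",
    "REFERENCE_MALTOSE_TIME",
]

# Reference migration time (minutes) of the APTS-maltose internal standard in
# the package's nominal separation; a config default, not a published value.
REFERENCE_MALTOSE_TIME = 10.38


class CalibrationError(ValueError):
    """Raised when the dextran-ladder calibration cannot be fitted."""


@dataclass(frozen=True)
class Electropherogram:
    """A single-channel fluorescence trace: time in minutes vs intensity."""

    time: np.ndarray
    intensity: np.ndarray
    channel_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError("time and intensity must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
            raise ValueError("trace contains non-finite values")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass
class DetectedPeak:
    """A quantified peak; GU and assignment are populated downstream."""

    apex_time: float
    area: float
    height: float
    snr: float
    gu: Optional[float] = None
    assigned_peak_id: Optional[int] = None
    trait_class: Optional[str] = None

    def replace(self, **kw) -> "DetectedPeak":
        return dataclasses.replace(self, **kw)


def estimate_baseline(egram: Electropherogram, window_min: float = 0.75) -> np.ndarray:
    """Baseline estimate: rolling minimum followed by smoothing.

    ``window_min`` should be about five times the widest expected peak width
    so that peaks do not pull the baseline up.
    """
    n = max(3, int(round(window_min / egram.dt)) | 1)  # odd window
    rough = minimum_filter1d(egram.intensity, size=n, mode="nearest")
    return uniform_filter1d(rough, size=n, mode="nearest")


def _robust_noise(y: np.ndarray) -> float:
    """Robust noise SD from a low quantile of absolute successive differences.

    The 25th percentile stays inside the noise-only population even when a
    large share of samples sits on peak flanks, where successive differences
    reflect signal slope rather than noise.
    """
    d = np.abs(np.diff(y))
    # for |N(0, s)|, the 25th percentile is s * Phi^-1(0.625) = 0.3186 s
    return float(np.percentile(d, 25)) / (0.3186 * np.sqrt(2.0))


def detect_peaks(
    egram: Electropherogram,
    min_snr: float = 5.0,
    min_height_fraction: float = 0.002,
    baseline_window_min: float = 0.75,
) -> list[DetectedPeak]:
    """Detect and integrate peaks in a trace.

    Peaks are local maxima of the baseline-corrected signal whose height and
    prominence exceed ``min_snr`` times the robust noise estimate and
    ``min_height_fraction`` of the tallest peak.  Each peak is integrated by
    the trapezoid rule over an apex-centred window of +-4.5 estimated sigma
    (sigma from the measured full width at half maximum), clipped at the
    midpoints to neighbouring apexes so flanking peaks never share samples.
    A flat or all-noise trace yields an empty list.
    """
    if egram.time.size < 3:
        raise ValueError("trace must contain at least 3 samples")
    y = egram.intensity - estimate_baseline(egram, baseline_window_min)
    noise = _robust_noise(y)
    # the rolling-minimum baseline sits below the noise mean; recentre the
    # valley level at zero so integration over peak windows is unbiased
    if noise > 0:
        valley = y[y < 5.0 * noise]
        if valley.size:
            y = y - float(np.median(valley))
    ymax = float(np.max(y)) if y.size else 0.0
    if ymax <= 0:
        return []
    floor = max(min_snr * noise, 1e-12 * max(ymax, 1.0))
    idx, _ = signal.find_peaks(y, height=floor, prominence=floor)
    if idx.size == 0:
        return []
    heights = y[idx]
    idx = idx[heights >= min_height_fraction * float(np.max(heights))]
    if idx.size == 0:
        return []

    widths, _, _, _ = signal.peak_widths(y, idx, rel_height=0.5)
    n = y.size
    peaks: list[DetectedPeak] = []
    for k, i in enumerate(idx):
        sigma_pts = max(widths[k] / 2.3548, 1.0)  # FWHM -> Gaussian sigma
        lo = int(max(0, math.floor(i - 4.5 * sigma_pts)))
        hi = int(min(n - 1, math.ceil(i + 4.5 * sigma_pts)))
        if k > 0:
            lo = max(lo, (int(idx[k - 1]) + int(i)) // 2 + 1)
        if k < idx.size - 1:
            hi = min(hi, (int(i) + int(idx[k + 1])) // 2)
        if hi - lo < 2:
            continue
        area = float(np.trapezoid(y[lo : hi + 1], egram.time[lo : hi + 1]))
        if area <= 0:
            continue
        snr = float(y[i] / noise) if noise > 0 else float("inf")
        peaks.append(
            DetectedPeak(
                apex_time=float(egram.time[i]),
                area=area,
                height=float(y[i]),
                snr=max(snr, 0.0),
            )
        )
    peaks.sort(key=lambda p: p.apex_time)
    return peaks


def normalize_migration_time(
    peaks: Sequence[DetectedPeak],
    maltose_time: float,
    reference_maltose_time: float = REFERENCE_MALTOSE_TIME,
) -> list[DetectedPeak]:
    """Rescale apex times so the observed maltose peak lands at the reference
    maltose time.  A pure rescaling: ordering is preserved."""
    if not maltose_time > 0:
        raise ValueError(f"maltose_time must be positive, got {maltose_time}")
    if not reference_maltose_time > 0:
        raise ValueError("reference_maltose_time must be positive")
    factor = reference_maltose_time / maltose_time
    return [p.replace(apex_time=p.apex_time * factor) for p in peaks]


@dataclass(frozen=True)
class CalibrationModel:
    """Monotone piecewise-linear mapping from normalized time to GU."""

    maltose_time: float
    ladder_points: tuple[tuple[float, float], ...]  # (time_min, GU=DP)

    def __post_init__(self) -> None:
        t = np.array([p[0] for p in self.ladder_points])
        g = np.array([p[1] for p in self.ladder_points])
        if t.size < 2 or np.any(np.diff(t) <= 0) or np.any(np.diff(g) <= 0):
            raise CalibrationError("ladder points must be strictly increasing in time and GU")

    @property
    def span(self) -> tuple[float, float]:
        return self.ladder_points[0][0], self.ladder_points[-1][0]

    def __call__(self, time):
        """Map migration time(s) to glucose units; linear continuation of the
        edge segments outside the ladder span."""
        t = np.array([p[0] for p in self.ladder_points])
        g = np.array([p[1] for p in self.ladder_points])
        x = np.asarray(time, dtype=float)
        gu = np.interp(x, t, g)
        # np.interp clamps; continue the first/last segments linearly instead
        lo_slope = (g[1] - g[0]) / (t[1] - t[0])
        hi_slope = (g[-1] - g[-2]) / (t[-1] - t[-2])
        gu = np.where(x < t[0], g[0] + (x - t[0]) * lo_slope, gu)
        gu = np.where(x > t[-1], g[-1] + (x - t[-1]) * hi_slope, gu)
        return float(gu) if np.isscalar(time) else gu


def fit_gu_calibration(
    ladder_peaks: Sequence[DetectedPeak],
    dp_range: tuple[int, int] = (2, 15),
    maltose_time: float = REFERENCE_MALTOSE_TIME,
) -> CalibrationModel:
    """Fit the time -> GU calibration through detected dextran-ladder peaks.

    The i-th ladder peak (in elution order) is the oligomer of degree of
    polymerization ``dp_range[0] + i``; evaluating the mapping at a ladder
    apex returns its DP exactly (knot exactness).
    """
    lo, hi = int(dp_range[0]), int(dp_range[1])
    expected = hi - lo + 1
    if expected < 2:
        raise CalibrationError(f"dp_range {dp_range} spans fewer than 2 oligomers")
    times = [p.apex_time for p in ladder_peaks]
    if len(times) < 4:
        raise CalibrationError(f"need at least 4 ladder peaks, got {len(times)}")
    if len(times) != expected:
        raise CalibrationError(
            f"detected {len(times)} ladder peaks but dp_range {lo}-{hi} requires {expected}"
        )
    if any(b <= a for a, b in zip(times, times[1:])):
        raise CalibrationError("ladder peak times are not strictly increasing")
    points = tuple((float(t), float(dp)) for t, dp in zip(times, range(lo, hi + 1)))
    return CalibrationModel(maltose_time=maltose_time, ladder_points=points)


def annotate_peaks(
    peaks: Sequence[DetectedPeak],
    cal: CalibrationModel,
    ref: ReferenceTable,
) -> list[DetectedPeak]:
    """Assign detected peaks to reference peaks by GU proximity.

    Each detected peak maps to the reference peak with the nearest GU position
    provided the distance is within ``ref.gu_tolerance``; each reference peak
    accepts at most one detected peak (the nearest candidate wins, any other
    candidate stays unassigned).  Unassigned peaks are carried through with
    ``assigned_peak_id`` of None.
    """
    ref_gu = np.array([p.gu_position for p in ref.peaks])
    ref_ids = [p.peak_id for p in ref.peaks]
    out = []
    candidates: dict[int, list[tuple[float, int]]] = {}
    for j, p in enumerate(peaks):
        gu = float(cal(p.apex_time))
        out.append(p.replace(gu=gu, assigned_peak_id=None, trait_class=None))
        if ref_gu.size:
            k = int(np.argmin(np.abs(ref_gu - gu)))
            dist = abs(ref_gu[k] - gu)
            if dist <= ref.gu_tolerance:
                candidates.setdefault(ref_ids[k], []).append((dist, j))
    for rid, cands in candidates.items():
        _, j = min(cands)
        out[j].assigned_peak_id = rid
        out[j].trait_class = ref.trait_class_of(rid)
    return out


def relative_intensities(
    peaks: Sequence[DetectedPeak],
    include_unassigned: bool = False,
    reference: str = "default-22",
) -> GlycoProfile:
    """Relative peak areas: each assigned peak's area over the total area.

    By default the denominator is the summed area of assigned peaks only;
    with ``include_unassigned`` the denominator covers every detected peak and
    the unassigned mass is reported as ``unassigned_fraction``.
    """
    assigned = [p for p in peaks if p.assigned_peak_id is not None]
    if not assigned:
        raise ProfileError("no assigned peaks: cannot form a profile")
    denom_peaks = list(peaks) if include_unassigned else assigned
    total = sum(p.area for p in denom_peaks)
    if total <= 0:
        raise ProfileError("total peak area is not positive")
    areas = {int(p.assigned_peak_id): p.area / total for p in assigned}
    unassigned = 1.0 - sum(areas.values()) if include_unassigned else 0.0
    return GlycoProfile(
        relative_areas=areas,
        reference=reference,
        unassigned_fraction=max(unassigned, 0.0),
    )


# ---------------------------------------------------------------------- I/O

def write_electropherogram(path, egrams: Electropherogram | Sequence[Electropherogram]) -> None:
    """Write one or more channels as TSV (time_min, intensity[, channel_label])."""
    if isinstance(egrams, Electropherogram):
        egrams = [egrams]
    frames = []
    multi = len(egrams) > 1
    for e in egrams:
        df = pd.DataFrame({"time_min": e.time, "intensity": e.intensity})
        if multi:
            df["channel_label"] = e.channel_label
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_electropherogram(path) -> dict[str, Electropherogram]:
    """Read a TSV trace file; returns ``{channel_label: Electropherogram}``
    (single-channel files get the label '')."""
    df = pd.read_csv(path, sep="\t")
    required = {"time_min", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"trace file must have columns {sorted(required)}")
    out: dict[str, Electropherogram] = {}
    if "channel_label" in df.columns:
        for label, sub in df.groupby("channel_label", sort=False):
            out[str(label)] = Electropherogram(
                sub["time_min"].to_numpy(), sub["intensity"].to_numpy(), str(label)
            )
    else:
        out[""] = Electropherogram(df["time_min"].to_numpy(), df["intensity"].to_numpy())
    return out
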