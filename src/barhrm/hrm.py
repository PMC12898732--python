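"""High-resolution melt-curve analysis.

Derivative melting peaks (Savitzky–Golay smoothed −dF/dT with a
relative detection threshold and parabolic apex refinement), two-window
fluorescence normalization, difference curves against a reference
genotype's centroid, centroid-distance genotype calls with a
correlation-based confidence, ΔTm screening support,
predicted-vs-observed Tm reporting, and concordance statistics.

Genotypes are distinguished jointly by Tm and curve shape: calls
minimize the RMS deviation from each genotype centroid over the
analysis range between the normalization windows, so a pure Tm shift
and a shape change are both detected. Temperature shifting (which would
erase Tm information) is deliberately not applied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .io import MeltCurve

__all__ = [
    "MeltPeak",
    "NormalizedCurve",
    "DifferenceCurve",
    "GenotypeCall",
    "ConcordanceSummary",
    "melting_peaks",
    "normalize",
    "difference_curves",
    "call_genotypes",
    "delta_tm",
    "predicted_vs_observed",
    "concordance",
]

#: Margin (°C) between a normalization window and the analysis range.
ANALYSIS_MARGIN = 0.2
#: Auto window width (°C) and derivative quietness threshold.
AUTO_WINDOW_WIDTH = 1.5
QUIET_FRAC = 0.05


@dataclass(frozen=True)
class MeltPeak:
    tm_c: float
    height: float  # −dF/dT at the apex
    prominence: float  # height above the detection threshold
    width_c: float  # full width at half height


@dataclass
class NormalizedCurve:
    sample_id: str
    temperatures: np.ndarray
    values: np.ndarray  # percent scale, ~[0, 100]
    pre_window: tuple[float, float]
    post_window: tuple[float, float]
    declared_label: Optional[str] = None


@dataclass
class DifferenceCurve:
    sample_id: str
    temperatures: np.ndarray
    values: np.ndarray  # normalized(sample) − reference centroid


@dataclass
class GenotypeCall:
    sample_id: str
    call: str
    confidence: float  # [0, 100]
    tm_c: float
    distance_to_centroids: dict[str, float]


@dataclass
class ConcordanceSummary:
    percent_agreement: float  # 1 decimal, round-half-even
    confusion: pd.DataFrame  # rows: truth, cols: call
    discordant: list[str]
    mislabeled: list[str]  # call != declared label


# ---------------------------------------------------------------------------
# Derivative peaks
# ---------------------------------------------------------------------------

def _neg_derivative(curve: MeltCurve, smooth_width_c: float) -> np.ndarray:
    """Smoothed −dF/dT via local quadratic least squares over a window
    spanning ±smooth_width_c around each point."""
    step = curve.step
    half = int(round(smooth_width_c / step))
    window = 2 * half + 1
    if window < 7:
        raise ValueError(
            f"smoothing window of {window} points (< 7); widen smooth_width_c "
            f"or refine the grid"
        )
    if window > curve.temperatures.size:
        raise ValueError("smoothing window exceeds the curve length")
    return -savgol_filter(curve.fluorescence, window, polyorder=2, deriv=1, delta=step)


def melting_peaks(
    curve: MeltCurve,
    smooth_width_c: float = 0.5,
    threshold_frac: float = 0.10,
) -> list[MeltPeak]:
    """Detect melting events as local maxima of smoothed −dF/dT.

    Only maxima at or above ``threshold_frac`` of the global maximum
    count as melting events (the software-style noise threshold); each
    apex is refined by a least-squares parabola over the points within
    ±``smooth_width_c`` of the discrete maximum, which keeps the Tm
    estimate stable against fluorescence noise. Peaks return sorted by
    height, tallest first.
    """
    d = _neg_derivative(curve, smooth_width_c)
    t = curve.temperatures
    step = curve.step
    dmax = float(d.max())
    if dmax <= 0:
        return []
    threshold = threshold_frac * dmax
    idx, _ = find_peaks(d, height=threshold)
    if idx.size == 0:
        return []
    widths = peak_widths(d, idx, rel_height=0.5)[0] * step
    half = int(round(smooth_width_c / step))

    peaks: list[MeltPeak] = []
    for k, i in enumerate(idx):
        lo, hi = max(0, i - half), min(d.size, i + half + 1)
        a, b, c = np.polyfit(t[lo:hi], d[lo:hi], 2)
        if a < 0:
            tm = float(np.clip(-b / (2.0 * a), t[lo], t[hi - 1]))
            height = float(a * tm * tm + b * tm + c)
        else:  # degenerate neighborhood; fall back to the grid point
            tm, height = float(t[i]), float(d[i])
        peaks.append(
            MeltPeak(
                tm_c=float(tm),
                height=float(height),
                prominence=float(height - threshold),
                width_c=float(widths[k]),
            )
        )
    peaks.sort(key=lambda p: -p.height)
    return peaks


# ---------------------------------------------------------------------------
# Normalization and difference curves
# ---------------------------------------------------------------------------

def _auto_windows(
    curve: MeltCurve, smooth_width_c: float, mode: str = "adjacent"
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Place 1.5 °C pre-/post-melt windows in the derivative-quiet baselines.

    The melt transition is the contiguous run of |−dF/dT| above 5 % of
    its maximum around the global derivative apex (isolated noisy
    excursions elsewhere do not shrink the windows). In ``adjacent``
    mode (default, matching how melt-analysis cursors are placed) the
    windows hug the transition, which keeps the fitted baselines from
    being extrapolated far and so keeps normalization noise down; in
    ``ends`` mode they sit at the extremes of the grid.
    """
    d = _neg_derivative(curve, smooth_width_c)
    t = curve.temperatures
    loud = np.abs(d) > QUIET_FRAC * float(np.abs(d).max())
    apex = int(np.argmax(d))
    lo = apex
    while lo > 0 and loud[lo - 1]:
        lo -= 1
    hi = apex
    while hi < t.size - 1 and loud[hi + 1]:
        hi += 1
    if t[lo] <= t[0] or t[hi] >= t[-1]:
        raise ValueError(
            f"sample {curve.sample_id!r}: melt transition reaches the grid edge; "
            "set normalization windows explicitly"
        )
    if mode == "adjacent":
        pre = (max(float(t[0]), float(t[lo]) - AUTO_WINDOW_WIDTH), float(t[lo]))
        post = (float(t[hi]), min(float(t[-1]), float(t[hi]) + AUTO_WINDOW_WIDTH))
    elif mode == "ends":
        pre = (float(t[0]), min(float(t[0]) + AUTO_WINDOW_WIDTH, float(t[lo])))
        post = (max(float(t[-1]) - AUTO_WINDOW_WIDTH, float(t[hi])), float(t[-1]))
    else:
        raise ValueError(f"unknown window placement mode {mode!r}")
    return pre, post


def _fit_line(t: np.ndarray, f: np.ndarray, window: tuple[float, float], which: str):
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if mask.sum() < 2:
        raise ValueError(f"{which} normalization window contains fewer than 2 grid points")
    slope, intercept = np.polyfit(t[mask], f[mask], 1)
    return slope, intercept


def normalize(
    curve: MeltCurve,
    pre_window: Optional[tuple[float, float]] = None,
    post_window: Optional[tuple[float, float]] = None,
    smooth_width_c: float = 0.5,
    window_mode: str = "adjacent",
) -> NormalizedCurve:
    """Two-window fluorescence normalization to the 100 %/0 % scale.

    Straight lines are least-squares fitted in the pre-melt and
    post-melt windows and the trace rescaled as
    ``100·(F − L_post)/(L_pre − L_post)``; the result is invariant to
    per-sample affine transforms of fluorescence with positive gain.
    Windows are auto-placed in the derivative-quiet baselines when not
    given (see ``_auto_windows`` for placement modes).
    """
    t = curve.temperatures
    f = curve.fluorescence
    if pre_window is None or post_window is None:
        auto_pre, auto_post = _auto_windows(curve, smooth_width_c, window_mode)
        pre_window = pre_window or auto_pre
        post_window = post_window or auto_post
    if not (pre_window[0] < pre_window[1] <= post_window[0] < post_window[1]):
        raise ValueError("windows must be disjoint with pre below post")

    pre_slope, pre_int = _fit_line(t, f, pre_window, "pre-melt")
    post_slope, post_int = _fit_line(t, f, post_window, "post-melt")
    l_pre = pre_slope * t + pre_int
    l_post = post_slope * t + post_int

    inner = (t >= pre_window[1] - 1e-9) & (t <= post_window[0] + 1e-9)
    denom = l_pre - l_post
    # The pre-melt line must stay above the post-melt line by a non-vanishing
    # margin (relative to the trace's dynamic range) across the melt region.
    if np.any(denom[inner] <= 1e-6 * max(float(np.ptp(f)), 1e-12)):
        raise ValueError(
            f"sample {curve.sample_id!r}: degenerate curve — pre-melt baseline does "
            "not stay above post-melt baseline between the windows"
        )
    values = 100.0 * (f - l_post) / denom
    return NormalizedCurve(
        sample_id=curve.sample_id,
        temperatures=t.copy(),
        values=values,
        pre_window=(float(pre_window[0]), float(pre_window[1])),
        post_window=(float(post_window[0]), float(post_window[1])),
        declared_label=curve.declared_label,
    )


def _check_shared_grid(norms: Sequence[NormalizedCurve]) -> np.ndarray:
    grid = norms[0].temperatures
    for n in norms[1:]:
        if n.temperatures.shape != grid.shape or not np.allclose(n.temperatures, grid):
            raise ValueError("normalized curves are not on a shared temperature grid")
    return grid


def difference_curves(
    norms: Sequence[NormalizedCurve],
    reference_label: str,
    labels: Mapping[str, str],
) -> list[DifferenceCurve]:
    """Subtract the reference genotype's centroid from every sample.

    ``labels`` maps sample_id to genotype label; samples carrying
    ``reference_label`` define the centroid (their differences average
    to zero by construction).
    """
    grid = _check_shared_grid(norms)
    ref = [n for n in norms if labels.get(n.sample_id) == reference_label]
    if not ref:
        raise ValueError(f"no sample carries the reference label {reference_label!r}")
    centroid = np.mean([n.values for n in ref], axis=0)
    return [
        DifferenceCurve(sample_id=n.sample_id, temperatures=grid.copy(),
                        values=n.values - centroid)
        for n in norms
    ]


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------

def _primary_tm(peaks: Sequence[MeltPeak], sample_id: str) -> float:
    if not peaks:
        raise ValueError(f"sample {sample_id!r}: no melting peak detected")
    return peaks[0].tm_c


def call_genotypes(
    norms: Sequence[NormalizedCurve],
    diffs: Sequence[DifferenceCurve],
    peaks: Mapping[str, Sequence[MeltPeak]],
    reference_sets: Mapping[str, Sequence[str]],
) -> list[GenotypeCall]:
    """Assign each sample to the genotype with the nearest centroid.

    Per-genotype centroids are the mean normalized curves of the
    reference samples; distance is RMS deviation over the analysis
    range (inside both normalization windows by a 0.2 °C margin).
    Confidence is 100× the positive part of the Pearson correlation
    between the sample's curve and its assigned centroid over that
    range (mean-centered), so a reference sample identical to its
    centroid scores 100. Distance ties break toward the genotype whose
    centroid Tm is closest to the sample's, then lexicographically.
    """
    for label, ids in reference_sets.items():
        if not ids:
            raise ValueError(f"reference set for genotype {label!r} is empty")
    grid = _check_shared_grid(norms)
    by_id = {n.sample_id: n for n in norms}

    pre_hi = max(n.pre_window[1] for n in norms)
    post_lo = min(n.post_window[0] for n in norms)
    window = (grid >= pre_hi + ANALYSIS_MARGIN) & (grid <= post_lo - ANALYSIS_MARGIN)
    if window.sum() < 3:
        raise ValueError("analysis range between the normalization windows is empty")

    centroids: dict[str, np.ndarray] = {}
    centroid_tm: dict[str, float] = {}
    for label, ids in reference_sets.items():
        missing = [s for s in ids if s not in by_id]
        if missing:
            raise ValueError(f"reference sample(s) {missing} not among the normalized curves")
        centroids[label] = np.mean([by_id[s].values for s in ids], axis=0)
        centroid_tm[label] = float(np.mean([_primary_tm(peaks[s], s) for s in ids]))

    calls: list[GenotypeCall] = []
    for n in norms:
        sample_tm = _primary_tm(peaks[n.sample_id], n.sample_id)
        dist = {
            label: float(np.sqrt(np.mean((n.values[window] - c[window]) ** 2)))
            for label, c in centroids.items()
        }
        dmin = min(dist.values())
        tied = [lab for lab, d in dist.items() if d <= dmin + 1e-12]
        call = min(tied, key=lambda lab: (abs(centroid_tm[lab] - sample_tm), lab))

        x = n.values[window] - n.values[window].mean()
        y = centroids[call][window] - centroids[call][window].mean()
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        corr = float(x @ y / (nx * ny)) if nx > 0 and ny > 0 else 1.0
        confidence = 100.0 * max(0.0, min(1.0, corr))
        calls.append(
            GenotypeCall(
                sample_id=n.sample_id,
                call=call,
                confidence=confidence,
                tm_c=sample_tm,
                distance_to_centroids=dist,
            )
        )
    return calls


@dataclass
class CohortAnalysis:
    norms: list[NormalizedCurve]
    diffs: list[DifferenceCurve]
    peaks: dict[str, list[MeltPeak]]
    calls: list[GenotypeCall]


def analyze_cohort(
    curves: Sequence[MeltCurve],
    reference_sets: Mapping[str, Sequence[str]],
    reference_label: Optional[str] = None,
    smooth_width_c: float = 0.5,
    threshold_frac: float = 0.10,
    window_mode: str = "adjacent",
) -> CohortAnalysis:
    """Full melt-curve workflow: peaks → normalization → difference curves
    against the reference genotype → genotype calls.

    ``reference_sets`` maps genotype labels to verified sample ids;
    ``reference_label`` picks the difference-curve baseline genotype
    (default: lexicographically first reference label).
    """
    for label, ids in reference_sets.items():
        if not ids:
            raise ValueError(f"reference set for genotype {label!r} is empty")
    peaks = {
        c.sample_id: melting_peaks(c, smooth_width_c, threshold_frac) for c in curves
    }
    norms = [normalize(c, smooth_width_c=smooth_width_c, window_mode=window_mode)
             for c in curves]
    if reference_label is None:
        reference_label = min(reference_sets)
    ref_labels = {
        sid: label for label, ids in reference_sets.items() for sid in ids
    }
    diffs = difference_curves(norms, reference_label, ref_labels)
    calls = call_genotypes(norms, diffs, peaks, reference_sets)
    return CohortAnalysis(norms=norms, diffs=diffs, peaks=peaks, calls=calls)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def delta_tm(group_peaks: Mapping[str, Sequence[MeltPeak]]) -> dict[tuple[str, str], float]:
    """|group-mean Tm difference| for every unordered label pair."""
    means: dict[str, float] = {}
    for label, plist in group_peaks.items():
        if not plist:
            raise ValueError(f"group {label!r} has no melting peaks")
        means[label] = float(np.mean([p.tm_c for p in plist]))
    return {
        tuple(sorted((a, b))): abs(means[a] - means[b])
        for a, b in itertools.combinations(sorted(means), 2)
    }


def predicted_vs_observed(
    predictions: Mapping[str, float],
    observed: Mapping[str, float],
    band: tuple[float, float] = (0.7, 1.5),
) -> pd.DataFrame:
    """Observed-minus-predicted Tm per label, flagged against the expected
    dye-stabilization band (report only — no assertion)."""
    if set(predictions) != set(observed):
        raise ValueError(
            f"label mismatch: predictions {sorted(predictions)} vs observed {sorted(observed)}"
        )
    rows = []
    for label in sorted(predictions):
        delta = observed[label] - predictions[label]
        rows.append(
            {
                "label": label,
                "predicted_tm_c": predictions[label],
                "observed_tm_c": observed[label],
                "delta_c": delta,
                "in_band": bool(band[0] <= delta <= band[1]),
            }
        )
    return pd.DataFrame(rows)


def concordance(
    calls: Sequence[GenotypeCall],
    truth: Mapping[str, str],
    declared: Optional[Mapping[str, str]] = None,
) -> ConcordanceSummary:
    """Agreement between genotype calls and an independent truth labeling.

    Percent agreement is reported to 1 decimal (round-half-even). When
    declared (as-sold) labels are supplied, samples whose call differs
    from their declared label are listed as mislabeled products.
    """
    missing = [c.sample_id for c in calls if c.sample_id not in truth]
    if missing:
        raise ValueError(f"truth table missing sample(s) {missing}")
    call_s = pd.Series({c.sample_id: c.call for c in calls})
    truth_s = pd.Series({c.sample_id: truth[c.sample_id] for c in calls})
    agree = (call_s == truth_s)
    percent = round(100.0 * agree.mean(), 1)
    confusion = pd.crosstab(truth_s, call_s, rownames=["truth"], colnames=["call"])
    discordant = sorted(call_s.index[~agree])
    mislabeled: list[str] = []
    if declared is not None:
        mislabeled = sorted(
            c.sample_id for c in calls
            if c.sample_id in declared and c.call != declared[c.sample_id]
        )
    return ConcordanceSummary(
        percent_agreement=float(percent),
        confusion=confusion,
        discordant=discordant,
        mislabeled=mislabeled,
    )
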