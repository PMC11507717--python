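"""Calcium-trace normalization, smoothing, and pre/post comparison.

Worm-to-worm variability in GCaMP expression is removed by dividing every
frame of a worm's pre- and post-exposure recordings by the bottom 5th
percentile of the *pre* (naive) trace, so that a value of 1 means "the
healthy worm's baseline".  Traces are then smoothed with a centered moving
average over a 6-second window (94 samples at the 15.625 Hz acquisition
rate) before histogramming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_FPS = 15.625


@dataclass(frozen=True)
class CalciumTrace:
    """Raw fluorescence time series for one neuron in one worm."""

    worm_id: str
    neuron: str
    condition: str  # 'pre' | 'post'
    fps: float
    values: np.ndarray  # arbitrary units, strictly positive

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.condition not in ("pre", "post"):
            raise ValueError(f"condition must be 'pre' or 'post', got {self.condition!r}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if values.ndim != 1 or values.size == 0:
            raise ValueError("trace must be a non-empty 1-D array")
        if np.any(values <= 0):
            raise ValueError("fluorescence intensities must be strictly positive")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fps


@dataclass(frozen=True)
class NormalizedTrace:
    """Trace in units of fold-over-naive-baseline."""

    worm_id: str
    neuron: str
    condition: str
    fps: float
    values: np.ndarray
    baseline: float  # the 5th-percentile divisor, raw units
    smoothing_window_s: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


def normalize_pair(pre: CalciumTrace, post: CalciumTrace,
                   percentile: float = 5.0,
                   method: str = "linear") -> tuple:
    """Normalize a worm's pre/post traces by the pre-trace baseline.

    The baseline is the ``percentile``-th percentile (linear interpolation
    between order statistics by default; any numpy percentile ``method`` is
    accepted) of the *pre* trace; both traces are divided by this single
    value.  Post traces never define their own baseline.
    """
    if (pre.worm_id, pre.neuron) != (post.worm_id, post.neuron):
        raise ValueError("pre and post traces must come from the same worm and neuron")
    baseline = float(np.percentile(pre.values, percentile, method=method))
    if baseline <= 0:
        raise ValueError(f"non-positive baseline {baseline}")
    mk = lambda t: NormalizedTrace(
        worm_id=t.worm_id, neuron=t.neuron, condition=t.condition,
        fps=t.fps, values=t.values / baseline, baseline=baseline,
    )
    return mk(pre), mk(post)


def smooth_trace(trace: NormalizedTrace, window_s: float = 6.0) -> NormalizedTrace:
    """Centered moving average over ``window_s`` seconds.

    The window is ``round(window_s * fps)`` samples (94 at 15.625 fps).
    An even window is centered with one extra sample on the left.  At the
    edges the window is truncated and renormalized, so the output has the
    same length as the input.
    """
    window = int(round(window_s * trace.fps))
    if window < 1:
        raise ValueError("window must span at least one sample")
    x = trace.values
    n = x.size
    left = window // 2
    right = window - 1 - left
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)
    return NormalizedTrace(
        worm_id=trace.worm_id, neuron=trace.neuron, condition=trace.condition,
        fps=trace.fps, values=smoothed, baseline=trace.baseline,
        smoothing_window_s=window_s,
    )


@dataclass(frozen=True)
class ActivityHistogram:
    """Pooled and per-worm activity histograms on common bin edges."""

    bin_edges: np.ndarray
    counts: np.ndarray  # pooled frame counts
    frequencies: np.ndarray  # pooled, sums to 1
    per_worm: dict  # worm_id -> frequency array
    n_worms: int


def activity_histogram(traces, bins) -> ActivityHistogram:
    """Histogram of normalized activity pooled across worms.

    Frames are pooled with equal weight per frame; per-worm frequency
    histograms are retained as well, so worm-weighted mixtures can be
    formed by the caller.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to histogram")
    bins = np.asarray(bins, dtype=float)
    pooled = np.concatenate([t.values for t in traces])
    counts, edges = np.histogram(pooled, bins=bins)
    per_worm = {}
    for t in traces:
        c, _ = np.histogram(t.values, bins=bins)
        per_worm[t.worm_id] = c / max(c.sum(), 1)
    return ActivityHistogram(
        bin_edges=edges, counts=counts,
        frequencies=counts / max(counts.sum(), 1),
        per_worm=per_worm, n_worms=len(traces),
    )


def compare_pre_post(pre_set, post_set) -> tuple:
    """Median activity shift (post minus pre) and a rank-sum p-value.

    The effect size is the difference of pooled medians.  The test is a
    two-sided Wilcoxon rank-sum on *per-worm* medians rather than pooled
    frames, so that the heavy within-worm frame dependence does not
    inflate significance.
    """
    pre_set, post_set = list(pre_set), list(post_set)
    if not pre_set or not post_set:
        raise ValueError("need at least one worm per condition")
    pooled_pre = np.concatenate([t.values for t in pre_set])
    pooled_post = np.concatenate([t.values for t in post_set])
    effect = float(np.median(pooled_post) - np.median(pooled_pre))
    med_pre = [float(np.median(t.values)) for t in pre_set]
    med_post = [float(np.median(t.values)) for t in post_set]
    if len(med_pre) > 1 or len(med_post) > 1:
        res = stats.mannwhitneyu(med_post, med_pre, alternative="two-sided")
        pvalue = float(res.pvalue)
    else:
        pvalue = float("nan")  # a single worm per arm cannot support a rank test
    return effect, pvalue
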