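"""From per-line +/-ATR replicate measurements to screen phenotype vectors.

Each transgenic line is measured with (+ATR, photoinhibition effective)
and without (-ATR, light-insensitive control) the opsin cofactor.  The
screen phenotype of a line is the mean difference between conditions for
a behavioral metric, gated by a significance test: lines whose inhibition
effect does not pass the test are assigned a phenotype of exactly zero.
The resulting vector, ordered like the measurement matrix's rows, is the
P of the linear system M w = P.

Sign convention: positive phenotype = inhibition increases aversion
(more exits, longer re-entry latency, lower retention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior import OccupancyCurve


@dataclass(frozen=True)
class LinePhenotype:
    """Replicate values for one line, one metric, both ATR conditions."""

    line_id: str
    metric: str
    plus_atr: np.ndarray
    minus_atr: np.ndarray

    def __post_init__(self):
        plus = np.asarray(self.plus_atr, dtype=float)
        minus = np.asarray(self.minus_atr, dtype=float)
        object.__setattr__(self, "plus_atr", plus)
        object.__setattr__(self, "minus_atr", minus)
        if not (np.isfinite(plus).all() and np.isfinite(minus).all()):
            raise ValueError(f"line {self.line_id}: replicate values must be finite")


@dataclass(frozen=True)
class PhenotypeVector:
    """Per-line phenotype scalars with their significance record.

    ``values[i]`` is exactly 0 whenever ``pvalues[i] > alpha`` — the
    zeroing of non-significant lines is part of the vector's contract,
    not a presentation choice.
    """

    metric: str
    line_ids: tuple
    values: np.ndarray
    pvalues: np.ndarray
    alpha: float

    def __post_init__(self):
        object.__setattr__(self, "line_ids", tuple(self.line_ids))
        values = np.asarray(self.values, dtype=float)
        pvals = np.asarray(self.pvalues, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pvalues", pvals)
        if not len(self.line_ids) == len(values) == len(pvals):
            raise ValueError("line_ids, values and pvalues must have equal length")
        if np.any(values[pvals > self.alpha] != 0):
            raise ValueError("non-significant lines must have phenotype exactly 0")

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.pvalues <= self.alpha))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "line_id": list(self.line_ids), "metric": self.metric,
            "value": self.values, "pvalue": self.pvalues, "alpha": self.alpha,
        })


def differential_retention_index(curve_minus: OccupancyCurve,
                                 curve_plus: OccupancyCurve) -> float:
    """Area between paired occupancy curves, in occupancy-hours.

    Trapezoidal integral of (no-inhibition minus inhibition) occupancy
    over the assay; positive when inhibition accelerates lawn evacuation.
    """
    if not np.array_equal(curve_minus.times, curve_plus.times):
        raise ValueError("occupancy curves must share an identical time grid")
    diff = curve_minus.fraction_on - curve_plus.fraction_on
    return float(np.trapezoid(diff, curve_minus.times))


def retention_significance(index: float, control_indices,
                           z_threshold: float = 2.0) -> tuple:
    """Gate a retention index against the spread of uninhibited controls.

    Returns ``(significant, z)`` where z = (index - mean(controls)) /
    sd(controls) and significance means |z| >= ``z_threshold``.
    """
    control = np.asarray(control_indices, dtype=float)
    if control.size < 3:
        raise ValueError("need at least 3 control indices")
    sd = control.std(ddof=1)
    if sd == 0:
        raise ValueError("control indices have zero standard deviation; "
                         "z-score is undefined")
    z = float((index - control.mean()) / sd)
    return abs(z) >= z_threshold, z


def metric_difference_test(pheno: LinePhenotype,
                           equal_var: bool = False) -> tuple:
    """Two-sided t-test of +ATR vs -ATR replicates for one line.

    Welch's unequal-variance variant by default (replicate counts are
    small and variances unknown); set ``equal_var`` for the pooled test.
    Returns ``(mean(plus) - mean(minus), p)``.  Degenerate zero-variance
    inputs are resolved by the means: p = 1 if they agree, p = 0 if not.
    """
    plus, minus = pheno.plus_atr, pheno.minus_atr
    if len(plus) < 2 or len(minus) < 2:
        raise ValueError(
            f"line {pheno.line_id}: need >= 2 replicates per condition")
    diff = float(plus.mean() - minus.mean())
    if plus.std() == 0 and minus.std() == 0:
        return diff, 1.0 if diff == 0 else 0.0
    res = stats.ttest_ind(plus, minus, equal_var=equal_var)
    return diff, float(res.pvalue)


def build_phenotype_vector(phenos, metric: str, alpha: float = 0.05,
                           line_order=None, equal_var: bool = False,
                           fdr: bool = False) -> PhenotypeVector:
    """Assemble the screen phenotype vector for one metric.

    ``phenos`` maps one :class:`LinePhenotype` per line; ``line_order``
    (typically the measurement matrix's ``line_ids``) fixes the ordering.
    Non-significant lines get exactly 0.  No multiple-testing correction
    is applied across lines by default; ``fdr`` switches the gate to
    Benjamini-Hochberg adjusted p-values.
    """
    by_line = {p.line_id: p for p in phenos}
    if line_order is None:
        line_order = tuple(by_line)
    missing = [lid for lid in line_order if lid not in by_line]
    if missing:
        raise KeyError(f"missing phenotypes for lines: {missing}")

    diffs, pvals = [], []
    for lid in line_order:
        p = by_line[lid]
        if p.metric != metric:
            raise ValueError(f"line {lid} holds metric {p.metric!r}, not {metric!r}")
        d, pv = metric_difference_test(p, equal_var=equal_var)
        diffs.append(d)
        pvals.append(pv)
    pvals = np.asarray(pvals)
    gate = multipletests(pvals, alpha=alpha, method="fdr_bh")[1] if fdr else pvals
    values = np.where(gate <= alpha, diffs, 0.0)
    return PhenotypeVector(metric=metric, line_ids=tuple(line_order),
                           values=values, pvalues=np.asarray(gate), alpha=alpha)


def phenotypes_from_table(table: pd.DataFrame, metric: str) -> list:
    """Split a tidy replicate table into per-line :class:`LinePhenotype`.

    Expects columns line_id, metric, condition (plusATR/minusATR), value;
    line order follows first appearance in the table.
    """
    sub = table[table["metric"] == metric]
    out = []
    for lid in sub["line_id"].drop_duplicates():
        rows = sub[sub["line_id"] == lid]
        out.append(LinePhenotype(
            line_id=str(lid), metric=metric,
            plus_atr=rows.loc[rows["condition"] == "plusATR", "value"].to_numpy(),
            minus_atr=rows.loc[rows["condition"] == "minusATR", "value"].to_numpy(),
        ))
    return out
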