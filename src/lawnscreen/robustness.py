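"""Robustness and recoverability diagnostics for the screen inference.

Three empirical checks of how stable the inferred circuit is:

* **Matrix corruption** — variable opsin expression means a nominal "1" in
  the incidence matrix may really be a partial expression level.  A fixed
  fraction of the nonzero entries is replaced with values in [0, 0.5] and
  the inference re-run over many corrupted matrices.
* **Promoter removal** — would a small subset of lines drive the result?
  1-5 rows are removed at random, many times, and the inference re-run on
  the reduced screen.
* **Planted-truth recovery** — fresh k-sparse ground truths are planted
  and pushed through the full pipeline (replicates, significance gate,
  inference), yielding per-neuron recovery and true-positive rates and
  overall false-positive/false-negative rates.

All rates are conditional frequencies over repetitions; definitions are
stated on :func:`recovery_simulation` since no single convention exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import SUPPORT_REL_TOL, ElbowScreenLasso, ScreenLasso, _support
from .matrix import MeasurementMatrix
from .screen import build_phenotype_vector, phenotypes_from_table
from .synthetic import plant_ground_truth, simulate_phenotypes


@dataclass(frozen=True)
class RobustnessReport:
    """Per-neuron and overall robustness rates plus the full run config."""

    neuron_ids: tuple
    per_neuron: pd.DataFrame  # columns: selection_frequency [, recovery_rate, true_positive_rate]
    overall: dict  # e.g. false_positive_rate / false_negative_rate
    config: dict

    def __post_init__(self):
        for col in self.per_neuron.columns:
            vals = self.per_neuron[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"rate column {col!r} outside [0, 1]")

    @property
    def n_reps(self) -> int:
        return int(self.config["n_reps"])


def corrupt_matrix(M: MeasurementMatrix, fraction: float = 0.1,
                   low: float = 0.0, high: float = 0.5,
                   seed: int = 0) -> MeasurementMatrix:
    """Corrupt a fixed fraction of the *nonzero* entries.

    Exactly ``round(fraction * nnz)`` distinct nonzero positions, chosen
    uniformly without replacement, are replaced by Uniform(low, high)
    draws.  Zero entries are never touched and the input is unchanged.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if not 0 <= low < high <= 1:
        raise ValueError("need 0 <= low < high <= 1")
    rng = np.random.default_rng(seed)
    values = M.values.copy()
    rows, cols = np.nonzero(values)
    n_corrupt = int(round(fraction * len(rows)))
    pick = rng.choice(len(rows), size=n_corrupt, replace=False)
    values[rows[pick], cols[pick]] = rng.uniform(low, high, size=n_corrupt)
    return MeasurementMatrix(line_ids=M.line_ids, neuron_ids=M.neuron_ids,
                             values=values,
                             class_annotation=dict(M.class_annotation))


def _solve(M_values, P_values, lam_policy, lam, neuron_like, **elbow_kwargs):
    """One inference under the given penalty policy; returns weights."""
    if lam_policy == "fixed":
        if lam is None:
            raise ValueError("lam_policy='fixed' requires lam")
        return ScreenLasso(alpha=lam).fit(M_values, P_values).coef_
    if lam_policy == "elbow":
        return ElbowScreenLasso(**elbow_kwargs).fit(M_values, P_values).coef_
    raise ValueError(f"unknown lam_policy {lam_policy!r}")


def _selected(w, baseline_scale=None):
    """Support indices; judged against the *baseline* solution's dominant
    weight when one is given.  A corrupted entry (say 0.25 instead of 1)
    inflates its neuron's weight fourfold, and a per-solution relative
    threshold would then spuriously drop every other neuron — anchoring
    the dominance cut to the unperturbed solution avoids that artifact."""
    if baseline_scale is None or baseline_scale == 0:
        return _support(w)
    return np.nonzero(np.abs(w) > SUPPORT_REL_TOL * baseline_scale)[0]


def corruption_scan(M: MeasurementMatrix, P, n_matrices: int = 1000,
                    fraction: float = 0.1, low: float = 0.0, high: float = 0.5,
                    lam_policy: str = "fixed", lam: float | None = None,
                    seed: int = 0, **elbow_kwargs) -> RobustnessReport:
    """Selection frequency of each neuron across corrupted matrices."""
    if lam_policy == "fixed" and lam is None:
        est = ElbowScreenLasso(**elbow_kwargs).fit(M, P)
        lam = est.lam_
    P_values = P.values if hasattr(P, "values") else np.asarray(P, float)
    baseline = _solve(M.values, P_values, lam_policy, lam, M, **elbow_kwargs)
    scale = float(np.max(np.abs(baseline)))
    rng = np.random.default_rng(seed)
    counts = np.zeros(M.n_neurons)
    for _ in range(n_matrices):
        Mc = corrupt_matrix(M, fraction, low, high,
                            seed=int(rng.integers(2 ** 31)))
        w = _solve(Mc.values, P_values, lam_policy, lam, M, **elbow_kwargs)
        counts[_selected(w, scale)] += 1
    per_neuron = pd.DataFrame(
        {"selection_frequency": counts / n_matrices},
        index=list(M.neuron_ids))
    return RobustnessReport(
        neuron_ids=M.neuron_ids, per_neuron=per_neuron, overall={},
        config={"n_reps": n_matrices, "fraction": fraction, "low": low,
                "high": high, "lam_policy": lam_policy, "lam": lam,
                "seed": seed})


def promoter_removal_scan(M: MeasurementMatrix, replicate_table: pd.DataFrame,
                          metric: str, alpha: float = 0.05,
                          n_remove: int = 5, reps_per_level: int = 200,
                          lam_policy: str = "elbow", lam: float | None = None,
                          seed: int = 0, **elbow_kwargs) -> dict:
    """Selection frequencies after random removal of 1..n_remove lines.

    For each removal level r, ``reps_per_level`` draws remove r distinct
    rows; the phenotype vector is rebuilt on the remaining lines (the
    per-line significance test does not involve other lines, so this is a
    row subset) and the weights re-inferred.  Draws that leave a neuron
    with no covering line are kept but the neuron is flagged
    unidentifiable for that draw (its column is all zero).  Returns
    ``{r: RobustnessReport}``; with the defaults that is 5 levels x 200
    reps = 1000 inferences.
    """
    if n_remove >= M.n_lines:
        raise ValueError("cannot remove as many lines as the screen has")
    P_full = build_phenotype_vector(
        phenotypes_from_table(replicate_table, metric), metric, alpha=alpha,
        line_order=M.line_ids)
    baseline = _solve(M.values, P_full.values, lam_policy, lam, M,
                      **elbow_kwargs)
    scale = float(np.max(np.abs(baseline)))
    rng = np.random.default_rng(seed)
    reports = {}
    for r in range(1, n_remove + 1):
        counts = np.zeros(M.n_neurons)
        uncovered = np.zeros(M.n_neurons)
        for _ in range(reps_per_level):
            drop = rng.choice(M.n_lines, size=r, replace=False)
            keep = np.setdiff1d(np.arange(M.n_lines), drop)
            Mv = M.values[keep]
            uncovered += Mv.sum(axis=0) == 0
            w = _solve(Mv, P_full.values[keep], lam_policy, lam, M,
                       **elbow_kwargs)
            counts[_selected(w, scale)] += 1
        per_neuron = pd.DataFrame(
            {"selection_frequency": counts / reps_per_level,
             "unidentifiable_frequency": uncovered / reps_per_level},
            index=list(M.neuron_ids))
        reports[r] = RobustnessReport(
            neuron_ids=M.neuron_ids, per_neuron=per_neuron, overall={},
            config={"n_reps": reps_per_level, "n_remove": r, "alpha": alpha,
                    "lam_policy": lam_policy, "lam": lam, "seed": seed})
    return reports


def recovery_simulation(M: MeasurementMatrix, k: int, noise: float,
                        n_reps: int = 100, lam_policy: str = "elbow",
                        lam: float | None = None, seed: int = 0,
                        weight_low: float = 20.0, weight_high: float = 60.0,
                        n_replicates: int = 5, alpha: float = 0.05,
                        metric: str = "reentry_latency",
                        **elbow_kwargs) -> RobustnessReport:
    """Planted-truth recovery rates through the full screen pipeline.

    Each repetition plants a fresh k-sparse truth, simulates
    ``n_replicates`` +/-ATR replicates per line with Gaussian replicate
    noise of SD ``noise`` (same units as the phenotype), builds the gated
    phenotype vector and infers weights under ``lam_policy``.  Rates:

    * per-neuron ``recovery_rate``   = P(selected | planted),
    * per-neuron ``true_positive_rate`` = P(planted | selected),
    * overall ``false_positive_rate`` = mean fraction of the inferred
      support outside the truth,
    * overall ``false_negative_rate`` = mean fraction of the truth missed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    planted_count = np.zeros(M.n_neurons)
    selected_count = np.zeros(M.n_neurons)
    both_count = np.zeros(M.n_neurons)
    fp_fracs, fn_fracs = [], []
    for _ in range(n_reps):
        truth = plant_ground_truth(
            M, k, weight_low, weight_high,
            noise_sd={"exit_rate": noise, "reentry_latency": noise},
            seed=int(rng.integers(2 ** 31)))
        table = simulate_phenotypes(M, truth, n_reps=n_replicates,
                                    seed=int(rng.integers(2 ** 31)))
        P = build_phenotype_vector(
            phenotypes_from_table(table, metric), metric, alpha=alpha,
            line_order=M.line_ids)
        w = _solve(M.values, P.values, lam_policy, lam, M, **elbow_kwargs)
        sel = np.zeros(M.n_neurons, dtype=bool)
        sel[_support(w)] = True
        pla = np.zeros(M.n_neurons, dtype=bool)
        pla[truth.support(metric)] = True
        planted_count += pla
        selected_count += sel
        both_count += sel & pla
        n_sel = int(sel.sum())
        fp_fracs.append((sel & ~pla).sum() / n_sel if n_sel else 0.0)
        fn_fracs.append((pla & ~sel).sum() / k)
    with np.errstate(invalid="ignore"):
        recovery = np.where(planted_count > 0, both_count
                            / np.maximum(planted_count, 1), np.nan)
        tpr = np.where(selected_count > 0, both_count
                       / np.maximum(selected_count, 1), np.nan)
    per_neuron = pd.DataFrame(
        {"recovery_rate": recovery, "true_positive_rate": tpr,
         "selection_frequency": selected_count / n_reps},
        index=list(M.neuron_ids))
    return RobustnessReport(
        neuron_ids=M.neuron_ids, per_neuron=per_neuron,
        overall={"false_positive_rate": float(np.mean(fp_fracs)),
                 "false_negative_rate": float(np.mean(fn_fracs))},
        config={"n_reps": n_reps, "k": k, "noise": noise,
                "lam_policy": lam_policy, "lam": lam, "seed": seed,
                "weight_low": weight_low, "weight_high": weight_high,
                "n_replicates": n_replicates, "alpha": alpha,
                "metric": metric})
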