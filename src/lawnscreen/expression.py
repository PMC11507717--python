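"""Expression specificity: relative expression and inverse participation ratio.

For a gene with mean expression :math:`E_i` in neuron type *i*, define the
participation probabilities :math:`p_i = E_i / \\sum_i E_i`.  The inverse
participation ratio

.. math:: \\mathrm{IPR} = 1 / \\sum_i p_i^2

is the effective number of neuron types expressing the gene: 1 for a gene
expressed in a single type, N for perfectly uniform expression over N
types.  Candidate neuropeptides for a neuron of interest are genes that
are both specific (low IPR) and maximally expressed in that neuron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x neuron-type mean expression table (non-negative)."""

    gene_ids: tuple
    neuron_ids: tuple
    E: np.ndarray

    def __post_init__(self):
        E = np.asarray(self.E, dtype=float)
        object.__setattr__(self, "E", E)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "neuron_ids", tuple(self.neuron_ids))
        if E.shape != (len(self.gene_ids), len(self.neuron_ids)):
            raise ValueError("expression matrix shape does not match labels")
        if np.any(E < 0):
            raise ValueError("expression values must be non-negative")

    def gene(self, gene_id: str) -> np.ndarray:
        return self.E[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.E, index=list(self.gene_ids),
                            columns=list(self.neuron_ids)).rename_axis("gene_id")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(gene_ids=tuple(str(g) for g in frame.index),
                   neuron_ids=tuple(str(n) for n in frame.columns),
                   E=frame.to_numpy(dtype=float))


def relative_expression(e_gene) -> np.ndarray:
    """Expression divided by the maximum over neurons; max entry is 1."""
    e = np.asarray(e_gene, dtype=float)
    m = e.max()
    if m <= 0:
        raise ValueError("cannot compute relative expression of an all-zero gene")
    return e / m


def inverse_participation_ratio(e_gene) -> float:
    """IPR = 1 / sum_i p_i^2, with p_i the gene's expression fractions."""
    e = np.asarray(e_gene, dtype=float)
    total = e.sum()
    if total <= 0:
        raise ValueError("IPR undefined for an all-zero gene")
    p = e / total
    return float(1.0 / np.sum(p * p))


def candidate_neuropeptides(E: ExpressionMatrix, target_neuron: str,
                            ipr_max: float = 5.0,
                            expr_quantile: float = 0.75) -> pd.DataFrame:
    """Rank genes highly and uniquely expressed in a target neuron type.

    A candidate must (i) have IPR <= ``ipr_max`` (specific), (ii) reach
    its maximal expression in ``target_neuron`` (relative expression 1
    there), and (iii) have peak expression above the ``expr_quantile``
    quantile of peak expression across all genes (highly expressed).
    Candidates are ranked by ascending IPR (most specific first).
    """
    if target_neuron not in E.neuron_ids:
        raise KeyError(f"unknown neuron {target_neuron!r}")
    j = E.neuron_ids.index(target_neuron)
    nonzero = E.E.sum(axis=1) > 0
    peak = E.E.max(axis=1)
    cutoff = float(np.quantile(peak[nonzero], expr_quantile)) if nonzero.any() else 0.0

    rows = []
    for gi, gene in enumerate(E.gene_ids):
        if not nonzero[gi]:
            continue
        e = E.E[gi]
        ipr = inverse_participation_ratio(e)
        rel_target = e[j] / peak[gi]
        if ipr <= ipr_max and rel_target >= 1.0 and (
                expr_quantile <= 0 or peak[gi] >= cutoff):
            rows.append({"gene_id": gene, "ipr": ipr,
                         "target_expression": e[j], "peak_expression": peak[gi]})
    out = pd.DataFrame(rows, columns=["gene_id", "ipr", "target_expression",
                                      "peak_expression"])
    return out.sort_values("ipr", kind="stable").reset_index(drop=True)
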