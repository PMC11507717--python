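"""Packaged synthetic measurement-matrix fixture.

A frozen 29-line x 87-neuron binary incidence matrix emulating the shape
and class composition of a real promoter panel (54 interneuron, 25 sensory
and 8 motor neuron classes).  Neuron-class labels are real C. elegans
neuron classes; promoter names are plausible line labels.  The entries are
synthetic: they are generated once from a fixed internal seed with per-row
densities in the 2-15 range typical of promoter lines, then cached, so the
fixture is bit-identical across calls and installs.  It does not reproduce
any real line's expression pattern.
"""

from __future__ import annotations

import numpy as np

from .matrix import MeasurementMatrix

INTERNEURONS = (
    "ADA", "AIA", "AIB", "AIM", "AIN", "AIY", "AIZ", "ALA", "AUA", "AVA",
    "AVB", "AVD", "AVE", "AVF", "AVG", "AVH", "AVJ", "AVK", "AVL", "BDU",
    "DVA", "DVB", "DVC", "I1", "I2", "I3", "I4", "I5", "I6", "LUA",
    "PVC", "PVN", "PVP", "PVQ", "PVR", "PVT", "PVW", "RIA", "RIB", "RIC",
    "RID", "RIF", "RIG", "RIH", "RIM", "RIP", "RIR", "RIS", "RIV", "RMG",
    "SAA", "SDQ", "SIA", "SIB",
)
SENSORY = (
    "ADE", "ADF", "ADL", "AFD", "ALM", "AQR", "ASE", "ASG", "ASH", "ASI",
    "ASJ", "ASK", "AWA", "AWB", "AWC", "BAG", "CEP", "FLP", "IL2", "OLL",
    "PDE", "PHA", "PHB", "PLM", "URX",
)
MOTOR = ("HSN", "M1", "M2", "M3", "M4", "M5", "MC", "MI")

PROMOTERS = (
    "dop-2", "flp-4", "mpz-1", "sams-5", "ttx-3", "npr-4", "flp-1", "glr-1",
    "nmr-1", "tdc-1", "ceh-36", "odr-2", "sra-11", "mod-1", "tph-1", "cat-2",
    "unc-47", "unc-17", "eat-4", "gcy-35", "flp-18", "flp-21", "nlp-12",
    "ins-1", "mgl-1", "ser-2", "dat-1", "che-1", "ocr-2",
)

_FIXTURE_SEED = 198712  # internal; frozen so the fixture is bit-identical
_N_CANDIDATES = 50  # candidate draws scored for mutual coherence
_cache: MeasurementMatrix | None = None


def _draw(seed: int, n_lines: int, n_neurons: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    values = np.zeros((n_lines, n_neurons))
    for i in range(n_lines):
        nnz = int(rng.integers(2, 16))  # row densities in the 2-15 range
        cols = rng.choice(n_neurons, size=nnz, replace=False)
        values[i, cols] = 1.0
    # every neuron must be covered by at least one line
    for j in np.nonzero(values.sum(axis=0) == 0)[0]:
        values[int(rng.integers(n_lines)), j] = 1.0
    # distinct columns: identical coverage patterns would make two neurons
    # indistinguishable to the inference, so break ties deterministically
    guard = 0
    while True:
        _, first = np.unique(values.T, axis=0, return_index=True)
        dupes = sorted(set(range(n_neurons)) - set(first.tolist()))
        if not dupes:
            return values
        for j in dupes:
            zero_rows = np.nonzero(values[:, j] == 0)[0]
            values[int(rng.choice(zero_rows)), j] = 1.0
        guard += 1
        if guard > 100:  # pragma: no cover - construction is deterministic
            raise RuntimeError("fixture construction failed to deduplicate columns")


def _coherence_score(values: np.ndarray) -> tuple:
    """Coherence badness of a candidate design; lower is better.

    Ranked by the number of near-collinear column pairs (coherence >=
    0.65), then by the worst pair, then by mean coherence: sparse
    recovery breaks down through individual highly coherent pairs, so
    their count matters more than the average.
    """
    cols = values / np.linalg.norm(values, axis=0, keepdims=True)
    gram = np.abs(cols.T @ cols)
    np.fill_diagonal(gram, 0.0)
    n_bad = int((np.triu(gram) >= 0.65).sum())
    return n_bad, float(gram.max()), float(gram.mean())


def _build() -> MeasurementMatrix:
    neuron_ids = INTERNEURONS + SENSORY + MOTOR
    assert len(INTERNEURONS) == 54 and len(SENSORY) == 25 and len(MOTOR) == 8
    assert len(PROMOTERS) == 29
    n_lines, n_neurons = len(PROMOTERS), len(neuron_ids)
    # sparse recovery from an underdetermined design needs an incoherent
    # matrix: score candidate draws and keep the least coherent one
    master = np.random.default_rng(_FIXTURE_SEED)
    seeds = master.integers(0, 2 ** 31, size=_N_CANDIDATES)
    values = min((_draw(int(s), n_lines, n_neurons) for s in seeds),
                 key=_coherence_score)

    annotation = {n: "interneuron" for n in INTERNEURONS}
    annotation.update({n: "sensory" for n in SENSORY})
    annotation.update({n: "motor" for n in MOTOR})
    return MeasurementMatrix(
        line_ids=PROMOTERS, neuron_ids=neuron_ids,
        values=values, class_annotation=annotation,
    )


def fixture_matrix() -> MeasurementMatrix:
    """The packaged 29 x 87 fixture matrix (cached, bit-identical)."""
    global _cache
    if _cache is None:
        _cache = _build()
    return _cache
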