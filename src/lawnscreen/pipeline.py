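"""End-to-end pipeline: simulate (or load) -> phenotypes -> inference -> robustness.

A :class:`PipelineConfig` collects every stage parameter with the package
defaults; :func:`run_pipeline` executes the stages deterministically under
one seed hierarchy and writes all reports plus a provenance record next to
the outputs.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .inference import (ElbowScreenLasso, SUPPORT_REL_TOL, bootstrap_weights)
from .io import (read_matrix, read_replicates, write_json_report, write_matrix,
                 write_phenotype_vector, write_replicates)
from .robustness import corruption_scan, promoter_removal_scan
from .screen import build_phenotype_vector, phenotypes_from_table
from .synthetic import make_fixture_matrix, plant_ground_truth, simulate_phenotypes


@dataclass
class PipelineConfig:
    """Fully-resolved configuration of one screen-deconvolution run."""

    seed: int = 0
    out_dir: str = "lawnscreen_out"
    # inputs: either paths to a measurement matrix + replicate table ...
    matrix_path: str | None = None
    annotation_path: str | None = None
    replicates_path: str | None = None
    # ... or a simulated screen with planted ground truth
    simulate: bool = True
    k: int = 4
    weight_low: float = 20.0
    weight_high: float = 60.0
    noise_sd: float = 0.0
    n_replicates: int = 5
    # phenotype stage
    metric: str = "reentry_latency"
    alpha: float = 0.05
    # inference stage
    n_points: int = 60
    span: float = 1e6
    rel_tol: float = 0.001
    support_rel_tol: float = SUPPORT_REL_TOL
    n_boot: int = 1000
    # robustness stage
    corruption_fraction: float = 0.1
    corruption_n: int = 200
    removal_max: int = 5
    removal_reps: int = 40

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, log=lambda msg: print(msg, file=sys.stderr)) -> dict:
    """Run the full screen deconvolution; returns the report bundle.

    Deterministic given ``config.seed``; every randomized stage draws
    from its own child of one seeded generator.  Writes the weight
    solution, sparsity sweep, bootstrap and robustness reports, and a
    provenance JSON into ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    seeds = {name: int(root.integers(2 ** 31)) for name in
             ("truth", "phenotypes", "bootstrap", "corruption", "removal")}

    if config.simulate:
        log("simulating screen with planted ground truth")
        M = make_fixture_matrix()
        truth = plant_ground_truth(M, config.k, config.weight_low,
                                   config.weight_high, config.noise_sd,
                                   seed=seeds["truth"])
        table = simulate_phenotypes(M, truth, n_reps=config.n_replicates,
                                    seed=seeds["phenotypes"])
        planted = [M.neuron_ids[i] for i in truth.support(config.metric)]
    else:
        if not config.matrix_path or not config.replicates_path:
            raise ValueError("matrix_path and replicates_path are required "
                             "when simulate is false")
        log(f"loading {config.matrix_path} and {config.replicates_path}")
        M = read_matrix(config.matrix_path, config.annotation_path)
        table = read_replicates(config.replicates_path)
        planted = None

    write_matrix(M, out / "matrix.csv", out / "matrix_classes.csv")
    write_replicates(table, out / "replicates.csv")

    log(f"building {config.metric} phenotype vector (alpha={config.alpha})")
    P = build_phenotype_vector(phenotypes_from_table(table, config.metric),
                               config.metric, alpha=config.alpha,
                               line_order=M.line_ids)
    write_phenotype_vector(P, out / "phenotypes.csv")

    log(f"sweeping {config.n_points} penalties over {config.span:g}x range")
    est = ElbowScreenLasso(n_points=config.n_points, span=config.span,
                           rel_tol=config.rel_tol,
                           support_rel_tol=config.support_rel_tol).fit(M, P)
    est.sweep_.to_frame().to_csv(out / "sweep.csv", index=False)

    log(f"bootstrap: {config.n_boot} draws at lambda={est.lam_:.4g}")
    boot = bootstrap_weights(M, table, config.metric, config.alpha,
                             lam=est.lam_, n_boot=config.n_boot,
                             seed=seeds["bootstrap"])
    boot.to_frame().to_csv(out / "bootstrap.csv", index=False)

    log(f"corruption scan: {config.corruption_n} matrices")
    corr = corruption_scan(M, P, n_matrices=config.corruption_n,
                           fraction=config.corruption_fraction,
                           lam_policy="fixed", lam=est.lam_,
                           seed=seeds["corruption"])
    log(f"promoter removal: {config.removal_max} x {config.removal_reps}")
    removal = promoter_removal_scan(
        M, table, config.metric, alpha=config.alpha,
        n_remove=config.removal_max, reps_per_level=config.removal_reps,
        lam_policy="fixed", lam=est.lam_, seed=seeds["removal"])

    support_ids = [M.neuron_ids[i] for i in est.support_]
    bundle = {
        "config": config.to_dict(),
        "version": __version__,
        "seeds": seeds,
        "planted_support": planted,
        "weights": {n: float(w) for n, w in zip(M.neuron_ids, est.coef_)},
        "lam": est.lam_,
        "chi2": est.chi2_,
        "support": support_ids,
        "bootstrap": {
            "selection_frequency": {
                n: float(f) for n, f in
                zip(M.neuron_ids, boot.selection_frequency)},
            "median_weight": {n: float(w) for n, w in
                              zip(M.neuron_ids, boot.median)},
        },
        "corruption_selection_frequency": {
            n: float(f) for n, f in
            zip(M.neuron_ids, corr.per_neuron["selection_frequency"])},
        "removal_selection_frequency": {
            str(r): {n: float(f) for n, f in
                     zip(M.neuron_ids, rep.per_neuron["selection_frequency"])}
            for r, rep in removal.items()},
    }
    write_json_report(bundle, out / "report.json")
    write_json_report({"config": config.to_dict(), "version": __version__,
                       "seeds": seeds}, out / "provenance.json")
    log(f"done; reports in {out}")
    return bundle
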