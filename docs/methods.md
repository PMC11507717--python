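# Methods

This note documents the models, estimators and numerical conventions
implemented in `lawnscreen`, the defaults and why they were chosen, and
what the synthetic data can and cannot show.

## Behavioral model and event logs

Each worm on an assay plate is a three-state machine: on-lawn → (exit) →
off-lawn → (contact) → at-edge → (entry) → on-lawn.  All internal times
are seconds; grid steps, windows and summaries convert to minutes/hours
at the interface.  A worm stalled at the lawn edge counts as off-lawn for
occupancy (the stalled animals are visibly outside the lawn); the
opposite convention is available via `edge_counts_as_on`.

The synthetic generator draws logs from an inhomogeneous renewal process:

* **Exit hazard** (applies while on-lawn):
  `r(t) = r0 + (r_max − r0)·σ((t − t_half_r)/tau_r)` with defaults
  r0 = 0, r_max = 3.0 /h, t_half_r = 7 h, tau_r = 1.5 h, sampled by
  thinning against the plateau.
* **Contact delay** after an exit: Exponential with mean 3 min.
* **Re-entry stall**: LogNormal with
  `μ(t) = μ_lo + (μ_hi − μ_lo)·σ((t − 6.5)/0.6)` (log-seconds),
  μ_lo = 0.7786 (mean ≈ 3 s), μ_hi = 7.3775 (mean ≈ 36.7 min),
  σ_lat = 0.8.  Stalls that outlast the assay leave the worm at the edge
  (right-censored re-entry).

**Calibration.**  The defaults are fixed by the printed anchors of the
pathogen assay: measured plateau exit rate ≈ 1 event per (total)
worm-hour over hours 10–18, mean re-entry latency ≈ 36.7 min for contacts
near 12 h, latencies of seconds before ~5 h, and half-evacuation around
8 h.  Two calibration points deserve comment:

* The *measured* rate constant divides events by all assayed worms, but
  worms can only exit while on the lawn.  At late times a cycle spends
  ≈ 1/r_max h on-lawn and ≈ 0.66 h off-lawn (contact + stall), so an
  on-lawn hazard plateau of 3.0/h — not 1.0/h — produces the measured
  plateau of ~1 exit/worm-hour (cycle time ≈ 1 h).  This renewal argument
  was confirmed by simulation once and frozen.
* The latency sigmoid saturates before 11 h so that the mean over the
  11–13 h contact window equals the 12-h anchor.  σ_lat = 0.8 gives a
  per-event coefficient of variation ≈ 0.95, consistent with the printed
  plate-to-plate SEM.  Per-event aggregation is the default estimator;
  per-worm means are available but are upward-biased for this quantity,
  because long-latency worms complete fewer cycles and would be
  up-weighted.

The generator emulates event timing only: no posture, trajectories,
lawn microbiology, or worm-to-worm interaction.  Tests passing on it
show that the estimators recover known generating parameters — not that
real assays satisfy the renewal assumptions (real latencies are likely
non-stationary within a worm, and real hazards vary between plates).

## Screen phenotypes

Per line and metric, the phenotype is `mean(+ATR) − mean(−ATR)` gated by
a two-sided Welch t-test at α = 0.05 (pooled-variance variant behind a
flag): lines failing the gate are set to exactly 0, as the screen's
contract requires.  No multiple-testing correction is applied across the
29 lines by default (Benjamini–Hochberg behind a flag), matching the
screen's per-line testing; the synthetic null-screen calibration test
confirms the per-line type-I rate ≈ α.  The differential retention index
is the trapezoidal integral of (−ATR minus +ATR) occupancy over the
assay, gated by a z-score against uninhibited-control spread with
threshold |z| ≥ 2.  Sign convention throughout: positive = inhibition
increases aversion.  Replicate-level measurement is used everywhere
(replicates are plates of ~10 worms); the replicate noise SD is a free
generator parameter, as no empirical value is published.

## Sparse inference

The solver minimizes `(1/2n)‖P − Mw‖² + λ‖w‖₁` (n = number of lines),
no intercept, no column standardization — the design is binary and
standardization would destroy the weights' units (phenotype change per
unit expression).  Under this 1/(2n) scaling, λ is measured in phenotype
units; multiply by 2n to convert to the unscaled objective.  Coordinate
descent (scikit-learn's Lasso) does the numerical work; λ = 0 falls back
to minimum-norm least squares.  Every solution is checked against the
KKT conditions — `(1/n)Mⱼᵀ(P − Mw) = λ·sign(wⱼ)` on the active set,
`|(1/n)Mⱼᵀ(P − Mw)| ≤ λ` off it — within `1e-6 × max(1, λ_max)`; the
scale factor makes the certificate unit-independent.  Failure raises
after one retry with a 20× iteration budget.  An exhaustive support/sign
enumeration oracle (`brute_force_solve`, ≤ 14 columns) provides the
independent check: a candidate satisfying full KKT is the global optimum
of the convex objective.

**Path and elbow.**  The sweep covers 60 log-spaced penalties spanning
six orders of magnitude up to the data's λ_max, warm-starting from the
sparse end (each point still carries its own certificate, so the result
is start-independent).  The elbow rule keeps the largest λ whose χ²
stays within `rel_tol` of the path floor, relative to the full χ² range.
The default `rel_tol = 0.001` reads "error began to increase" literally:
χ² has risen by no more than 0.1% of its eventual range.  Larger
tolerances (0.01–0.05) select visibly into the rise, where shrinkage
already distorts small true weights and planted-support recovery on
noiseless synthetic screens degrades from ~95% to ~50–80%.

**Support.**  On binary promoter designs the lasso path carries
persistent small nonzero coefficients at every λ — correlated columns
absorbing residual structure and gate-leaked replicate noise — so a
machine-precision nonzero test never yields a clean support.  A neuron
is therefore reported as selected when its weight is within a factor of
5 of the dominant weight (`support_rel_tol = 0.2`).  Under the
generator's screen conditions, noise-driven weights measure ~0.1 of the
dominant weight and planted weights ≥ ~0.3, so the cut sits in the gap;
it is exposed as a parameter everywhere.

**Bootstrap.**  Replicates are resampled with replacement within each
line × condition, the significance gate re-run, and the system re-solved
at the original elbow λ (per-draw re-selection behind a flag; the
published procedure implies a single λ).  What the published 10,000
draws resampled is not stated; replicate-level resampling is this
package's interpretation, consistent with replicate-level testing.
Reported: per-neuron median weight, 2.5/97.5 percentile interval, and
selection frequency.

## Robustness diagnostics

* **Corruption**: exactly `round(0.1·nnz)` nonzero entries (fraction
  configurable) are replaced by Uniform(0, 0.5) draws; zeros are never
  touched.  1000 corrupted matrices are solved at the fixed baseline λ.
* **Promoter removal**: r ∈ 1..5 rows removed at random, 200 repetitions
  per level (1000 inferences total); the phenotype vector restricted to
  the remaining lines (the per-line gate does not involve other lines,
  so this is a row subset).  Draws leaving a neuron uncovered are kept
  and the neuron flagged unidentifiable for that draw.
* **Selection scale**: perturbation scans judge selection against the
  *unperturbed* solution's dominant weight.  Corrupting an entry to c
  inflates its neuron's weight by 1/c, and a per-solution relative
  threshold would spuriously drop every other neuron.
* **Recovery simulation**: fresh k-sparse truths are planted each
  repetition and pushed through the full pipeline (replicates → gate →
  elbow inference).  Definitions, stated because no published convention
  exists: per-neuron recovery rate = P(selected | planted), per-neuron
  true positive rate = P(planted | selected); overall FP rate = mean
  fraction of the inferred support outside the truth; FN rate = mean
  fraction of the truth missed.

Retention under perturbation is coverage-dependent: a neuron reached by
a single line loses identification when that one entry is corrupted low
or its line removed.  On planted synthetic screens, per-neuron retention
spans ~0.15–1.0 with coverage while the planted-set mean stays ≥ 0.8 —
the same fragile-column phenomenon that limits exact-support recovery
(measured ~85–90% of planted k=4 screens at 5% replicate noise; in the
failing screens no penalty on the path achieves the exact support, so
this is a property of the design's coherence, not of the solver).  The
packaged fixture is drawn once from a frozen seed (row densities 2–15,
all columns distinct and covered) and selected among 50 candidate draws
for minimal near-collinear column-pair count, emulating the incoherent
designs this method needs.

## Calcium processing

Baselines are the 5th percentile (linear interpolation between order
statistics; other percentile methods behind a flag) of the worm's own
*pre*-exposure trace; both conditions divide by this single value, so 1.0
means "healthy baseline" and post traces never define their own scale.
Smoothing is a centered moving average of `round(window_s × fps)`
samples — 94 at 6 s × 15.625 fps; the even window takes one extra sample
left of center, and edges truncate and renormalize, preserving length.
Pre/post comparison reports the pooled-median shift and a two-sided
Wilcoxon rank-sum p-value computed on per-worm medians, not pooled
frames — frames within a worm are strongly dependent and pooling them
would fabricate precision.  Histograms are emitted both frame-pooled and
per-worm, since either weighting is defensible.  The synthetic traces
(Poisson transients, exponential-decay kernel, Gaussian sensor noise)
emulate amplitude statistics only — no photobleaching, motion artifacts
or ROI segmentation error.

## Expression specificity

For a gene with expression Eᵢ across neuron types, relative expression
divides by the maximum; IPR = 1/Σpᵢ² with pᵢ = Eᵢ/ΣEᵢ is the effective
number of expressing types (1 = perfectly specific, N = uniform).
Candidate neuropeptides for a target neuron must be specific
(IPR ≤ `ipr_max`, default 5), maximal in the target (relative
expression 1 there; ties count), and highly expressed (peak above the
0.75 quantile of peaks).  The two thresholds are interpretations — no
published cutoffs exist — and are configuration values.

## Problem sizes and determinism

Every randomized operation draws from an explicitly seeded
`numpy.random.Generator`; pipelines derive child seeds from one root, so
whole runs are byte-reproducible.  Default test-suite problem sizes are
chosen to keep the full suite under ~2 minutes: 400 simulated screens
for the null-calibration test, ~100–200 property-test examples, 100
planted screens / 1000 bootstrap draws / 1000 corruption matrices /
5×200 removal draws for the end-to-end checks; the published-scale
10,000-draw bootstrap runs unchanged through the same code path by
raising `n_boot`.

## Known limitations

* Exact-support recovery is bounded by design coherence (above); the
  bootstrap selection frequency is the more robust readout, and is what
  the screen's published analysis relied on.
* The behavioral generator's renewal assumptions (iid stalls given
  contact time, memoryless contact delays) are conveniences, not
  measured properties of real worms.
* The elbow rule presumes a χ² path with a floor-then-rise shape; on
  problems where noise dominates signal the "floor" is noise
  interpolation and the selected λ is small — inspect the sweep rather
  than trusting the elbow blindly.
* `brute_force_solve` is exponential in columns and exists for
  verification, not analysis.
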