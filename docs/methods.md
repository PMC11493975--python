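# Methods

`isletage` implements the quantitative machinery of a stable-isotope
birth-dating study of pancreatic islet cells under diet interventions,
together with the companion analyses such studies run alongside it:
consensus filtering of stochastically inferred gene-regulatory networks,
ROC-based imaging-metabolomics screening, and glucose-homeostasis
phenotyping. Every stage can be driven end to end from the synthetic-data
generators, which carry full ground truth.

## Label-dilution birth-dating

### Model

Animals are raised on a ¹⁵N-enriched diet until nuclear DNA is saturated,
then chased on ¹⁴N diet. Nuclear nitrogen is dominated by DNA, which is
replicated semi-conservatively: each division hands half of the labeled
strands to each daughter, so the nuclear ¹⁵N *excess* (atom fraction above
the natural abundance f_nat) after k divisions is

    e(k) = e0 · 0.5^k

with e0 the excess at the end of labeling. The inverse,
k = log₂(e0 / e), converts a measured excess into a continuous division
count, clipped below at zero (a measured excess above reference reflects
noise, not negative divisions). Measurements with e ≤ 0 are noise-dominated
— the label has diluted into background — and are flagged indeterminate;
for classification they are counted as young (maximally diluted), and they
are excluded from mixture fitting.

Division counts are computed on **excess**, not on the raw ¹⁵N/¹⁴N ratio:
the raw ratio includes the natural-abundance floor and stops halving once
the label approaches background.

Key parameters:

| parameter | default | units | meaning |
|---|---|---|---|
| `natural_abundance` (f_nat) | 0.0037 | atom fraction | natural ¹⁵N abundance (physical constant) |
| `diet_enrichment` | 0.98 | atom fraction | ¹⁵N content of the labeling diet |
| `initial_excess` (e0) | `diet_enrichment − f_nat` | atom fraction | saturation excess; a stand-in for the instrument-measured saturation level, override when known |
| `chase_months` (T) | 12 | months | duration of the ¹⁴N chase |

### LLC classification

Post-mitotic cortical neurons define the reference retention level of a
never-divided cell. Both the mean and the minimum neuron ratio are
computed; by default a cell is called long-lived (LLC) iff its ratio is at
or above the **lowest** neuron ratio (inclusive ≥). The minimum is the most
permissive bound consistent with zero divisions; the stricter mean rule is
selectable (`rule="mean"`). Cohort LLC fractions carry a cell-level
percentile-bootstrap CI (B = 2000, seeded).

### Division-count mixture

Cohort heterogeneity (a quiescent "reserve pool" plus cycling cells) is
deconvolved by EM on

    log2(e_i) ~ Σ_k w_k · Normal(log2(e_ref) − k, σ²),   k = 0..K_max

where component means are pinned by the dilution law (one log2 unit per
division) and only the weights w and the shared measurement noise σ are
free. Initialization: uniform weights, σ = sample SD of log2 excess
(floored at 1e-3); convergence when the log-likelihood gain drops below
1e-8, cap 1000 iterations. The log-likelihood is non-decreasing by
construction and the fit is cross-checked in the tests against an
independent maximizer of the same likelihood (simplex grid plus
Nelder–Mead). σ is floored at 1e-6 in the M-step to avoid component
collapse on degenerate inputs. K_max defaults to 6; weights beyond the true
support converge to ~0.

## MIMS quantification

Per-nucleus ratios are **ratios of summed counts** over the ROI,
r = Σ¹⁵N / Σ¹⁴N, and atom fraction f = Σ¹⁵N / (Σ¹⁵N + Σ¹⁴N). This is the
Poisson maximum-likelihood combination; per-pixel ratios are unstable
wherever ¹⁴N counts are low, and averaging per-frame ratios weights frames
equally instead of by information (the test suite demonstrates the variance
penalty empirically). Frames are accumulated by element-wise summation
before ratioing; a nucleus with Σ¹⁴N = 0 is reported unmeasurable rather
than silently infinite.

Segmentation is deliberately simple — Otsu threshold plus 8-connected
components, minimum area 50 px — because callers with instrument ROIs
bypass it. The default threshold channel is ¹⁴N, the usual structure
channel when label levels are modest; `channel="total_n"` (¹⁵N + ¹⁴N)
thresholds on total nitrogen instead, which tracks DNA density regardless
of isotope composition and is the robust choice when nuclei may be nearly
fully labeled (a saturated nucleus is dark in ¹⁴N alone). Dead-time and
quasi-simultaneous-arrival corrections are out of scope (instrument-side
processing).

Registration to EM coordinates is a least-squares 2D affine fit on ≥ 3
non-collinear fiducial pairs (³²S landmarks), solved by `lstsq` on the
design [x, y, 1]; collinearity is rejected via a rank test. Masks are
mapped with nearest-neighbor rounding. Coordinates are 0-based (row, col)
with pixel centers at integers.

## Consensus network filtering

Stochastic co-expression inference is run repeatedly (the study design uses
100 runs); an edge enters the consensus iff it appears in at least
`min_support` of the runs, default 0.80, **inclusive**. Support is the
exact rational appearances/n_runs, compared in `fractions.Fraction`
arithmetic so that 80/100 or 12/15 sit exactly on the boundary with no
floating drift. Each retained edge's importance is the mean over the runs
containing it; `absent_as_zero=True` averages over all runs instead (the
merge convention is ambiguous in common toolchains, so both are exposed).

Regulon activity (rank-based AUC scores in [0, 1]) is binarized per regulon
by a two-component Gaussian mixture on logit-transformed activities.
Boundary-clipped values are excluded from the fit — their logits would
masquerade as a mode — and a column is accepted as bimodal only if the
two-component model wins by BIC, both components carry ≥ 5% of the mass,
and the modes are well separated (Ashman's D ≥ 3). Anything else falls back
to all-OFF, the conservative call for a regulon with no evidence of an
active subpopulation; the threshold is the posterior crossing point between
the component means. This will miss regulons that are ON in < 5% of cells
or whose modes overlap heavily — a deliberate trade against spurious
activations from skewed unimodal score distributions.

TF co-activity modules come from Pearson correlation across cells followed
by average-linkage hierarchical clustering on distance 1 − r
(zero-variance regulons excluded with a warning). Influence is ranked by
betweenness centrality on the directed, unweighted consensus graph
(cross-checked against exhaustive shortest-path enumeration in the tests);
an importance-weighted variant uses 1/mean-importance as edge length.

## Imaging-metabolomics ROC screen

For each ion, pixels of two labeled regions are compared by the rank-sum
identity AUC = U/(n_a·n_b) = P(B > A) + ½P(B = A). Pixel-level
observations are the ROC units, mirroring imaging-software behavior. Ions
are retained iff |AUC − 0.5| ≥ 0.1, two-sided and inclusive on both
boundaries, so one screen reports enrichment in either direction; a
one-sided mode is selectable. Retained masses are identified by accurate
mass within a hard ±0.00565 Da gate (instrument mass resolution; a 1e-12 Da
epsilon absorbs float representation error at the boundary), with the ppm
deviation reported diagnostically rather than used as a filter. Peak
detection and spectrum processing are upstream of this package.

## Metabolic phenotyping

* **MTT AUC** — the pre-bolus sample (minute −10 by default, configurable
  via `baseline_index`) is subtracted from all post-bolus points and the
  trapezoidal integral is taken over post-bolus timepoints only. Net signed
  area is kept, making the statistic invariant to constant shifts.
* **Kitt** — OLS slope of ln(glucose) on time over points in [0, 60] min;
  Kitt = −slope × 100 (%/min, positive for falling glucose). The
  regression standard error is returned alongside; note that with the
  8-point sampling grid the slope error has only 6 degrees of freedom, so a
  ±3 SE band covers ~97.6% of replicates, not the Gaussian 99.7%.
* **HOMA-IR** — glucose [mmol/L] × insulin [mU/L] / 22.5, the conventional
  normalization.
* **CR ration** — steady state is (1 − restriction) × mean ad libitum
  intake (default restriction 0.20); during a ramp the restriction steps
  from 0.10 toward the target by 0.10/week.
* **Digested energy** — intake minus fecal energy (kcal/day), with fecal >
  intake rejected as inconsistent calorimetry. Diet energy densities ship
  as named constants (chow 4.11, high-fat 5.10 kcal/g).

Curves declare their units (`mg/dL`, minutes) and mismatched declarations
are rejected at construction.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed); the same call is
byte-identical. Every generator returns its ground truth.

* **Cohorts** — a two-component turnover model: quiescent with probability
  p_q, else k ~ Poisson(λT). This reproduces the bimodal per-cell ¹⁵N
  distributions and the reserve-pool reading of islet turnover. Group
  defaults (p_q, λ per month): CR (0.80, 0.10), AL (0.55, 0.20), HFD
  (0.30, 0.40) — chosen once so that 12-month simulated outcomes sit near
  the reported long-lived fractions (≈80% CR, ≈30% HFD, AL between).
* **MIMS rasters** — 512×512 px, 3 frames; inside a nucleus with atom
  fraction f, ¹⁵N ~ Poisson(D·f·h) and ¹⁴N ~ Poisson(D·(1−f)·h), with
  D = 200 counts/px/frame and h a heterochromatin hotspot factor (2.0 over
  15% of nucleus pixels). Hotspots scale dose only — denser DNA yields more
  counts at the same isotope composition — so ratios are unbiased by
  design. ³²S carries fiducial marks. Expected channel counts partition the
  dose exactly before Poisson sampling. Not emulated: detector dead time,
  beam drift, sub-pixel mixing at nucleus boundaries, non-nuclear ¹⁵N
  (e.g., myelin), or EM image content.
* **GRN run sets** — each run keeps each true edge with probability p_true
  (importance × lognormal noise) and each non-edge with probability
  p_false. Run-to-run correlation of inference errors is not modeled, so
  real consensus filtering may face more structured noise.
* **Activity matrices** — per-regulon two-component Gaussian mixtures in
  [0, 1] with known ON labels; real AUC scores are skewed and
  inter-regulon correlated.
* **Ion images** — region-wise lognormal intensities with an additive
  log-scale effect; zero effect makes regions exchangeable. Spatial
  autocorrelation within regions is not modeled, which makes pixel-level
  ROC slightly better calibrated here than in real imaging data.
* **Tolerance curves** — mono-exponential glucose decay with multiplicative
  lognormal noise; real curves depart from a single exponential outside the
  0–60 min window (hence Kitt's window).

Passing the recovery suites therefore demonstrates correctness of the
estimators under their own statistical assumptions — Poisson counting
statistics, independent run errors, exchangeable null pixels — not
robustness to instrument systematics those assumptions exclude.

## Problem sizes and numerical choices

Replicate experiments in the test and acceptance suites use: 1000 nucleus
replicates over fifty 512×512 rasters (≥ 1e5 counts/nucleus) for ratio
quantification; 500 replicates × 3 groups × 200 cells (plus 20 reference
neurons at total dose 1.5e5 counts) for diet-group ordering; n = 2000 for
mixture recovery; 500 replicates for Kitt and bootstrap-coverage checks;
100 random digraphs (≤ 8 nodes) for the betweenness oracle. Large replicate
experiments inject counting noise directly at the nucleus level
(`simulate_nucleus_counts`) rather than rendering a raster per replicate;
the raster and nucleus-level paths share the same count model.

Tie-breaks and degenerate inputs: classification boundaries are inclusive
(a cell exactly at the reference minimum is an LLC; an AUC exactly at
0.6/0.4 is retained; a mass exactly at the Da tolerance matches); blank
rasters segment to zero nuclei rather than erroring; empty match lists are
returned rather than raised.

## Known limitations

* e0 defaults to diet enrichment minus natural abundance; real saturation
  excess is lower and instrument-dependent, so absolute division counts
  should be read against a measured `e_ref`, as the API requires.
* The LLC call inherits the variance of the reference-minimum order
  statistic: with ~20 neurons the effective cutoff varies between
  experiments, which widens the spread of cohort LLC fractions (ordering
  between groups within an experiment is unaffected).
* The mixture EM assumes a shared σ across division classes and independent
  cells; overdispersed or spatially correlated measurement noise will
  inflate σ rather than be detected.
* Binarization is conservative by construction (see above).
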