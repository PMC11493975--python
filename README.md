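# isletage

Quantitative toolkit for stable-isotope birth-dating of pancreatic islet
cells under diet interventions (caloric restriction, ad libitum, high-fat
diet), with the companion analyses such studies run alongside it:
consensus filtering of stochastically inferred gene-regulatory networks,
ROC-based imaging-metabolomics screening, and glucose-homeostasis
phenotyping. It is aimed at researchers analyzing multi-isotope imaging
mass spectrometry (MIMS) data — or building and validating such pipelines —
and ships synthetic-data generators with full ground truth so every stage
is testable without instrument data.

## The core model

During a ¹⁵N pulse–¹⁴N chase, each cell division halves the nuclear ¹⁵N
excess (atom fraction above the natural abundance f_nat = 0.0037):

    e(k) = e0 · 0.5^k        ⇒        k = log2(e0 / e)

Per-nucleus excess comes from MIMS count rasters as the summed-count ratio
f = Σ¹⁵N/(Σ¹⁵N+Σ¹⁴N), e = f − f_nat. Cells at or above the lowest ratio of
post-mitotic reference neurons are classified long-lived (LLC); cohort
heterogeneity is deconvolved by an EM mixture over division counts k with
means pinned one log2 unit apart. The companion modules implement the
≥ 80%-of-runs consensus edge filter with importance averaging, pixel-level
ROC AUC with a 0.5 ± 0.1 retention band and ±0.00565 Da accurate-mass
matching, and the phenotyping statistics (baseline-normalized MTT AUC,
Kitt = −100 × d ln G/dt over 0–60 min, HOMA-IR = G·I/22.5, the 80% CR
ration rule).

See `docs/methods.md` for models, assumptions, parameter defaults, and
limitations.

## Worked example

`examples/` holds one short script per capability. Birth-dating three
simulated diet cohorts (`python examples/birthdate_cohorts.py`):

```
initial excess e0 = 0.9763 atom fraction

LLC fraction per diet (200 beta cells each, 95% bootstrap CI):
   CR: 0.78 [0.73, 0.83], mean divisions 0.34
   AL: 0.56 [0.50, 0.63], mean divisions 1.20
  HFD: 0.27 [0.21, 0.35], mean divisions 3.51

Division-count mixture EM on a planted 70/30 cohort:
  weights w_k = [0.697 0.    0.    0.303] (truth 0.7/0/0/0.3)
  sigma = 0.100 log2 units, converged in 9 iterations
```

Each line gives the fraction of beta cells whose nuclear ¹⁵N stayed at the
post-mitotic neuron reference level — cells that did not divide during the
12-month chase. Caloric restriction keeps most beta cells long-lived; a
high-fat diet drives turnover, diluting the label. The mixture fit recovers
the planted quiescent/divided split to within ~0.01.

The other examples quantify a synthetic 512×512 MIMS raster nucleus by
nucleus (`quantify_mims_raster.py`), filter a consensus network from 100
noisy inference runs and rank TF influence (`consensus_network.py`), screen
ion images for islet-enriched metabolites and match cholesterol sulfate by
accurate mass (`maldi_enrichment.py`), and compute Kitt/MTT-AUC/HOMA-IR and
the CR ration schedule (`metabolic_phenotyping.py`).

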