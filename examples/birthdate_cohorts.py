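"""Birth-date simulated beta-cell cohorts under three diets.

Simulates 15N-labeled cohorts chased for 12 months on ad libitum (AL),
caloric restriction (CR), and high-fat diet (HFD), adds Poisson ion-count
noise, classifies each cell as long-lived (LLC) or young against a
post-mitotic neuron reference, and deconvolves the division-count mixture.
"""

import numpy as np

from isletage.birthdating import fit_division_mixture
from isletage.pipeline import simulated_llc_experiment
from isletage.synthetic import DEFAULT_TURNOVER, LabelingProtocol

protocol = LabelingProtocol()  # 98% 15N diet, 12-month 14N chase
print(f"initial excess e0 = {protocol.e0:.4f} atom fraction")

summaries = simulated_llc_experiment(
    protocol, DEFAULT_TURNOVER, n_cells=200, seed=42
)
print("\nLLC fraction per diet (200 beta cells each, 95% bootstrap CI):")
for group in ("CR", "AL", "HFD"):
    s = summaries[group]
    print(
        f"  {group:>3}: {s.llc_fraction:.2f} "
        f"[{s.ci_low:.2f}, {s.ci_high:.2f}], mean divisions {s.mean_k_est:.2f}"
    )
# A higher LLC fraction means more cells kept near-reference nuclear 15N,
# i.e. fewer divisions during the chase: CR slows beta-cell turnover.

rng = np.random.default_rng(0)
k = rng.choice([0, 1, 2, 3], p=[0.7, 0.0, 0.0, 0.3], size=2000)
excess = protocol.e0 * 2.0 ** (-(k + rng.normal(0.0, 0.1, 2000)))
fit = fit_division_mixture(excess, protocol.e0, k_max=3)
print("\nDivision-count mixture EM on a planted 70/30 cohort:")
print(f"  weights w_k = {np.round(fit.weights, 3)} (truth 0.7/0/0/0.3)")
print(f"  sigma = {fit.sigma:.3f} log2 units, converged in {fit.n_iter} iterations")
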