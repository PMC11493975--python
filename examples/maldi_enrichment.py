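"""Screen synthetic ion images for islet-enriched metabolites.

Generates per-ion intensity images over two labeled tissue regions with
graded effect sizes, computes each ion's ROC AUC at pixel level, retains
ions with |AUC - 0.5| >= 0.1, and matches one retained mass against a small
accurate-mass reference list.
"""

import numpy as np

from isletage.maldi import MetaboliteRef, enrichment_filter, ion_auc, match_metabolite
from isletage.synthetic import IonSpec, synthesize_ion_images

# two disjoint regions: "acinar" (A) and "islet" (B)
region_a = np.zeros((60, 60), dtype=bool)
region_b = np.zeros((60, 60), dtype=bool)
region_a[:, :30] = True
region_b[20:40, 35:55] = True

specs = [
    IonSpec(mz=465.304, effect_size=1.2),   # islet-enriched
    IonSpec(mz=391.225, effect_size=-0.9),  # acinar-enriched
    IonSpec(mz=512.100, effect_size=0.0),   # null
]
images = synthesize_ion_images(region_a, region_b, specs, seed=6)

aucs = [(img.mz, ion_auc(img, region_a, region_b)) for img in images]
results = enrichment_filter(aucs, deviation=0.1)
print("per-ion ROC screen (class B = islet pixels):")
for r in results:
    status = f"enriched in {'islet' if r.direction == 'B' else 'acinar'}" if r.retained else "not retained"
    print(f"  m/z {r.mz:8.3f}  AUC {r.auc:.3f}  -> {status}")
# AUC is the probability a random islet pixel out-ranks a random acinar
# pixel; 0.5 means no enrichment either way.

refs = [
    MetaboliteRef("cholesterol sulfate", 465.30443),
    MetaboliteRef("CPA 16:0", 391.22486),
]
print("\naccurate-mass matching of the islet-enriched ion (tol 0.00565 Da):")
for m in match_metabolite(465.304, refs):
    print(f"  {m.name}: delta {m.delta_da*1e3:+.2f} mDa ({m.delta_ppm:.2f} ppm)")
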