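"""Generate a small labeled phantom cohort and inspect its ground truth.

Run:  python examples/01_generate_phantoms.py
"""

import numpy as np

from folliscan import default_normal_spec, default_pcos_spec, generate_dataset

data = generate_dataset(5, default_pcos_spec(), default_normal_spec(), seed=42)

for item in data:
    cov = item.image.pixels.std() / item.image.pixels.mean()
    print(
        f"{item.label:6s}  follicles={item.n_follicles:2d}  "
        f"mask px={int(item.mask.sum()):5d}  intensity CoV={cov:.2f}"
    )

pcos_counts = [d.n_follicles for d in data if d.label == "PCOS"]
norm_counts = [d.n_follicles for d in data if d.label == "normal"]
print(
    f"\nmean follicle count: PCOS {np.mean(pcos_counts):.1f} vs normal "
    f"{np.mean(norm_counts):.1f} — the morphological signal the classifiers learn."
)
print("CoV ~0.5 is the fully-developed-speckle level (Gamma shape 4).")
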