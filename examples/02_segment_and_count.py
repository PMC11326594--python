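"""Segment one PCOS phantom with the FCM + active-contour hybrid.

Run:  python examples/02_segment_and_count.py
"""

from folliscan import count_follicles, default_pcos_spec, generate_phantom, preprocess_image, segment_follicles

item = generate_phantom(default_pcos_spec(n_follicles=12, seed=7))
pre = preprocess_image(item.image)  # grayscale -> CLAHE -> Gaussian
seg = segment_follicles(pre)  # FCM(4) -> darkest cluster -> snakes -> filters

n, boxes = count_follicles(seg)
gt = item.mask
dice = 2 * (seg.mask & gt).sum() / (seg.mask.sum() + gt.sum())

print(f"true follicles: {item.n_follicles}, detected: {n}")
print(f"Dice overlap with ground truth: {dice:.3f}")
print("per-follicle equivalent diameters (mm):")
for comp in seg.components:
    print(f"  {comp.equivalent_diameter_mm:.1f} mm  bbox(x,y,w,h)={comp.bbox}")
print("\nA detected count near the true count and Dice > 0.9 means the dark")
print("cluster + contour refinement recovered each follicle individually.")
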