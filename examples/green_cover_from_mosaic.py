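"""Segment a microplot image into green vs soil pixels and report cover.

Trains the maximum-margin pixel classifier on one synthetic mosaic with
known labels, then measures green cover fraction (GCF) on an independent
mosaic whose true fraction is 37.5%.
"""

from canopytraits import rgb, synthetic

train_img, train_labels, _ = synthetic.gen_mosaic(0.5, size=(64, 64), seed=1)
clf = rgb.train_pixel_classifier(train_img.pixels.reshape(-1, 3), train_labels.ravel())

img, _, truth = synthetic.gen_mosaic(0.375, size=(128, 128), seed=7)
balanced = rgb.white_balance(img)
mask = rgb.classify_green(balanced, clf)
print(f"true green fraction      = {truth.gcf:.4f}")
print(f"classified green fraction = {mask.gcf:.4f}")
# GCF is the share of pixels that are green vegetation; 1 - GCF is the gap
# fraction that feeds the GAI inversion.
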