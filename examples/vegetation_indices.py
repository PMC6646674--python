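"""Calibrate a spectroradiometer scan and compute NDVI, MTCI and MCARI2.

A fully vegetated and a bare-soil scene are generated as raw digital-number
scans plus a reference-panel scan; calibration ratios them into reflectance
(usable 450-820 nm) and the three indices are sampled with 3 nm FWHM
Gaussian bands.
"""

from canopytraits import spectral, synthetic

for mix, label in [(1.0, "full canopy"), (0.0, "bare soil")]:
    canopy_scan, panel_scan, _ = synthetic.gen_spectrum(mix, seed=3)
    spec = spectral.calibrate_reflectance(canopy_scan, panel_scan, panel_reflectance=0.99)
    print(
        f"{label:12s} NDVI = {spectral.ndvi(spec):.3f}  "
        f"MTCI = {spectral.mtci(spec):.3f}  MCARI2 = {spectral.mcari2(spec):.3f}"
    )
# NDVI tracks the amount of vegetation, MTCI the red-edge chlorophyll
# signal, MCARI2 targets green LAI; dense green canopies push NDVI
# toward 1 while soil stays near 0.
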