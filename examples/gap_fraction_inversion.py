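"""Invert multi-angle gap fractions to green area index and leaf angle.

A wheat canopy with GAI 3.0 and average leaf angle 60 degrees is observed
at the platform's two camera angles (nadir and 45 degrees); the forward
Poisson model gives the gap fractions, 1% multiplicative noise emulates
segmentation error, and the look-up-table search recovers the pair.
"""

from canopytraits import canopy, synthetic

obs, truth = synthetic.gen_gap_fractions(gai=3.0, ala=60.0, noise_sd=0.01, seed=42)
print("observed gap fractions:", {a: round(p, 4) for a, p in obs.po_by_angle.items()})

lut = canopy.build_lut(angles=(0.0, 45.0))
est = canopy.invert_gai_ala(obs, lut)
print(f"estimated GAI  = {est.gai:.2f}  (truth {truth.gai})")
print(f"estimated ALA  = {est.ala:.0f} deg  (truth {truth.ala})")
print(f"fit RMSE       = {est.cost:.5f}")
# GAI is the m2 of green tissue per m2 of ground; ALA summarises how erect
# the leaves are (90 deg = fully erectophile). Both come from how gap
# fraction varies with view angle.
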