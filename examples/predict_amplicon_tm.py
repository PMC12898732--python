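"""Predict amplicon melting temperatures and screen for hairpins.

Builds a GC-rich and an AT-rich amplicon-sized sequence, predicts their
duplex Tm with the nearest-neighbor model at assay conditions (50 nM
strands, 50 mM Na+), and screens each for stable stem-loop structures.
"""

import numpy as np

import barhrm as b

rng = np.random.default_rng(1)


def random_seq(length, gc):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


for label, gc in (("GC-rich (60%)", 0.60), ("AT-rich (33%)", 0.33)):
    seq = random_seq(162, gc)
    pred = b.predict_tm_nn(seq)
    hairpin = b.hairpin_screen(seq)
    dg = f"{hairpin.min_dG:+.2f}" if np.isfinite(hairpin.min_dG) else "none"
    print(
        f"{label}: length {pred.length} bp, GC {100 * pred.gc_fraction:.1f}%, "
        f"predicted Tm {pred.tm_c:.2f} degC, hairpin dG {dg} kcal/mol"
        f"{' (flagged)' if hairpin.flagged else ''}"
    )

print()
print("Higher GC raises the predicted Tm at identical length; a hairpin")
print("more stable than -2 kcal/mol would be flagged as a melt-shape risk.")
print("On-instrument Tm runs ~0.7-1.5 degC above these predictions because")
print("the saturating dye stabilizes the duplex.")
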