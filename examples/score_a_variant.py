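"""Score a single missense variant end to end.

Assembles the five predictors for G566R — domain-normalized MAPP score,
SIFT, PolyPhen-2 HumVar, side-chain heavy-atom change and relative
accessibility (supplied as an override here, as one would for a position
missing from the crystal) — and evaluates the logistic joint score.
"""

import pandas as pd

from codp import default_model, msh6_domain_map, predict_variants

variants = pd.DataFrame(
    [
        {
            "variant": "G566R", "position": 566, "wt": "G", "mut": "R",
            "mapp_raw": 8.2, "sift": 0.01, "pph2_humvar": 0.99,
            "rel_acc_override": 0.05,
        }
    ]
)

table, errors = predict_variants(variants, msh6_domain_map(), default_model())
row = table.iloc[0]
print(f"{row['variant']} (MutS domain, raw MAPP threshold 4.1):")
print(f"  mapp_norm   = {row['mapp_norm']:.3f}   (raw {row['mapp_raw']} / 4.1)")
print(f"  delta_heavy = {row['delta_heavy']}       (G: 0 -> R: 7 side-chain heavy atoms)")
print(f"  rel_acc     = {row['rel_acc']}    (buried position)")
print(f"  joint score q = {row['q']:.4f} -> {row['category']}")
print("A buried, conserved position with a large side-chain change scores as pathogenic.")
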