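#!/usr/bin/env python
"""Optional check: mean relative accessibility of LLS vs ULS positions on MSH6.

Needs a user-supplied MSH6-MSH2 heterodimer structure (PDB entry 2o8b or a
loop-completed derivative) — nothing is downloaded.  Positions absent from
the crystal (unmodeled loops / residues) are reported and skipped unless an
override table supplies them.

The published study computed these means (about 0.14 for pathogenic-variant
positions and 0.59 for benign ones) on a loop-completed structure with an
unstated radius set and normalization, so agreement here is approximate by
construction: this script is a sanity check, not a gating test.

Usage:
    python scripts/reproduce_accessibility_means.py path/to/2o8b.pdb \
        [--chain A] [--acc-overrides overrides.tsv] [--sphere-points 960]
"""

from __future__ import annotations

import argparse

import numpy as np

from codp.datasets import load_classified_variants
from codp.io import parse_variant, read_tsv
from codp.structure import accessibility_table, read_structure


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("pdb", help="MSH6-containing PDB file (e.g. 2o8b)")
    parser.add_argument("--chain", default="A", help="chain carrying MSH6")
    parser.add_argument("--acc-overrides", help="TSV with columns position, rel_acc")
    parser.add_argument("--sphere-points", type=int, default=960)
    parser.add_argument("--probe-radius", type=float, default=1.4)
    args = parser.parse_args()

    with open(args.pdb) as fh:
        structure = read_structure(fh.read())
    table = accessibility_table(
        structure, probe_radius=args.probe_radius, n_sphere_points=args.sphere_points
    )
    table = table[table["chain"] == args.chain]
    acc = dict(zip(table["resnum"], table["rel_acc"]))
    if args.acc_overrides:
        ov = read_tsv(args.acc_overrides, required=("position", "rel_acc"))
        acc.update(zip(ov["position"].astype(int), ov["rel_acc"].astype(float)))

    variants = load_classified_variants()
    for label in ("LLS", "ULS"):
        positions = [
            parse_variant(v).position
            for v in variants.loc[variants["label"] == label, "variant"]
        ]
        found = [acc[p] for p in positions if p in acc and np.isfinite(acc[p])]
        missing = sorted(p for p in positions if p not in acc)
        mean = np.mean(found) if found else float("nan")
        print(
            f"{label}: mean relative accessibility {mean:.3f} over "
            f"{len(found)}/{len(positions)} positions"
            + (f" (missing from structure: {missing})" if missing else "")
        )


if __name__ == "__main__":
    main()
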