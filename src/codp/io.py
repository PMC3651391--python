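"""TSV/JSON conventions and variant-string parsing.

Tables are tab-separated UTF-8 with '#' comment lines and '.' for missing
values.  Variants use the protein one-letter convention printed throughout
the MSH6 literature: wild-type letter, 1-based position, mutant letter
(e.g. "E1193K").
"""

from __future__ import annotations

import re
from typing import NamedTuple

import pandas as pd

from .aa_properties import SIDE_CHAIN_HEAVY_ATOMS

__all__ = ["Substitution", "parse_variant", "read_tsv", "write_tsv"]

_VARIANT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class Substitution(NamedTuple):
    wt: str
    position: int
    mut: str

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


def parse_variant(text: str) -> Substitution:
    """Parse "E1193K"-style variant strings; canonical residues only."""
    m = _VARIANT_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed variant string {text!r} (expected e.g. 'E1193K')")
    wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    for code in (wt, mut):
        if code not in SIDE_CHAIN_HEAVY_ATOMS:
            raise ValueError(f"non-canonical residue code {code!r} in variant {text!r}")
    if pos < 1:
        raise ValueError(f"position must be >= 1 in variant {text!r}")
    return Substitution(wt, pos, mut)


def read_tsv(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["."])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")
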