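"""Packaged study data and synthetic generators.

The package ships reviewable TSV transcriptions of the curated MSH6 study
data: the 34 evidence-classified variant carriers (15 LLS / 19 ULS) with
every clinical and molecular field, and the 260 unclassified variants with
their published joint scores.  Each row carries a provenance tag naming the
source table and row so transcriptions stay diffable.

Synthetic generators provide structures with known accessibility geometry
and labelled feature tables drawn from a known logistic model, for testing
the accessibility engine and the fitting machinery.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pandas as pd

from .combiner import FEATURE_NAMES, FeatureVector, LogisticModel, joint_score
from .structure import StructureModel, read_structure

__all__ = [
    "load_classified_variants",
    "load_uv_scores",
    "generate_synthetic_structure",
    "generate_labeled_dataset",
    "DEFAULT_FEATURE_RANGES",
]


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    with resources.files("codp.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", na_values=["."])


def load_classified_variants() -> pd.DataFrame:
    """The 34 evidence-classified MSH6 variant carriers (15 LLS, 19 ULS)."""
    df = _read_packaged_tsv("classified_variants_msh6.tsv")
    # the evidence enums use '.' only for maf; everything else is explicit
    for col in df.columns:
        if col != "maf":
            df[col] = df[col].astype(str)
    df["maf"] = pd.to_numeric(df["maf"], errors="coerce")
    return df


def load_uv_scores() -> pd.DataFrame:
    """The 260 unclassified variants with their published joint scores."""
    df = _read_packaged_tsv("uv_joint_scores_msh6.tsv")
    df["score"] = df["score"].astype(float)
    return df


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: int, xyz, element: str
) -> str:
    x, y, z = xyz
    pad = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {pad:<4s} {resname:>3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


def generate_synthetic_structure(
    layout: str, n_residues: int = 1, seed: int = 0, residue: str = "GLY"
) -> tuple[str, StructureModel]:
    """Deterministic synthetic PDB structures for accessibility testing.

    Layouts: ``isolated`` (one idealized residue), ``helix`` (a C-alpha
    poly-alanine trace on ideal alpha-helix parameters: 1.5 Å rise, 100°
    twist, 2.3 Å radius, i.e. 3.8 Å between consecutive C-alphas) and
    ``caged`` (a central residue enclosed in a shell of occluding carbon
    atoms, fully buried by construction).  Returns the PDB text and the
    parsed :class:`StructureModel`.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    lines: list[str] = []
    serial = 1

    if layout == "isolated":
        from .structure import ideal_residue_structure

        model = ideal_residue_structure(residue)
        for a in model.atoms:
            lines.append(
                _pdb_atom_line(serial, a.atom_name, a.residue_name, "A", 1, a.coords, a.element)
            )
            serial += 1
    elif layout == "helix":
        rise, twist, radius = 1.5, math.radians(100.0), 2.3
        for i in range(n_residues):
            xyz = (radius * math.cos(i * twist), radius * math.sin(i * twist), i * rise)
            lines.append(_pdb_atom_line(serial, "CA", "ALA", "A", i + 1, xyz, "C"))
            serial += 1
    elif layout == "caged":
        from .structure import golden_spiral_points, ideal_residue_structure

        model = ideal_residue_structure(residue)
        coords = np.array([a.coords for a in model.atoms])
        center = coords.mean(axis=0)
        for a in model.atoms:
            lines.append(
                _pdb_atom_line(serial, a.atom_name, a.residue_name, "A", 1, a.coords, a.element)
            )
            serial += 1
        # shell radius: just outside the residue, well inside probe reach
        extent = float(np.max(np.linalg.norm(coords - center, axis=1)))
        shell = golden_spiral_points(200) * (extent + 2.0) + center
        for i, xyz in enumerate(shell):
            lines.append(_pdb_atom_line(serial, "C", "CAG", "B", i + 2, tuple(xyz), "C"))
            serial += 1
    else:
        raise ValueError(f"unknown layout {layout!r}; use isolated, helix or caged")

    text = "".join(lines) + "END\n"
    return text, read_structure(text)


DEFAULT_FEATURE_RANGES: dict[str, tuple[float, float]] = {
    "mapp_norm": (0.0, 4.0),
    "sift": (0.0, 1.0),
    "pph2_humvar": (0.0, 1.0),
    "delta_heavy": (0.0, 10.0),  # integer-valued draw
    "rel_acc": (0.0, 1.0),
}


def generate_labeled_dataset(
    model: LogisticModel,
    n: int,
    seed: int,
    feature_ranges: dict[str, tuple[float, float]] | None = None,
) -> tuple[list[FeatureVector], np.ndarray]:
    """Features drawn uniformly from the stated ranges with Bernoulli(q) labels.

    ``delta_heavy`` is drawn as an integer over its range; all other
    predictors are continuous uniforms.  Reproducible by ``seed``.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    ranges = DEFAULT_FEATURE_RANGES if feature_ranges is None else feature_ranges
    for name in FEATURE_NAMES:
        lo, hi = ranges[name]
        if hi < lo:
            raise ValueError(f"empty range for {name}")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in FEATURE_NAMES:
        lo, hi = ranges[name]
        if name == "delta_heavy":
            cols[name] = rng.integers(int(lo), int(hi) + 1, size=n).astype(float)
        else:
            cols[name] = rng.uniform(lo, hi, size=n)
    features = [
        FeatureVector(**{name: cols[name][i] for name in FEATURE_NAMES}) for i in range(n)
    ]
    q = np.array([joint_score(f, model) for f in features])
    labels = (rng.uniform(size=n) < q).astype(int)
    return features, labels
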