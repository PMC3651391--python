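"""The joint logistic score combining sequence and structure predictors.

Five predictors feed a logistic regression: the domain-normalized MAPP
impact score, the SIFT score, the PolyPhen-2 HumVar score, the side-chain
heavy-atom change and the relative solvent accessibility of the wild-type
residue.  The joint score

    q = 1 / (1 + exp(-(Z + sum_i b_i X_i)))

is read as the probability that the substitution is pathogenic.  The
packaged default coefficients are the published MSH6 fit: variants with
q <= 0.56 are called non-pathogenic, 0.56 < q <= 0.65 moderate impact and
q > 0.65 impaired function.  PolyPhen-2 HumDiv is deliberately not a
predictor (it discriminated worse than HumVar on the MSH6 set); it may be
carried in input tables but never enters the model.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .aa_properties import delta_heavy_atoms
from .mapp import DomainMap, normalize_mapp
from .structure import MissingResidueError

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "LogisticModel",
    "ImpactCategory",
    "ImpactCall",
    "FitResult",
    "CompleteSeparationError",
    "default_model",
    "joint_score",
    "classify_impact",
    "fit_logistic",
    "predict_variants",
    "T_LOW",
    "T_HIGH",
]

FEATURE_NAMES = ("mapp_norm", "sift", "pph2_humvar", "delta_heavy", "rel_acc")
T_LOW = 0.56
T_HIGH = 0.65


class CompleteSeparationError(RuntimeError):
    """The two classes are perfectly separable; the MLE does not exist.

    Refit with ``ridge`` set to a positive penalty to obtain a finite,
    shrunken solution.
    """


class ImpactCategory(str, Enum):
    NON_PATHOGENIC = "non_pathogenic"
    MODERATE = "moderate"
    IMPAIRED = "impaired"


@dataclass(frozen=True)
class FeatureVector:
    mapp_norm: float
    sift: float
    pph2_humvar: float
    delta_heavy: float
    rel_acc: float

    def __post_init__(self):
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite feature in {self}")
        if not 0.0 <= self.sift <= 1.0:
            raise ValueError(f"SIFT score {self.sift} outside [0, 1]")
        if not 0.0 <= self.pph2_humvar <= 1.0:
            raise ValueError(f"PolyPhen-2 HumVar score {self.pph2_humvar} outside [0, 1]")
        if self.delta_heavy < 0 or self.rel_acc < 0 or self.mapp_norm < 0:
            raise ValueError("mapp_norm, delta_heavy and rel_acc must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mapp_norm, self.sift, self.pph2_humvar, self.delta_heavy, self.rel_acc],
            dtype=float,
        )


@dataclass(frozen=True)
class LogisticModel:
    intercept: float
    coefficients: tuple[float, float, float, float, float]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("one coefficient per feature required")
        if not (math.isfinite(self.intercept) and all(map(math.isfinite, self.coefficients))):
            raise ValueError("model parameters must be finite")

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        coef = d["coefficients"]
        names = tuple(coef)
        return cls(float(d["intercept"]), tuple(float(coef[n]) for n in names), names)

    @classmethod
    def from_json(cls, path) -> "LogisticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(zip(self.feature_names, self.coefficients)),
        }


def default_model() -> LogisticModel:
    """The packaged published MSH6 coefficients."""
    text = resources.files("codp.data").joinpath("codp_model.json").read_text()
    return LogisticModel.from_dict(json.loads(text))


def joint_score(features: FeatureVector, model: LogisticModel | None = None) -> float:
    """The logistic joint score q in (0, 1)."""
    model = default_model() if model is None else model
    x = features.as_array()
    if model.feature_names != FEATURE_NAMES:
        order = [model.feature_names.index(n) for n in FEATURE_NAMES]
        b = np.array(model.coefficients, dtype=float)[order]
    else:
        b = np.array(model.coefficients, dtype=float)
    eta = model.intercept + float(b @ x)
    # expit, written out to avoid overflow warnings at extreme eta
    if eta >= 0:
        return 1.0 / (1.0 + math.exp(-eta))
    z = math.exp(eta)
    return z / (1.0 + z)


@dataclass(frozen=True)
class ImpactCall:
    q: float
    category: ImpactCategory
    pathogenic: bool


def classify_impact(q: float, t_low: float = T_LOW, t_high: float = T_HIGH) -> ImpactCall:
    """Three-way impact call from a joint score.

    q <= t_low: non-pathogenic; t_low < q <= t_high: moderate impact;
    q > t_high: impaired function.  The pathogenic flag is q > t_low.
    """
    if not 0.0 < t_low < t_high < 1.0:
        raise ValueError("need 0 < t_low < t_high < 1")
    if not (np.isfinite(q) and 0.0 < q < 1.0):
        # printed scores are rounded and may reach the closed endpoints
        if not (np.isfinite(q) and 0.0 <= q <= 1.0):
            raise ValueError(f"joint score {q!r} outside [0, 1]")
    if q <= t_low:
        cat = ImpactCategory.NON_PATHOGENIC
    elif q <= t_high:
        cat = ImpactCategory.MODERATE
    else:
        cat = ImpactCategory.IMPAIRED
    return ImpactCall(q=float(q), category=cat, pathogenic=q > t_low)


@dataclass(frozen=True)
class FitResult:
    model: LogisticModel
    log_likelihood: float
    standard_errors: tuple[float, ...] | None
    n_iterations: int
    converged: bool
    separation_warning: bool
    ridge: float = 0.0


def _design(features: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(features, np.ndarray):
        x = np.asarray(features, dtype=float)
    else:
        x = np.array([f.as_array() for f in features], dtype=float)
    if x.ndim != 2 or x.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"feature matrix must be n x {len(FEATURE_NAMES)}")
    return x


def fit_logistic(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[int],
    ridge: float = 0.0,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> FitResult:
    """Maximum-likelihood logistic regression of pathogenic labels on the five predictors.

    Newton iterations (via statsmodels) run until the largest parameter change
    falls below ``tol`` or ``maxiter`` is reached.  Perfectly separable data
    have no MLE: a :class:`CompleteSeparationError` is raised unless a
    positive ``ridge`` penalty (L2, applied to the coefficients) is given, in
    which case a shrunken fit (via scikit-learn) is returned without
    standard errors.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = _design(features)
    y = np.asarray(labels, dtype=float)
    if len(y) != len(x):
        raise ValueError("features and labels differ in length")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 examples of each class")

    if ridge > 0:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000)
        clf.fit(x, y)
        model = LogisticModel(float(clf.intercept_[0]), tuple(map(float, clf.coef_[0])))
        q = np.array([joint_score(FeatureVector(*row), model) for row in x])
        ll = float(np.sum(y * np.log(q) + (1 - y) * np.log1p(-q)))
        return FitResult(model, ll, None, clf.n_iter_[0], True, False, ridge)

    design = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(method="newton", tol=tol, maxiter=maxiter, disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise CompleteSeparationError(
                "classes are perfectly separated; pass ridge > 0 to regularize"
            ) from exc
    separation = any("separat" in str(w.message).lower() for w in caught)
    params = np.asarray(res.params, dtype=float)
    if separation or not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e4:
        raise CompleteSeparationError(
            "classes are perfectly (or quasi-perfectly) separated; "
            "pass ridge > 0 to regularize"
        )
    bse = np.asarray(res.bse, dtype=float)
    return FitResult(
        model=LogisticModel(float(params[0]), tuple(map(float, params[1:]))),
        log_likelihood=float(res.llf),
        standard_errors=tuple(map(float, bse)),
        n_iterations=int(res.mle_retvals.get("iterations", 0)),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation_warning=separation,
    )


def predict_variants(
    variant_table: pd.DataFrame,
    domain_map: DomainMap,
    model: LogisticModel | None = None,
    structure=None,
    chain: str | None = None,
    accessibility_overrides: dict[int, float] | None = None,
    t_low: float = T_LOW,
    t_high: float = T_HIGH,
    **asa_kwargs,
) -> tuple[pd.DataFrame, list[dict]]:
    """End-to-end per-variant prediction.

    The input frame needs columns ``variant, position, wt, mut, mapp_raw,
    sift, pph2_humvar`` and optionally ``rel_acc_override``.  Relative
    accessibility is resolved per row from, in order: the row override, the
    ``accessibility_overrides`` map, then the structure (requires ``chain``).
    Returns the annotated output frame plus a list of row-level error
    records; a missing score or unmodeled residue skips the row, it never
    aborts the run.
    """
    from .structure import accessibility_table

    model = default_model() if model is None else model
    acc_from_structure: dict[int, float] = {}
    if structure is not None:
        if chain is None:
            raise ValueError("a chain id is required when resolving accessibility from a structure")
        tab = accessibility_table(structure, **asa_kwargs)
        tab = tab[tab["chain"] == chain]
        acc_from_structure = dict(zip(tab["resnum"], tab["rel_acc"]))
    overrides = accessibility_overrides or {}

    rows, errors = [], []
    for _, row in variant_table.iterrows():
        name = row.get("variant", f"row{_}")
        try:
            pos = int(row["position"])
            for col in ("mapp_raw", "sift", "pph2_humvar"):
                if col not in row or pd.isna(row[col]):
                    raise ValueError(f"missing component score {col!r}")
            if "rel_acc_override" in row and not pd.isna(row.get("rel_acc_override")):
                rel_acc = float(row["rel_acc_override"])
            elif pos in overrides:
                rel_acc = float(overrides[pos])
            elif pos in acc_from_structure and np.isfinite(acc_from_structure[pos]):
                rel_acc = float(acc_from_structure[pos])
            else:
                raise MissingResidueError(chain or "?", pos)
            fv = FeatureVector(
                mapp_norm=normalize_mapp(float(row["mapp_raw"]), pos, domain_map),
                sift=float(row["sift"]),
                pph2_humvar=float(row["pph2_humvar"]),
                delta_heavy=delta_heavy_atoms(str(row["wt"]), str(row["mut"])),
                rel_acc=rel_acc,
            )
            q = joint_score(fv, model)
            call = classify_impact(q, t_low, t_high)
            out = dict(row)
            out.update(
                mapp_norm=fv.mapp_norm,
                delta_heavy=fv.delta_heavy,
                rel_acc=fv.rel_acc,
                q=q,
                category=call.category.value,
                pathogenic=call.pathogenic,
            )
            rows.append(out)
        except MissingResidueError as exc:
            errors.append({"variant": name, "error": "missing residue", "detail": str(exc)})
        except (ValueError, KeyError) as exc:
            errors.append({"variant": name, "error": type(exc).__name__, "detail": str(exc)})
    return pd.DataFrame(rows), errors
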