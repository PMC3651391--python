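"""Evidence-based classification of MSH6 variant carriers.

A carrier is "likely to be Lynch syndrome" (LLS, i.e. carries a pathogenic
variant) or "unlikely" (ULS) when it fulfils at least one criterion of the
corresponding column:

LLS-1  abnormal functional assay AND (IHC loss of only MSH6 OR MSI-H)
LLS-2  IHC loss of only MSH6 AND MSI-H
LLS-3  (IHC loss of only MSH6 OR supportive segregation) AND at least two of
       {striking family history, early/multiple proband tumours,
        allele absent from >= 100 healthy controls}
ULS-1  polymorphism (minor allele frequency >= 0.01)
ULS-2  normal functional assay AND (MSS OR normal MSH6 IHC)
ULS-3  MSS AND normal MSH6 IHC

Unknown / not-determined / inconclusive observations never satisfy a
predicate.  A record firing criteria on both sides is labelled ``conflict``
and surfaced, never silently resolved; a record firing none is an
unclassified variant (UV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

__all__ = [
    "Tri",
    "Msi",
    "ClinicalRecord",
    "EvidenceLabel",
    "EvidenceCall",
    "ihc_only_msh6_abnormal",
    "functional_assay_state",
    "classify_evidence",
    "classify_evidence_table",
    "record_from_row",
]

_IHC_VALUES = {"normal", "abnormal", "inconclusive", "nd", "na"}
_ASSAY_VALUES = {"normal", "abnormal", "inconclusive", "nd"}
_MSI_VALUES = {"H", "L", "S", "nd"}
_YESNO_VALUES = {"yes", "no", "nd"}
_CTRL_VALUES = {"yes", "no", "inconclusive", "nd"}

ASSAY_FIELDS = (
    "assay_mmr_activity",
    "assay_msh2_interaction",
    "assay_localization",
    "assay_atp_hydrolysis",
    "assay_mismatch_recognition",
)


class Tri(str, Enum):
    ABNORMAL = "abnormal"
    NORMAL = "normal"
    UNKNOWN = "unknown"


class Msi(str, Enum):
    HIGH = "H"
    LOW = "L"
    STABLE = "S"
    ND = "nd"


class EvidenceLabel(str, Enum):
    LLS = "LLS"
    ULS = "ULS"
    UV = "UV"
    CONFLICT = "conflict"


@dataclass(frozen=True)
class ClinicalRecord:
    ihc_mlh1: str = "nd"
    ihc_msh2: str = "nd"
    ihc_msh6: str = "nd"
    msi: str = "nd"
    assay_mmr_activity: str = "nd"
    assay_msh2_interaction: str = "nd"
    assay_localization: str = "nd"
    assay_atp_hydrolysis: str = "nd"
    assay_mismatch_recognition: str = "nd"
    segregation_supportive: str = "nd"
    family_history_met: str = "nd"
    proband_tumor_met: str = "nd"
    control_freq_zero_n100: str = "nd"
    minor_allele_frequency: float | None = None

    def __post_init__(self):
        for name in ("ihc_mlh1", "ihc_msh2", "ihc_msh6"):
            if getattr(self, name) not in _IHC_VALUES:
                raise ValueError(f"{name}={getattr(self, name)!r} not in {sorted(_IHC_VALUES)}")
        for name in ASSAY_FIELDS:
            if getattr(self, name) not in _ASSAY_VALUES:
                raise ValueError(f"{name}={getattr(self, name)!r} not in {sorted(_ASSAY_VALUES)}")
        if self.msi not in _MSI_VALUES:
            raise ValueError(f"msi={self.msi!r} not in {sorted(_MSI_VALUES)}")
        for name in ("segregation_supportive", "family_history_met", "proband_tumor_met"):
            if getattr(self, name) not in _YESNO_VALUES:
                raise ValueError(f"{name}={getattr(self, name)!r} not in {sorted(_YESNO_VALUES)}")
        if self.control_freq_zero_n100 not in _CTRL_VALUES:
            raise ValueError(
                f"control_freq_zero_n100={self.control_freq_zero_n100!r} not in {sorted(_CTRL_VALUES)}"
            )
        if self.minor_allele_frequency is not None and not (
            0.0 <= self.minor_allele_frequency <= 1.0
        ):
            raise ValueError("minor allele frequency must lie in [0, 1]")


@dataclass(frozen=True)
class EvidenceCall:
    label: EvidenceLabel
    criteria_met: tuple[str, ...]
    trace: tuple[str, ...] = field(default=())


def ihc_only_msh6_abnormal(record: ClinicalRecord) -> bool:
    """IHC loss of MSH6 with MLH1 and MSH2 not lost.

    Inconclusive / not-determined MLH1 or MSH2 staining does not veto — the
    criterion asks whether MSH6 is the only protein *shown* lost.
    """
    return (
        record.ihc_msh6 == "abnormal"
        and record.ihc_mlh1 != "abnormal"
        and record.ihc_msh2 != "abnormal"
    )


def functional_assay_state(record: ClinicalRecord) -> Tri:
    """Aggregate the five biochemical assays.

    Any single abnormal assay makes the aggregate abnormal; otherwise one or
    more normal results (and none abnormal) make it normal; otherwise it is
    unknown.  Inconclusive results are ignored.
    """
    states = [getattr(record, f) for f in ASSAY_FIELDS]
    if "abnormal" in states:
        return Tri.ABNORMAL
    if "normal" in states:
        return Tri.NORMAL
    return Tri.UNKNOWN


def classify_evidence(record: ClinicalRecord) -> EvidenceCall:
    """Evaluate all six criteria and return the label with a rule-firing trace."""
    only_msh6 = ihc_only_msh6_abnormal(record)
    assay = functional_assay_state(record)
    msi_h = record.msi == "H"
    mss = record.msi == "S"
    msh6_normal = record.ihc_msh6 == "normal"

    minor_criteria = [
        ("family history", record.family_history_met == "yes"),
        ("proband tumour feature", record.proband_tumor_met == "yes"),
        ("absent in >=100 controls", record.control_freq_zero_n100 == "yes"),
    ]
    n_minor = sum(met for _, met in minor_criteria)
    maf = record.minor_allele_frequency
    polymorphism = maf is not None and maf >= 0.01

    fired: list[str] = []
    trace: list[str] = []

    def rule(name: str, value: bool, why: str):
        trace.append(f"{name}: {'FIRED' if value else 'not met'} ({why})")
        if value:
            fired.append(name)

    rule(
        "LLS-1",
        assay is Tri.ABNORMAL and (only_msh6 or msi_h),
        f"assay={assay.value}, only-MSH6-IHC={only_msh6}, MSI-H={msi_h}",
    )
    rule("LLS-2", only_msh6 and msi_h, f"only-MSH6-IHC={only_msh6}, MSI-H={msi_h}")
    rule(
        "LLS-3",
        (only_msh6 or record.segregation_supportive == "yes") and n_minor >= 2,
        f"only-MSH6-IHC={only_msh6}, segregation={record.segregation_supportive}, "
        f"minor criteria met={n_minor}/3",
    )
    rule("ULS-1", polymorphism, f"MAF={maf}")
    rule(
        "ULS-2",
        assay is Tri.NORMAL and (mss or msh6_normal),
        f"assay={assay.value}, MSS={mss}, MSH6-IHC-normal={msh6_normal}",
    )
    rule("ULS-3", mss and msh6_normal, f"MSS={mss}, MSH6-IHC-normal={msh6_normal}")

    lls = any(c.startswith("LLS") for c in fired)
    uls = any(c.startswith("ULS") for c in fired)
    if lls and uls:
        label = EvidenceLabel.CONFLICT
    elif lls:
        label = EvidenceLabel.LLS
    elif uls:
        label = EvidenceLabel.ULS
    else:
        label = EvidenceLabel.UV
    return EvidenceCall(label=label, criteria_met=tuple(fired), trace=tuple(trace))


def record_from_row(row: "pd.Series | dict") -> ClinicalRecord:
    """Build a :class:`ClinicalRecord` from a fixture/TSV row ('.' = unknown)."""
    def get(name, default="nd"):
        v = row.get(name, default)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == ".":
            return default
        return str(v)

    maf_raw = row.get("maf", row.get("minor_allele_frequency", "."))
    maf = None
    if maf_raw not in (None, ".", "") and not (isinstance(maf_raw, float) and pd.isna(maf_raw)):
        maf = float(maf_raw)
    return ClinicalRecord(
        ihc_mlh1=get("ihc_mlh1"),
        ihc_msh2=get("ihc_msh2"),
        ihc_msh6=get("ihc_msh6"),
        msi=get("msi"),
        assay_mmr_activity=get("assay_mmr_activity"),
        assay_msh2_interaction=get("assay_msh2_interaction"),
        assay_localization=get("assay_localization"),
        assay_atp_hydrolysis=get("assay_atp_hydrolysis"),
        assay_mismatch_recognition=get("assay_mismatch_recognition"),
        segregation_supportive=get("segregation_supportive"),
        family_history_met=get("family_history_met"),
        proband_tumor_met=get("proband_tumor_met"),
        control_freq_zero_n100=get("control_freq_zero_n100"),
        minor_allele_frequency=maf,
    )


def classify_evidence_table(
    table: pd.DataFrame, conflict_as_uv: bool = False
) -> pd.DataFrame:
    """Classify every row of an evidence table.

    Returns a frame with ``variant, label, criteria_met, trace`` columns.
    With ``conflict_as_uv`` records firing both sides are downgraded to UV
    instead of carrying the explicit conflict label.
    """
    rows = []
    for _, row in table.iterrows():
        call = classify_evidence(record_from_row(row))
        label = call.label
        if conflict_as_uv and label is EvidenceLabel.CONFLICT:
            label = EvidenceLabel.UV
        rows.append(
            {
                "variant": row.get("variant", f"row{_}"),
                "label": label.value,
                "criteria_met": ",".join(call.criteria_met),
                "trace": " | ".join(call.trace),
            }
        )
    return pd.DataFrame(rows)
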