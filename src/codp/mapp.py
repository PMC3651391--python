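"""Domain-aware normalization of MAPP impact scores.

MAPP's raw impact score measures how strongly a substitution violates the
physicochemical conservation seen in an orthologue alignment.  Because
conservation differs between regions of MSH6, the optimal decision threshold
differs per domain (8.5 for the whole-sequence alignment, 4.1 for the
PCNA-binding motif, 5.0 for the PWWP domain, 4.1 for the MutS domain).
Dividing each raw score by the threshold of its covering domain puts the
decision boundary at 1.0 everywhere along the sequence.

Raw MAPP scoring itself (alignment building and per-column statistics) is a
consumed input, not computed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "DomainEntry",
    "DomainMap",
    "INTER_DOMAIN",
    "msh6_domain_map",
    "domain_of",
    "normalize_mapp",
]

INTER_DOMAIN = "inter-domain"


@dataclass(frozen=True)
class DomainEntry:
    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    threshold: float

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad domain span {self.start}..{self.end} for {self.name!r}")
        if self.threshold <= 0:
            raise ValueError(f"threshold for {self.name!r} must be positive")


@dataclass(frozen=True)
class DomainMap:
    entries: tuple[DomainEntry, ...] = ()
    default_threshold: float = 8.5

    def __post_init__(self):
        if self.default_threshold <= 0:
            raise ValueError("default_threshold must be positive")
        spans = sorted((e.start, e.end, e.name) for e in self.entries)
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"domains {n1!r} and {n2!r} overlap")

    @classmethod
    def from_dict(cls, d: dict) -> "DomainMap":
        entries = tuple(
            DomainEntry(e["name"], int(e["start"]), int(e["end"]), float(e["threshold"]))
            for e in d.get("domains", ())
        )
        return cls(entries=entries, default_threshold=float(d.get("default_threshold", 8.5)))

    @classmethod
    def from_json(cls, path) -> "DomainMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "default_threshold": self.default_threshold,
            "domains": [
                {"name": e.name, "start": e.start, "end": e.end, "threshold": e.threshold}
                for e in self.entries
            ],
        }


def msh6_domain_map() -> DomainMap:
    """The packaged MSH6 domain map (PCNA motif, PWWP and MutS domains)."""
    text = resources.files("codp.data").joinpath("msh6_domain_map.json").read_text()
    return DomainMap.from_dict(json.loads(text))


def domain_of(position: int, domain_map: DomainMap) -> str:
    """Name of the domain covering a 1-based position, else ``"inter-domain"``."""
    if position < 1:
        raise ValueError("protein positions are 1-based")
    for e in domain_map.entries:
        if e.start <= position <= e.end:
            return e.name
    return INTER_DOMAIN


def threshold_at(position: int, domain_map: DomainMap) -> float:
    if position < 1:
        raise ValueError("protein positions are 1-based")
    for e in domain_map.entries:
        if e.start <= position <= e.end:
            return e.threshold
    return domain_map.default_threshold


def normalize_mapp(raw_score: float, position: int, domain_map: DomainMap) -> float:
    """Raw MAPP impact score divided by the threshold of its covering domain.

    A normalized score of exactly 1.0 sits on the domain's decision boundary;
    positions outside every named domain use the whole-sequence threshold.
    """
    if raw_score < 0:
        raise ValueError("raw MAPP impact scores are non-negative")
    return raw_score / threshold_at(position, domain_map)
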