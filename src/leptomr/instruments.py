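"""Instrument selection and quality control.

Genetic variants only qualify as instrumental variables when they are
robustly associated with the exposure.  Selection applies a p-value
threshold (genome-wide 5e-8 by default, relaxed to a nominal threshold for
subgroup-derived effect sizes) and the conventional instrument-strength
filter F >= 10, with F = (beta/se)^2.  When an instrument is absent from the
outcome study, a proxy variant in high LD substitutes for it; proxy choice
ranks by r^2, then distance to the lead variant, then non-palindromic
alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .sumstats import SummaryAssociation, classify_palindromic

__all__ = [
    "InstrumentRecord",
    "ProxyCandidate",
    "f_statistic",
    "select_instruments",
    "retained",
    "select_proxy",
    "read_proxy_candidates",
]


@dataclass(frozen=True)
class InstrumentRecord:
    """An exposure association annotated with strength and selection status."""

    association: SummaryAssociation
    f_stat: float
    selected: bool
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.selected != (self.exclusion_reason == ""):
            raise ValueError("exclusion_reason must be non-empty iff not selected")

    @property
    def snp_id(self) -> str:
        return self.association.snp_id


@dataclass(frozen=True)
class ProxyCandidate:
    """A variant in LD with a lead instrument, candidate replacement."""

    snp_id: str
    r2: float
    distance: float
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if not (0 <= self.r2 <= 1):
            raise ValueError(f"{self.snp_id}: r2 must be in [0, 1], got {self.r2}")
        if self.distance < 0:
            raise ValueError(f"{self.snp_id}: negative distance")

    @property
    def palindromic(self) -> bool:
        return classify_palindromic(self.effect_allele, self.other_allele)


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic, (beta/se)^2."""
    if not se > 0:
        raise ValueError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def select_instruments(
    records: Sequence[SummaryAssociation],
    p_primary: float = 5e-8,
    p_subgroup: float = 0.05,
    f_min: float = 10.0,
    subgroup: bool = False,
) -> list[InstrumentRecord]:
    """Annotate exposure associations with strength and selection status.

    A record is selected when its p-value is below the applicable threshold
    (``p_subgroup`` when ``subgroup`` is set, for effect sizes re-estimated
    in a subgroup of the discovery study; else ``p_primary``) and its
    F statistic is at least ``f_min``.  Weak instruments are reported with
    reason ``"weak_instrument"``, insufficiently associated ones with
    ``"nonsignificant"``.  Input order is preserved and every record is
    returned; use :func:`retained` for the selected subset.
    """
    threshold = p_subgroup if subgroup else p_primary
    out: list[InstrumentRecord] = []
    for assoc in records:
        f = f_statistic(assoc.beta, assoc.se)
        if f < f_min:
            out.append(InstrumentRecord(assoc, f, False, "weak_instrument"))
        elif assoc.pval >= threshold:
            out.append(InstrumentRecord(assoc, f, False, "nonsignificant"))
        else:
            out.append(InstrumentRecord(assoc, f, True))
    return out


def retained(records: Sequence[InstrumentRecord]) -> list[SummaryAssociation]:
    """The selected associations, in input order."""
    return [r.association for r in records if r.selected]


def select_proxy(
    lead: SummaryAssociation,
    candidates: Sequence[ProxyCandidate],
    r2_min: float = 0.80,
) -> ProxyCandidate | None:
    """Pick the best proxy for a lead variant absent from the outcome study.

    Among candidates with ``r2 >= r2_min``: highest r^2 first, then smallest
    distance to the lead variant, then non-palindromic alleles preferred,
    with a final lexicographic snp_id tie-break for determinism.  Returns
    ``None`` when no candidate qualifies.
    """
    passing = [c for c in candidates if c.r2 >= r2_min]
    if not passing:
        return None
    return min(passing, key=lambda c: (-c.r2, c.distance, c.palindromic, c.snp_id))


def read_proxy_candidates(path: str | Path) -> list[ProxyCandidate]:
    """Read proxy candidates from a TSV with columns snp, r2, distance, ea, oa."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str})
    return [
        ProxyCandidate(
            snp_id=str(row["snp"]),
            r2=float(row["r2"]),
            distance=float(row["distance"]),
            effect_allele=str(row["ea"]),
            other_allele=str(row["oa"]),
        )
        for _, row in df.iterrows()
    ]
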