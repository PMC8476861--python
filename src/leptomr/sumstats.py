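"""Data model, I/O and harmonization for two-sample GWAS/EWAS summary statistics.

Two-sample Mendelian randomization consumes per-SNP association summaries
from two independent studies: one for the exposure (here: circulating leptin
levels) and one for the outcome (here: anorexia nervosa, effects on the
log-odds scale).  Before any causal estimator can be applied the two sets of
effects must be expressed for the same allele of each variant
("harmonization"): allele labels are matched, swapped or strand-complemented,
and strand-ambiguous (palindromic) A/T and C/G variants are resolved from
allele frequencies, from a user-supplied LD-proxy direction table, or dropped.

This module also bundles the published leptin/anorexia instrument tables as
plain-TSV fixtures so the full analysis is runnable without downloads; see
:func:`load_fixture`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SummaryAssociation",
    "HarmonizedInstrument",
    "HarmonizePolicy",
    "ValidationError",
    "HarmonizationError",
    "PalindromicUnresolvableError",
    "or_to_beta",
    "classify_palindromic",
    "complement",
    "harmonize",
    "harmonize_pairs",
    "read_sumstats",
    "write_sumstats",
    "load_fixture",
    "LD_PROXY_DIRECTIONS",
    "FIXTURE_NAMES",
]

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical TSV column order for the summary-statistic dialect.
TSV_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]


class ValidationError(ValueError):
    """A summary-statistic record or file violates a type invariant."""


class HarmonizationError(ValueError):
    """Exposure and outcome records cannot be placed on a common allele."""


class PalindromicUnresolvableError(HarmonizationError):
    """A strand-ambiguous variant could not be resolved under the policy."""


@dataclass(frozen=True)
class SummaryAssociation:
    """One SNP-trait association from a summary-statistics file.

    ``beta`` is the additive effect per copy of ``effect_allele`` on the
    trait scale (log odds ratio for binary traits).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None
    trait_id: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: invalid effect allele {self.effect_allele!r}"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: invalid other allele {self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: non-finite beta")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects expressed for a common allele.

    ``bx``/``sx`` are the exposure effect and SE, ``by``/``sy`` the outcome
    effect and SE, all per copy of ``orientation`` (the allele the effects
    refer to after harmonization).  ``flipped`` records whether the outcome
    effect was sign-flipped relative to its input; ``palindromic`` marks
    strand-ambiguous variants.
    """

    snp_id: str
    bx: float
    sx: float
    by: float
    sy: float
    orientation: str
    eaf_x: float | None = None
    eaf_y: float | None = None
    palindromic: bool = False
    flipped: bool = False

    def __post_init__(self) -> None:
        if not (self.sx > 0 and self.sy > 0):
            raise ValidationError(f"{self.snp_id}: harmonized SEs must be positive")


@dataclass(frozen=True)
class HarmonizePolicy:
    """How to align outcome alleles onto exposure alleles.

    palindromic
        ``"eaf-resolve"`` (default) infers strand from allele frequencies
        when both studies' EAFs are far enough from 0.5
        (``|eaf - 0.5| > eaf_threshold``), falls back to
        ``proxy_directions`` (SNP id -> ``"same"``/``"flipped"``, typically
        derived from inspecting effect directions of LD proxies), and
        otherwise raises :class:`PalindromicUnresolvableError` so callers can
        drop the variant with a warning.  ``"strict"`` refuses all
        palindromic variants; ``"keep"`` assumes both studies report the
        forward strand.
    orientation
        ``"exposure-positive"`` re-orients each instrument so the exposure
        effect is non-negative (flips both betas, swaps alleles,
        complements EAFs); required by Egger regression.  ``"as-is"`` leaves
        signs untouched.
    """

    palindromic: str = "eaf-resolve"
    orientation: str = "exposure-positive"
    eaf_threshold: float = 0.08
    proxy_directions: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.palindromic not in {"eaf-resolve", "strict", "keep"}:
            raise ValueError(f"unknown palindromic policy {self.palindromic!r}")
        if self.orientation not in {"exposure-positive", "as-is"}:
            raise ValueError(f"unknown orientation policy {self.orientation!r}")


def or_to_beta(odds_ratio: float) -> float:
    """Convert an odds ratio to a log-odds effect size (natural log)."""
    if not odds_ratio > 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    return math.log(odds_ratio)


def complement(allele: str) -> str:
    """Reverse-strand complement of a single-base allele."""
    try:
        return _COMPLEMENT[allele]
    except KeyError:
        raise ValueError(f"invalid allele {allele!r}") from None


def classify_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G)."""
    for a in (effect_allele, other_allele):
        if a not in VALID_ALLELES:
            raise ValueError(f"invalid allele {a!r}")
    return complement(effect_allele) == other_allele


def _flip(by: float, eaf: float | None) -> tuple[float, float | None]:
    return -by, None if eaf is None else 1.0 - eaf


def harmonize(
    exposure: SummaryAssociation,
    outcome: SummaryAssociation,
    policy: HarmonizePolicy | None = None,
) -> HarmonizedInstrument:
    """Express exposure and outcome effects for a common allele.

    Outcome alleles equal to the exposure's are taken as-is; swapped alleles
    flip the outcome sign; for non-palindromic variants a strand flip is
    resolved by complementing before comparison.  Palindromic variants are
    resolved per ``policy``.  Raises :class:`HarmonizationError` when the
    allele sets are incompatible.
    """
    policy = policy or HarmonizePolicy()
    if exposure.snp_id != outcome.snp_id:
        raise HarmonizationError(
            f"snp_id mismatch: {exposure.snp_id} vs {outcome.snp_id}"
        )
    snp = exposure.snp_id
    exp_pair = (exposure.effect_allele, exposure.other_allele)
    out_pair = (outcome.effect_allele, outcome.other_allele)
    palindromic = classify_palindromic(*exp_pair)
    if palindromic != classify_palindromic(*out_pair):
        raise HarmonizationError(f"{snp}: allele sets incompatible {exp_pair} vs {out_pair}")

    by, eaf_y, flipped = outcome.beta, outcome.eaf, False
    if out_pair == exp_pair:
        pass
    elif out_pair == exp_pair[::-1]:
        by, eaf_y = _flip(by, eaf_y)
        flipped = True
    elif not palindromic:
        comp_pair = (complement(out_pair[0]), complement(out_pair[1]))
        if comp_pair == exp_pair:
            pass
        elif comp_pair == exp_pair[::-1]:
            by, eaf_y = _flip(by, eaf_y)
            flipped = True
        else:
            raise HarmonizationError(
                f"{snp}: allele mismatch not explainable by swap/complement: "
                f"{exp_pair} vs {out_pair}"
            )
    # palindromic complement == swap, so the two branches above are exhaustive

    if palindromic:
        if policy.palindromic == "strict":
            raise PalindromicUnresolvableError(
                f"{snp}: palindromic variant dropped under strict policy"
            )
        if policy.palindromic == "eaf-resolve":
            thr = policy.eaf_threshold
            ex, ey = exposure.eaf, eaf_y
            if (
                ex is not None
                and ey is not None
                and abs(ex - 0.5) > thr
                and abs(ey - 0.5) > thr
            ):
                if (ex < 0.5) != (ey < 0.5):  # discordant frequency: other strand
                    by, eaf_y = _flip(by, eaf_y)
                    flipped = not flipped
            else:
                direction = (policy.proxy_directions or {}).get(snp)
                if direction == "same":
                    pass
                elif direction == "flipped":
                    by, eaf_y = _flip(by, eaf_y)
                    flipped = not flipped
                else:
                    raise PalindromicUnresolvableError(
                        f"{snp}: palindromic variant with uninformative allele "
                        "frequencies and no proxy direction"
                    )
        # "keep": label-based alignment stands

    bx, eaf_x = exposure.beta, exposure.eaf
    orientation = exposure.effect_allele
    if policy.orientation == "exposure-positive" and bx < 0:
        bx, by = -bx, -by
        eaf_x = None if eaf_x is None else 1.0 - eaf_x
        eaf_y = None if eaf_y is None else 1.0 - eaf_y
        orientation = exposure.other_allele

    return HarmonizedInstrument(
        snp_id=snp,
        bx=bx,
        sx=exposure.se,
        by=by,
        sy=outcome.se,
        orientation=orientation,
        eaf_x=eaf_x,
        eaf_y=eaf_y,
        palindromic=palindromic,
        flipped=flipped,
    )


def harmonize_pairs(
    exposures: Sequence[SummaryAssociation],
    outcomes: Sequence[SummaryAssociation],
    policy: HarmonizePolicy | None = None,
) -> tuple[list[HarmonizedInstrument], dict[str, str]]:
    """Harmonize matching SNPs of two association lists.

    Returns the harmonized instruments (exposure order preserved) and a map
    of dropped SNP id -> reason (missing in outcome, or unresolvable
    palindromic variant under the policy).
    """
    out_by_id = {a.snp_id: a for a in outcomes}
    kept: list[HarmonizedInstrument] = []
    dropped: dict[str, str] = {}
    for exp in exposures:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            dropped[exp.snp_id] = "missing_in_outcome"
            continue
        try:
            kept.append(harmonize(exp, out, policy))
        except PalindromicUnresolvableError as err:
            dropped[exp.snp_id] = f"palindromic_unresolved: {err}"
    return kept, dropped


# ---------------------------------------------------------------------------
# TSV I/O


def _canonical_frame(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in ("snp", "ea", "oa", "beta", "se", "pval") if c not in df.columns]
    if missing:
        raise ValidationError(f"missing mandatory column(s): {', '.join(missing)}")
    return df


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "",
) -> list[SummaryAssociation]:
    """Read a summary-statistic TSV into validated association records.

    The native dialect has a header row with columns
    ``snp chr pos ea oa eaf beta se pval n`` and ``NA`` for missing values;
    ``column_map`` maps canonical names to foreign headers, e.g.
    ``{"snp": "MarkerName", "beta": "Effect"}``.  Rows violating invariants
    are rejected collectively with row-indexed messages; duplicated SNP ids
    within the file are an error, never a silent dedup.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp": str}, na_values=["NA"],
                     keep_default_na=True, float_precision="round_trip")
    df = _canonical_frame(df, column_map)
    records: list[SummaryAssociation] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            records.append(
                SummaryAssociation(
                    snp_id=str(row["snp"]),
                    chrom=None if pd.isna(row.get("chr")) else str(row["chr"]),
                    pos=None if pd.isna(row.get("pos")) else int(row["pos"]),
                    effect_allele=str(row["ea"]),
                    other_allele=str(row["oa"]),
                    eaf=None if pd.isna(row.get("eaf")) else float(row["eaf"]),
                    beta=float(row["beta"]),
                    se=float(row["se"]),
                    pval=float(row["pval"]),
                    n=None if pd.isna(row.get("n")) else float(row["n"]),
                    trait_id=trait_id,
                )
            )
        except (ValidationError, ValueError, TypeError) as err:
            errors.append(f"row {idx}: {err}")
    if errors:
        raise ValidationError("; ".join(errors))
    seen: dict[str, int] = {}
    for i, rec in enumerate(records):
        if rec.snp_id in seen:
            raise ValidationError(
                f"duplicate snp_id {rec.snp_id!r} at rows {seen[rec.snp_id]} and {i}"
            )
        seen[rec.snp_id] = i
    return records


def write_sumstats(records: Iterable[SummaryAssociation], path: str | Path) -> None:
    """Write association records in the native TSV dialect (NA for missing)."""
    rows = [
        {
            "snp": r.snp_id,
            "chr": r.chrom,
            "pos": r.pos,
            "ea": r.effect_allele,
            "oa": r.other_allele,
            "eaf": r.eaf,
            "beta": repr(r.beta),
            "se": repr(r.se),
            "pval": repr(r.pval),
            "n": r.n,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Packaged fixtures: published leptin instruments and their AN associations

#: Strand resolution for palindromic instruments established by inspecting
#: effect directions of LD proxies (rs791600:G:A and rs2167289:G:T, r² = 0.98
#: with rs10487505): both studies report the same strand.
LD_PROXY_DIRECTIONS: Mapping[str, str] = {"rs10487505": "same"}

_FIXTURE_FILES = {
    "gwas_combined": ("leptin_gwas.tsv", "an_gwas_for_gwas_snps.tsv"),
    "gwas_combined_bmi_adj": ("leptin_gwas_bmi_adj.tsv", "an_gwas_for_gwas_snps.tsv"),
    "ewas_eur": ("leptin_ewas_eur.tsv", "an_gwas_for_ewas_snps.tsv"),
    "ewas_eur_bmi_adj": ("leptin_ewas_eur_bmi_adj.tsv", "an_gwas_for_ewas_snps.tsv"),
}

FIXTURE_NAMES = tuple(_FIXTURE_FILES)

_FIXTURE_TRAITS = {
    "leptin_gwas.tsv": "leptin_gwas",
    "leptin_gwas_bmi_adj.tsv": "leptin_gwas_bmi_adj",
    "leptin_ewas_eur.tsv": "leptin_ewas_eur",
    "leptin_ewas_eur_bmi_adj.tsv": "leptin_ewas_eur_bmi_adj",
    "an_gwas_for_gwas_snps.tsv": "an_gwas",
    "an_gwas_for_ewas_snps.tsv": "an_gwas",
}


def load_fixture(name: str) -> tuple[list[SummaryAssociation], list[SummaryAssociation]]:
    """Load a packaged exposure/outcome association pair.

    ``name`` is one of ``gwas_combined`` (5 genome-wide leptin loci, with
    anorexia nervosa outcome effects), ``gwas_combined_bmi_adj`` (the same
    loci, exposure effects adjusted for BMI), ``ewas_eur`` (9 exome-wide
    leptin variants in Europeans) or ``ewas_eur_bmi_adj``.
    """
    try:
        exp_file, out_file = _FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    base = resources.files(__package__) / "fixtures"
    exposures = read_sumstats(str(base / exp_file), trait_id=_FIXTURE_TRAITS[exp_file])
    outcomes = read_sumstats(str(base / out_file), trait_id=_FIXTURE_TRAITS[out_file])
    return exposures, outcomes
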