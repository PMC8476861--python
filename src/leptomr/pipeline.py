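"""End-to-end two-sample MR orchestration, power analysis and reporting.

``run_pipeline`` wires the stages together: read summary statistics (from
TSV files or the packaged fixtures), select instruments, harmonize onto a
common allele, run the configured estimator suite and the diagnostics, and
serialize a provenance-carrying report (JSON with full precision plus TSV
tables).  Reverse-direction analyses — does the outcome trait causally
affect the exposure trait? — swap the roles of the two sources.

``mr_power_binary`` computes approximate power of an MR analysis with a
binary outcome: with outcome-study size N, case fraction K, instrumented
exposure variance R^2 and alternative odds ratio OR, the IVW z statistic is
approximately |ln OR| * sqrt(N * R^2 * K(1-K)) under the alternative, and
power follows from the two-sided normal test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from . import diagnostics as diag
from . import estimators as est
from .instruments import InstrumentRecord, retained, select_instruments
from .sumstats import (
    FIXTURE_NAMES,
    HarmonizePolicy,
    LD_PROXY_DIRECTIONS,
    SummaryAssociation,
    harmonize_pairs,
    load_fixture,
    read_sumstats,
)

__all__ = [
    "PowerConfig",
    "PipelineConfig",
    "ZeroInstrumentsError",
    "mr_power_binary",
    "exclude_bmi_nonrobust",
    "run_pipeline",
]

ALL_METHODS = tuple(est.MULTI_SNP_METHODS)


class ZeroInstrumentsError(RuntimeError):
    """No instrument survived quality control; carries the exclusion map."""

    def __init__(self, exclusions: Mapping[str, str]):
        self.exclusions = dict(exclusions)
        detail = "; ".join(f"{k}: {v}" for k, v in self.exclusions.items()) or "no input"
        super().__init__(f"zero instruments after QC ({detail})")


@dataclass(frozen=True)
class PowerConfig:
    """Inputs to the binary-outcome MR power approximation."""

    n_total: float
    case_fraction: float
    r2: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if not 0 <= self.r2 <= 1:
            raise ValueError("r2 must be in [0, 1]")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def mr_power_binary(cfg: PowerConfig) -> float:
    """Two-sided power to detect ``or_alt`` at level ``alpha``.

    power = Phi(z - z_{1-alpha/2}) + Phi(-z - z_{1-alpha/2}) with
    z = |ln OR| * sqrt(N * R^2 * K * (1-K)).  At OR = 1 this is exactly
    ``alpha`` (both rejection tails).
    """
    z_alt = abs(math.log(cfg.or_alt)) * math.sqrt(
        cfg.n_total * cfg.r2 * cfg.case_fraction * (1.0 - cfg.case_fraction)
    )
    z_crit = stats.norm.ppf(1.0 - cfg.alpha / 2.0)
    return float(stats.norm.cdf(z_alt - z_crit) + stats.norm.cdf(-z_alt - z_crit))


def exclude_bmi_nonrobust(
    instruments: Sequence[InstrumentRecord],
    bmi_adjusted: Sequence[SummaryAssociation],
    p_keep: float = 0.05,
) -> list[InstrumentRecord]:
    """Drop instruments whose BMI-adjusted exposure association is weak.

    A leptin instrument that loses its association once leptin levels are
    adjusted for BMI plausibly acts on the outcome through adiposity rather
    than through leptin itself, violating the exclusion restriction.  Any
    selected instrument whose adjusted p-value is >= ``p_keep`` is
    deselected with reason ``"bmi_nonrobust"``; a missing adjusted record
    for a selected instrument is an error.
    """
    adj_p = {a.snp_id: a.pval for a in bmi_adjusted}
    out: list[InstrumentRecord] = []
    for rec in instruments:
        if rec.selected:
            if rec.snp_id not in adj_p:
                raise KeyError(f"no BMI-adjusted record for instrument {rec.snp_id}")
            if adj_p[rec.snp_id] >= p_keep:
                rec = InstrumentRecord(rec.association, rec.f_stat, False, "bmi_nonrobust")
        out.append(rec)
    return out


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run one forward or reverse MR analysis.

    Sources are either a packaged ``fixture`` name or a pair of TSV paths.
    ``exclude_snps`` removes named variants up front (e.g. instruments that
    fail the BMI-robustness check); ``bmi_adjusted_path`` applies that check
    automatically.  ``seed`` drives every stochastic component (bootstrap
    SEs, MR-PRESSO) and is mandatory when any is enabled.
    """

    fixture: str | None = None
    exposure_path: str | None = None
    outcome_path: str | None = None
    direction: str = "forward"
    p_primary: float = 5e-8
    p_subgroup: float = 0.05
    subgroup: bool = False
    f_min: float = 10.0
    palindromic_policy: str = "eaf-resolve"
    use_fixture_proxy_directions: bool = True
    exclude_snps: tuple[str, ...] = ()
    bmi_adjusted_path: str | None = None
    methods: tuple[str, ...] = ALL_METHODS
    boot_reps: int = 1000
    presso_n_sim: int = 1000
    run_presso: bool = True
    seed: int | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.fixture is None) == (self.exposure_path is None):
            raise ValueError("provide either a fixture name or exposure/outcome paths")
        if self.fixture is not None and self.fixture not in FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.fixture!r}")
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")
        unknown = set(self.methods) - set(est.MULTI_SNP_METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        stochastic = self.run_presso or any(
            m in self.methods
            for m in ("simple_median", "weighted_median", "penalised_weighted_median",
                      "simple_mode", "weighted_mode")
        )
        if stochastic and self.seed is None:
            raise ValueError("seed is required when stochastic components are enabled")


def _load_sources(cfg: PipelineConfig):
    if cfg.fixture is not None:
        exposures, outcomes = load_fixture(cfg.fixture)
    else:
        exposures = read_sumstats(cfg.exposure_path, trait_id="exposure")
        outcomes = read_sumstats(cfg.outcome_path, trait_id="outcome")
    if cfg.direction == "reverse":
        exposures, outcomes = outcomes, exposures
    return exposures, outcomes


def _run_method(name: str, instruments, cfg: PipelineConfig) -> est.CausalEstimate:
    func, _ = est.MULTI_SNP_METHODS[name]
    if name in ("ivw", "egger"):
        return func(instruments)
    if name == "raps":
        return func(instruments, seed=cfg.seed)
    return func(instruments, boot_reps=cfg.boot_reps, seed=cfg.seed)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute read -> select -> harmonize -> estimate -> diagnose.

    Returns the full report as a dict (and writes ``report.json``,
    ``estimates.tsv``, ``singles.tsv`` and the diagnostics files when
    ``cfg.outdir`` is set).  Raises :class:`ZeroInstrumentsError`, listing
    every exclusion with its reason, when nothing survives QC.  Estimators
    whose preconditions are not met (too few instruments) are skipped with a
    recorded warning, not an error.
    """
    exposures, outcomes = _load_sources(cfg)

    exclusions: dict[str, str] = {}
    kept_assoc = []
    for a in exposures:
        if a.snp_id in cfg.exclude_snps:
            exclusions[a.snp_id] = "excluded_by_config"
        else:
            kept_assoc.append(a)

    records = select_instruments(
        kept_assoc, p_primary=cfg.p_primary, p_subgroup=cfg.p_subgroup,
        f_min=cfg.f_min, subgroup=cfg.subgroup,
    )
    if cfg.bmi_adjusted_path is not None:
        records = exclude_bmi_nonrobust(records, read_sumstats(cfg.bmi_adjusted_path))
    for rec in records:
        if not rec.selected:
            exclusions[rec.snp_id] = rec.exclusion_reason

    proxy_dirs = LD_PROXY_DIRECTIONS if cfg.use_fixture_proxy_directions else None
    policy = HarmonizePolicy(
        palindromic=cfg.palindromic_policy, proxy_directions=proxy_dirs
    )
    instruments, dropped = harmonize_pairs(retained(records), outcomes, policy)
    exclusions.update(dropped)
    if not instruments:
        raise ZeroInstrumentsError(exclusions)
    J = len(instruments)

    singles = [est.wald_ratio(h) for h in instruments]
    estimates: list[est.CausalEstimate] = []
    warnings: list[str] = []
    if J == 1:
        warnings.append("single instrument: multi-SNP estimators skipped, Wald ratio reported")
    for name in cfg.methods:
        _, min_j = est.MULTI_SNP_METHODS[name]
        if J < min_j:
            warnings.append(f"{name} skipped: needs >= {min_j} instruments, have {J}")
            continue
        estimates.append(_run_method(name, instruments, cfg))

    heterogeneity = []
    if J >= 2:
        heterogeneity.append(diag.cochran_q(instruments, "ivw"))
    if J >= 3:
        heterogeneity.append(diag.cochran_q(instruments, "egger"))
    presso_result = None
    if cfg.run_presso:
        if J >= 4:
            presso_result = diag.presso(instruments, n_sim=cfg.presso_n_sim, seed=cfg.seed)
        else:
            warnings.append(f"presso skipped: needs >= 4 instruments, have {J}")
    loo = diag.leave_one_out(instruments) if J >= 3 else None
    overall_for_plots = estimates if estimates else singles
    plots = diag.assemble_plot_data(instruments, overall_for_plots, loo)

    report = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "n_instruments": J,
        "instruments": [
            {
                "snp": h.snp_id, "bx": h.bx, "sx": h.sx, "by": h.by, "sy": h.sy,
                "orientation": h.orientation, "palindromic": h.palindromic,
                "flipped": h.flipped,
            }
            for h in instruments
        ],
        "exclusions": exclusions,
        "warnings": warnings,
        "singles": [asdict(e) for e in singles],
        "estimates": [asdict(e) for e in estimates],
        "heterogeneity": [asdict(h) for h in heterogeneity],
        "presso": None,
        "seed": cfg.seed,
    }
    if presso_result is not None:
        p = asdict(presso_result)
        if presso_result.corrected is not None:
            p["corrected"] = asdict(presso_result.corrected)
        report["presso"] = p

    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        _estimates_tsv(estimates, outdir / "estimates.tsv")
        _estimates_tsv(singles, outdir / "singles.tsv")
        diag.write_diagnostics(outdir, heterogeneity, presso_result, plots)
    return report


def _estimates_tsv(estimates: Sequence[est.CausalEstimate], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "method": e.method,
                "snp": e.extras.get("snp_id", ""),
                "b": e.b,
                "se": e.se,
                "pval": e.pval,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_snp": e.n_snp,
            }
            for e in estimates
        ]
    ).to_csv(path, sep="\t", index=False)
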