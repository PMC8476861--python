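"""Heterogeneity, pleiotropy and outlier diagnostics.

A causal interpretation of two-sample MR rests on every instrument affecting
the outcome only through the exposure.  This module quantifies departures:
Cochran's Q measures heterogeneity of the per-variant ratio estimates about
the pooled IVW estimate (or about the Egger fit); the Egger intercept tests
for directional pleiotropy; MR-PRESSO detects individual pleiotropic
outliers by comparing observed residual sums of squares to a parametric
simulation under the no-pleiotropy model; leave-one-out analysis exposes
single influential variants; and funnel/forest/scatter tables provide the
standard visual diagnostics as plain data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import CausalEstimate, egger, ivw, ratio_estimates, wald_ratio
from .sumstats import HarmonizedInstrument

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "cochran_q",
    "egger_intercept_test",
    "presso",
    "leave_one_out",
    "assemble_plot_data",
    "write_diagnostics",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q about the IVW estimate (df = J-1) or the Egger fit (J-2)."""

    reference: str
    Q: float
    df: int
    pval: float
    per_snp: dict[str, float]

    def __post_init__(self) -> None:
        if self.Q < 0 or self.df < 1:
            raise ValueError("invalid heterogeneity result")


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_p: float
    outlier_pvals: dict[str, float]
    outliers: list[str]
    distortion_p: float | None
    corrected: CausalEstimate | None
    n_sim: int
    seed: int


def cochran_q(
    instruments: Sequence[HarmonizedInstrument],
    reference: Literal["ivw", "egger"] = "ivw",
) -> HeterogeneityResult:
    """Heterogeneity of per-variant causal estimates.

    ``ivw``: Q = sum_j w_j (r_j - b_ivw)^2 with w_j = bx_j^2/sy_j^2 and
    df = J-1.  ``egger``: the weighted residual sum of squares about the
    Egger regression line with weights 1/sy^2 and df = J-2.  The p-value is
    the upper chi-square tail at the stated df.
    """
    J = len(instruments)
    if reference == "ivw":
        if J < 2:
            raise ValueError("Q about IVW needs at least 2 instruments")
        ratios = ratio_estimates(instruments)
        b = ivw(instruments).b
        contrib = {re.snp_id: re.weight * (re.ratio - b) ** 2 for re in ratios}
        df = J - 1
    elif reference == "egger":
        if J < 3:
            raise ValueError("Q about Egger needs at least 3 instruments")
        fit = egger(instruments)
        a, b = fit.extras["intercept"], fit.b
        sign = np.array([1.0 if h.bx > 0 else -1.0 for h in instruments])
        contrib = {
            h.snp_id: (1.0 / h.sy**2) * (s * h.by - (a + b * s * h.bx)) ** 2
            for h, s in zip(instruments, sign)
        }
        df = J - 2
    else:
        raise ValueError(f"unknown reference {reference!r}")
    q = float(sum(contrib.values()))
    return HeterogeneityResult(reference, q, df, float(stats.chi2.sf(q, df)), contrib)


def egger_intercept_test(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[float, float, float]:
    """Egger intercept, its SE and two-sided p-value (t with J-2 df).

    A non-significant intercept is read as no evidence of directional
    pleiotropy.
    """
    fit = egger(instruments)
    ex = fit.extras
    return ex["intercept"], ex["intercept_se"], ex["intercept_p"]


def _loo_ivw_theta(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW point estimates, theta_{-j}, vectorized.

    Supports batched inputs of shape (n_sim, J); sy broadcasts.
    """
    num = bx * by / sy**2
    den = bx**2 / sy**2
    num_tot = num.sum(axis=-1, keepdims=True)
    den_tot = den.sum(axis=-1, keepdims=True)
    return (num_tot - num) / (den_tot - den)


def presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO pleiotropy residual sum of squares and outlier test.

    Global test: the observed RSS = sum_j (by_j - theta_{-j} bx_j)^2, with
    theta_{-j} the leave-one-out IVW estimate, is compared against the same
    statistic on ``n_sim`` datasets simulated under the no-pleiotropy model
    (by*_j ~ N(theta_{-j} bx_j, sy_j), bx*_j ~ N(bx_j, sx_j)); the empirical
    p is (1 + #{sim >= obs}) / (n_sim + 1), so never exactly 0.

    Outlier test: each variant's observed squared residual against its
    parametric null distribution — simulated residuals measured against the
    same leave-one-out slope that generated them, so that pleiotropy in the
    tested variant cannot contaminate its own reference distribution —
    Bonferroni-flagged at ``outlier_alpha / J``.  (The global statistic, by
    contrast, re-estimates the leave-one-out slopes on each simulated
    dataset so its null distribution matches the observed statistic's.)

    Distortion test: the observed change of the IVW estimate after removing
    outliers is compared to changes under bootstrap resampling (with
    replacement) of the non-outlier variants.  The outlier-corrected
    estimate is the IVW on the non-outlier set.
    """
    J = len(instruments)
    if J < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    if seed is None:
        raise ValueError("MR-PRESSO is stochastic: a seed is required")
    rng = np.random.default_rng(seed)

    bx = np.array([h.bx for h in instruments])
    sx = np.array([h.sx for h in instruments])
    by = np.array([h.by for h in instruments])
    sy = np.array([h.sy for h in instruments])
    snp_ids = [h.snp_id for h in instruments]

    theta_loo = _loo_ivw_theta(bx, by, sy)
    obs_res2 = (by - theta_loo * bx) ** 2
    obs_rss = float(obs_res2.sum())

    # parametric simulation under the no-pleiotropy model
    bx_sim = rng.normal(bx, sx, size=(n_sim, J))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    theta_loo_sim = _loo_ivw_theta(bx_sim, by_sim, sy)
    sim_rss = ((by_sim - theta_loo_sim * bx_sim) ** 2).sum(axis=1)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1))
    # per-SNP null residuals against the generating slopes (see docstring)
    sim_res2 = (by_sim - theta_loo * bx_sim) ** 2
    outlier_p = (1 + (sim_res2 >= obs_res2).sum(axis=0)) / (n_sim + 1)
    outlier_pvals = dict(zip(snp_ids, (float(p) for p in outlier_p)))
    flagged = [s for s, p in outlier_pvals.items() if p < outlier_alpha / J]

    corrected: CausalEstimate | None = None
    distortion_p: float | None = None
    if flagged:
        keep = [h for h in instruments if h.snp_id not in flagged]
        corrected = ivw(keep) if len(keep) >= 2 else wald_ratio(keep[0])
        full = ivw(instruments)
        d_obs = full.b - corrected.b
        keep_idx = np.array([i for i, s in enumerate(snp_ids) if s not in flagged])
        out_idx = np.array([i for i, s in enumerate(snp_ids) if s in flagged])
        n_boot = 1000
        d_boot = np.empty(n_boot)
        for i in range(n_boot):
            res = rng.choice(keep_idx, size=keep_idx.size, replace=True)
            idx = np.concatenate([res, out_idx])
            w = bx[idx] ** 2 / sy[idx] ** 2
            theta_all_b = np.sum(w * by[idx] / bx[idx]) / np.sum(w)
            w_k = bx[res] ** 2 / sy[res] ** 2
            theta_keep_b = np.sum(w_k * by[res] / bx[res]) / np.sum(w_k)
            d_boot[i] = theta_all_b - theta_keep_b
        distortion_p = float(
            (1 + np.sum(np.abs(d_boot) >= abs(d_obs))) / (n_boot + 1)
        )

    return PressoResult(
        global_rss=obs_rss,
        global_p=global_p,
        outlier_pvals=outlier_pvals,
        outliers=flagged,
        distortion_p=distortion_p,
        corrected=corrected,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    method: Literal["ivw"] = "ivw",
) -> list[CausalEstimate]:
    """IVW estimates omitting each instrument in turn.

    Returns J estimates on J-1 instruments each, labelled by the omitted
    SNP in ``extras["omitted"]``; a single influential or pleiotropic
    variant shows up as the one omission that moves the estimate.
    """
    if method != "ivw":
        raise ValueError(f"unsupported leave-one-out method {method!r}")
    J = len(instruments)
    if J < 3:
        raise ValueError("leave-one-out needs at least 3 instruments")
    out = []
    for j, omitted in enumerate(instruments):
        rest = [h for i, h in enumerate(instruments) if i != j]
        est = ivw(rest) if len(rest) >= 2 else wald_ratio(rest[0])
        est.extras["omitted"] = omitted.snp_id
        out.append(est)
    return out


def assemble_plot_data(
    instruments: Sequence[HarmonizedInstrument],
    estimates: Sequence[CausalEstimate],
    loo: Sequence[CausalEstimate] | None = None,
) -> dict[str, pd.DataFrame]:
    """Build funnel, scatter, forest and leave-one-out plot tables.

    funnel: per-variant ratio against precision 1/se_ratio (asymmetry hints
    at directional pleiotropy).  scatter: (bx, by) with SEs plus one
    regression line per method (slope = estimate; intercept non-zero only
    for Egger).  forest: per-variant ratios with 95% CIs and one overall row
    per method.  loo: the leave-one-out series when provided.
    """
    if not estimates:
        raise ValueError("at least one overall estimate is required")
    ratios = ratio_estimates(instruments)
    funnel = pd.DataFrame(
        {
            "snp": [r.snp_id for r in ratios],
            "ratio": [r.ratio for r in ratios],
            "precision": [1.0 / r.se_ratio for r in ratios],
        }
    )
    scatter_points = pd.DataFrame(
        {
            "snp": [h.snp_id for h in instruments],
            "bx": [h.bx for h in instruments],
            "sx": [h.sx for h in instruments],
            "by": [h.by for h in instruments],
            "sy": [h.sy for h in instruments],
        }
    )
    lines = pd.DataFrame(
        {
            "method": [e.method for e in estimates],
            "slope": [e.b for e in estimates],
            "intercept": [e.extras.get("intercept", 0.0) for e in estimates],
        }
    )
    scatter = scatter_points.merge(lines, how="cross")

    forest_rows = [
        {
            "label": r.snp_id,
            "kind": "snp",
            "b": r.ratio,
            "ci_low": r.ratio - 1.96 * r.se_ratio,
            "ci_high": r.ratio + 1.96 * r.se_ratio,
        }
        for r in ratios
    ] + [
        {
            "label": e.method,
            "kind": "overall",
            "b": e.b,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
        }
        for e in estimates
    ]
    forest = pd.DataFrame(forest_rows)

    tables = {"funnel": funnel, "scatter": scatter, "forest": forest}
    if loo is not None:
        tables["loo"] = pd.DataFrame(
            {
                "omitted": [e.extras["omitted"] for e in loo],
                "b": [e.b for e in loo],
                "ci_low": [e.ci_low for e in loo],
                "ci_high": [e.ci_high for e in loo],
            }
        )
    return tables


def write_diagnostics(
    outdir: str | Path,
    heterogeneity: Sequence[HeterogeneityResult] = (),
    presso_result: PressoResult | None = None,
    plot_tables: dict[str, pd.DataFrame] | None = None,
) -> None:
    """Serialize diagnostics to ``diagnostics.json`` plus TSV plot tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"heterogeneity": [asdict(h) for h in heterogeneity]}
    if presso_result is not None:
        p = asdict(presso_result)
        if presso_result.corrected is not None:
            p["corrected"] = asdict(presso_result.corrected)
        report["presso"] = p
    (outdir / "diagnostics.json").write_text(json.dumps(report, indent=2))
    for name, df in (plot_tables or {}).items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
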