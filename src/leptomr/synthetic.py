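"""Synthetic two-sample summary statistics with known ground truth.

The generator emulates the statistical structure two-sample MR assumes:
J independent biallelic instruments with latent true exposure effects
gamma_j, observed in the exposure study with sampling noise sx, and outcome
effects by_j = theta * gamma_j + alpha_j + noise(sy), where alpha_j is a
per-variant direct (pleiotropic) effect on the outcome.  Pleiotropy can be
absent, balanced (mean zero), directional (non-zero mean, InSIDE holding),
or InSIDE-violating (alpha correlated 0.5 with gamma).  Gross outliers —
variants whose direct effect dwarfs the outcome SE — can be planted at known
indices.  Everything is a deterministic function of the seed.

Default parameters mirror the scale of the leptin/anorexia study: ~50
instruments with exposure effects of SD 0.03 measured with SE 0.005 and
outcome log-OR SE 0.0136.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .sumstats import SummaryAssociation

__all__ = ["SimConfig", "SimTruth", "simulate_summary_stats"]

Pleiotropy = Literal["none", "balanced", "directional", "inside_violating"]

#: Correlation between direct effects and instrument strengths in the
#: InSIDE-violating mode.
INSIDE_VIOLATION_RHO = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a simulated two-sample dataset.

    theta is the true causal effect (outcome units per exposure unit);
    gamma_sd the SD of latent exposure effects; sx and sy the per-study
    summary SEs (scalar or per-SNP); alpha_mean/alpha_sd parameterize the
    pleiotropy distribution; n_outliers variants additionally receive a
    direct effect of outlier_scale * sy.
    """

    J: int = 50
    theta: float = 0.0
    gamma_sd: float = 0.03
    sx: float | Sequence[float] = 0.005
    sy: float | Sequence[float] = 0.0136
    pleiotropy: Pleiotropy = "none"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    n_outliers: int = 0
    outlier_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 2:
            raise ValueError("J must be at least 2")
        if np.any(np.asarray(self.sx, dtype=float) <= 0) or np.any(
            np.asarray(self.sy, dtype=float) <= 0
        ):
            raise ValueError("sx and sy must be positive")
        if not 0 <= self.n_outliers < self.J:
            raise ValueError("n_outliers must be in [0, J)")
        if self.gamma_sd <= 0:
            raise ValueError("gamma_sd must be positive")
        if self.pleiotropy not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        for name in ("sx", "sy"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim not in (0, 1) or (v.ndim == 1 and v.size != self.J):
                raise ValueError(f"{name} must be scalar or length J")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated dataset."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    outlier_indices: np.ndarray
    seed: int


def _per_snp(value: float | Sequence[float], J: int) -> np.ndarray:
    return np.broadcast_to(np.asarray(value, dtype=float), (J,)).copy()


def simulate_summary_stats(
    cfg: SimConfig,
) -> tuple[list[SummaryAssociation], list[SummaryAssociation], SimTruth]:
    """Draw one two-sample dataset; fully determined by ``cfg.seed``.

    Returns exposure associations, outcome associations (shared SNP ids and
    alleles, A/G with EAF ~ U(0.1, 0.9)) and the ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    J = cfg.J
    sx = _per_snp(cfg.sx, J)
    sy = _per_snp(cfg.sy, J)

    # Latent effects are expressed for the exposure-increasing allele
    # (half-normal magnitudes): MR estimators re-orient instruments so the
    # exposure effect is positive, and only pleiotropy defined relative to
    # that orientation can be directional.  With symmetric signed effects,
    # re-orientation would fold a constant mean direct effect into a
    # balanced one, and aligning the direct effect with the sign of gamma
    # would instead correlate it with instrument strength (InSIDE broken).
    gamma = np.abs(rng.normal(0.0, cfg.gamma_sd, size=J))
    if cfg.pleiotropy == "none":
        alpha = np.zeros(J)
    elif cfg.pleiotropy == "balanced":
        alpha = rng.normal(0.0, cfg.alpha_sd, size=J)
    elif cfg.pleiotropy == "directional":
        alpha = rng.normal(cfg.alpha_mean, cfg.alpha_sd, size=J)
    else:  # inside_violating: direct effects track instrument strength
        rho = INSIDE_VIOLATION_RHO
        # standardize gamma by its half-normal moments so that
        # corr(alpha, gamma) = rho
        mu_g = cfg.gamma_sd * np.sqrt(2 / np.pi)
        sd_g = cfg.gamma_sd * np.sqrt(1 - 2 / np.pi)
        z_g = (gamma - mu_g) / sd_g
        z = rng.normal(size=J)
        alpha = cfg.alpha_mean + cfg.alpha_sd * (
            rho * z_g + np.sqrt(1 - rho**2) * z
        )

    outlier_idx = (
        rng.choice(J, size=cfg.n_outliers, replace=False)
        if cfg.n_outliers
        else np.empty(0, dtype=int)
    )
    alpha = alpha.copy()
    alpha[outlier_idx] += cfg.outlier_scale * sy[outlier_idx]

    bx = gamma + rng.normal(0.0, sx)
    by = cfg.theta * gamma + alpha + rng.normal(0.0, sy)
    eaf = rng.uniform(0.1, 0.9, size=J)

    width = len(str(J))
    exposures, outcomes = [], []
    for j in range(J):
        snp = f"snp_{j:0{width}d}"
        px = float(2 * stats.norm.sf(abs(bx[j] / sx[j])))
        py = float(2 * stats.norm.sf(abs(by[j] / sy[j])))
        common = dict(snp_id=snp, effect_allele="A", other_allele="G",
                      chrom="1", eaf=float(eaf[j]))
        exposures.append(
            SummaryAssociation(beta=float(bx[j]), se=float(sx[j]),
                               pval=max(px, 1e-300), trait_id="sim_exposure", **common)
        )
        outcomes.append(
            SummaryAssociation(beta=float(by[j]), se=float(sy[j]),
                               pval=max(py, 1e-300), trait_id="sim_outcome", **common)
        )
    truth = SimTruth(
        theta=cfg.theta, gamma=gamma, alpha=alpha,
        outlier_indices=outlier_idx, seed=cfg.seed,
    )
    return exposures, outcomes, truth
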