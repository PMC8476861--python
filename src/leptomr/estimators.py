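"""Causal-effect estimators for two-sample Mendelian randomization.

Every estimator consumes harmonized instruments (exposure effect bx with SE
sx, outcome effect by with SE sy, expressed for a common allele) and returns
a :class:`CausalEstimate` with point estimate, standard error, two-sided
p-value and a 95% Wald interval b +/- 1.96*se.  The per-variant building
block is the Wald ratio r_j = by_j/bx_j with first-order delta-method SE
sy_j/|bx_j| and inverse-variance weight w_j = bx_j^2/sy_j^2.

Implemented methods and their identifying assumptions:

* ``ivw`` — inverse-variance-weighted mean of ratios, equivalently weighted
  least squares of by on bx through the origin; assumes every instrument is
  valid.  Uses a multiplicative random-effects variance: the fixed-effect SE
  1/sqrt(sum w_j) is inflated by the residual scale sqrt(Q/(J-1)) when that
  exceeds 1.
* ``egger`` — weighted least squares of by on bx *with* intercept; the
  intercept estimates average directional pleiotropy, the slope is a
  consistent causal estimate under the InSIDE assumption.  p-values use a
  t distribution with J-2 df; SEs carry the same max(1, residual sd) floor.
* ``median_estimator`` — simple/weighted/penalised-weighted median of the
  ratio estimates; consistent when up to half of the weight comes from
  invalid instruments.  SE by parametric bootstrap.
* ``mode_estimator`` — kernel-density mode of the ratio estimates
  (zero-modal pleiotropy assumption); SE by parametric bootstrap.
* ``raps`` — robust adjusted profile score: accounts for sampling error in
  bx and for systematic pleiotropy through an overdispersion parameter
  tau^2 >= 0; optional Huber loss bounds the influence of idiosyncratic
  outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .sumstats import HarmonizedInstrument

__all__ = [
    "RatioEstimate",
    "CausalEstimate",
    "ConvergenceError",
    "ratio_estimates",
    "weighted_median",
    "kernel_mode",
    "wald_ratio",
    "ivw",
    "egger",
    "median_estimator",
    "mode_estimator",
    "raps",
    "MULTI_SNP_METHODS",
]

Z95 = 1.96  #: normal quantile used for all reported 95% intervals


class ConvergenceError(RuntimeError):
    """An iterative estimator failed to converge within its iteration budget."""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio with delta-method SE and IVW weight."""

    snp_id: str
    ratio: float
    se_ratio: float
    weight: float


@dataclass(frozen=True)
class CausalEstimate:
    """A causal-effect estimate: change in outcome (log-OR for binary
    outcomes) per unit change in exposure."""

    method: str
    b: float
    se: float
    pval: float
    ci_low: float
    ci_high: float
    n_snp: int
    df: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.method}: se must be positive")
        if not (self.ci_low <= self.b <= self.ci_high):
            raise ValueError(f"{self.method}: CI does not bracket the estimate")


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([h.bx for h in instruments], dtype=float)
    sx = np.array([h.sx for h in instruments], dtype=float)
    by = np.array([h.by for h in instruments], dtype=float)
    sy = np.array([h.sy for h in instruments], dtype=float)
    return bx, sx, by, sy


def _orient_positive(bx: np.ndarray, by: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Joint sign flip of (bx, by) so that bx > 0 for every instrument."""
    sign = np.sign(bx)
    return bx * sign, by * sign


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _estimate(method: str, b: float, se: float, pval: float, n_snp: int,
              df: int | None = None, **extras) -> CausalEstimate:
    return CausalEstimate(
        method=method, b=float(b), se=float(se), pval=float(pval),
        ci_low=float(b - Z95 * se), ci_high=float(b + Z95 * se),
        n_snp=n_snp, df=df, extras=extras,
    )


def ratio_estimates(instruments: Sequence[HarmonizedInstrument]) -> list[RatioEstimate]:
    """Per-variant Wald ratios; the input to median/mode estimation."""
    out = []
    for h in instruments:
        if h.bx == 0:
            raise ValueError(f"{h.snp_id}: zero exposure effect, ratio undefined")
        out.append(
            RatioEstimate(
                snp_id=h.snp_id,
                ratio=h.by / h.bx,
                se_ratio=h.sy / abs(h.bx),
                weight=h.bx**2 / h.sy**2,
            )
        )
    return out


def wald_ratio(h: HarmonizedInstrument) -> CausalEstimate:
    """Single-variant causal estimate b = by/bx, SE = sy/|bx|."""
    if h.bx == 0:
        raise ValueError(f"{h.snp_id}: bx = 0, Wald ratio undefined")
    b = h.by / h.bx
    se = h.sy / abs(h.bx)
    return _estimate("wald_ratio", b, se, _normal_p(b / se), 1, snp_id=h.snp_id)


def ivw(instruments: Sequence[HarmonizedInstrument]) -> CausalEstimate:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    b = sum(w_j r_j)/sum(w_j) with w_j = bx_j^2/sy_j^2; the fixed-effect SE
    1/sqrt(sum w_j) is multiplied by the residual scale
    sigma = sqrt(Q/(J-1)) when sigma > 1 (floored at 1 otherwise), so the SE
    never drops below its fixed-effect value.
    """
    J = len(instruments)
    if J < 2:
        raise ValueError("IVW needs at least 2 instruments; use wald_ratio for one")
    bx, _, by, sy = _arrays(instruments)
    if np.any(bx == 0):
        raise ValueError("zero exposure effect among instruments")
    w = bx**2 / sy**2
    r = by / bx
    b = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (r - b) ** 2))
    sigma = math.sqrt(q / (J - 1))
    se = se_fixed * max(1.0, sigma)
    return _estimate(
        "ivw", b, se, _normal_p(b / se), J, df=J - 1,
        residual_scale=sigma, se_fixed=se_fixed, Q=q,
    )


def egger(instruments: Sequence[HarmonizedInstrument]) -> CausalEstimate:
    """MR-Egger regression: WLS of by on bx with intercept, weights 1/sy^2.

    The slope is the causal estimate; the intercept estimates the average
    pleiotropic effect.  Instruments are re-oriented internally so bx > 0
    (the Egger model is only identified up to that orientation); a zero
    exposure effect is an error.  Both SEs are divided by min(1, residual
    sd) relative to the usual WLS SEs — i.e. the residual scale is floored
    at 1 — and p-values are two-sided from a t distribution with J-2 df.
    """
    J = len(instruments)
    if J < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    bx, _, by, sy = _arrays(instruments)
    if np.any(bx == 0):
        raise ValueError("zero exposure effect among instruments")
    bx, by = _orient_positive(bx, by)

    import statsmodels.api as sm

    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    sigma = math.sqrt(fit.scale)  # residual sd, weighted RSS/(J-2)
    unscaled = fit.bse / sigma
    se_int, se_slope = (float(s * max(1.0, sigma)) for s in unscaled)
    intercept, slope = (float(v) for v in fit.params)
    df = J - 2
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), df))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), df))
    return _estimate(
        "egger", slope, se_slope, p_slope, J, df=df,
        intercept=intercept, intercept_se=se_int, intercept_p=p_int,
        residual_scale=sigma, Q=float(fit.scale * df),
    )


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation over standardized
    cumulative weights p_j = (cumsum(w) - w_j/2) / sum(w)."""
    order = np.argsort(values)
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, v))


def _median_point(r: np.ndarray, w: np.ndarray, kind: str, penalty: float = 20.0) -> float:
    if kind == "simple":
        return weighted_median(r, np.ones_like(r))
    b_wm = weighted_median(r, w)
    if kind == "weighted":
        return b_wm
    if kind == "penalised":
        q = stats.chi2.sf(w * (r - b_wm) ** 2, df=1)
        return weighted_median(r, w * np.minimum(1.0, penalty * q))
    raise ValueError(f"unknown median kind {kind!r}")


def median_estimator(
    instruments: Sequence[HarmonizedInstrument],
    kind: Literal["simple", "weighted", "penalised"] = "weighted",
    boot_reps: int = 1000,
    seed: int | None = None,
) -> CausalEstimate:
    """Median-based causal estimate (simple, weighted or penalised weighted).

    Weights are 1 (simple) or the IVW weights bx^2/sy^2; the penalised kind
    down-weights each variant's contribution by min(1, 20*q_j) where q_j is
    the upper chi^2_1 tail probability of its heterogeneity contribution
    about the weighted median.  The SE comes from a parametric bootstrap
    (by* ~ N(by, sy), bx* ~ N(bx, sx)) with the given seed.
    """
    J = len(instruments)
    if J < 3:
        raise ValueError("median estimator needs at least 3 instruments")
    bx, sx, by, sy = _arrays(instruments)
    r = by / bx
    w = bx**2 / sy**2
    b = _median_point(r, w, kind)

    rng = np.random.default_rng(seed)
    boots = np.empty(boot_reps)
    for i in range(boot_reps):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        boots[i] = _median_point(by_b / bx_b, bx_b**2 / sy**2, kind)
    se = float(np.std(boots, ddof=1))
    label = "penalised_weighted_median" if kind == "penalised" else f"{kind}_median"
    return _estimate(
        label, b, se, _normal_p(b / se), J,
        boot_reps=boot_reps, seed=seed,
    )


def kernel_mode(
    values: np.ndarray,
    weights: np.ndarray,
    phi: float = 1.0,
    grid_points: int = 512,
) -> float:
    """Mode of a weighted normal-kernel density over ``values``.

    Bandwidth is phi * 0.9 * min(sd, mad/0.6745) * J^(-1/5) computed on the
    values; the density is scanned on a regular grid spanning
    [min - 3h, max + 3h] and argmax ties break toward smaller magnitude.
    All values identical returns the common value.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    if np.ptp(v) == 0:
        return float(v[0])
    spread = min(np.std(v, ddof=1), stats.median_abs_deviation(v, scale="normal"))
    h = phi * 0.9 * spread * len(v) ** (-0.2)
    if h <= 0:  # degenerate spread (e.g. mad 0 with distinct extremes)
        h = phi * 0.9 * np.std(v, ddof=1) * len(v) ** (-0.2)
    grid = np.linspace(v.min() - 3 * h, v.max() + 3 * h, grid_points)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - v[None, :]) / h) ** 2)).sum(axis=1)
    peak = dens.max()
    candidates = grid[np.isclose(dens, peak, rtol=0, atol=1e-12 * max(peak, 1.0))]
    return float(candidates[np.argmin(np.abs(candidates))])


def mode_estimator(
    instruments: Sequence[HarmonizedInstrument],
    weighted: bool = True,
    phi: float = 1.0,
    boot_reps: int = 1000,
    seed: int | None = None,
) -> CausalEstimate:
    """Mode-based causal estimate under the zero-modal pleiotropy assumption.

    The estimate is the argmax of a normal-kernel density over the ratio
    estimates, weighted equally (simple) or by bx^2/sy^2 (weighted); ``phi``
    scales the bandwidth.  SE by parametric bootstrap with the given seed.
    """
    J = len(instruments)
    if J < 3:
        raise ValueError("mode estimator needs at least 3 instruments")
    bx, sx, by, sy = _arrays(instruments)
    r = by / bx
    w = bx**2 / sy**2 if weighted else np.ones(J)
    b = kernel_mode(r, w, phi=phi)

    rng = np.random.default_rng(seed)
    boots = np.empty(boot_reps)
    for i in range(boot_reps):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        w_b = bx_b**2 / sy**2 if weighted else np.ones(J)
        boots[i] = kernel_mode(by_b / bx_b, w_b, phi=phi)
    se = float(np.std(boots, ddof=1))
    method = "weighted_mode" if weighted else "simple_mode"
    return _estimate(
        method, b, se, _normal_p(b / se), J,
        phi=phi, boot_reps=boot_reps, seed=seed,
    )


_HUBER_K = 1.345
# E[psi_k(Z)^2] and E[psi_k'(Z)] for Z ~ N(0,1), used to keep the Huber
# score Fisher-consistent for the scale and to correct the information.
_HUBER_EPSI2 = float(
    2 * (stats.norm.cdf(_HUBER_K) - 0.5)
    - 2 * _HUBER_K * stats.norm.pdf(_HUBER_K)
    + 2 * _HUBER_K**2 * stats.norm.sf(_HUBER_K)
)
_HUBER_EDPSI = float(2 * stats.norm.cdf(_HUBER_K) - 1)


def _huber_psi(u: np.ndarray) -> np.ndarray:
    return np.clip(u, -_HUBER_K, _HUBER_K)


def raps(
    instruments: Sequence[HarmonizedInstrument],
    overdispersion: bool = True,
    loss: Literal["l2", "huber"] = "l2",
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> CausalEstimate:
    """Robust adjusted profile score estimate.

    theta solves the profile score sum bx_j (by_j - theta bx_j) / sigma_j^2
    = 0 with sigma_j^2 = sy_j^2 + theta^2 sx_j^2 + tau^2, where the
    overdispersion tau^2 >= 0 (systematic pleiotropy) is estimated jointly
    from the moment condition sum (resid^2 - sigma^2)/sigma^4 = 0 (set to 0
    when ``overdispersion`` is off).  The Huber loss replaces the
    standardized residual in the score by its bounded psi, limiting the
    influence of idiosyncratically pleiotropic variants.  The SE is the
    model-based profile information 1/sqrt(sum bx^2/sigma^2), with the usual
    efficiency correction under the Huber loss.  Raises
    :class:`ConvergenceError` if the fixed-point iteration does not settle.
    """
    J = len(instruments)
    if J < 3:
        raise ValueError("RAPS needs at least 3 instruments")
    bx, sx, by, sy = _arrays(instruments)

    def sig2(theta: float, tau2: float) -> np.ndarray:
        return sy**2 + theta**2 * sx**2 + tau2

    def solve_theta(theta0: float, tau2: float) -> float:
        if loss == "l2":
            s2 = sig2(theta0, tau2)
            return float(np.sum(bx * by / s2) / np.sum(bx**2 / s2))

        def score(theta: float) -> float:
            s = np.sqrt(sig2(theta, tau2))
            return float(np.sum(bx / s * _huber_psi((by - theta * bx) / s)))

        span = 1.0 + abs(theta0)
        lo, hi = theta0 - span, theta0 + span
        for _ in range(60):
            if score(lo) * score(hi) <= 0:
                break
            span *= 2.0
            lo, hi = theta0 - span, theta0 + span
        else:
            raise ConvergenceError("huber score has no sign change in bracket")
        return float(optimize.brentq(score, lo, hi))

    def solve_tau2(theta: float) -> float:
        resid2 = (by - theta * bx) ** 2
        scale = _HUBER_EPSI2 / _HUBER_EDPSI**2 if loss == "huber" else 1.0

        def moment(tau2: float) -> float:
            s2 = sig2(theta, tau2)
            return float(np.sum((resid2 / scale - s2) / s2**2))

        if moment(0.0) <= 0:
            return 0.0
        hi = 1.0
        while moment(hi) > 0 and hi < 1e6:
            hi *= 10.0
        return float(optimize.brentq(moment, 0.0, hi))

    # fixed-point iteration on (theta, tau2), started from fixed-effect IVW
    w0 = bx**2 / sy**2
    theta = float(np.sum(w0 * (by / bx)) / np.sum(w0))
    tau2 = 0.0
    for _ in range(max_iter):
        tau2_new = solve_tau2(theta) if overdispersion else 0.0
        theta_new = solve_theta(theta, tau2_new)
        done = abs(theta_new - theta) < tol and abs(tau2_new - tau2) < tol
        theta, tau2 = theta_new, tau2_new
        if done:
            break
    else:
        raise ConvergenceError(f"RAPS did not converge in {max_iter} iterations")

    s2 = sig2(theta, tau2)
    info = float(np.sum(bx**2 / s2))
    se = 1.0 / math.sqrt(info)
    if loss == "huber":
        se *= math.sqrt(_HUBER_EPSI2) / _HUBER_EDPSI
    return _estimate(
        "raps", theta, se, _normal_p(theta / se), J,
        tau2=tau2, overdispersion=overdispersion, loss=loss, seed=seed,
    )


#: Registry of the multi-SNP methods the pipeline can run, with minimum J.
MULTI_SNP_METHODS = {
    "ivw": (ivw, 2),
    "egger": (egger, 3),
    "simple_median": (lambda ins, **kw: median_estimator(ins, "simple", **kw), 3),
    "weighted_median": (lambda ins, **kw: median_estimator(ins, "weighted", **kw), 3),
    "penalised_weighted_median": (lambda ins, **kw: median_estimator(ins, "penalised", **kw), 3),
    "simple_mode": (lambda ins, **kw: mode_estimator(ins, weighted=False, **kw), 3),
    "weighted_mode": (lambda ins, **kw: mode_estimator(ins, weighted=True, **kw), 3),
    "raps": (raps, 3),
}
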