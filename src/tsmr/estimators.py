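"""Univariable two-sample MR estimators on harmonized summary statistics.

All estimators regress the SNP-outcome effects (Gamma_j, log-odds for a
binary outcome) on the SNP-exposure effects (gamma_j, per-SD units) using
only summary statistics.  The causal parameter theta is the log-odds change
in the outcome per SD increase in the exposure; exp(theta) is the odds
ratio reported downstream.

Methods and their identifying assumptions:

* Wald ratio — single-SNP estimate Gamma/gamma; first-order SE.
* IVW — inverse-variance-weighted regression through the origin; unbiased
  when pleiotropy is balanced.  The multiplicative random-effects (MRE)
  variant scales the fixed-effect SE by the residual overdispersion.
* MR-Egger — allows directional pleiotropy under InSIDE; the intercept
  estimates the average pleiotropic effect and tests its presence.
* Weighted median — consistent when >= 50% of the weight is on valid SNPs.
* Weighted mode — consistent when the largest group of SNPs sharing a ratio
  is valid, even if a majority are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import EstimationError
from .summary_io import HarmonizedInstrumentSet

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MrEstimate:
    """One method's causal estimate with uncertainty and method extras."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_snps": self.n_snps,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": float(np.exp(self.ci_low)),
            "or_ci_high": float(np.exp(self.ci_high)),
        }
        d.update(self.extras)
        return d


def _normal_estimate(method: str, theta: float, se: float, n_snps: int,
                     extras: dict | None = None) -> MrEstimate:
    z = theta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MrEstimate(method=method, theta=float(theta), se=float(se),
                      ci_low=float(theta - _Z95 * se),
                      ci_high=float(theta + _Z95 * se),
                      pvalue=float(p), n_snps=n_snps, extras=extras or {})


def wald_ratio(beta_exposure: float, se_exposure: float,
               beta_outcome: float, se_outcome: float) -> MrEstimate:
    """Single-SNP causal estimate Gamma/gamma with first-order delta SE.

    The SE ignores exposure-side uncertainty (sigma_Y / |gamma|), the
    dominant convention; adequate when the instrument is strong
    (se_exposure / |beta_exposure| small).
    """
    if beta_exposure == 0:
        raise EstimationError("wald ratio undefined for beta_exposure = 0")
    theta = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    return _normal_estimate("wald", theta, se, 1)


def ivw(hset: HarmonizedInstrumentSet, mode: str = "mre") -> MrEstimate:
    """Inverse-variance-weighted estimate: weighted regression through origin.

    theta = sum(w g G) / sum(w g^2) with w = 1/se_outcome^2.  ``mode='fixed'``
    uses the fixed-effect SE; ``mode='mre'`` multiplies it by sqrt(phi) where
    phi = Q/(J-1) is the residual overdispersion (not floored at 1 — a pure
    multiplicative error model).  A single SNP degrades to the Wald ratio.
    """
    if mode not in ("fixed", "mre"):
        raise EstimationError(f"unknown ivw mode {mode!r}")
    g = hset.beta_exposure
    G = hset.beta_outcome
    sy = hset.se_outcome
    J = hset.n_snps
    if J == 1:
        est = wald_ratio(g[0], hset.se_exposure[0], G[0], sy[0])
        est.method = f"ivw_{'fe' if mode == 'fixed' else 'mre'}"
        return est
    w = 1.0 / sy ** 2
    sxx = np.sum(w * g ** 2)
    if sxx == 0:
        raise EstimationError("all exposure betas are zero")
    theta = np.sum(w * g * G) / sxx
    se_fixed = sxx ** -0.5
    q = float(np.sum(w * (G - theta * g) ** 2))
    phi = q / (J - 1)
    extras = {"cochran_q": q, "phi": phi}
    if mode == "fixed":
        return _normal_estimate("ivw_fe", theta, se_fixed, J, extras)
    se = se_fixed * np.sqrt(phi)
    return _normal_estimate("ivw_mre", theta, se, J, extras)


def egger(hset: HarmonizedInstrumentSet) -> MrEstimate:
    """MR-Egger weighted regression with intercept (directional pleiotropy).

    Each SNP is oriented so its exposure beta is non-negative, then
    Gamma = b0 + theta * gamma is fit by WLS with weights 1/se_outcome^2.
    SEs carry a multiplicative overdispersion phi = RSS/(J-2) floored at 1;
    p-values use the t distribution with J-2 df.  The intercept b0 estimates
    the average direct (pleiotropic) effect; its test is the standard check
    for unbalanced horizontal pleiotropy.
    """
    J = hset.n_snps
    if J < 3:
        raise EstimationError("MR-Egger requires at least 3 SNPs")
    flip = np.sign(hset.beta_exposure)
    flip[flip == 0] = 1.0
    g = hset.beta_exposure * flip
    G = hset.beta_outcome * flip
    w = 1.0 / hset.se_outcome ** 2

    X = sm.add_constant(g)
    fit = sm.WLS(G, X, weights=w).fit()
    b0, theta = fit.params
    rss = float(np.sum(w * (G - fit.fittedvalues) ** 2))
    phi = max(1.0, rss / (J - 2))
    # bse from WLS already includes scale = rss/(J-2); rescale to floored phi
    scale_adj = np.sqrt(phi / fit.scale) if fit.scale > 0 else 1.0
    se_b0, se_theta = fit.bse * scale_adj
    tdist = stats.t(J - 2)
    p_theta = 2.0 * tdist.sf(abs(theta / se_theta))
    p_b0 = 2.0 * tdist.sf(abs(b0 / se_b0))
    tcrit = tdist.ppf(0.975)
    return MrEstimate(
        method="egger", theta=float(theta), se=float(se_theta),
        ci_low=float(theta - tcrit * se_theta),
        ci_high=float(theta + tcrit * se_theta),
        pvalue=float(p_theta), n_snps=J,
        extras={
            "egger_intercept": float(b0),
            "intercept_se": float(se_b0),
            "intercept_p": float(p_b0),
            "phi": phi,
        },
    )


def _ratio_estimates(hset: HarmonizedInstrumentSet):
    theta_j = hset.beta_outcome / hset.beta_exposure
    # first-order variance of the per-SNP ratio
    var_j = hset.se_outcome ** 2 / hset.beta_exposure ** 2
    return theta_j, 1.0 / var_j


def _weighted_median_point(theta_j: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta_j)
    th = theta_j[order]
    ww = w[order]
    s = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
    return float(np.interp(0.5, s, th))


def weighted_median(hset: HarmonizedInstrumentSet, bootstrap_reps: int = 1000,
                    seed: int = 0) -> MrEstimate:
    """Weighted median of the per-SNP Wald ratios.

    Consistent when valid instruments carry a majority of the inverse-
    variance weight.  The SE comes from a seeded parametric bootstrap
    resampling the exposure and outcome betas from normals with their SEs.
    """
    J = hset.n_snps
    if J < 3:
        raise EstimationError("weighted median requires at least 3 SNPs")
    theta_j, w = _ratio_estimates(hset)
    theta = _weighted_median_point(theta_j, w)

    rng = np.random.default_rng(seed)
    g_star = rng.normal(hset.beta_exposure, hset.se_exposure,
                        size=(bootstrap_reps, J))
    G_star = rng.normal(hset.beta_outcome, hset.se_outcome,
                        size=(bootstrap_reps, J))
    boots = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        g = g_star[b]
        ok = g != 0
        t_b = G_star[b, ok] / g[ok]
        w_b = g[ok] ** 2 / hset.se_outcome[ok] ** 2
        boots[b] = _weighted_median_point(t_b, w_b)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_median", theta, se, J,
                            {"bootstrap_reps": bootstrap_reps, "seed": seed})


def _mode_bandwidth(theta_j: np.ndarray, factor: float) -> float:
    J = theta_j.size
    sd = np.std(theta_j, ddof=1)
    mad = stats.median_abs_deviation(theta_j, scale="normal")
    spread = min(sd, mad) if mad > 0 else sd
    return factor * 0.9 * spread * J ** (-1 / 5)


def _weighted_mode_point(theta_j: np.ndarray, w: np.ndarray,
                         factor: float) -> tuple[float, float]:
    if np.allclose(theta_j, theta_j[0]):
        return float(theta_j[0]), 0.0
    h = _mode_bandwidth(theta_j, factor)
    if h <= 0:
        return float(theta_j[np.argmax(w)]), 0.0
    # the argmax lives where weight concentrates: span the ratios carrying
    # the central 99.8% of weight, so a near-zero-weight wild ratio (from a
    # tiny denominator) cannot blow the grid up
    order = np.argsort(theta_j)
    cw = np.cumsum(w[order]) / w.sum()
    keep = order[(cw > 0.001) & (cw - w[order] / w.sum() < 0.999)]
    if keep.size == 0:
        keep = order
    lo = theta_j[keep].min() - 3 * h
    hi = theta_j[keep].max() + 3 * h
    step = h / 10.0
    n_grid = int(np.ceil((hi - lo) / step)) + 1
    if n_grid > 200_000:  # hard cap; coarsen rather than stall
        step = (hi - lo) / 200_000
        n_grid = 200_001
    best_val, best_dens = lo, -np.inf
    # evaluate the weighted KDE in grid chunks to bound memory
    chunk = 4096
    wn = w / w.sum()
    for start in range(0, n_grid, chunk):
        grid = lo + step * np.arange(start, min(start + chunk, n_grid))
        dens = np.sum(wn * np.exp(-0.5 * ((grid[:, None] - theta_j) / h) ** 2),
                      axis=1)
        i = int(np.argmax(dens))
        # strict > keeps the first (smallest-theta) argmax on ties
        if dens[i] > best_dens:
            best_dens = float(dens[i])
            best_val = float(grid[i])
    return best_val, h


def weighted_mode(hset: HarmonizedInstrumentSet, bandwidth_factor: float = 1.0,
                  bootstrap_reps: int = 1000, seed: int = 0) -> MrEstimate:
    """Mode of the weighted kernel density of the per-SNP Wald ratios.

    Identifies the causal effect with the largest cluster of agreeing
    ratios (the ZEMPA/plurality assumption).  Bandwidth follows the
    modified Silverman rule 0.9 min(sd, mad/0.6745) J^(-1/5) scaled by
    ``bandwidth_factor``; the density argmax is found on a grid padded by
    3h at resolution h/10, ties toward the smaller theta.  SE by seeded
    parametric bootstrap.
    """
    J = hset.n_snps
    if J < 3:
        raise EstimationError("weighted mode requires at least 3 SNPs")
    theta_j, w = _ratio_estimates(hset)
    theta, h = _weighted_mode_point(theta_j, w, bandwidth_factor)

    rng = np.random.default_rng(seed)
    g_star = rng.normal(hset.beta_exposure, hset.se_exposure,
                        size=(bootstrap_reps, J))
    G_star = rng.normal(hset.beta_outcome, hset.se_outcome,
                        size=(bootstrap_reps, J))
    boots = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        g = g_star[b]
        ok = g != 0
        t_b = G_star[b, ok] / g[ok]
        w_b = g[ok] ** 2 / hset.se_outcome[ok] ** 2
        boots[b], _ = _weighted_mode_point(t_b, w_b, bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_mode", theta, se, J,
                            {"bootstrap_reps": bootstrap_reps, "seed": seed,
                             "bandwidth": h})


def cochran_q(hset: HarmonizedInstrumentSet, theta: float,
              df_reduction: int = 1) -> tuple[float, float]:
    """Cochran's Q heterogeneity about a fitted slope.

    Q = sum w_j (Gamma_j - theta gamma_j)^2 with w = 1/se_outcome^2,
    referred to chi-square with J - df_reduction degrees of freedom
    (df_reduction=2 for Egger residuals).
    """
    if not np.isfinite(theta):
        raise EstimationError("theta must be finite")
    w = 1.0 / hset.se_outcome ** 2
    q = float(np.sum(w * (hset.beta_outcome - theta * hset.beta_exposure) ** 2))
    df = hset.n_snps - df_reduction
    p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, p


#: the standard univariable battery run by the pipeline
ALL_METHODS = ("ivw_mre", "egger", "weighted_median", "weighted_mode")


def run_all(hset: HarmonizedInstrumentSet, bootstrap_reps: int = 1000,
            seed: int = 0) -> dict[str, MrEstimate]:
    """Run the full univariable estimator battery on one instrument set."""
    out = {"ivw_mre": ivw(hset, mode="mre")}
    if hset.n_snps >= 3:
        out["egger"] = egger(hset)
        out["weighted_median"] = weighted_median(hset, bootstrap_reps, seed)
        out["weighted_mode"] = weighted_mode(hset, bootstrap_reps=bootstrap_reps,
                                             seed=seed + 1)
    return out
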