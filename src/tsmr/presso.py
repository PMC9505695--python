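"""Pleiotropy residual-sum-and-outlier analysis (MR-PRESSO style).

A simulation-based framework with three parts:

* **global test** — compares the observed leave-one-out residual sum of
  squares against its distribution under the no-pleiotropy null, obtained by
  parametric simulation from the per-SNP standard errors;
* **outlier test** — per-SNP empirical p-values for the same residuals, with
  Bonferroni control across instruments; flagged SNPs are removed and an
  outlier-corrected IVW estimate is reported;
* **distortion test** — asks whether removing the flagged SNPs changed the
  causal estimate more than removing an equally sized random subset would.

All leave-one-out IVW slopes are computed in closed form from running sums,
so the simulation loop is fully vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError
from .estimators import MrEstimate, ivw
from .summary_io import HarmonizedInstrumentSet


@dataclass
class PressoResult:
    """Bundle of global/outlier/distortion outputs."""

    rss_obs: float
    global_p: float
    outlier_p: dict[str, float]
    outlier_ids: list[str]
    theta_raw: MrEstimate
    theta_corrected: MrEstimate | None
    distortion_p: float | None
    n_simulations: int
    seed: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "global_p": self.global_p,
            "outlier_ids": list(self.outlier_ids),
            "theta_raw": self.theta_raw.to_dict(),
            "theta_corrected": (self.theta_corrected.to_dict()
                                if self.theta_corrected else None),
            "distortion_p": self.distortion_p,
            "n_simulations": self.n_simulations,
            "seed": self.seed,
        }


def _loo_thetas(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes via subtraction from the full sums."""
    sxx = np.sum(w * g ** 2)
    sxy = np.sum(w * g * G)
    denom = sxx - w * g ** 2
    if np.any(denom <= 0):
        raise EstimationError("degenerate leave-one-out system (single informative SNP)")
    return (sxy - w * g * G) / denom


def _observed_residuals(hset: HarmonizedInstrumentSet) -> np.ndarray:
    g, G = hset.beta_exposure, hset.beta_outcome
    w = 1.0 / hset.se_outcome ** 2
    theta_loo = _loo_thetas(g, G, w)
    return w * (G - theta_loo * g) ** 2


def presso_global(hset: HarmonizedInstrumentSet, n_simulations: int = 1000,
                  seed: int = 0) -> dict:
    """Global pleiotropy test: empirical p for the observed leave-one-out RSS.

    Simulated datasets draw Gamma*_j ~ N(theta_loo_j * gamma_j, se_Yj^2) and
    gamma*_j ~ N(gamma_j, se_Xj^2), then recompute the same leave-one-out
    residual sum.  The empirical p uses the add-one (1+k)/(N+1) convention.
    Returns the observed RSS, global p, and per-SNP simulated residuals
    (reused by the outlier test so both share one definition of the
    residual).
    """
    J = hset.n_snps
    if J < 4:
        raise EstimationError("the global pleiotropy test requires at least 4 SNPs")
    if n_simulations < 100:
        raise EstimationError("n_simulations must be >= 100")
    # canonicalize SNP order so results are invariant to input ordering
    perm = np.argsort(np.asarray(hset.variant_ids))
    inv = np.argsort(perm)
    g, G = hset.beta_exposure[perm], hset.beta_outcome[perm]
    sx, sy = hset.se_exposure[perm], hset.se_outcome[perm]
    w = 1.0 / sy ** 2
    theta_loo = _loo_thetas(g, G, w)
    r2_obs = w * (G - theta_loo * g) ** 2
    rss_obs = float(np.sum(r2_obs))

    rng = np.random.default_rng(seed)
    g_star = rng.normal(g, sx, size=(n_simulations, J))
    G_star = rng.normal(theta_loo * g, sy, size=(n_simulations, J))
    sxx = np.sum(w * g_star ** 2, axis=1, keepdims=True)
    sxy = np.sum(w * g_star * G_star, axis=1, keepdims=True)
    theta_loo_star = (sxy - w * g_star * G_star) / (sxx - w * g_star ** 2)
    r2_star = w * (G_star - theta_loo_star * g_star) ** 2  # (nsim, J)
    rss_star = np.sum(r2_star, axis=1)
    global_p = (1.0 + np.sum(rss_star >= rss_obs)) / (n_simulations + 1.0)
    return {
        "rss_obs": rss_obs,
        "global_p": float(global_p),
        "r2_obs": r2_obs[inv],
        "r2_star": r2_star[:, inv],
        "n_simulations": n_simulations,
        "seed": seed,
    }


def presso_outlier(hset: HarmonizedInstrumentSet, global_result: dict,
                   significance: float = 0.05) -> dict:
    """Per-SNP outlier test with Bonferroni control; outlier-corrected IVW.

    SNP j is flagged when its empirical residual p-value falls below
    significance / J.  The corrected estimate is IVW-MRE on the unflagged
    subset.

    Because the smallest attainable empirical p is 1/(n_simulations + 1),
    the Bonferroni threshold is only reachable when
    n_simulations > J / significance - 1 (e.g. > 3,679 simulations for
    184 SNPs at family level 0.05); with fewer simulations no SNP can ever
    be flagged.
    """
    J = hset.n_snps
    r2_obs = global_result["r2_obs"]
    r2_star = global_result["r2_star"]
    nsim = global_result["n_simulations"]
    p_j = (1.0 + np.sum(r2_star >= r2_obs, axis=0)) / (nsim + 1.0)
    flagged = p_j < significance / J
    outlier_ids = [v for v, f in zip(hset.variant_ids, flagged) if f]
    if len(outlier_ids) == J:
        raise EstimationError("every SNP flagged as an outlier; no estimable subset")
    theta_corrected = None
    if outlier_ids:
        keep = ~flagged
        theta_corrected = ivw(hset.subset(keep), mode="mre")
    return {
        "outlier_p": dict(zip(hset.variant_ids, p_j.astype(float))),
        "outlier_ids": outlier_ids,
        "theta_corrected": theta_corrected,
    }


def presso_distortion(hset: HarmonizedInstrumentSet, outlier_ids: list[str],
                      theta_raw: MrEstimate | None = None,
                      theta_corrected: MrEstimate | None = None,
                      n_resamples: int = 1000, seed: int = 0) -> dict:
    """Distortion test: is the outlier-driven shift in theta unusual?

    Observed distortion is (theta_raw - theta_corrected)/theta_corrected;
    the null removes |outlier_ids| SNPs at random and recomputes the same
    quantity.  Two-sided empirical p.  With no outliers the test is marked
    not applicable rather than raising.
    """
    if not outlier_ids:
        return {"distortion": None, "distortion_p": None, "applicable": False}
    theta_raw = theta_raw or ivw(hset, mode="mre")
    keep = [v for v in hset.variant_ids if v not in set(outlier_ids)]
    theta_corrected = theta_corrected or ivw(hset.subset(keep), mode="mre")
    if theta_corrected.theta == 0:
        return {"distortion": None, "distortion_p": None, "applicable": False}
    d_obs = (theta_raw.theta - theta_corrected.theta) / theta_corrected.theta

    rng = np.random.default_rng(seed)
    J = hset.n_snps
    k = len(outlier_ids)
    d_null = np.empty(n_resamples)
    g, G = hset.beta_exposure, hset.beta_outcome
    w = 1.0 / hset.se_outcome ** 2
    sxx_full = np.sum(w * g ** 2)
    sxy_full = np.sum(w * g * G)
    theta_full = sxy_full / sxx_full
    for b in range(n_resamples):
        drop = rng.choice(J, size=k, replace=False)
        sxx = sxx_full - np.sum(w[drop] * g[drop] ** 2)
        sxy = sxy_full - np.sum(w[drop] * g[drop] * G[drop])
        theta_b = sxy / sxx
        d_null[b] = np.inf if theta_b == 0 else (theta_full - theta_b) / theta_b
    p = (1.0 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_resamples + 1.0)
    return {"distortion": float(d_obs), "distortion_p": float(p),
            "applicable": True}


def presso(hset: HarmonizedInstrumentSet, n_simulations: int = 1000,
           significance: float = 0.05, n_resamples: int = 1000,
           seed: int = 0) -> PressoResult:
    """Run the full global → outlier → distortion cascade."""
    glob = presso_global(hset, n_simulations=n_simulations, seed=seed)
    outl = presso_outlier(hset, glob, significance=significance)
    theta_raw = ivw(hset, mode="mre")
    dist = presso_distortion(hset, outl["outlier_ids"], theta_raw=theta_raw,
                             theta_corrected=outl["theta_corrected"],
                             n_resamples=n_resamples, seed=seed + 1)
    return PressoResult(
        rss_obs=glob["rss_obs"],
        global_p=glob["global_p"],
        outlier_p=outl["outlier_p"],
        outlier_ids=outl["outlier_ids"],
        theta_raw=theta_raw,
        theta_corrected=outl["theta_corrected"],
        distortion_p=dist["distortion_p"],
        n_simulations=n_simulations,
        seed=seed,
        extras={"distortion": dist["distortion"]},
    )
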