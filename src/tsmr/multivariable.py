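"""Multivariable MR and two-step mediation analysis.

Multivariable MR regresses the SNP-outcome effects jointly on several
exposures' SNP effects, estimating each exposure's direct effect with the
others held fixed.  Two-step mediation decomposes a total causal effect
into the product beta1 * beta2 of the exposure→mediator and (adjusted)
mediator→outcome effects; the proportion mediated is indirect / total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import EstimationError, HarmonizationError
from .estimators import MrEstimate, ivw
from .presso import presso
from .summary_io import HarmonizedInstrumentSet, SummaryStatRecord, harmonize

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MvmrEstimate:
    """Joint direct-effect estimates for K exposures on one outcome."""

    exposure_ids: list[str]
    theta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    pvalues: np.ndarray
    n_snps: int
    phi: float = 1.0

    def to_dict(self) -> dict:
        return {
            "exposure_ids": list(self.exposure_ids),
            "theta": [float(t) for t in self.theta],
            "se": [float(s) for s in self.se],
            "pvalues": [float(p) for p in self.pvalues],
            "odds_ratio": [float(np.exp(t)) for t in self.theta],
            "n_snps": self.n_snps,
            "phi": self.phi,
        }

    def estimate_for(self, exposure_id: str) -> MrEstimate:
        k = self.exposure_ids.index(exposure_id)
        t, s = float(self.theta[k]), float(self.se[k])
        return MrEstimate(
            method="mvmr_ivw", theta=t, se=s,
            ci_low=t - _Z95 * s, ci_high=t + _Z95 * s,
            pvalue=float(self.pvalues[k]), n_snps=self.n_snps)


@dataclass
class MediationResult:
    """Product-of-coefficients mediation decomposition."""

    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    indirect_or: float
    ci_low: float
    ci_high: float
    total_effect: float
    proportion_mediated: float | None
    bootstrap_reps: int
    seed: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "beta1": self.beta1, "se1": self.se1,
            "beta2": self.beta2, "se2": self.se2,
            "indirect": self.indirect, "indirect_or": self.indirect_or,
            "or_ci_low": self.ci_low, "or_ci_high": self.ci_high,
            "total_effect": self.total_effect,
            "proportion_mediated": self.proportion_mediated,
            "bootstrap_reps": self.bootstrap_reps, "seed": self.seed,
        }
        d.update(self.extras)
        return d


def mvmr_ivw(beta_exposures: np.ndarray, beta_outcome: np.ndarray,
             se_outcome: np.ndarray, exposure_ids: list[str] | None = None
             ) -> MvmrEstimate:
    """Multivariable IVW: WLS of Gamma on the J x K exposure-effect matrix.

    No intercept; weights 1/se_outcome^2; multiplicative overdispersion
    phi = RSS/(J-K) floored at 1 applied to the SEs; normal p-values.
    Raises on a rank-deficient exposure matrix, naming the collinear
    exposures.
    """
    X = np.atleast_2d(np.asarray(beta_exposures, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(beta_outcome)) == X.shape[1]:
        X = X.T
    y = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    J, K = X.shape
    if exposure_ids is None:
        exposure_ids = [f"exposure_{k}" for k in range(K)]
    if J <= K:
        raise EstimationError(f"need more SNPs ({J}) than exposures ({K})")
    if np.linalg.matrix_rank(X) < K:
        raise EstimationError(
            f"rank-deficient exposure matrix; collinear exposures among {exposure_ids}")
    w = 1.0 / sy ** 2
    fit = sm.WLS(y, X, weights=w).fit()
    rss = float(np.sum(w * (y - fit.fittedvalues) ** 2))
    phi = max(1.0, rss / (J - K))
    xtwx_inv = np.asarray(fit.normalized_cov_params)
    cov = xtwx_inv * phi
    se = np.sqrt(np.diag(cov))
    z = fit.params / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return MvmrEstimate(exposure_ids=list(exposure_ids),
                        theta=np.asarray(fit.params, dtype=float),
                        se=se, cov=cov, pvalues=p, n_snps=J, phi=phi)


def harmonize_multi(exposure_records: dict[str, list[SummaryStatRecord]],
                    outcome_records: list[SummaryStatRecord],
                    snp_panel: list[str] | None = None):
    """Align several exposures and one outcome onto a common SNP panel.

    The first exposure's alleles define the reference orientation; every
    other trait is harmonized against it pairwise, then the variant lists
    are intersected (optionally restricted to ``snp_panel``).  Returns
    (variant_ids, X matrix J x K, beta_outcome, se_outcome, exposure_ids).
    """
    exposure_ids = list(exposure_records)
    if not exposure_ids:
        raise HarmonizationError("no exposures supplied")
    ref = exposure_records[exposure_ids[0]]
    aligned: dict[str, dict[str, tuple[float, float]]] = {}
    for eid in exposure_ids[1:]:
        h = harmonize(ref, exposure_records[eid], exposure_id=exposure_ids[0],
                      outcome_id=eid)
        aligned[eid] = {v: (b, s) for v, b, s in
                        zip(h.variant_ids, h.beta_outcome, h.se_outcome)}
    h_out = harmonize(ref, outcome_records, exposure_id=exposure_ids[0],
                      outcome_id="outcome")
    out_map = {v: (b, s) for v, b, s in
               zip(h_out.variant_ids, h_out.beta_outcome, h_out.se_outcome)}

    common = [r.variant_id for r in ref if r.variant_id in out_map]
    for eid in exposure_ids[1:]:
        common = [v for v in common if v in aligned[eid]]
    if snp_panel is not None:
        panel = set(snp_panel)
        common = [v for v in common if v in panel]
    if len(common) <= len(exposure_ids):
        raise HarmonizationError(
            f"only {len(common)} SNPs shared across all traits")
    ref_map = {r.variant_id: r for r in ref}
    X = np.empty((len(common), len(exposure_ids)))
    for i, v in enumerate(common):
        X[i, 0] = ref_map[v].beta
        for k, eid in enumerate(exposure_ids[1:], start=1):
            X[i, k] = aligned[eid][v][0]
    by = np.array([out_map[v][0] for v in common])
    sy = np.array([out_map[v][1] for v in common])
    return common, X, by, sy, exposure_ids


def mediate_two_step(beta1: float, se1: float, beta2: float, se2: float,
                     total_effect: float, bootstrap_reps: int = 10_000,
                     seed: int = 0) -> MediationResult:
    """Product-of-coefficients mediation with a parametric bootstrap CI.

    indirect = beta1 * beta2; the CI is the 2.5/97.5 percentile of
    exp(beta1* x beta2*) over independent normal draws of each stage
    estimate.  proportion_mediated = indirect / total_effect; undefined
    (None, flagged) when the total effect is zero.
    """
    if se1 <= 0 or se2 <= 0:
        raise EstimationError("stage SEs must be > 0")
    indirect = beta1 * beta2
    rng = np.random.default_rng(seed)
    b1 = rng.normal(beta1, se1, size=bootstrap_reps)
    b2 = rng.normal(beta2, se2, size=bootstrap_reps)
    ors = np.exp(b1 * b2)
    ci_low, ci_high = np.percentile(ors, [2.5, 97.5])
    proportion = None if total_effect == 0 else indirect / total_effect
    return MediationResult(
        beta1=beta1, se1=se1, beta2=beta2, se2=se2,
        indirect=float(indirect), indirect_or=float(np.exp(indirect)),
        ci_low=float(ci_low), ci_high=float(ci_high),
        total_effect=float(total_effect), proportion_mediated=proportion,
        bootstrap_reps=bootstrap_reps, seed=seed,
        extras={"total_undefined": total_effect == 0},
    )


def mediation_pipeline(exposure_records: list[SummaryStatRecord],
                       mediator_records: list[SummaryStatRecord],
                       outcome_records: list[SummaryStatRecord],
                       exposure_instruments: list[str],
                       mediator_instruments: list[str],
                       presso_exclude: bool = True,
                       presso_simulations: int = 1000,
                       bootstrap_reps: int = 10_000,
                       seed: int = 0) -> MediationResult:
    """Full two-step mediation: exposure → mediator → outcome.

    Stage 1 estimates the exposure→mediator effect by univariable IVW on
    the exposure's instruments.  Stage 2 estimates the mediator→outcome
    effect adjusted for the exposure by multivariable IVW on the union
    panel of both traits' instruments, optionally after removing
    pleiotropy-outlier SNPs flagged on the univariable mediator→outcome
    set.  The total effect is univariable IVW of the outcome on the
    exposure's instruments.
    """
    exp_map = {r.variant_id: r for r in exposure_records}
    med_map = {r.variant_id: r for r in mediator_records}

    def _stage(label, fn):
        try:
            return fn()
        except Exception as exc:  # re-raise with the failing stage named
            raise EstimationError(f"mediation stage '{label}' failed: {exc}") from exc

    # stage 1: exposure -> mediator
    exp_inst = [exp_map[v] for v in exposure_instruments if v in exp_map]
    h1 = _stage("exposure->mediator harmonization",
                lambda: harmonize(exp_inst, mediator_records))
    stage1 = _stage("exposure->mediator IVW", lambda: ivw(h1, mode="mre"))

    # total effect: exposure -> outcome
    h_total = _stage("exposure->outcome harmonization",
                     lambda: harmonize(exp_inst, outcome_records))
    total = _stage("total-effect IVW", lambda: ivw(h_total, mode="mre"))

    # optional outlier exclusion on the univariable mediator->outcome set
    panel = sorted(set(exposure_instruments) | set(mediator_instruments))
    excluded: list[str] = []
    if presso_exclude:
        med_inst = [med_map[v] for v in mediator_instruments if v in med_map]
        h_my = _stage("mediator->outcome harmonization",
                      lambda: harmonize(med_inst, outcome_records))
        if h_my.n_snps >= 4:
            pres = _stage("mediator->outcome outlier scan",
                          lambda: presso(h_my, n_simulations=presso_simulations,
                                         seed=seed + 11))
            excluded = pres.outlier_ids
            panel = [v for v in panel if v not in set(excluded)]

    # stage 2: mediator -> outcome adjusted for exposure
    def _stage2():
        _, X, by, sy, ids = harmonize_multi(
            {"mediator": mediator_records, "exposure": exposure_records},
            outcome_records, snp_panel=panel)
        return mvmr_ivw(X, by, sy, exposure_ids=ids)
    mv = _stage("adjusted mediator->outcome MVMR", _stage2)
    stage2 = mv.estimate_for("mediator")

    result = mediate_two_step(stage1.theta, stage1.se, stage2.theta, stage2.se,
                              total_effect=total.theta,
                              bootstrap_reps=bootstrap_reps, seed=seed)
    result.extras.update({
        "presso_excluded": excluded,
        "stage1_p": stage1.pvalue,
        "stage2_p": stage2.pvalue,
        "total_p": total.pvalue,
        "n_snps_stage1": stage1.n_snps,
        "n_snps_stage2": stage2.n_snps,
    })
    return result
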