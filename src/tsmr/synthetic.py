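"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of a large vitamin-D-style
MR study: ~184 independent instruments jointly explaining ~4% of a
rank-normalized, variance-1 exposure measured in ~400k individuals, and a
common binary outcome measured by case-control GWAS with tens of thousands
of cases.  True per-SNP effects, pleiotropy, planted outliers and planted
reverse-causal variants are all recorded in a truth object so estimator
bias, coverage and filter sensitivity can be computed exactly.

Summary statistics are generated directly on the summary level:

* exposure SE per SNP: sigma_X = (2 maf (1-maf) n_exposure)^(-1/2)
  (variance-1 quantitative trait);
* outcome SE: sigma_Y = (2 maf (1-maf) n phi (1-phi))^(-1/2) with phi the
  case fraction (large-sample log-odds approximation);
* observed effects: gamma_hat ~ N(gamma, sigma_X^2),
  Gamma_hat ~ N(theta gamma + alpha, sigma_Y^2).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ConfigurationError
from .summary_io import LdMatrix, SummaryStatRecord

_CHROMS = [str(c) for c in range(1, 23)]


@dataclass
class SimulationConfig:
    """Generative settings for one two-sample simulation.

    Defaults reproduce the study conditions this package is tested under:
    184 instruments, total exposure PVE 4%, a true causal log-odds effect of
    ln(0.916) per SD, an exposure GWAS of 417,580 and a pooled case-control
    outcome GWAS of ~808k with ~8.5% cases.
    """

    seed: int
    n_snps: int = 184
    n_exposure: int = 417_580
    n_outcome: int = 808_000
    case_fraction: float = 0.085
    theta: float = float(np.log(0.916))
    pve_target: float = 0.04
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: per-SNP strength profile: 'longtail' boosts a few major loci (the
    #: shape of large biomarker GWAS hits); 'even' gives comparable shares
    strength_profile: str = "longtail"
    # pleiotropy regime
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    rho_inside: float = 0.0
    fraction_invalid: float = 0.0
    # planted pathologies
    n_outliers: int = 0
    outlier_offset: float = 0.0  # in units of sigma_Y
    n_reverse_causal: int = 0
    #: z-score range of the reverse SNPs' echo on the exposure; the default
    #: keeps them genome-wide significant (a realistic trap for filtering),
    #: (0, 1) makes them null exposure loci
    reverse_echo_t: tuple[float, float] = (5.6, 7.5)
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"

    def validate(self) -> None:
        if self.n_snps < 3:
            raise ConfigurationError("n_snps must be >= 3")
        for name in ("case_fraction", "fraction_invalid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1]")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.pve_target <= 0 or self.pve_target >= 1:
            raise ConfigurationError("pve_target must be in (0,1)")
        # a mean per-SNP share above 10% of a variance-1 complex trait is
        # outside anything the generator is meant to emulate
        if self.pve_target / self.n_snps > 0.1:
            raise ConfigurationError("pve_target infeasible for n_snps")
        if self.n_reverse_causal + self.n_outliers > self.n_snps:
            raise ConfigurationError("more pathological SNPs than SNPs")


@dataclass
class TruthRecord:
    """Latent quantities behind one simulated dataset."""

    config: dict
    variant_ids: list[str]
    maf: list[float]
    gamma: list[float]
    alpha: list[float]
    sigma_x: list[float]
    sigma_y: list[float]
    is_invalid: list[bool]
    is_outlier: list[bool]
    is_reverse: list[bool]
    theta: float
    pve_total: float
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _panel_positions(n: int) -> tuple[list[str], list[int]]:
    """Spread SNPs over the autosomes, far apart and clear of chr6:25-34 Mb."""
    chroms, positions = [], []
    for i in range(n):
        chroms.append(_CHROMS[i % 22])
        positions.append(40_000_000 + (i // 22) * 15_000_000)
    return chroms, positions


def _draw_gammas(rng: np.random.Generator, maf: np.ndarray,
                 pve_target: float, profile: str = "longtail") -> np.ndarray:
    """True per-SD effects with a realistic instrument-strength profile.

    Per-SNP variance shares are shifted-exponential (keeping the weakest
    instruments at roughly a third of the mean — every SNP stays clearly
    genome-wide significant) with a few strongly boosted loci mimicking the
    handful of major biomarker genes that dominate large GWAS instrument
    sets.  Shares are normalized so total PVE hits the target exactly; the
    per-SNP F statistic is ~ n * pve_j, so strengths span roughly
    30 to 2,500 at the default sample size.
    """
    J = maf.size
    shares = 0.35 + rng.exponential(0.5, size=J)
    if profile == "longtail" and J >= 8:
        big = rng.choice(J, size=3, replace=False)
        shares[big] *= np.array([30.0, 12.0, 6.0])
    pve_j = pve_target * shares / shares.sum()
    mag = np.sqrt(pve_j / (2.0 * maf * (1.0 - maf)))
    return mag * rng.choice([-1.0, 1.0], size=maf.size)


def _normal_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def simulate_two_sample(config: SimulationConfig
                        ) -> tuple[list[SummaryStatRecord],
                                   list[SummaryStatRecord], TruthRecord]:
    """Draw one exposure GWAS + one outcome GWAS over a shared SNP panel."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    J = config.n_snps
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=J)

    gamma = _draw_gammas(rng, maf, config.pve_target, config.strength_profile)

    phi = config.case_fraction
    sigma_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    sigma_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome
                            * phi * (1.0 - phi))

    # pleiotropy: invalid SNPs get a direct effect alpha; rho_inside
    # correlates alpha with instrument strength (InSIDE violation)
    is_invalid = np.zeros(J, dtype=bool)
    n_invalid = int(round(config.fraction_invalid * J))
    if n_invalid:
        is_invalid[rng.choice(J, size=n_invalid, replace=False)] = True
    elif config.sigma_alpha > 0 or config.mu_alpha != 0:
        is_invalid[:] = True  # pleiotropy on all SNPs unless a fraction is set
    alpha = np.zeros(J)
    if is_invalid.any():
        z_g = (np.abs(gamma) - np.abs(gamma).mean()) / (np.abs(gamma).std() or 1.0)
        z = (config.rho_inside * z_g
             + np.sqrt(max(0.0, 1.0 - config.rho_inside ** 2)) * rng.normal(size=J))
        alpha[is_invalid] = (config.mu_alpha
                             + config.sigma_alpha * z[is_invalid])
        # direct effects are defined per exposure-increasing allele, so a
        # nonzero mu_alpha is genuinely directional rather than cancelling
        # against the arbitrary sign of the effect allele
        alpha *= np.where(gamma >= 0, 1.0, -1.0)

    # planted pathologies
    is_outlier = np.zeros(J, dtype=bool)
    is_reverse = np.zeros(J, dtype=bool)
    special = rng.permutation(J)
    if config.n_outliers:
        is_outlier[special[:config.n_outliers]] = True
    if config.n_reverse_causal:
        start = config.n_outliers
        is_reverse[special[start:start + config.n_reverse_causal]] = True

    Gamma = config.theta * gamma + alpha
    if config.n_outliers:
        signs = rng.choice([-1.0, 1.0], size=int(is_outlier.sum()))
        Gamma[is_outlier] += config.outlier_offset * sigma_y[is_outlier] * signs
    if config.n_reverse_causal:
        # outcome-first variants: dominant outcome association with a weaker
        # (but still genome-wide-significant) echo on the exposure
        n_rev = int(is_reverse.sum())
        t_y = rng.uniform(13.0, 20.0, size=n_rev)
        sign = rng.choice([-1.0, 1.0], size=n_rev)
        Gamma[is_reverse] = sign * t_y * sigma_y[is_reverse]
        lo_t, hi_t = config.reverse_echo_t
        gamma[is_reverse] = sign * rng.uniform(lo_t, hi_t, size=n_rev) \
            * sigma_x[is_reverse]

    gamma_hat = rng.normal(gamma, sigma_x)
    Gamma_hat = rng.normal(Gamma, sigma_y)

    chroms, positions = _panel_positions(J)
    variant_ids = [f"rs{config.seed % 100_000}_{i:04d}" for i in range(J)]
    n_cases = round(config.n_outcome * phi)

    exposure = [
        SummaryStatRecord(
            variant_id=variant_ids[j], chrom=chroms[j], pos=positions[j],
            effect_allele="A", other_allele="G", eaf=float(maf[j]),
            beta=float(gamma_hat[j]), se=float(sigma_x[j]),
            pvalue=float(_normal_p(gamma_hat[j:j + 1], sigma_x[j:j + 1])[0]),
            n=float(config.n_exposure), trait_id=config.exposure_id)
        for j in range(J)
    ]
    outcome = [
        SummaryStatRecord(
            variant_id=variant_ids[j], chrom=chroms[j], pos=positions[j],
            effect_allele="A", other_allele="G", eaf=float(maf[j]),
            beta=float(Gamma_hat[j]), se=float(sigma_y[j]),
            pvalue=float(_normal_p(Gamma_hat[j:j + 1], sigma_y[j:j + 1])[0]),
            n=float(config.n_outcome), n_cases=float(n_cases),
            trait_id=config.outcome_id)
        for j in range(J)
    ]
    truth = TruthRecord(
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()},
        variant_ids=variant_ids,
        maf=maf.tolist(), gamma=gamma.tolist(), alpha=alpha.tolist(),
        sigma_x=sigma_x.tolist(), sigma_y=sigma_y.tolist(),
        is_invalid=is_invalid.tolist(), is_outlier=is_outlier.tolist(),
        is_reverse=is_reverse.tolist(), theta=config.theta,
        pve_total=float(np.sum(2.0 * gamma ** 2 * maf * (1.0 - maf))),
    )
    return exposure, outcome, truth


def simulate_mediation_chain(config_x: SimulationConfig,
                             config_m: SimulationConfig,
                             config_y: SimulationConfig,
                             beta_xm: float, beta_my: float
                             ) -> tuple[list[SummaryStatRecord],
                                        list[SummaryStatRecord],
                                        list[SummaryStatRecord], TruthRecord]:
    """Simulate an exposure → mediator → outcome chain on the summary level.

    The SNP panel is the union of the exposure's instruments (config_x) and
    the mediator's own instruments (config_m).  Effects on the mediator are
    beta_xm * gamma_X + gamma_M_own; effects on the outcome combine the
    direct path (config_y.theta per SD exposure) and the mediated path
    beta_my per SD mediator.  The total exposure→outcome effect is therefore
    config_y.theta + beta_xm * beta_my, stored in the truth record.

    Returns (exposure_gwas, mediator_gwas, outcome_gwas, truth); the truth
    extras list which variants instrument which trait.
    """
    for c in (config_x, config_m, config_y):
        c.validate()
    rng = np.random.default_rng(config_x.seed)
    Jx, Jm = config_x.n_snps, config_m.n_snps
    J = Jx + Jm
    maf = rng.uniform(*config_x.maf_range, size=J)

    def _scaled_effects(idx: np.ndarray, pve: float) -> np.ndarray:
        out = np.zeros(J)
        out[idx] = _draw_gammas(rng, maf[idx], pve, config_x.strength_profile)
        return out

    idx_x = np.arange(Jx)
    idx_m = np.arange(Jx, J)
    gamma_x = _scaled_effects(idx_x, config_x.pve_target)
    gamma_m_own = _scaled_effects(idx_m, config_m.pve_target)
    gamma_m = beta_xm * gamma_x + gamma_m_own
    theta_direct = config_y.theta
    Gamma = theta_direct * gamma_x + beta_my * gamma_m

    phi = config_y.case_fraction
    het = 2.0 * maf * (1.0 - maf)
    sigma_x = 1.0 / np.sqrt(het * config_x.n_exposure)
    sigma_m = 1.0 / np.sqrt(het * config_m.n_exposure)
    sigma_yv = 1.0 / np.sqrt(het * config_y.n_outcome * phi * (1.0 - phi))

    bx = rng.normal(gamma_x, sigma_x)
    bm = rng.normal(gamma_m, sigma_m)
    by = rng.normal(Gamma, sigma_yv)

    chroms, positions = _panel_positions(J)
    vids = [f"rs{config_x.seed % 100_000}_{i:04d}" for i in range(J)]

    def _records(beta, se, n, trait, n_cases=None):
        return [SummaryStatRecord(
            variant_id=vids[j], chrom=chroms[j], pos=positions[j],
            effect_allele="A", other_allele="G", eaf=float(maf[j]),
            beta=float(beta[j]), se=float(se[j]),
            pvalue=float(_normal_p(beta[j:j + 1], se[j:j + 1])[0]),
            n=float(n), n_cases=n_cases, trait_id=trait)
            for j in range(J)]

    exposure = _records(bx, sigma_x, config_x.n_exposure, config_x.exposure_id)
    mediator = _records(bm, sigma_m, config_m.n_exposure,
                        config_m.exposure_id or "mediator")
    outcome = _records(by, sigma_yv, config_y.n_outcome, config_y.outcome_id,
                       n_cases=float(round(config_y.n_outcome * phi)))
    truth = TruthRecord(
        config={"seed": config_x.seed, "beta_xm": beta_xm, "beta_my": beta_my,
                "theta_direct": theta_direct},
        variant_ids=vids, maf=maf.tolist(), gamma=gamma_x.tolist(),
        alpha=[0.0] * J, sigma_x=sigma_x.tolist(), sigma_y=sigma_yv.tolist(),
        is_invalid=[False] * J, is_outlier=[False] * J, is_reverse=[False] * J,
        theta=theta_direct + beta_xm * beta_my,
        pve_total=float(np.sum(2.0 * gamma_x ** 2 * maf * (1.0 - maf))),
        extras={
            "exposure_instruments": vids[:Jx],
            "mediator_instruments": vids[Jx:],
            "gamma_mediator": gamma_m.tolist(),
            "theta_direct": theta_direct,
            "beta_xm": beta_xm, "beta_my": beta_my,
            "total_effect": theta_direct + beta_xm * beta_my,
        },
    )
    return exposure, mediator, outcome, truth


def simulate_ld_blocks(n_snps: int, block_size: int, within_r2: float,
                       seed: int = 0, variant_ids: list[str] | None = None
                       ) -> LdMatrix:
    """Block-diagonal r^2 matrix: ``within_r2`` inside blocks, 0 between."""
    if not 0.0 <= within_r2 <= 1.0:
        raise ConfigurationError("within_r2 must be in [0,1]")
    if variant_ids is None:
        variant_ids = [f"rs{seed % 100_000}_{i:04d}" for i in range(n_snps)]
    r2 = np.zeros((n_snps, n_snps))
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        r2[start:stop, start:stop] = within_r2
    np.fill_diagonal(r2, 1.0)
    return LdMatrix(variant_ids=variant_ids, r2=r2)


def truth_harmonized(exposure, outcome, truth: TruthRecord):
    """Convenience: harmonize a simulated pair (alleles always already aligned)."""
    from .summary_io import harmonize
    return harmonize(exposure, outcome)
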