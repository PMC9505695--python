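"""Instrument-strength and study-design diagnostics.

Per-SNP F statistics and proportion of variance explained quantify how
strong the genetic instruments are; I^2_GX measures regression dilution of
the SNP-exposure effects (a prerequisite check for MR-Egger under NOME
violation); the sample-overlap approximation bounds the bias introduced when
exposure and outcome GWAS share participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError, ValidationError


@dataclass
class InstrumentDiagnostics:
    """Per-SNP and aggregate instrument-strength summaries."""

    variant_ids: list[str]
    f_stat: np.ndarray
    pve: np.ndarray
    pve_total: float = field(init=False)
    f_min: float = field(init=False)
    f_max: float = field(init=False)
    i2_gx: float = 0.0

    def __post_init__(self):
        self.f_stat = np.asarray(self.f_stat, dtype=float)
        self.pve = np.asarray(self.pve, dtype=float)
        self.pve_total = float(self.pve.sum())
        self.f_min = float(self.f_stat.min())
        self.f_max = float(self.f_stat.max())

    def to_dict(self) -> dict:
        return {
            "n_snps": len(self.variant_ids),
            "f_min": self.f_min,
            "f_max": self.f_max,
            "f_mean": float(self.f_stat.mean()),
            "pve_total": self.pve_total,
            "i2_gx": self.i2_gx,
        }


def f_statistic(beta, se):
    """Per-SNP instrument F statistic, beta^2 / se^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValidationError("se must be > 0 for the F statistic")
    return beta ** 2 / se ** 2


def variance_explained(beta, eaf):
    """Proportion of a variance-1 trait explained: 2 beta^2 maf (1 - maf).

    ``beta`` must be in per-SD units of the (unit-variance) phenotype; maf is
    folded from the effect-allele frequency.
    """
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValidationError("eaf must be in (0,1)")
    maf = np.minimum(eaf, 1.0 - eaf)
    return 2.0 * beta ** 2 * maf * (1.0 - maf)


def i2_gx(beta_exposure, se_exposure) -> float:
    """I^2 heterogeneity of the SNP-exposure effects (instrument variability).

    Standard meta-analytic I^2 applied to the exposure betas with inverse-
    variance weights: values near 1 indicate instrument strength varies far
    beyond its measurement error, supporting the use of MR-Egger.
    Floored at 0 by convention.
    """
    g = np.asarray(beta_exposure, dtype=float)
    s = np.asarray(se_exposure, dtype=float)
    if g.size < 2:
        raise EstimationError("i2_gx needs at least 2 SNPs")
    if np.any(s <= 0):
        raise ValidationError("se must be > 0")
    w = 1.0 / s ** 2
    gbar = np.sum(w * g) / np.sum(w)
    q = float(np.sum(w * (g - gbar) ** 2))
    if q == 0.0:
        return 0.0
    return max(0.0, (q - (g.size - 1)) / q)


def overlap_bias(f_mean: float, overlap_fraction: float,
                 confounded_assoc: float) -> dict:
    """First-order weak-instrument bias from exposure/outcome sample overlap.

    With fully overlapping samples the IVW estimate is pulled toward the
    confounded observational association by a factor of roughly 1/F; with
    partial overlap the pull interpolates linearly in the overlap fraction:

        bias ~ overlap_fraction * confounded_assoc / f_mean

    Returns absolute and relative bias.  Requires mean F > 1 (the
    approximation is meaningless for weaker instruments).
    """
    if f_mean <= 1:
        raise EstimationError("overlap_bias requires mean F > 1")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValidationError("overlap_fraction must be in [0,1]")
    bias = overlap_fraction * confounded_assoc / f_mean
    return {
        "bias": bias,
        "relative_bias": overlap_fraction / f_mean,
    }


def diagnose(hset, exposure_is_quantitative: bool = True) -> InstrumentDiagnostics:
    """Full diagnostics for a harmonized instrument set."""
    f = f_statistic(hset.beta_exposure, hset.se_exposure)
    pve = variance_explained(hset.beta_exposure, hset.eaf)
    diag = InstrumentDiagnostics(variant_ids=list(hset.variant_ids), f_stat=f, pve=pve)
    diag.i2_gx = i2_gx(hset.beta_exposure, hset.se_exposure)
    return diag
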