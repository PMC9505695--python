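"""Directionality (Steiger) testing and filtering.

An instrument that explains more variance in the outcome than in the
exposure is more plausibly acting outcome-first — a signature of reverse
causation.  The Steiger test compares the two variant-trait correlations
via Fisher z; filtering keeps only SNPs whose exposure correlation is both
larger and significantly so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EstimationError, ValidationError
from .summary_io import HarmonizedInstrumentSet


@dataclass
class SteigerRecord:
    variant_id: str
    r2_exposure: float
    r2_outcome: float
    direction_true: bool
    steiger_p: float


def r2_from_summary(beta, se, n):
    """Squared variant-trait correlation from a summary statistic.

    Uses the t-to-r conversion r^2 = t^2/(t^2 + n - 2) with t = beta/se.
    For binary traits the formula is applied to the logistic-scale statistic
    as an approximation (the liability-scale conversion is a documented
    alternative, not implemented).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2):
        raise ValidationError("r2_from_summary requires n > 2")
    if np.any(se <= 0):
        raise ValidationError("se must be > 0")
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def steiger_test(r2_exposure: float, n_exposure: float,
                 r2_outcome: float, n_outcome: float) -> tuple[bool, float]:
    """Two-sample Fisher-z test comparing variant-exposure vs variant-outcome r.

    Both correlations are the square roots of the r^2 inputs; the difference
    of their z-transforms is referred to a normal with variance
    1/(n_exposure-3) + 1/(n_outcome-3).  Returns (direction_true, p) where
    direction_true means the variant is more strongly coupled to the
    exposure.  Ties give direction_true = False.
    """
    for r2, n in ((r2_exposure, n_exposure), (r2_outcome, n_outcome)):
        if not 0.0 <= r2 < 1.0:
            raise ValidationError("r2 must be in [0,1)")
        if n <= 3:
            raise ValidationError("steiger_test requires n > 3")
    zx = np.arctanh(np.sqrt(r2_exposure))
    zy = np.arctanh(np.sqrt(r2_outcome))
    denom = np.sqrt(1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
    z = (zx - zy) / denom
    p = float(2.0 * stats.norm.sf(abs(z)))
    return bool(r2_exposure > r2_outcome), p


def steiger_filter(hset: HarmonizedInstrumentSet, p_threshold: float = 0.01
                   ) -> tuple[HarmonizedInstrumentSet, list[SteigerRecord]]:
    """Drop instruments with appreciable probability of reverse causation.

    Retains SNPs whose exposure r^2 exceeds the outcome r^2 with Steiger
    p < ``p_threshold`` (default 0.01).  Returns the filtered set plus the
    full per-SNP record list for audit.  An empty retained set is flagged in
    the returned records; downstream estimators will refuse it.
    """
    r2x = r2_from_summary(hset.beta_exposure, hset.se_exposure, hset.n_exposure)
    r2y = r2_from_summary(hset.beta_outcome, hset.se_outcome, hset.n_outcome)
    records = []
    keep = np.zeros(hset.n_snps, dtype=bool)
    for j, vid in enumerate(hset.variant_ids):
        direction, p = steiger_test(float(r2x[j]), float(hset.n_exposure[j]),
                                    float(r2y[j]), float(hset.n_outcome[j]))
        records.append(SteigerRecord(vid, float(r2x[j]), float(r2y[j]),
                                     direction, p))
        keep[j] = direction and p < p_threshold
    filtered = hset.subset(keep)
    filtered.provenance = dict(hset.provenance)
    filtered.provenance["steiger_removed"] = int((~keep).sum())
    return filtered, records


def steiger_records_frame(records: list[SteigerRecord]):
    import pandas as pd
    return pd.DataFrame([r.__dict__ for r in records])
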