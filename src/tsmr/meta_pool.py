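"""Fixed-effects inverse-variance pooling of per-SNP effects across GWAS.

Combines SNP-outcome effects from non-overlapping datasets into a single
pooled summary file (the METAL-style fixed-effects model), which downstream
MR then treats as one outcome GWAS.  SNPs present in only a subset of the
datasets are pooled over that subset and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError
from .summary_io import SummaryStatRecord, _match_alleles

logger = logging.getLogger(__name__)


@dataclass
class PooledRecord:
    """One SNP's pooled effect plus provenance over the contributing datasets."""

    record: SummaryStatRecord
    n_datasets: int
    dataset_mask: str  # e.g. '101': present in datasets 0 and 2


def meta_fixed(effects: list[tuple[float, float]]) -> tuple[float, float, float]:
    """Fixed-effects inverse-variance pooling of (beta, se) pairs.

    beta = sum(w b)/sum(w), se = sum(w)^-1/2 with w = 1/se^2; two-sided
    normal p.  Associative by construction.
    """
    if not effects:
        raise EstimationError("meta_fixed requires at least one effect")
    b = np.array([e[0] for e in effects], dtype=float)
    s = np.array([e[1] for e in effects], dtype=float)
    if np.any(s <= 0):
        raise EstimationError("all SEs must be > 0")
    w = 1.0 / s ** 2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def pool_datasets(datasets: list[list[SummaryStatRecord]],
                  trait_id: str = "pooled") -> tuple[list[PooledRecord], dict]:
    """Align alleles across datasets and pool each SNP's effect.

    The first dataset containing a SNP defines its reference orientation;
    later datasets are sign-flipped where their alleles are swapped, and
    dropped for that SNP (with an audit entry) when irreconcilable.  Sample
    sizes and case counts are summed over contributors; the reference
    dataset's frequency is kept.
    """
    if not datasets:
        raise EstimationError("no datasets to pool")
    audit = {"n_datasets": len(datasets), "irreconcilable": []}
    order: list[str] = []
    ref: dict[str, SummaryStatRecord] = {}
    contributions: dict[str, list[tuple[int, float, float, float, float | None]]] = {}
    for d_idx, ds in enumerate(datasets):
        for rec in ds:
            if rec.variant_id not in ref:
                ref[rec.variant_id] = rec
                order.append(rec.variant_id)
                contributions[rec.variant_id] = [
                    (d_idx, rec.beta, rec.se, rec.n, rec.n_cases)]
            else:
                match = _match_alleles(ref[rec.variant_id], rec)
                if match is None:
                    audit["irreconcilable"].append((rec.variant_id, d_idx))
                    continue
                beta = rec.beta if match == "same" else -rec.beta
                contributions[rec.variant_id].append(
                    (d_idx, beta, rec.se, rec.n, rec.n_cases))

    pooled: list[PooledRecord] = []
    for vid in order:
        contribs = contributions[vid]
        beta, se, p = meta_fixed([(b, s) for _, b, s, _, _ in contribs])
        n_total = sum(n for _, _, _, n, _ in contribs)
        cases = [c for _, _, _, _, c in contribs if c is not None]
        n_cases = sum(cases) if cases else None
        base = ref[vid]
        rec = replace(base, beta=beta, se=se, pvalue=max(p, 1e-300),
                      n=n_total, n_cases=n_cases, trait_id=trait_id)
        present = {d for d, *_ in contribs}
        mask = "".join("1" if d in present else "0" for d in range(len(datasets)))
        pooled.append(PooledRecord(record=rec, n_datasets=len(contribs),
                                   dataset_mask=mask))
    logger.info("pool_datasets: %d SNPs pooled from %d datasets, %d irreconcilable",
                len(pooled), len(datasets), len(audit["irreconcilable"]))
    return pooled, audit


def pooled_records(pooled: list[PooledRecord]) -> list[SummaryStatRecord]:
    """Extract the plain summary records from a pooled result."""
    return [p.record for p in pooled]


def write_pooled(pooled: list[PooledRecord], path) -> None:
    """Write the pooled summary dialect with N_DATASETS and DATASET_MASK columns."""
    rows = []
    for p in pooled:
        r = p.record
        rows.append({
            "SNP": r.variant_id, "CHR": r.chrom, "POS": r.pos,
            "EA": r.effect_allele, "OA": r.other_allele, "EAF": r.eaf,
            "BETA": r.beta, "SE": r.se, "P": r.pvalue, "N": r.n,
            "N_CASES": r.n_cases if r.n_cases is not None else "",
            "N_DATASETS": p.n_datasets, "DATASET_MASK": p.dataset_mask,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
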