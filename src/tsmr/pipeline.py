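"""Configuration-driven orchestration of the full MR analysis.

Runs, per outcome: the primary IVW-MRE analysis, the sensitivity battery
(MR-Egger with intercept test, weighted median, weighted mode, pleiotropy
residual-sum-and-outlier scan with corrected estimate), and three
sensitivity reruns that only ever remove SNPs — (1) a supplied list of
confounder-associated SNPs, (2) directionality (Steiger) failures, (3) the
union of both.  Optionally pools several outcome datasets first, runs
two-step mediation through a supplied mediator GWAS, and runs the reverse
analysis with exposure and outcome roles swapped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from configparser import ConfigParser
from dataclasses import dataclass, field

import pandas as pd

from .directionality import steiger_filter
from .errors import ConfigurationError, EstimationError
from .estimators import ivw, run_all
from .presso import presso
from .summary_io import SummaryStatRecord, harmonize

logger = logging.getLogger(__name__)

SENSITIVITY_LEVELS = ("primary", "sensitivity1", "sensitivity2", "sensitivity3")


@dataclass
class AnalysisConfig:
    """Settings for one end-to-end run."""

    exposure_id: str = "exposure"
    outcome_ids: list[str] = field(default_factory=list)
    # filters
    p_threshold: float = 5e-8
    maf_min: float = 0.01
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000
    # estimator settings
    bootstrap_reps: int = 1000
    presso_simulations: int = 1000
    presso_significance: float = 0.05
    steiger_p: float = 0.01
    seed: int = 0
    # sensitivity toggles
    confounder_snps: list[str] = field(default_factory=list)
    run_steiger: bool = True
    run_reverse: bool = False
    # significance policy: strict Bonferroni level across the co-primary
    # outcome datasets, then nominal
    strict_threshold: float = 0.017
    nominal_threshold: float = 0.05

    def __post_init__(self):
        if not self.strict_threshold < self.nominal_threshold:
            raise ConfigurationError("strict threshold must be < nominal threshold")

    @classmethod
    def from_ini(cls, path) -> "AnalysisConfig":
        parser = ConfigParser()
        if not parser.read(path):
            raise ConfigurationError(f"cannot read config {path}")
        kw = {}
        sec = parser["analysis"] if parser.has_section("analysis") else parser["DEFAULT"]
        for fld, cast in [("p_threshold", float), ("maf_min", float),
                          ("clump_r2", float), ("clump_window_kb", float),
                          ("bootstrap_reps", int), ("presso_simulations", int),
                          ("presso_significance", float), ("steiger_p", float),
                          ("seed", int), ("strict_threshold", float),
                          ("nominal_threshold", float)]:
            if sec.get(fld) is not None:
                kw[fld] = cast(sec[fld])
        if sec.get("confounder_snps"):
            kw["confounder_snps"] = sec["confounder_snps"].split(",")
        return cls(**kw)


def label_significance(pvalue: float, strict: float = 0.017,
                       nominal: float = 0.05) -> str:
    """Three-tier significance label: p < strict → 'significant';
    strict <= p < nominal → 'nominal'; else 'null'.  A p-value exactly on a
    boundary falls in the weaker category."""
    if not (0 < strict < 1 and 0 < nominal < 1):
        raise ConfigurationError("thresholds must be in (0,1)")
    if pvalue < strict:
        return "significant"
    if pvalue < nominal:
        return "nominal"
    return "null"


def _analyse_branch(hset, config: AnalysisConfig, seed: int) -> dict:
    """Estimator battery + outlier scan on one instrument set."""
    out = {"n_snps": hset.n_snps, "estimates": {}}
    for name, est in run_all(hset, bootstrap_reps=config.bootstrap_reps,
                             seed=seed).items():
        out["estimates"][name] = est
    if hset.n_snps >= 4:
        pres = presso(hset, n_simulations=config.presso_simulations,
                      significance=config.presso_significance, seed=seed + 7)
        out["presso"] = pres
        if pres.theta_corrected is not None:
            out["estimates"]["presso_corrected"] = pres.theta_corrected
    return out


def run_outcome_analysis(exposure_instruments: list[SummaryStatRecord],
                         outcome_records: list[SummaryStatRecord],
                         config: AnalysisConfig, seed: int) -> dict:
    """Primary analysis plus the three SNP-removal sensitivity reruns."""
    hset = harmonize(exposure_instruments, outcome_records)
    result = {"harmonization": dict(hset.provenance)}
    branches = {"primary": hset}

    confounders = set(config.confounder_snps)
    if confounders:
        keep = [v for v in hset.variant_ids if v not in confounders]
        branches["sensitivity1"] = hset.subset(keep)
    steiger_pass = None
    if config.run_steiger:
        filtered, records = steiger_filter(hset, p_threshold=config.steiger_p)
        steiger_pass = set(filtered.variant_ids)
        branches["sensitivity2"] = filtered
        result["steiger_records"] = records
    if confounders and steiger_pass is not None:
        keep = [v for v in hset.variant_ids
                if v not in confounders and v in steiger_pass]
        branches["sensitivity3"] = hset.subset(keep)

    result["branches"] = {}
    for i, level in enumerate(SENSITIVITY_LEVELS):
        branch_set = branches.get(level)
        if branch_set is None:
            continue
        if branch_set.n_snps == 0:
            result["branches"][level] = {"error": "no SNPs retained"}
            continue
        try:
            result["branches"][level] = _analyse_branch(
                branch_set, config, seed + 100 * i)
        except EstimationError as exc:
            result["branches"][level] = {"error": str(exc)}
            logger.warning("branch %s failed: %s", level, exc)
    return result


def run_analysis(exposure_instruments: list[SummaryStatRecord],
                 outcomes: dict[str, list[SummaryStatRecord]],
                 config: AnalysisConfig,
                 exposure_full: list[SummaryStatRecord] | None = None
                 ) -> dict:
    """Run every outcome branch; failures abort one branch, not the run.

    ``exposure_full`` (the unfiltered exposure GWAS) is only needed for the
    reverse analysis, where outcome-associated instruments are regressed on
    the exposure's full summary statistics with roles swapped.
    """
    bundle = {"config_seed": config.seed, "outcomes": {}}
    for i, (oid, records) in enumerate(sorted(outcomes.items())):
        try:
            bundle["outcomes"][oid] = run_outcome_analysis(
                exposure_instruments, records, config,
                seed=config.seed + 10_000 * (i + 1))
        except (EstimationError, Exception) as exc:
            bundle["outcomes"][oid] = {"error": f"outcome branch failed: {exc}"}
            logger.warning("outcome %s failed: %s", oid, exc)
    if config.run_reverse and exposure_full is not None:
        for i, (oid, records) in enumerate(sorted(outcomes.items())):
            try:
                # roles swapped: instrument the outcome, estimate on exposure
                rev_instruments = [r for r in records
                                   if r.pvalue < config.p_threshold]
                if len(rev_instruments) < 3:
                    raise EstimationError("too few outcome instruments")
                h_rev = harmonize(rev_instruments, exposure_full)
                rev = {"ivw_mre": ivw(h_rev, mode="mre")}
                filtered, _ = steiger_filter(h_rev, p_threshold=config.steiger_p)
                if filtered.n_snps >= 2:
                    rev["ivw_mre_steiger"] = ivw(filtered, mode="mre")
                bundle.setdefault("reverse", {})[oid] = rev
            except (EstimationError, Exception) as exc:
                bundle.setdefault("reverse", {})[oid] = {"error": str(exc)}
    return bundle


def render_report(bundle: dict, config: AnalysisConfig) -> tuple[pd.DataFrame, dict]:
    """Flatten a results bundle into one row per (outcome, method, level).

    Every number is copied from the stored estimate objects — nothing is
    recomputed at render time.
    """
    rows = []
    for oid, res in bundle.get("outcomes", {}).items():
        if "error" in res:
            continue
        for level, branch in res.get("branches", {}).items():
            if "error" in branch:
                continue
            for method, est in branch["estimates"].items():
                d = est.to_dict()
                rows.append({
                    "outcome": oid, "sensitivity": level, "method": method,
                    "n_snps": d["n_snps"], "theta": d["theta"], "se": d["se"],
                    "odds_ratio": d["odds_ratio"],
                    "or_ci_low": d["or_ci_low"], "or_ci_high": d["or_ci_high"],
                    "pvalue": d["pvalue"],
                    "significance": label_significance(
                        d["pvalue"], config.strict_threshold,
                        config.nominal_threshold),
                })
    meta = {
        "seed": config.seed,
        "strict_threshold": config.strict_threshold,
        "nominal_threshold": config.nominal_threshold,
        "config_hash": config_hash(config),
    }
    return pd.DataFrame(rows), meta


def config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(
        {k: v for k, v in sorted(vars(config).items())}, sort_keys=True,
        default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
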