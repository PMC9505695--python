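"""GWAS summary-statistic I/O, instrument filtering, LD clumping and harmonization.

Summary statistics travel as lists of :class:`SummaryStatRecord`; the unit all
MR estimators consume is a :class:`HarmonizedInstrumentSet`, which holds the
per-SNP exposure and outcome effects aligned onto a common effect allele.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, HarmonizationError, ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

#: default header names for the tab-separated summary dialect
DEFAULT_COLUMNS = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
    "n_cases": "N_CASES",
}
MANDATORY_FIELDS = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
)


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP-trait association from a GWAS summary file.

    ``beta`` is the effect per copy of ``effect_allele``: per-SD units for a
    quantitative trait, log-odds for a binary trait.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float
    n_cases: float | None = None
    trait_id: str = ""

    def validate(self) -> None:
        if self.se <= 0:
            raise ValidationError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if not 0.0 < self.eaf < 1.0:
            raise ValidationError(f"{self.variant_id}: eaf must be in (0,1), got {self.eaf}")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValidationError(f"{self.variant_id}: pvalue must be in (0,1], got {self.pvalue}")
        if self.pos < 1:
            raise ValidationError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: effect and other allele identical")
        for allele in (self.effect_allele, self.other_allele):
            if allele not in VALID_BASES:
                raise ValidationError(f"{self.variant_id}: allele {allele!r} not in A/C/G/T")
        if self.n_cases is not None and self.n < self.n_cases:
            raise ValidationError(f"{self.variant_id}: n < n_cases")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in PALINDROMIC_PAIRS


@dataclass
class HarmonizedInstrumentSet:
    """Allele-aligned per-SNP exposure and outcome effects.

    All arrays share the order of ``variant_ids``.  ``provenance`` records how
    many SNPs were sign-flipped, dropped as palindromic, or dropped as
    unmatched during harmonization.
    """

    exposure_id: str
    outcome_id: str
    variant_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    eaf: np.ndarray
    n_exposure: np.ndarray
    n_outcome: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("beta_exposure", "se_exposure", "beta_outcome",
                     "se_outcome", "eaf", "n_exposure", "n_outcome"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValidationError("duplicate variant_id in harmonized set")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValidationError("harmonized set contains non-positive SEs")

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)

    def subset(self, keep: np.ndarray | list) -> "HarmonizedInstrumentSet":
        """Return a new set restricted to a boolean mask or list of variant ids."""
        if isinstance(keep, (list, tuple, set, frozenset)) and not isinstance(keep, np.ndarray):
            keep_set = set(keep)
            mask = np.array([v in keep_set for v in self.variant_ids])
        else:
            mask = np.asarray(keep, dtype=bool)
        idx = np.flatnonzero(mask)
        return HarmonizedInstrumentSet(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            variant_ids=[self.variant_ids[i] for i in idx],
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            eaf=self.eaf[idx],
            n_exposure=self.n_exposure[idx],
            n_outcome=self.n_outcome[idx],
            provenance=dict(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant_id": self.variant_ids,
            "beta_exposure": self.beta_exposure,
            "se_exposure": self.se_exposure,
            "beta_outcome": self.beta_outcome,
            "se_outcome": self.se_outcome,
            "eaf": self.eaf,
            "n_exposure": self.n_exposure,
            "n_outcome": self.n_outcome,
        })


@dataclass
class LdMatrix:
    """Symmetric matrix of squared correlations (r^2) between variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise ValidationError("LD matrix shape does not match variant list")
        if not np.allclose(self.r2, self.r2.T):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValidationError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValidationError("LD r2 values must lie in [0,1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise ValidationError(f"variant {exc.args[0]!r} missing from LD matrix") from exc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids)


# ---------------------------------------------------------------------------
# reading / writing

def read_summary(path, column_map: dict | None = None,
                 trait_id: str = "") -> list[SummaryStatRecord]:
    """Read a tab-separated summary-statistics file into validated records.

    ``column_map`` maps record field names to file column names; unspecified
    fields use the package default header (SNP, CHR, POS, EA, OA, EAF, BETA,
    SE, P, N, N_CASES).  Malformed rows raise :class:`ValidationError` naming
    the offending 1-based data row numbers.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for fld in MANDATORY_FIELDS:
        if colmap[fld] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {colmap[fld]!r} (field {fld}) missing from {path}")
    has_cases = colmap["n_cases"] in df.columns

    records: list[SummaryStatRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            n_cases_raw = row.get(colmap["n_cases"]) if has_cases else None
            n_cases = None
            if n_cases_raw is not None and str(n_cases_raw) not in ("", "nan", "NA"):
                n_cases = float(n_cases_raw)
            rec = SummaryStatRecord(
                variant_id=str(row[colmap["variant_id"]]),
                chrom=str(row[colmap["chrom"]]),
                pos=int(float(row[colmap["pos"]])),
                effect_allele=str(row[colmap["effect_allele"]]).upper(),
                other_allele=str(row[colmap["other_allele"]]).upper(),
                eaf=float(row[colmap["eaf"]]),
                beta=float(row[colmap["beta"]]),
                se=float(row[colmap["se"]]),
                pvalue=float(row[colmap["pvalue"]]),
                n=float(row[colmap["n"]]),
                n_cases=n_cases,
                trait_id=trait_id,
            )
            rec.validate()
            records.append(rec)
        except (ValidationError, ValueError, TypeError) as exc:
            bad_rows.append((i, str(exc)))
    if bad_rows:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:10])
        raise ValidationError(
            f"{len(bad_rows)} malformed row(s) in {path}: {detail}")
    return records


def write_summary(records: list[SummaryStatRecord], path) -> None:
    """Write records in the default tab-separated dialect."""
    df = pd.DataFrame({
        "SNP": [r.variant_id for r in records],
        "CHR": [r.chrom for r in records],
        "POS": [r.pos for r in records],
        "EA": [r.effect_allele for r in records],
        "OA": [r.other_allele for r in records],
        "EAF": [r.eaf for r in records],
        "BETA": [r.beta for r in records],
        "SE": [r.se for r in records],
        "P": [r.pvalue for r in records],
        "N": [r.n for r in records],
        "N_CASES": [r.n_cases if r.n_cases is not None else "" for r in records],
    })
    df.to_csv(path, sep="\t", index=False)


def read_ld_matrix(path) -> LdMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LdMatrix(variant_ids=list(df.index.astype(str)), r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path) -> None:
    ld.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# instrument filtering

def filter_instruments(
    records: list[SummaryStatRecord],
    p_threshold: float = 5e-8,
    maf_min: float = 0.01,
    drop_palindromic: bool = True,
    drop_multiallelic: bool = True,
    exclusion_regions: list[tuple[str, int, int]] | None = None,
) -> tuple[list[SummaryStatRecord], dict]:
    """Apply the standard instrument-selection filters.

    Filters, in order of attribution: association p-value, minor-allele
    frequency, duplicated variant id (multiallelic proxy — all copies drop),
    palindromic allele pair, and genomic exclusion regions given as
    (chrom, start, end) closed 1-based intervals.  Returns the retained
    records and an audit dict with one count per filter; each dropped record
    is attributed to exactly the first filter it fails, so the audit counts
    plus the retained count always sum to the input count.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ConfigurationError("p_threshold must be in (0,1)")
    exclusion_regions = exclusion_regions or []
    dup_counts = Counter(r.variant_id for r in records)

    audit = {
        "input": len(records),
        "pvalue": 0,
        "maf": 0,
        "multiallelic": 0,
        "palindromic": 0,
        "region": 0,
        "retained": 0,
        "empty_output": False,
    }
    kept: list[SummaryStatRecord] = []
    for rec in records:
        if not rec.pvalue < p_threshold:
            audit["pvalue"] += 1
            continue
        if rec.maf < maf_min:
            audit["maf"] += 1
            continue
        if drop_multiallelic and dup_counts[rec.variant_id] > 1:
            audit["multiallelic"] += 1
            continue
        if drop_palindromic and rec.is_palindromic:
            audit["palindromic"] += 1
            continue
        in_region = any(
            rec.chrom == str(chrom) and start <= rec.pos <= end
            for chrom, start, end in exclusion_regions
        )
        if in_region:
            audit["region"] += 1
            continue
        kept.append(rec)
    audit["retained"] = len(kept)
    audit["empty_output"] = not kept
    logger.info("filter_instruments: %s", audit)
    return kept, audit


def clump(
    records: list[SummaryStatRecord],
    ld: LdMatrix,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000,
) -> list[SummaryStatRecord]:
    """Greedy LD clumping: keep the most significant SNP in each LD neighbourhood.

    Repeatedly selects the remaining record with the smallest p-value (ties
    broken by lexicographic variant_id) and discards remaining records on the
    same chromosome within ``window_kb`` kilobases whose r^2 with the index
    SNP is >= ``r2_threshold``.  Returns retained records in selection order.
    """
    for rec in records:
        if rec.variant_id not in ld._index:
            raise ValidationError(f"variant {rec.variant_id!r} missing from LD matrix")
    window_bp = window_kb * 1000.0
    pool = sorted(records, key=lambda r: (r.pvalue, r.variant_id))
    selected: list[SummaryStatRecord] = []
    alive = {r.variant_id for r in pool}
    for rec in pool:
        if rec.variant_id not in alive:
            continue
        selected.append(rec)
        alive.discard(rec.variant_id)
        for other in pool:
            if other.variant_id not in alive:
                continue
            if other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) > window_bp:
                continue
            if ld.lookup(rec.variant_id, other.variant_id) >= r2_threshold:
                alive.discard(other.variant_id)
    logger.info("clump: %d of %d retained", len(selected), len(records))
    return selected


# ---------------------------------------------------------------------------
# harmonization

def _match_alleles(exp: SummaryStatRecord, out: SummaryStatRecord) -> str | None:
    """Classify the outcome's allele pair relative to the exposure's.

    Returns 'same', 'swap', or None (irreconcilable).  Strand flips
    (complement pairs) count as matches because palindromic SNPs — the only
    case where a strand flip is ambiguous — are dropped upstream.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    pair = (out.effect_allele, out.other_allele)
    if pair == (ea, oa) or pair == (cea, coa):
        return "same"
    if pair == (oa, ea) or pair == (coa, cea):
        return "swap"
    return None


def harmonize(
    exposure_records: list[SummaryStatRecord],
    outcome_records: list[SummaryStatRecord],
    palindrome_policy: str = "drop",
    exposure_id: str | None = None,
    outcome_id: str | None = None,
) -> HarmonizedInstrumentSet:
    """Align outcome effects onto the exposure's effect alleles.

    Intersects on variant_id; where the outcome's alleles are swapped
    relative to the exposure the outcome beta is negated and its frequency
    reflected.  SNPs with irreconcilable allele pairs are dropped, as are
    palindromic SNPs under ``palindrome_policy='drop'``.
    """
    if palindrome_policy not in ("drop", "keep"):
        raise ConfigurationError("palindrome_policy must be 'drop' or 'keep'")
    out_by_id = {r.variant_id: r for r in outcome_records}
    prov = {"sign_flipped": 0, "palindromic_dropped": 0, "unmatched_dropped": 0}

    rows = []
    for exp in exposure_records:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            continue
        if palindrome_policy == "drop" and (exp.is_palindromic or out.is_palindromic):
            prov["palindromic_dropped"] += 1
            continue
        match = _match_alleles(exp, out)
        if match is None:
            prov["unmatched_dropped"] += 1
            continue
        beta_out, eaf_out = out.beta, out.eaf
        if match == "swap":
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            prov["sign_flipped"] += 1
        rows.append((exp.variant_id, exp.beta, exp.se, beta_out, out.se,
                     exp.eaf, exp.n, out.n))
    if not rows:
        raise HarmonizationError("zero overlapping SNPs after harmonization")
    cols = list(zip(*rows))
    hset = HarmonizedInstrumentSet(
        exposure_id=exposure_id or (exposure_records[0].trait_id or "exposure"),
        outcome_id=outcome_id or (outcome_records[0].trait_id or "outcome"),
        variant_ids=list(cols[0]),
        beta_exposure=cols[1], se_exposure=cols[2],
        beta_outcome=cols[3], se_outcome=cols[4],
        eaf=cols[5], n_exposure=cols[6], n_outcome=cols[7],
        provenance=prov,
    )
    logger.info("harmonize: %d SNPs retained, provenance %s", hset.n_snps, prov)
    return hset
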