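import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tsmr.errors import ConfigurationError, HarmonizationError, ValidationError
from tsmr.summary_io import (LdMatrix, SummaryStatRecord, clump,
                             filter_instruments, harmonize, read_summary,
                             write_summary)
from tsmr.synthetic import SimulationConfig, simulate_two_sample

from conftest import make_record


class TestReadWrite:
    def test_identity_read_back(self, tmp_path):
        records = [make_record(variant_id=f"rs{i}", pos=1000 + i, beta=0.01 * (i + 1))
                   for i in range(3)]
        path = tmp_path / "sumstats.tsv"
        write_summary(records, path)
        back = read_summary(path)
        assert len(back) == 3
        for a, b in zip(records, back):
            assert a.variant_id == b.variant_id
            assert a.beta == pytest.approx(b.beta)
            assert a.effect_allele == b.effect_allele

    def test_zero_se_row_rejected_with_row_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
            "rs1\t1\t100\tA\tG\t0.3\t0.05\t0.01\t1e-9\t1000\n"
            "rs2\t1\t200\tA\tG\t0.3\t0.05\t0\t1e-9\t1000\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_summary(path)

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        path = tmp_path / "nocol.tsv"
        path.write_text("SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tN\nx\t1\t1\tA\tG\t.3\t.1\t.1\t10\n")
        with pytest.raises(ConfigurationError, match="P"):
            read_summary(path)

    def test_random_roundtrip(self, tmp_path, rng):
        records = [
            make_record(variant_id=f"rs{i}", chrom=str(rng.integers(1, 23)),
                        pos=int(rng.integers(1, 10**8)),
                        eaf=float(rng.uniform(0.05, 0.95)),
                        beta=float(rng.normal(0, 0.05)),
                        se=float(rng.uniform(0.001, 0.02)),
                        pvalue=float(rng.uniform(1e-30, 1)),
                        n=float(rng.integers(1000, 10**6)))
            for i in range(50)
        ]
        path = tmp_path / "roundtrip.tsv"
        write_summary(records, path)
        back = read_summary(path)
        for a, b in zip(records, back):
            assert a.pos == b.pos
            assert a.beta == pytest.approx(b.beta, rel=1e-12)
            assert a.se == pytest.approx(b.se, rel=1e-12)
            assert a.pvalue == pytest.approx(b.pvalue, rel=1e-12)


class TestFilterInstruments:
    def test_hla_region_excluded(self):
        rec = make_record(variant_id="rs_hla", chrom="6", pos=30_000_000)
        kept, audit = filter_instruments(
            [rec], exclusion_regions=[("6", 25_000_000, 34_000_000)])
        assert kept == []
        assert audit["region"] == 1

    def test_palindromic_excluded(self):
        rec = make_record(ea="A", oa="T")
        kept, audit = filter_instruments([rec], drop_palindromic=True)
        assert kept == []
        assert audit["palindromic"] == 1

    def test_clean_snp_retained(self):
        rec = make_record(eaf=0.5, pvalue=1e-9, chrom="1")
        kept, audit = filter_instruments([rec])
        assert len(kept) == 1 and audit["retained"] == 1

    def test_maf_and_pvalue_filters(self):
        records = [make_record(variant_id="rare", eaf=0.005),
                   make_record(variant_id="weak", pvalue=1e-5),
                   make_record(variant_id="good")]
        kept, audit = filter_instruments(records)
        assert [r.variant_id for r in kept] == ["good"]
        assert audit["maf"] == 1 and audit["pvalue"] == 1

    def test_multiallelic_duplicates_all_dropped(self):
        records = [make_record(variant_id="dup", ea="A", oa="G"),
                   make_record(variant_id="dup", ea="A", oa="C"),
                   make_record(variant_id="solo")]
        kept, audit = filter_instruments(records)
        assert [r.variant_id for r in kept] == ["solo"]
        assert audit["multiallelic"] == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_audit_counts_partition_input(self, seed):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(30):
            ea, oa = rng.choice([("A", "G"), ("A", "T"), ("C", "G"), ("T", "C")])
            records.append(make_record(
                variant_id=f"rs{rng.integers(0, 20)}", ea=ea, oa=oa,
                chrom=str(rng.integers(1, 8)),
                pos=int(rng.integers(1, 5 * 10**7)),
                eaf=float(rng.uniform(0.001, 0.999)),
                pvalue=float(rng.uniform(1e-12, 1e-4))))
        kept, audit = filter_instruments(
            records, exclusion_regions=[("6", 25_000_000, 34_000_000)])
        dropped = sum(audit[k] for k in
                      ("pvalue", "maf", "multiallelic", "palindromic", "region"))
        assert dropped + audit["retained"] == audit["input"] == 30


def _identity_ld(ids):
    return LdMatrix(variant_ids=list(ids), r2=np.eye(len(ids)))


class TestClump:
    def test_identity_ld_keeps_all(self):
        records = [make_record(variant_id=f"rs{i}", pos=1000 * i + 1,
                               pvalue=10**-(9 + i)) for i in range(5)]
        ld = _identity_ld([r.variant_id for r in records])
        assert len(clump(records, ld)) == 5

    def test_stronger_snp_dominates(self):
        a = make_record(variant_id="rsA", pos=1000, pvalue=1e-10)
        b = make_record(variant_id="rsB", pos=2000, pvalue=1e-9)
        ld = LdMatrix(variant_ids=["rsA", "rsB"],
                      r2=np.array([[1.0, 0.99], [0.99, 1.0]]))
        kept = clump([a, b], ld, r2_threshold=0.01, window_kb=10_000)
        assert [r.variant_id for r in kept] == ["rsA"]

    def test_missing_variant_in_ld_raises(self):
        rec = make_record(variant_id="rsX")
        with pytest.raises(ValidationError, match="rsX"):
            clump([rec], _identity_ld(["rsOther"]))

    def test_matches_bruteforce_greedy_oracle(self, rng):
        # independent re-implementation of greedy-by-p selection
        J = 20
        records = [make_record(variant_id=f"rs{i:02d}",
                               chrom=str(1 + i % 2), pos=int(1 + i * 400_000),
                               pvalue=float(rng.uniform(1e-12, 1e-6)))
                   for i in range(J)]
        raw = rng.uniform(0, 1, (J, J))
        r2 = (raw + raw.T) / 2 * 0.5
        np.fill_diagonal(r2, 1.0)
        ids = [r.variant_id for r in records]
        ld = LdMatrix(variant_ids=ids, r2=r2)

        def oracle():
            idx = {v: i for i, v in enumerate(ids)}
            remaining = sorted(records, key=lambda r: (r.pvalue, r.variant_id))
            out = []
            while remaining:
                head = remaining.pop(0)
                out.append(head.variant_id)
                remaining = [
                    r for r in remaining
                    if not (r.chrom == head.chrom
                            and abs(r.pos - head.pos) <= 500 * 1000
                            and r2[idx[head.variant_id], idx[r.variant_id]] >= 0.1)]
            return out

        kept = clump(records, ld, r2_threshold=0.1, window_kb=500)
        assert [r.variant_id for r in kept] == oracle()


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp = make_record(ea="A", oa="G", beta=0.05)
        out = make_record(ea="G", oa="A", beta=0.2, eaf=0.7)
        h = harmonize([exp], [out])
        assert h.beta_outcome[0] == pytest.approx(-0.2)
        assert h.provenance["sign_flipped"] == 1

    def test_identical_alleles_unchanged(self):
        exp = make_record(beta=0.05)
        out = make_record(beta=0.2)
        h = harmonize([exp], [out])
        assert h.beta_outcome[0] == pytest.approx(0.2)

    def test_strand_flip_recognised(self):
        exp = make_record(ea="A", oa="G", beta=0.05)
        out = make_record(ea="T", oa="C", beta=0.2)  # complement strand
        h = harmonize([exp], [out])
        assert h.beta_outcome[0] == pytest.approx(0.2)

    def test_irreconcilable_alleles_dropped(self):
        exp = make_record(variant_id="rs1", ea="A", oa="G")
        out1 = make_record(variant_id="rs1", ea="A", oa="C")
        out2 = make_record(variant_id="rs2")
        exp2 = make_record(variant_id="rs2")
        h = harmonize([exp, exp2], [out1, out2])
        assert h.variant_ids == ["rs2"]
        assert h.provenance["unmatched_dropped"] == 1

    def test_zero_overlap_raises(self):
        with pytest.raises(HarmonizationError):
            harmonize([make_record(variant_id="rs1")],
                      [make_record(variant_id="rs2")])

    def test_idempotence(self):
        exp, out, _ = simulate_two_sample(SimulationConfig(seed=42, n_snps=20))
        h1 = harmonize(exp, out)
        # reconstitute outcome records from the harmonized set and re-harmonize
        from dataclasses import replace
        out_map = {r.variant_id: r for r in out}
        recon = [replace(out_map[v], beta=float(h1.beta_outcome[i]))
                 for i, v in enumerate(h1.variant_ids)]
        h2 = harmonize(exp, recon)
        np.testing.assert_allclose(h2.beta_outcome, h1.beta_outcome)
        assert h2.variant_ids == h1.variant_ids

    def test_commutes_with_global_outcome_negation(self):
        from dataclasses import replace
        exp, out, _ = simulate_two_sample(SimulationConfig(seed=43, n_snps=15))
        h = harmonize(exp, out)
        negated = [replace(r, beta=-r.beta) for r in out]
        h_neg = harmonize(exp, negated)
        np.testing.assert_allclose(h_neg.beta_outcome, -h.beta_outcome)


def test_filter_then_clump_is_order_stable(rng):
    """Clumping never reintroduces a SNP that filtering removed."""
    exp, _, truth = simulate_two_sample(SimulationConfig(seed=77, n_snps=30))
    filtered, _ = filter_instruments(exp, p_threshold=1e-8)
    ld = _identity_ld([r.variant_id for r in exp])
    clumped = clump(filtered, ld)
    assert {r.variant_id for r in clumped} <= {r.variant_id for r in filtered}
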