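"""Summary-statistic parsing, allele harmonization, LD, and pruning."""

import itertools

import numpy as np
import pytest

from gpgemr.sumstats import (
    AssociationRecord,
    HarmonizationDrop,
    LDMatrix,
    SumstatsFormatError,
    Variant,
    greedy_ld_prune,
    harmonize_alleles,
    ld_from_genotypes,
    read_sumstats,
    write_sumstats,
)

from conftest import make_record

HEADER = "variant_id\tchrom\tpos\teffect_allele\tother_allele\tbeta\tse\tpvalue\teaf\tn\n"


class TestReadSumstats:
    def _write(self, tmp_path, body, header=HEADER):
        p = tmp_path / "sumstats.tsv"
        p.write_text(header + body)
        return p

    def test_valid_rows_parse_identically(self, tmp_path):
        body = (
            "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.0455\t0.3\t1000\n"
            "rs2\t1\t200\tT\tC\t-0.1\t0.1\t0.317\t0.4\t1000\n"
            "rs3\t2\t300\tG\tA\t0.0\t0.2\t1.0\t0.5\t1000\n"
        )
        records = read_sumstats(self._write(tmp_path, body), "trait")
        assert len(records) == 3
        assert records[0].variant.id == "rs1"
        assert records[0].beta == pytest.approx(0.2)
        assert records[1].variant.effect_allele == "T"
        assert all(r.trait_id == "trait" for r in records)

    def test_nonpositive_se_row_dropped(self, tmp_path, caplog):
        body = (
            "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.0455\t0.3\t1000\n"
            "rs2\t1\t200\tT\tC\t-0.1\t0\t0.317\t0.4\t1000\n"
            "rs3\t2\t300\tG\tA\t0.1\t0.2\t0.617\t0.5\t1000\n"
        )
        with caplog.at_level("WARNING"):
            records = read_sumstats(self._write(tmp_path, body), "trait")
        assert [r.variant.id for r in records] == ["rs1", "rs3"]
        assert "dropped 1" in caplog.text

    def test_missing_se_column_is_format_error(self, tmp_path):
        header = HEADER.replace("\tse", "\tstderr")
        p = self._write(tmp_path, "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.05\t0.3\t1000\n", header)
        with pytest.raises(SumstatsFormatError, match="column se not found"):
            read_sumstats(p, "trait")

    def test_unparsable_numeric_names_line(self, tmp_path):
        p = self._write(tmp_path, "rs1\t1\t100\tA\tG\tnot_a_number\t0.1\t0.05\t0.3\t1000\n")
        with pytest.raises(SumstatsFormatError, match="line 2"):
            read_sumstats(p, "trait")

    def test_round_trip(self, tmp_path):
        records = [make_record("rs1", beta=0.123456), make_record("rs2", ea="T", oa="C", beta=-0.5, pos=77)]
        p = tmp_path / "out.tsv"
        write_sumstats(records, p)
        back = read_sumstats(p, "t")
        assert [r.variant.id for r in back] == ["rs1", "rs2"]
        assert back[0].beta == records[0].beta
        assert back[1].eaf == records[1].eaf


class TestVariantAndRecordInvariants:
    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            Variant("rs1", "1", 1, "A", "A")

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            Variant("rs1", "1", 1, "A", "N")

    def test_palindromic_flag(self):
        assert Variant("rs1", "1", 1, "A", "T").is_palindromic
        assert Variant("rs2", "1", 1, "C", "G").is_palindromic
        assert not Variant("rs3", "1", 1, "A", "G").is_palindromic
        assert not Variant("rs4", "1", 1, "AT", "A").is_palindromic  # indel: not checkable

    def test_zscore_pvalue_consistency_check(self):
        ok = make_record("rs1", beta=0.2, se=0.1)
        assert ok.check_consistency()
        bad = AssociationRecord(ok.variant, beta=1.0, se=0.1, pvalue=0.5, trait_id="t")
        assert not bad.check_consistency()

    def test_se_must_be_positive(self):
        with pytest.raises(ValueError, match="se"):
            make_record("rs1", se=0.0)


class TestHarmonizeAlleles:
    @pytest.mark.parametrize(
        "rec_alleles,ref_alleles,expect_beta,expect_eaf",
        [
            (("A", "G"), ("A", "G"), 0.2, 0.3),  # direct match
            (("A", "G"), ("G", "A"), -0.2, 0.7),  # swap
            (("A", "G"), ("T", "C"), 0.2, 0.3),  # strand flip
            (("A", "G"), ("C", "T"), -0.2, 0.7),  # strand flip + swap
        ],
    )
    def test_orientation_cases(self, rec_alleles, ref_alleles, expect_beta, expect_eaf):
        rec = make_record("rs1", *rec_alleles, beta=0.2, eaf=0.3)
        ref = Variant("rs1", "1", 1000, *ref_alleles)
        out = harmonize_alleles(rec, ref)
        assert out.beta == pytest.approx(expect_beta)
        assert out.eaf == pytest.approx(expect_eaf)
        assert out.variant.effect_allele == ref.effect_allele

    @pytest.mark.parametrize("eaf", [0.50, 0.42, 0.58, None])
    def test_palindromic_ambiguous_dropped(self, eaf):
        rec = make_record("rs1", "A", "T", eaf=eaf)
        out = harmonize_alleles(rec, Variant("rs1", "1", 1000, "A", "T"))
        assert isinstance(out, HarmonizationDrop)
        assert out.reason == "palindromic-ambiguous"

    def test_palindromic_with_informative_frequency_kept(self):
        rec = make_record("rs1", "A", "T", beta=0.2, eaf=0.1)
        out = harmonize_alleles(rec, Variant("rs1", "1", 1000, "A", "T"))
        assert isinstance(out, AssociationRecord)
        assert out.beta == pytest.approx(0.2)

    def test_irreconcilable_alleles_drop(self):
        rec = make_record("rs1", "A", "G")
        out = harmonize_alleles(rec, Variant("rs1", "1", 1000, "A", "C"))
        assert isinstance(out, HarmonizationDrop)
        assert out.reason == "allele mismatch"

    @pytest.mark.parametrize("ref_alleles", [("A", "G"), ("G", "A"), ("T", "C"), ("C", "T")])
    def test_involution(self, ref_alleles):
        """Harmonizing twice against the same reference equals harmonizing once."""
        rec = make_record("rs1", "A", "G", beta=0.2, eaf=0.3)
        ref = Variant("rs1", "1", 1000, *ref_alleles)
        once = harmonize_alleles(rec, ref)
        twice = harmonize_alleles(once, ref)
        assert twice == once


class TestLDFromGenotypes:
    def test_duplicated_column_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=50).astype(float)
        ld = ld_from_genotypes(np.column_stack([col, col]), ["v1", "v2"])
        assert ld.r[0, 1] == pytest.approx(1.0)

    def test_independent_columns_have_small_correlation(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, size=(10_000, 8)).astype(float)
        ld = ld_from_genotypes(g, [f"v{i}" for i in range(8)])
        off = ld.r[~np.eye(8, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)
        # dosage sd close to binomial sd sqrt(2 * 0.3 * 0.7)
        assert ld.sd == pytest.approx(np.sqrt(2 * 0.3 * 0.7), rel=0.05)

    def test_monomorphic_column_raises_with_id(self):
        g = np.column_stack([np.ones(20), np.arange(20, dtype=float)])
        with pytest.raises(ValueError, match="monomorphic.*vA"):
            ld_from_genotypes(g, ["vA", "vB"])

    def test_output_satisfies_matrix_invariants(self, small_panel):
        ld = small_panel.ld
        assert np.allclose(np.diag(ld.r), 1.0)
        assert np.linalg.eigvalsh(ld.r)[0] >= -1e-8
        assert len(ld.sd) == len(ld.variant_ids)
        assert np.all(ld.sd > 0)


def _brute_force_prune(records, ld, r2_max):
    """Independent oracle: best keep-set via explicit greedy over sorted list."""
    order = sorted(records, key=lambda r: (r.pvalue, r.variant.id))
    kept = []
    for rec in order:
        i = ld.index_of(rec.variant.id)
        if all(ld.r[i, ld.index_of(k.variant.id)] ** 2 <= r2_max for k in kept):
            kept.append(rec)
    return [r.variant.id for r in kept]


class TestGreedyLDPrune:
    def _three_variant_ld(self, r12):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = r12
        return LDMatrix(["v1", "v2", "v3"], r, np.ones(3))

    def test_correlated_pair_pruned_to_best(self):
        ld = self._three_variant_ld(np.sqrt(0.5))
        recs = [
            make_record("v1", p=1e-10, beta=0.65, se=0.1),
            make_record("v2", p=1e-9, beta=0.61, se=0.1),
            make_record("v3", p=1e-8, beta=0.57, se=0.1),
        ]
        kept = greedy_ld_prune(recs, ld, r2_max=0.01)
        assert [r.variant.id for r in kept] == ["v1", "v3"]
        assert [r.variant.id for r in kept] == _brute_force_prune(recs, ld, 0.01)

    def test_uncorrelated_records_all_kept(self):
        ld = self._three_variant_ld(0.0)
        recs = [make_record(v, p=p, beta=0.5, se=0.1) for v, p in [("v1", 1e-4), ("v2", 1e-3), ("v3", 1e-2)]]
        assert len(greedy_ld_prune(recs, ld, 0.01)) == 3

    def test_tie_broken_lexicographically(self):
        r = np.ones((2, 2))
        ld = LDMatrix(["vB", "vA"], r, np.ones(2))
        recs = [make_record("vB", p=1e-5, beta=0.44, se=0.1), make_record("vA", p=1e-5, beta=0.44, se=0.1)]
        kept = greedy_ld_prune(recs, ld, 0.01)
        assert [r.variant.id for r in kept] == ["vA"]

    def test_missing_variant_raises(self):
        ld = self._three_variant_ld(0.0)
        with pytest.raises(KeyError, match="vX"):
            greedy_ld_prune([make_record("vX")], ld, 0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_pairwise_r2_bounded_and_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, rng.uniform(0.1, 0.5, 12), size=(400, 12)).astype(float)
        g[:, 5] = g[:, 4]  # force one perfectly correlated pair
        ids = [f"v{i:02d}" for i in range(12)]
        ld = ld_from_genotypes(g, ids)
        recs = [make_record(v, p=float(p), beta=0.1, se=0.05) for v, p in zip(ids, rng.uniform(size=12))]
        r2_max = 0.2
        kept = greedy_ld_prune(recs, ld, r2_max)
        assert [r.variant.id for r in kept] == _brute_force_prune(recs, ld, r2_max)
        idx = [ld.index_of(r.variant.id) for r in kept]
        for i, j in itertools.combinations(idx, 2):
            assert ld.r[i, j] ** 2 <= r2_max
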