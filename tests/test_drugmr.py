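"""Proxied-drug MR: instruments, mechanism harmonization, meta-analysis,
IVW/Wald, Egger, Cochran's Q, random-effects inflation, report shape."""

import math

import numpy as np
import pytest

from gpgemr.drugmr import (
    DrugMRResult,
    EmptyInstruments,
    QResult,
    TissueInstrument,
    build_tissue_instruments,
    cochran_q,
    harmonize_by_mechanism,
    meta_exposure_dl,
    mr_egger_tissue,
    mr_ivw_tissue,
    mr_random_effects,
    mr_wald_single,
    summarize_drug_mr,
)
from gpgemr.twas import GPGEResult


def _inst(bx, by, sx=0.05, sy=0.05, tissue="t0", gene="G"):
    return TissueInstrument(gene, tissue, bx, sx, 0.01, by, sy)


def _insts(bxs, bys, sys_=None):
    sys_ = sys_ or [0.05] * len(bxs)
    return [_inst(bx, by, sy=sy, tissue=f"t{i}") for i, (bx, by, sy) in enumerate(zip(bxs, bys, sys_))]


def _gpge(gene, tissue, trait, effect, se, log10p):
    z = effect / se
    return GPGEResult(gene, tissue, trait, z, effect, se, log10p, 2, 1.0)


class TestBuildTissueInstruments:
    def _lists(self):
        ind = [
            _gpge("G", "liver", "htn", 0.4, 0.1, -4.0),
            _gpge("G", "adipose", "htn", 0.3, 0.1, math.log10(0.2)),  # p = 0.2: fails gate
            _gpge("G", "muscle", "htn", 0.2, 0.1, -2.0),
            _gpge("G", "skin", "htn", 0.2, 0.1, -3.0),  # no outcome counterpart
        ]
        out = [
            _gpge("G", "liver", "outcome", -0.1, 0.05, -1.5),
            _gpge("G", "adipose", "outcome", -0.1, 0.05, -1.5),
            _gpge("G", "muscle", "outcome", -0.05, 0.05, -0.5),
        ]
        return ind, out

    def test_p_gate_and_outcome_join(self):
        ind, out = self._lists()
        instruments = build_tissue_instruments("G", ind, out, p_threshold=0.05)
        assert {i.tissue for i in instruments} == {"liver", "muscle"}

    def test_no_survivor_signals_untestable(self):
        ind, out = self._lists()
        with pytest.raises(EmptyInstruments):
            build_tissue_instruments("G", ind, out, p_threshold=1e-10)

    def test_instrument_carries_both_effect_pairs(self):
        ind, out = self._lists()
        (liver,) = [i for i in build_tissue_instruments("G", ind, out) if i.tissue == "liver"]
        assert liver.beta_exposure == pytest.approx(0.4)
        assert liver.beta_outcome == pytest.approx(-0.1)


class TestMechanismHarmonization:
    def test_inhibitor_flips_both_effects_jointly(self):
        (out,) = harmonize_by_mechanism([_inst(0.3, 0.1)], "inhibitor")
        assert (out.beta_exposure, out.beta_outcome) == (-0.3, -0.1)
        assert out.mechanism_flipped
        assert out.wald == pytest.approx(0.1 / 0.3)  # ratio invariant

    def test_agonist_is_identity(self):
        ins = _inst(0.3, 0.1)
        assert harmonize_by_mechanism([ins], "agonist") == [ins]

    def test_double_harmonization_is_noop(self, caplog):
        once = harmonize_by_mechanism([_inst(0.3, 0.1)], "inhibitor")
        with caplog.at_level("WARNING"):
            twice = harmonize_by_mechanism(once, "inhibitor")
        assert twice == once
        assert "already" in caplog.text

    def test_unknown_mechanism_rejected(self):
        with pytest.raises(ValueError):
            harmonize_by_mechanism([_inst(0.3, 0.1)], "partial agonist")

    def test_mr_estimate_invariant_under_flip(self):
        ins = _insts([0.5, 0.4, 0.6], [0.2, 0.15, 0.25])
        beta_a, se_a = mr_ivw_tissue(harmonize_by_mechanism(ins, "agonist"))
        beta_i, se_i = mr_ivw_tissue(harmonize_by_mechanism(ins, "inhibitor"))
        assert beta_i == pytest.approx(beta_a)
        assert se_i == pytest.approx(se_a)


class TestDerSimonianLaird:
    def test_homogeneous_effects_have_zero_tau2(self):
        pooled, se, tau2 = meta_exposure_dl(_insts([0.5, 0.5], [0, 0], None))
        assert pooled == pytest.approx(0.5)
        assert tau2 == 0.0
        assert se == pytest.approx(0.05 / math.sqrt(2))

    def test_single_instrument_passes_through(self):
        pooled, se, tau2 = meta_exposure_dl([_inst(-0.11, 0.0, sx=0.05)])
        assert (pooled, se, tau2) == (-0.11, 0.05, 0.0)

    def test_heterogeneous_effects_inflate_se(self):
        """Oracle: direct evaluation of the DL formulas."""
        eff, se = np.array([0.2, 0.8]), np.array([0.1, 0.1])
        w = 1 / se**2
        mu = np.sum(w * eff) / np.sum(w)
        q = np.sum(w * (eff - mu) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2_expected = max(0.0, (q - 1) / c)
        w_star = 1 / (se**2 + tau2_expected)
        se_expected = 1 / math.sqrt(np.sum(w_star))

        ins = [_inst(0.2, 0.0, sx=0.1, tissue="a"), _inst(0.8, 0.0, sx=0.1, tissue="b")]
        pooled, se_dl, tau2 = meta_exposure_dl(ins)
        assert tau2 == pytest.approx(tau2_expected)
        assert tau2 > 0
        assert se_dl == pytest.approx(se_expected)
        assert se_dl > 0.1 / math.sqrt(2)  # larger than the homogeneous-case se
        assert pooled == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            meta_exposure_dl([])


class TestIVWAndWald:
    def test_ivw_closed_form(self):
        beta, se = mr_ivw_tissue(_insts([1.0, 1.0], [0.5, 0.5], [0.1, 0.1]))
        assert beta == pytest.approx(0.5)
        assert se == pytest.approx(0.1 / math.sqrt(2), rel=1e-9)

    def test_duplicated_instrument_shrinks_se_by_sqrt_k(self):
        one = _insts([0.8], [0.3], [0.07])
        k = 4
        many = _insts([0.8] * k, [0.3] * k, [0.07] * k)
        b1, _ = mr_wald_single(one[0]), None
        bk, sek = mr_ivw_tissue(many)
        assert bk == pytest.approx(0.3 / 0.8)
        assert sek == pytest.approx((0.07 / 0.8) / math.sqrt(k), rel=1e-9)

    def test_fewer_than_two_instruments_rejected(self):
        with pytest.raises(ValueError):
            mr_ivw_tissue(_insts([1.0], [0.5]))

    def test_wald_single_closed_form(self):
        beta, se = mr_wald_single(_inst(1.10, -0.094, sy=0.03))
        assert beta == pytest.approx(-0.094 / 1.10)
        assert se == pytest.approx(0.03 / 1.10)

    def test_wald_unit_exposure(self):
        beta, se = mr_wald_single(_inst(1.0, -0.2, sy=0.05))
        assert (beta, se) == (-0.2, 0.05)

    def test_wald_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            mr_wald_single(_inst(0.0, 0.1))


class TestEgger:
    def test_collinear_through_origin(self):
        ins = _insts([1.0, 2.0, 3.0], [0.5, 1.0, 1.5])
        egger = mr_egger_tissue(ins)
        assert egger.intercept == pytest.approx(0.0, abs=1e-12)
        assert egger.slope == pytest.approx(0.5)

    def test_two_instruments_yield_missing(self):
        assert mr_egger_tissue(_insts([1.0, 2.0], [0.5, 1.0])) is None

    def test_negative_exposures_oriented_before_fit(self):
        ins_pos = _insts([1.0, 2.0, 3.0], [0.5, 1.0, 1.5])
        ins_mixed = _insts([1.0, -2.0, 3.0], [0.5, -1.0, 1.5])
        a, b = mr_egger_tissue(ins_pos), mr_egger_tissue(ins_mixed)
        assert b.intercept == pytest.approx(a.intercept, abs=1e-12)
        assert b.slope == pytest.approx(a.slope)

    def test_constant_offset_produces_nonzero_intercept(self):
        ins = _insts([1.0, 2.0, 3.0, 4.0], [0.5 + 0.3, 1.0 + 0.3, 1.5 + 0.3, 2.0 + 0.3])
        egger = mr_egger_tissue(ins)
        assert egger.intercept == pytest.approx(0.3, abs=1e-9)
        assert egger.slope == pytest.approx(0.5, abs=1e-9)


class TestCochranQ:
    def test_homogeneous_ratios_give_zero_q(self):
        ins = _insts([1.0, 2.0], [0.5, 1.0])
        beta, _ = mr_ivw_tissue(ins)
        q = cochran_q(ins, beta)
        assert q.q == pytest.approx(0.0, abs=1e-12)
        assert q.pvalue == pytest.approx(1.0)

    def test_hand_evaluable_case(self):
        ins = _insts([1.0, 1.0], [0.0, 1.0], [1.0, 1.0])
        beta, _ = mr_ivw_tissue(ins)
        assert beta == pytest.approx(0.5)
        q = cochran_q(ins, beta)
        assert q.q == pytest.approx(0.5)
        assert q.df == 1

    def test_single_instrument_missing(self):
        assert cochran_q(_insts([1.0], [0.5]), 0.5) is None


class TestRandomEffects:
    def test_floor_at_one(self):
        q = QResult(q=3.0, df=9, pvalue=0.96)
        assert mr_random_effects(0.5, 0.1, q) == 0.1

    def test_q_four_times_df_doubles_se(self):
        q = QResult(q=36.0, df=9, pvalue=1e-4)
        assert mr_random_effects(0.5, 0.1, q) == pytest.approx(0.2)


class TestSummarize:
    def _result(self, **kw):
        base = dict(
            gene="G",
            drug="d",
            primary_indication="htn",
            n_tissues=3,
            pooled_exposure_change=0.3,
            pooled_exposure_se=0.05,
            tau2=0.0,
            beta_mr=0.0,
            se_mr=0.1,
            pvalue=1.0,
            log10_pvalue=0.0,
            method="ivw_fixed",
            egger_intercept=0.01,
            egger_intercept_p=0.5,
        )
        base.update(kw)
        return DrugMRResult(**base)

    def test_or_and_ci_from_log_odds(self):
        df = summarize_drug_mr([self._result()])
        row = df.iloc[0]
        assert row.ivw_or == pytest.approx(1.0)
        assert row.or_ci95_low == pytest.approx(math.exp(-1.96 * 0.1))
        assert row.or_ci95_high == pytest.approx(math.exp(1.96 * 0.1))
        assert (round(row.or_ci95_low, 2), round(row.or_ci95_high, 2)) == (0.82, 1.22)

    def test_single_tissue_egger_is_na(self):
        df = summarize_drug_mr([self._result(n_tissues=1, method="wald", egger_intercept=None, egger_intercept_p=None)])
        assert df.iloc[0].egger_pvalue == "N/A"

    def test_random_effects_carries_footnote_marker(self):
        df = summarize_drug_mr([self._result(method="ivw_random")])
        assert df.iloc[0].method == "ivw_random*"

    def test_rows_sorted_by_indication_gene_drug(self):
        df = summarize_drug_mr(
            [self._result(primary_indication="z"), self._result(primary_indication="a", gene="B")]
        )
        assert list(df.primary_indication) == ["a", "z"]
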