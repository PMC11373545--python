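"""Instrument selection, LD pruning, proxies and harmonization."""

import numpy as np
import pytest

from protmr.core_io import LDMatrix, SummaryStats
from protmr.instruments import (
    HarmonizedSet,
    f_statistic,
    filter_instruments,
    find_proxy,
    harmonize,
    ld_prune,
    select_and_harmonize,
)
from tests.conftest import make_assoc, make_sumstats


class TestFStatistic:
    def test_arithmetic(self):
        assert f_statistic(0.2, 0.02) == pytest.approx(100.0)
        assert f_statistic(0.0, 0.5) == 0.0

    def test_just_below_strength_cutoff(self):
        # (0.0316/0.01)^2 = 9.986 < 10: this instrument would be rejected
        assert f_statistic(0.0316, 0.01) == pytest.approx(9.986, abs=0.01)
        assert f_statistic(0.0316, 0.01) < 10

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)


class TestFilter:
    def test_strong_common_significant_variant_kept(self):
        s = make_sumstats([0.2], ses=[0.02], eaf=0.3)  # F = 100
        recs = filter_instruments(s, p_max=1e-3)
        assert recs[0].status == "kept"

    def test_weak_instrument_removed(self):
        s = make_sumstats([0.03], ses=[0.01], eaf=0.3)  # F = 9
        recs = filter_instruments(s, p_max=1.0)
        assert recs[0].status == "removed_f"

    def test_rare_variant_removed(self):
        s = make_sumstats([0.2], ses=[0.02], eaf=0.0005)
        recs = filter_instruments(s, p_max=1e-3)
        assert recs[0].status == "removed_maf"

    def test_first_failing_criterion_wins(self):
        # fails p, F and MAF; reported reason must be p
        s = make_sumstats([0.01], ses=[0.01], eaf=0.0005, pval=0.9)
        recs = filter_instruments(s, p_max=1e-3)
        assert recs[0].status == "removed_p"

    def test_statuses_partition_input(self):
        rng = np.random.default_rng(7)
        betas = rng.normal(0, 0.2, 20)
        s = make_sumstats(betas.tolist(), ses=[0.02] * 20, eaf=0.2)
        recs = filter_instruments(s, p_max=1e-4)
        assert len(recs) == 20
        assert sum(r.status == "kept" for r in recs) + sum(r.status != "kept" for r in recs) == 20

    def test_missing_eaf_policy(self):
        s = make_sumstats([0.2], ses=[0.02], eaf=None)
        assert filter_instruments(s, p_max=1e-3)[0].status == "removed_maf"
        assert filter_instruments(s, p_max=1e-3, missing_eaf_policy="keep")[0].status == "kept"


def _two_variant_records(dist_bp, f_high=200.0, f_low=50.0, r2=0.5):
    # F = (beta/se)^2, so choose betas giving the requested F at se=0.01
    s = make_sumstats(
        [0.01 * np.sqrt(f_high), 0.01 * np.sqrt(f_low)], ses=[0.01, 0.01], eaf=0.3
    )
    s.associations[1] = type(s.associations[1])(
        **{**s.associations[1].__dict__, "pos": s.associations[0].pos + dist_bp}
    )
    recs = filter_instruments(s, p_max=1.0)
    ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, r2], [r2, 1.0]]))
    return recs, ld


class TestLDPrune:
    def test_correlated_pair_keeps_stronger(self):
        recs, ld = _two_variant_records(dist_bp=100_000, r2=0.5)
        out = ld_prune(recs, ld)
        by_id = {r.variant_id: r.status for r in out}
        assert by_id["rs1"] == "kept"  # higher F
        assert by_id["rs2"] == "removed_ld"

    def test_below_threshold_both_kept(self):
        recs, ld = _two_variant_records(dist_bp=100_000, r2=0.1)
        out = ld_prune(recs, ld)
        assert all(r.status == "kept" for r in out)

    def test_outside_window_both_kept(self):
        recs, ld = _two_variant_records(dist_bp=600_000, r2=0.5)
        out = ld_prune(recs, ld)
        assert all(r.status == "kept" for r in out)

    def test_missing_pair_raises(self):
        recs, _ = _two_variant_records(dist_bp=100_000, r2=0.5)
        ld = LDMatrix(["rs1"], np.ones((1, 1)))
        with pytest.raises(ValueError, match="rs2"):
            ld_prune(recs, ld)

    def test_result_independent_of_input_order(self):
        rng = np.random.default_rng(3)
        betas = (rng.uniform(0.1, 0.5, 6)).tolist()
        s = make_sumstats(betas, ses=[0.01] * 6, eaf=0.3, start_pos=1_000_000)
        ids = [a.variant_id for a in s.associations]
        r2 = np.eye(6)
        pairs = [(0, 1, 0.9), (2, 3, 0.6), (1, 4, 0.3)]
        for i, j, v in pairs:
            r2[i, j] = r2[j, i] = v
        ld = LDMatrix(ids, r2)
        recs = filter_instruments(s, p_max=1.0)
        fwd = {r.variant_id: r.status for r in ld_prune(recs, ld)}
        recs_rev = filter_instruments(s, p_max=1.0)[::-1]
        rev = {r.variant_id: r.status for r in ld_prune(recs_rev, ld)}
        assert fwd == rev


class TestProxy:
    def _outcome(self):
        return make_sumstats([0.1, 0.1, 0.1], ses=[0.02] * 3, name="out")

    def test_argmax_selected(self):
        out = self._outcome()
        ld = LDMatrix(
            ["target", "rs1", "rs2", "rs3"],
            np.array(
                [
                    [1.0, 0.95, 0.85, 0.1],
                    [0.95, 1.0, 0.8, 0.1],
                    [0.85, 0.8, 1.0, 0.1],
                    [0.1, 0.1, 0.1, 1.0],
                ]
            ),
        )
        assert find_proxy("target", out, ld) == "rs1"

    def test_below_threshold_none(self):
        out = self._outcome()
        ld = LDMatrix(["target", "rs1"], np.array([[1.0, 0.7], [0.7, 1.0]]))
        assert find_proxy("target", out, ld) is None

    def test_tie_broken_by_position(self):
        out = self._outcome()  # rs1 at 1_000_000, rs2 at 1_100_000
        ld = LDMatrix(
            ["target", "rs1", "rs2"],
            np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.5], [0.9, 0.5, 1.0]]),
        )
        assert find_proxy("target", out, ld) == "rs1"

    def test_target_present_is_misuse(self):
        out = self._outcome()
        ld = LDMatrix(["rs1"], np.ones((1, 1)))
        with pytest.raises(ValueError, match="present"):
            find_proxy("rs1", out, ld)


class TestHarmonize:
    def test_swapped_alleles_flip_beta(self):
        exp = SummaryStats("e", [make_assoc(ea="A", oa="G", beta=0.10)])
        out = SummaryStats("o", [make_assoc(ea="G", oa="A", beta=-0.05, eaf=0.7)])
        h = harmonize(exp, out)
        assert h.action == ["flipped"]
        assert h.beta_out[0] == pytest.approx(0.05)

    def test_idempotent_when_aligned(self):
        exp = SummaryStats("e", [make_assoc(ea="A", oa="G", beta=0.10)])
        out = SummaryStats("o", [make_assoc(ea="A", oa="G", beta=-0.05)])
        h1 = harmonize(exp, out)
        h2 = harmonize(exp, out)
        assert h1.action == ["aligned"] == h2.action
        assert h1.beta_out[0] == h2.beta_out[0] == -0.05

    def test_ambiguous_palindromic_dropped(self):
        exp = SummaryStats("e", [make_assoc(ea="A", oa="T", eaf=0.3)])
        out = SummaryStats("o", [make_assoc(ea="A", oa="T", eaf=0.50)])
        with pytest.raises(Exception):
            harmonize(exp, out)  # only variant dropped -> empty-harmonization error

    def test_unambiguous_palindromic_oriented_by_eaf(self):
        exp = SummaryStats("e", [make_assoc(ea="A", oa="T", eaf=0.1, beta=0.2)])
        # outcome reports the complementary strand: eaf on the other side of 0.5
        out = SummaryStats("o", [make_assoc(ea="A", oa="T", eaf=0.9, beta=0.3)])
        h = harmonize(exp, out)
        assert h.action == ["flipped"]
        assert h.beta_out[0] == pytest.approx(-0.3)

    def test_allele_mismatch_dropped(self):
        exp = SummaryStats(
            "e", [make_assoc("rs1", ea="A", oa="G"), make_assoc("rs2", pos=2_000_000, ea="A", oa="G")]
        )
        out = SummaryStats(
            "o", [make_assoc("rs1", ea="A", oa="C"), make_assoc("rs2", pos=2_000_000, ea="A", oa="G")]
        )
        h = harmonize(exp, out)
        assert h.variant_ids == ["rs2"]
        assert ("rs1", "allele_mismatch") in h.dropped

    def test_orientation_invariance(self):
        """Pre-flipping an outcome record's alleles+beta leaves the result unchanged."""
        exp = SummaryStats("e", [make_assoc(ea="A", oa="G", beta=0.10)])
        out1 = SummaryStats("o", [make_assoc(ea="A", oa="G", beta=0.05, eaf=0.3)])
        out2 = SummaryStats("o", [out1.associations[0].flipped()])
        h1, h2 = harmonize(exp, out1), harmonize(exp, out2)
        assert h1.beta_out[0] == pytest.approx(h2.beta_out[0])
        assert h1.se_out[0] == h2.se_out[0]


class TestSelectAndHarmonize:
    def test_proxy_substitution(self):
        exp = make_sumstats([0.3], ses=[0.01], eaf=0.3, name="prot")
        # outcome lacks rs1 but carries a strong proxy
        out = SummaryStats("o", [make_assoc("rsP", pos=1_050_000, beta=0.02, se=0.01, eaf=0.3)])
        ld = LDMatrix(["rs1", "rsP"], np.array([[1.0, 0.95], [0.95, 1.0]]))
        records, h = select_and_harmonize(exp, out, ld=ld, p_max=1.0)
        assert records[0].status == "proxied"
        assert records[0].proxy_for == "rsP"
        assert h.beta_out[0] == pytest.approx(0.02)

    def test_no_instruments_raises(self):
        exp = make_sumstats([0.001], ses=[0.01], eaf=0.3)  # F << 10
        out = make_sumstats([0.01], ses=[0.01], name="o")
        with pytest.raises(Exception, match="no instruments"):
            select_and_harmonize(exp, out, p_max=1.0)


class TestHarmonizedSet:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            HarmonizedSet.from_arrays([0.1, 0.2], 0.01, [0.1, 0.2], 0.01, variant_ids=["a", "a"])

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            HarmonizedSet.from_arrays([0.1], 0.0, [0.1], 0.01)

    def test_subset_preserves_alignment(self, ratio_set):
        sub = ratio_set.subset(np.array([0, 2]))
        assert sub.variant_ids == ["v1", "v3"]
        np.testing.assert_allclose(sub.beta_out, [0.1, 0.3])
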