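"""Lipid parsing, normalization, moderated t, BH-FDR and enrichment."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from mitomorph.errors import DomainError, FormatError
from mitomorph.omics import (
    _enrichment_scores,
    bh_adjust,
    de_filter,
    dedupe_features,
    derive_lipid_sets,
    lsea,
    median_log2_normalize,
    moderated_t,
    parse_lipid_name,
)
from mitomorph.synthetic import make_lipidome


class TestParseLipidName:
    def test_two_chain_species(self):
        sp = parse_lipid_name("PC 16:0/18:1")
        assert sp.lipid_class == "PC"
        assert sp.chains == ((16, 0), (18, 1))
        assert (sp.total_carbons, sp.total_double_bonds) == (34, 1)

    def test_triacylglycerol_three_chains(self):
        sp = parse_lipid_name("TG 16:0/18:1/18:2")
        assert len(sp.chains) == 3
        assert (sp.total_carbons, sp.total_double_bonds) == (52, 3)

    @pytest.mark.parametrize("bad", ["mystery lipid", "", "16:0/18:1", "PC 16.0"])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(FormatError):
            parse_lipid_name(bad)

    def test_generated_names_all_parse(self):
        mat, _, _ = make_lipidome(seed=9)
        for name in mat.index:
            parse_lipid_name(name)


class TestDedupe:
    def test_keeps_highest_total_reading(self):
        m = pd.DataFrame(
            [[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]],
            index=["PC 16:0/18:1", "PC 16:0/18:1", "PE 16:0/18:1"],
            columns=["s1", "s2"],
        )
        out = dedupe_features(m)
        assert len(out) == 2
        assert out.loc["PC 16:0/18:1", "s1"] == 5.0


class TestMedianLog2Normalize:
    def test_reference_median_maps_to_zero(self):
        m = pd.DataFrame(
            {"y1": [2.0], "y2": [4.0], "y3": [8.0], "a1": [8.0]},
            index=["PC 16:0/18:1"],
        )
        groups = pd.Series({"y1": "young", "y2": "young", "y3": "young", "a1": "aged"})
        out = median_log2_normalize(m, groups)
        assert out.loc["PC 16:0/18:1", "a1"] == pytest.approx(1.0)  # log2(8/4)
        assert out.loc["PC 16:0/18:1", "y2"] == pytest.approx(0.0)

    def test_young_samples_center_at_zero_per_feature(self):
        # odd reference-group size: the median is an observed sample, so the
        # transformed reference median is exactly 0 per feature
        mat, groups, _ = make_lipidome(n_per_group=3, seed=2)
        out = median_log2_normalize(mat, groups)
        young = out.loc[:, groups == "young"]
        np.testing.assert_allclose(young.median(axis=1), 0.0, atol=1e-12)

    def test_nonpositive_median_feature_dropped_with_warning(self):
        m = pd.DataFrame({"y1": [0.0, 2.0], "y2": [0.0, 2.0], "a1": [1.0, 4.0]},
                         index=["bad", "good"])
        groups = pd.Series({"y1": "young", "y2": "young", "a1": "aged"})
        with pytest.warns(UserWarning):
            out = median_log2_normalize(m, groups)
        assert list(out.index) == ["good"]


class TestModeratedT:
    def test_d0_zero_is_ordinary_t(self):
        mat, groups, _ = make_lipidome(seed=4)
        lm = np.log2(mat)
        res = moderated_t(lm, groups, d0=0)
        a = lm.loc[:, groups == "young"].to_numpy()
        b = lm.loc[:, groups == "aged"].to_numpy()
        t_ref, p_ref = sps.ttest_ind(b, a, axis=1)
        np.testing.assert_allclose(res["t"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, rtol=1e-10)

    def test_d0_infinite_is_pooled_variance_z(self):
        mat, groups, _ = make_lipidome(seed=4)
        res = moderated_t(np.log2(mat), groups, d0=np.inf)
        s0 = np.sqrt(res.attrs["s0_sq"] * (1 / 4 + 1 / 4))
        z_ref = res["log_fc"] / s0
        np.testing.assert_allclose(res["t"], z_ref, rtol=1e-10)

    def test_shrinkage_converges_to_known_variance_z_with_more_features(self):
        """With one shared true variance, the moderated t approaches the
        statistic computed with the known variance as the prior is estimated
        from more features (averaged over replicate simulations)."""
        rng = np.random.default_rng(0)
        gaps = []
        for n_feat in (20, 500):
            reps = []
            for _ in range(10):
                data = rng.normal(0, 1.0, size=(n_feat, 8))
                mat = pd.DataFrame(
                    data,
                    index=[f"f{i}" for i in range(n_feat)],
                    columns=[f"s{j}" for j in range(8)],
                )
                groups = pd.Series(["young"] * 4 + ["aged"] * 4, index=mat.columns)
                res = moderated_t(mat, groups)
                z_true = res["log_fc"] / np.sqrt(1.0 * (1 / 4 + 1 / 4))
                reps.append(np.mean(np.abs(res["t"] - z_true)))
            gaps.append(np.mean(reps))
        assert gaps[1] < gaps[0]

    def test_null_type_one_error_calibrated(self):
        """No group effect: about 5% of raw p-values fall below 0.05."""
        rates = []
        for seed in range(30):
            mat, groups, _ = make_lipidome(
                class_sizes={"PC": 50, "PE": 50, "TG": 50, "Cer": 50}, seed=seed
            )
            res = moderated_t(np.log2(mat), groups)
            rates.append((res["p"] <= 0.05).mean())
        assert 0.03 <= np.mean(rates) <= 0.07


class TestBhAdjust:
    def test_closed_form_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_direct_formula_oracle(self, pvals):
        ours = bh_adjust(pvals)
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="stable")
        oracle = np.empty(m)
        running = np.inf
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            running = min(running, p[i] * m / (rank_from_top + 1))
            oracle[i] = min(running, 1.0)
        np.testing.assert_allclose(ours, oracle, rtol=1e-12)
        # idempotent and >= raw p
        np.testing.assert_allclose(bh_adjust(ours), bh_adjust(ours), rtol=0)
        assert (ours >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])


class TestDeFilter:
    def test_thresholds(self):
        res = pd.DataFrame(
            {"log_fc": [1.5, 0.5, 2.0], "adj_p": [0.01, 0.01, 0.2]},
            index=["keep", "small_fc", "big_p"],
        )
        assert list(de_filter(res)) == ["keep"]


class TestLsea:
    def test_set_of_all_features_scores_zero(self):
        w = np.array([3.0, 2.0, 1.0, 0.5])
        assert _enrichment_scores(w, np.ones(4, dtype=bool))[0] == 0.0

    def test_top_ranked_set_is_extremal_and_p_matches_enumeration(self):
        fc = np.array([3, 2.5, 2, 1.5, 1, 0.75, 0.5, 0.25])
        names = [f"PC {i + 30}:0/2:0" for i in range(8)]
        res = pd.DataFrame({"log_fc": fc}, index=names)
        ind_top = np.zeros(8, dtype=bool)
        ind_top[:4] = True
        es_top = _enrichment_scores(fc, ind_top)[0]
        devs = []
        for pick in itertools.combinations(range(8), 4):
            ind = np.zeros(8, dtype=bool)
            ind[list(pick)] = True
            devs.append(abs(_enrichment_scores(fc, ind)[0]))
        assert abs(es_top) == pytest.approx(max(devs), rel=1e-12)
        enum_p = np.mean([d >= abs(es_top) - 1e-12 for d in devs])
        enr = lsea(res, sets={"top": names[:4]}, n_perm=40_000, seed=3)
        assert enr["p"].iloc[0] == pytest.approx(enum_p, abs=0.005)

    def test_deterministic_given_seed_and_stable_across_seeds(self):
        mat, groups, _ = make_lipidome(shifted_classes={"TG": 1.5}, seed=6)
        res = moderated_t(np.log2(mat), groups)
        a = lsea(res, n_perm=3000, seed=42)
        b = lsea(res, n_perm=3000, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = lsea(res, n_perm=3000, seed=43)
        tested = a["tested"].to_numpy()
        assert np.allclose(a.loc[tested, "p"], c.loc[tested, "p"], atol=0.05)

    def test_small_sets_reported_untested(self):
        mat, groups, _ = make_lipidome(class_sizes={"PC": 8, "MG": 2}, seed=8)
        res = moderated_t(np.log2(mat), groups)
        enr = lsea(res, n_perm=200, seed=0)
        mg = enr[enr["set"] == "class:MG"]
        assert not mg.empty and not mg["tested"].iloc[0]

    def test_shifted_class_detected_as_top_set(self):
        hits = 0
        for seed in range(25):
            mat, groups, _ = make_lipidome(shifted_classes={"Cer": 2.0}, seed=seed)
            res = moderated_t(np.log2(mat), groups)
            enr = lsea(res, n_perm=1000, seed=seed)
            tested = enr[enr["tested"]].sort_values("p", kind="stable")
            row = enr[enr["set"] == "class:Cer"].iloc[0]
            hits += (tested.iloc[0]["set"] == "class:Cer") and (row["adj_p"] < 0.05)
        assert hits / 25 >= 0.95

    def test_null_data_rarely_enriched(self):
        clean = 0
        for seed in range(20):
            mat, groups, _ = make_lipidome(seed=1000 + seed)
            res = moderated_t(np.log2(mat), groups)
            enr = lsea(res, n_perm=500, seed=seed)
            adj = enr.loc[enr["tested"], "adj_p"]
            clean += (adj >= 0.05).all()
        assert clean / 20 >= 0.8


class TestDeriveSets:
    def test_class_and_chain_length_sets(self):
        sets = derive_lipid_sets(["PC 16:0/18:1", "PC 18:0/18:1", "TG 16:0/18:1/18:2"])
        assert sets["class:PC"] == ["PC 16:0/18:1", "PC 18:0/18:1"]
        assert "chain_length:34" in sets and "chain_length:52" in sets

    def test_unparseable_names_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            sets = derive_lipid_sets(["PC 16:0/18:1", "what is this"])
        assert sum(len(v) for v in sets.values()) == 2
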