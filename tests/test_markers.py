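import numpy as np
import pandas as pd
import pytest

from cuephylo import markers as mk
from cuephylo import phylocomp as pc
from cuephylo import synthetic_data as sd


class TestDensity:
    def test_counts_per_mbp(self):
        counts = pd.DataFrame({"K1": [10, 4], "genome_size": [5.0, 2.0]},
                              index=["a", "b"])
        dens = mk.standardize_density(counts)
        assert dens.loc["a", "K1"] == pytest.approx(2.0)
        assert dens.loc["b", "K1"] == pytest.approx(2.0)

    def test_zero_counts_and_linearity(self):
        counts = pd.DataFrame({"K1": [0, 6]}, index=["a", "b"])
        sizes = pd.Series([3.0, 3.0], index=["a", "b"])
        dens = mk.standardize_density(counts, sizes)
        assert dens.loc["a", "K1"] == 0.0
        doubled = mk.standardize_density(counts, 2 * sizes)
        assert np.allclose(doubled.to_numpy(), dens.to_numpy() / 2)

    def test_zero_genome_size_rejected(self):
        counts = pd.DataFrame({"K1": [1]}, index=["a"])
        with pytest.raises(ValueError):
            mk.standardize_density(counts, pd.Series([0.0], index=["a"]))


class TestPrevalence:
    def test_rare_feature_removed(self):
        table = pd.DataFrame({"rare": [1, 1] + [0] * 11,
                              "common": [1] * 13})
        kept = mk.prevalence_filter(table, min_prevalence=4)
        assert list(kept.columns) == ["common"]

    def test_min_one_is_identity_except_allzero(self):
        table = pd.DataFrame({"zero": [0, 0], "one": [0, 2]})
        kept = mk.prevalence_filter(table, min_prevalence=1)
        assert list(kept.columns) == ["one"]


@pytest.fixture(scope="module")
def planted():
    tree = sd.simulate_tree(sd.TreeSimParams(n_tips=13, seed=21))
    params = sd.GenomeSimParams(n_kos=60, n_causal=1, effect_size=0.12,
                                cue_noise_sigma2=0.0005, seed=22)
    features, cue, causal = sd.simulate_genomes(tree, params)
    dens = mk.standardize_density(features)
    return tree, dens, cue, causal, features


class TestExplore:
    def test_planted_marker_detected_with_correct_sign(self, planted):
        tree, dens, cue, causal, _ = planted
        cands = mk.explore_markers(tree, cue, dens, list(dens.index), alpha=0.05)
        row = cands.loc[causal[0]]
        assert row["candidate"]
        assert row["direction"] > 0

    def test_rare_features_never_tested(self, planted):
        tree, dens, cue, _, _ = planted
        dens = dens.copy()
        dens["K_rare"] = 0.0
        dens.iloc[0, dens.columns.get_loc("K_rare")] = 1.0
        cands = mk.explore_markers(tree, cue, dens, list(dens.index),
                                   min_prevalence=4)
        assert "K_rare" not in cands.index

    def test_too_few_taxa_rejected(self, planted):
        tree, dens, cue, _, _ = planted
        with pytest.raises(ValueError):
            mk.explore_markers(tree, cue, dens, list(dens.index)[:5])


def _candidate_frame(direction=1.0):
    return pd.DataFrame({
        "slope_explore": [0.1 * direction],
        "p_explore": [0.01],
        "direction": [direction],
        "candidate": [True],
    }, index=["K1"])


class TestSubstrateValidation:
    def _scan_inputs(self, slopes, ps, seed=5):
        tree = sd.simulate_tree(sd.TreeSimParams(n_tips=10, seed=seed))
        V, labels = pc.vcv_matrix(tree)
        rng = np.random.default_rng(seed)
        dens = pd.DataFrame({"K1": rng.uniform(1, 3, 10)}, index=labels)
        cues = {}
        for i, (sl, p_target) in enumerate(zip(slopes, ps)):
            noise_sd = 0.001 if p_target < 0.05 else 10.0
            cues[f"s{i}"] = pd.Series(
                sl * dens["K1"] + rng.normal(0, noise_sd, 10), index=labels)
        return tree, dens, cues

    def test_two_of_three_same_direction_passes(self):
        tree, dens, cues = self._scan_inputs([0.2, 0.2, 0.0], [0.01, 0.01, 0.9])
        out = mk.validate_other_substrates(_candidate_frame(), cues, tree, dens)
        assert out.loc["K1", "validated_other_substrates"]

    def test_opposite_direction_fails(self):
        tree, dens, cues = self._scan_inputs([-0.2, -0.2, 0.0], [0.01, 0.01, 0.9])
        out = mk.validate_other_substrates(_candidate_frame(+1), cues, tree, dens)
        assert not out.loc["K1", "validated_other_substrates"]


class TestMicrocosmValidation:
    def test_monotone_feature_with_matching_sign_passes(self):
        comm = pd.DataFrame({"K1": np.arange(8.0), "cue": np.arange(8.0) * 0.1})
        out = mk.validate_microcosm(_candidate_frame(+1), comm)
        assert out.loc["K1", "microcosm_rho"] == pytest.approx(1.0)
        assert out.loc["K1", "validated_microcosm"]

    def test_opposite_sign_fails(self):
        comm = pd.DataFrame({"K1": np.arange(8.0)[::-1], "cue": np.arange(8.0) * 0.1})
        out = mk.validate_microcosm(_candidate_frame(+1), comm)
        assert not out.loc["K1", "validated_microcosm"]

    def test_constant_feature_fails_with_nan(self):
        comm = pd.DataFrame({"K1": np.ones(8), "cue": np.arange(8.0)})
        out = mk.validate_microcosm(_candidate_frame(+1), comm)
        assert np.isnan(out.loc["K1", "microcosm_rho"])
        assert not out.loc["K1", "validated_microcosm"]

    def test_too_few_communities_rejected(self):
        comm = pd.DataFrame({"K1": np.ones(3), "cue": np.arange(3.0)})
        with pytest.raises(ValueError):
            mk.validate_microcosm(_candidate_frame(), comm)


class TestFinalize:
    def test_exploration_only_candidate_not_finalized(self, planted):
        tree, dens, cue, causal, _ = planted
        cands = mk.explore_markers(tree, cue, dens, list(dens.index))
        cands = cands[cands["candidate"]].copy()
        # no validation stages run: all validation flags default to False
        final, report = mk.finalize_markers(cands, tree, cue, dens)
        assert report.n_final == 0

    def test_planted_marker_present_everywhere_is_finalized(self, planted):
        tree, dens, cue, causal, features = planted
        params = sd.GenomeSimParams(n_kos=60, n_causal=1, effect_size=0.12, seed=22)
        cands = mk.explore_markers(tree, cue, dens, list(dens.index))
        cands = cands[cands["candidate"]].copy()
        subs = sd.simulate_substrate_cues(tree, features, causal, params,
                                          ["s1", "s2", "s3"], seed=31)
        cands = mk.validate_other_substrates(cands, subs, tree, dens)
        comm = sd.simulate_communities(12, list(dens.columns), causal,
                                       effect_size=1.0, noise_sd=0.05, seed=32)
        cands = mk.validate_microcosm(cands, comm)
        final, report = mk.finalize_markers(cands, tree, cue, dens,
                                            residual_seed=33)
        assert final.loc[causal[0], "final"]

    def test_venn_counts_partition_candidates(self, planted):
        tree, dens, cue, causal, _ = planted
        cands = mk.explore_markers(tree, cue, dens, list(dens.index))
        cands = cands[cands["candidate"]].copy()
        final, report = mk.finalize_markers(cands, tree, cue, dens)
        assert report.region_counts().sum() == report.n_explore
        assert int(report.overlap["full_glucose"].sum()) == report.n_full_glucose


class TestAPrioriHypotheses:
    def _traits(self, yule_tree):
        V, labels = pc.vcv_matrix(yule_tree)
        rng = np.random.default_rng(8)
        growth = rng.uniform(0.1, 0.6, len(labels))
        return pd.DataFrame({
            "cue": 0.3 + 0.5 * growth + rng.normal(0, 0.02, len(labels)),
            "max_growth_rate": growth,
            "rrN": 2 ** rng.integers(0, 4, len(labels)),
            "constant": 1.0,
        }, index=labels)

    def test_positive_association_recovered(self, yule16):
        table = mk.test_a_priori_hypotheses(
            yule16, self._traits(yule16), [("cue", "max_growth_rate")])
        row = table.iloc[0]
        assert row["slope"] > 0 and row["p"] < 0.05

    def test_log2_reparameterisation_is_consistent(self, yule16):
        traits = self._traits(yule16)
        table = mk.test_a_priori_hypotheses(
            yule16, traits, [("cue", "log2_rrN")])
        traits2 = traits.assign(log2_rrN=np.log2(traits["rrN"]))
        direct = mk.test_a_priori_hypotheses(
            yule16, traits2, [("cue", "log2_rrN")])
        assert table.iloc[0]["slope"] == pytest.approx(direct.iloc[0]["slope"])

    def test_degenerate_and_missing_predictors_reported(self, yule16):
        table = mk.test_a_priori_hypotheses(
            yule16, self._traits(yule16),
            [("cue", "constant"), ("cue", "absent_column")])
        assert "constant predictor" in table.iloc[0]["note"]
        assert "missing" in table.iloc[1]["note"]
        assert np.isnan(table.iloc[0]["slope"])
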