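import numpy as np
import pytest

from foldkspec import classifier, enrichment, seqio, spectrum, synthetic
from foldkspec.classifier import TrainedModel
from foldkspec.enrichment import (
    EnrichmentProfile,
    FeatureFilter,
    build_fragments,
    discover_false_features,
    eliminate,
    enrichment_scores,
    export_meme,
    parse_rendered,
    read_hit_table,
)
from foldkspec.seqio import Sequence


def _model(w, active_index=None):
    w = np.asarray(w, dtype=float)
    return TrainedModel(w=w, b=0.1, active_index=active_index, C=1.0,
                        seed=0, n_pos=1, n_neg=1)


def _vector(values, k=3, active_index=None):
    return spectrum.SpectrumVector("seq1", k, spectrum.NORMALIZED, spectrum.FULL,
                                   np.asarray(values, float), active_index=active_index)


class TestEnrichmentScores:
    def test_strict_cutoff_boundary(self):
        # 0.5 * 0.01 is exactly the double nearest 0.005, i.e. == cutoff
        profile = enrichment_scores(_model([0.5, -0.2]), _vector([0.01, 0.1]))
        assert np.allclose(profile.scores, [0.005, -0.02])
        assert len(profile.selected) == 0  # a score equal to the cutoff is not kept

    def test_above_cutoff_selected(self):
        profile = enrichment_scores(_model([0.2]), _vector([0.05]))
        assert np.allclose(profile.scores, [0.01])
        assert list(profile.selected) == [0]

    def test_scores_sum_to_decision_minus_bias(self):
        rng = np.random.default_rng(1)
        model = _model(rng.normal(size=20))
        x = _vector(rng.random(20))
        profile = enrichment_scores(model, x)
        assert profile.scores.sum() == pytest.approx(
            classifier.decision(model, x) - model.b
        )

    def test_index_mismatch_rejected(self):
        model = _model([1.0, 2.0], active_index=np.array([0, 1]))
        x = _vector([1.0, 2.0], active_index=np.array([0, 2]))
        with pytest.raises(ValueError):
            enrichment_scores(model, x)


class TestBuildFragments:
    def _profile(self, space, patterns, score=1.0):
        idx = np.array([space.feature_index(p) for p in patterns])
        return EnrichmentProfile("seq1", np.full(len(idx), score), idx, cutoff=0.005)

    def test_paper_worked_example(self, space3):
        frags = build_fragments(self._profile(space3, ["ANT", "TNT"]), space3)
        assert len(frags) == 1
        assert frags[0].render() == "(A/T)NT"
        assert frags[0].mask.decimal == 5

    def test_singleton_fragment(self, space3):
        frags = build_fragments(self._profile(space3, ["ANT"]), space3)
        assert frags[0].render() == "ANT"
        assert frags[0].counts[0].tolist() == [1, 0, 0, 0]

    def test_one_fragment_per_mask(self, space3):
        frags = build_fragments(self._profile(space3, ["ANT", "AAA", "TTT"]), space3)
        assert len(frags) == 2
        assert sorted(f.mask.decimal for f in frags) == [5, 7]

    def test_empty_profile_gives_no_fragments(self, space3):
        profile = EnrichmentProfile("s", np.array([0.0]), np.array([0]))
        assert build_fragments(profile, space3) == []

    def test_render_roundtrip(self, space3):
        frags = build_fragments(
            self._profile(space3, ["ANT", "TNT", "GNT"]), space3
        )
        sets = parse_rendered(frags[0].render())
        assert sets == [frozenset("AGT"), frozenset(), frozenset("T")]


class TestExportMeme:
    def test_probability_rows(self, space3, tmp_path):
        idx = np.array([space3.feature_index("ANT"), space3.feature_index("TNT")])
        profile = EnrichmentProfile("s1", np.ones(2), idx)
        frags = build_fragments(profile, space3)
        path = tmp_path / "frag.meme"
        export_meme(frags, path)
        text = path.read_text()
        assert "MEME version 4" in text
        block = text.split("letter-probability matrix")[1].splitlines()[1:4]
        rows = [list(map(float, line.split())) for line in block]
        assert rows[0] == [0.5, 0, 0, 0.5]
        assert rows[1] == [0.25, 0.25, 0.25, 0.25]
        assert rows[2] == [0, 0, 0, 1]

    def test_singleton_matrix(self, space3, tmp_path):
        idx = np.array([space3.feature_index("ANT")])
        frags = build_fragments(EnrichmentProfile("s1", np.ones(1), idx), space3)
        path = tmp_path / "one.meme"
        export_meme(frags, path)
        block = path.read_text().split("letter-probability matrix")[1].splitlines()[1:4]
        rows = [list(map(float, line.split())) for line in block]
        assert rows[0] == [1, 0, 0, 0]
        assert rows[2] == [0, 0, 0, 1]

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_meme([], tmp_path / "x.meme")


@pytest.fixture(scope="module")
def biased_positives():
    """A-rich positives whose composition alone drives enrichment."""
    rng = np.random.default_rng(9)
    seqs = []
    for i in range(8):
        residues = "".join(rng.choice(list("ACGT"), p=[0.7, 0.1, 0.1, 0.1], size=150))
        seqs.append(Sequence(f"pos{i}", residues, label=1))
    return seqs


class TestDiscoverFalseFeatures:
    def test_huge_cutoff_gives_empty_false_set(self, space3, biased_positives):
        filt = discover_false_features(
            biased_positives, space3, n_scrambles=2, cutoff=1e9, seed=0
        )
        assert set(filt.false_models_by_parent) == {s.id for s in biased_positives}
        assert all(not v for v in filt.false_models_by_parent.values())
        assert all(not v for v in filt.by_copy.values())

    def test_composition_driven_features_flagged(self, space3, biased_positives):
        # A-rich scrambles keep the bias, so A-dominated features enrich in
        # the scrambled-positive training and must be flagged false.
        filt = discover_false_features(
            biased_positives, space3, n_scrambles=3, seed=0
        )
        implicated = set().union(*filt.false_models_by_parent.values())
        assert implicated, "expected composition-driven false enrichments"
        flagged = set().union(*filt.by_copy.values())
        names = {space3.feature_name(n) for n in flagged}
        assert any(set(name) <= {"A", "N"} for name in names)

    def test_hit_table_marking_all_insignificant_empties_false_set(
        self, space3, biased_positives, tmp_path
    ):
        filt0 = discover_false_features(biased_positives, space3, n_scrambles=2, seed=0)
        frag_ids = set()
        for copy_id, selected in filt0.by_copy.items():
            for n in selected:
                frag_ids.add(f"{copy_id}|m{space3.model_of(int(n)).decimal}")
        assert frag_ids
        path = tmp_path / "hits.tsv"
        with open(path, "w") as fh:
            fh.write("fragment_id\tmotif_id\tp_value\n")
            for fid in sorted(frag_ids):
                fh.write(f"{fid}\tMA0000.1\t0.5\n")  # nothing significant
        filt = discover_false_features(
            biased_positives, space3, n_scrambles=2, seed=0,
            hits=read_hit_table(path),
        )
        assert all(not v for v in filt.by_copy.values())
        assert all(not v for v in filt.false_models_by_parent.values())

    def test_unknown_fragment_id_rejected(self, space3, biased_positives, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("fragment_id\tmotif_id\tp_value\nnope|m7\tMA0000.1\t1e-5\n")
        with pytest.raises(ValueError, match="unknown fragment"):
            discover_false_features(
                biased_positives, space3, n_scrambles=2, seed=0,
                hits=read_hit_table(path),
            )


class TestEliminate:
    def _profiles(self, space):
        i_aaa = space.feature_index("AAA")
        i_ant = space.feature_index("ANT")
        idx = np.array([i_aaa, i_ant])
        return [
            EnrichmentProfile("s1", np.array([0.02, 0.03]), idx),
            EnrichmentProfile("s2", np.array([0.04, 0.001]), idx),
        ]

    def test_empty_filter_is_identity(self, space3):
        profiles = self._profiles(space3)
        filtered, psi = eliminate(profiles, FeatureFilter.empty(), space3)
        for before, after in zip(profiles, filtered):
            assert np.array_equal(before.scores, after.scores)
        expected = set()
        for p in profiles:
            expected |= {int(n) for n in p.selected}
        assert set(psi.tolist()) == expected

    def test_by_model_zeroes_whole_contiguous_model(self, space3):
        profiles = self._profiles(space3)
        filt = FeatureFilter(
            by_copy={"s1_scr0": {space3.feature_index("TTT")}},
            parent_of_copy={"s1_scr0": "s1"},
            false_features_by_parent={"s1": {space3.feature_index("TTT")}, "s2": set()},
            false_models_by_parent={"s1": {7}, "s2": set()},
        )
        filtered, psi = eliminate(profiles, filt, space3, mode="by_model")
        # s1's contiguous-model feature AAA zeroed even though TTT was the flag
        assert filtered[0].scores[0] == 0
        assert filtered[0].scores[1] == pytest.approx(0.03)
        # s2 untouched
        assert np.array_equal(filtered[1].scores, profiles[1].scores)
        assert space3.feature_index("AAA") in psi  # survives via s2

    def test_by_feature_zeroes_exact_match_only(self, space3):
        profiles = self._profiles(space3)
        i_aaa = space3.feature_index("AAA")
        filt = FeatureFilter(
            by_copy={"s1_scr0": {i_aaa}},
            parent_of_copy={"s1_scr0": "s1"},
            false_features_by_parent={"s1": {i_aaa}, "s2": set()},
            false_models_by_parent={"s1": {7}, "s2": set()},
        )
        filtered, _ = eliminate(profiles, filt, space3, mode="by_feature")
        assert filtered[0].scores[0] == 0
        assert filtered[0].scores[1] == pytest.approx(0.03)

    def test_by_model_is_refinement_of_by_feature(self, space3):
        profiles = self._profiles(space3)
        i_aaa = space3.feature_index("AAA")
        filt = FeatureFilter(
            by_copy={"s1_scr0": {i_aaa}},
            parent_of_copy={"s1_scr0": "s1"},
            false_features_by_parent={"s1": {i_aaa}, "s2": set()},
            false_models_by_parent={"s1": {7}, "s2": set()},
        )
        _, psi_model = eliminate(profiles, filt, space3, mode="by_model")
        _, psi_feature = eliminate(profiles, filt, space3, mode="by_feature")
        assert set(psi_model.tolist()) <= set(psi_feature.tolist())

    def test_monotone_in_false_set(self, space3):
        profiles = self._profiles(space3)
        small = FeatureFilter(
            false_features_by_parent={"s1": set(), "s2": set()},
            false_models_by_parent={"s1": {5}, "s2": set()},
        )
        large = FeatureFilter(
            false_features_by_parent={"s1": set(), "s2": set()},
            false_models_by_parent={"s1": {5, 7}, "s2": {7}},
        )
        _, psi_small = eliminate(profiles, small, space3)
        _, psi_large = eliminate(profiles, large, space3)
        assert set(psi_large.tolist()) <= set(psi_small.tolist())

    def test_positive_missing_from_filter_rejected(self, space3):
        profiles = self._profiles(space3)
        filt = FeatureFilter(
            false_features_by_parent={"s1": set()},
            false_models_by_parent={"s1": {7}},
        )
        with pytest.raises(ValueError, match="s2"):
            eliminate(profiles, filt, space3)
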