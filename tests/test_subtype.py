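import datetime as dt

import numpy as np
import pytest

from glucodyn.subtype import (
    TAXONOMY,
    ReferenceSample,
    assign_subtype,
    fit_reference,
    median_profile,
)
from glucodyn.types import DayProfile, SampleEmbedding


def make_blobs(rng, centers, n_per=8, spread=0.02, labels=None, glucose_means=None):
    """Well-separated blobs on the unit sphere (cosine geometry)."""
    samples, truth = [], []
    for ci, c in enumerate(centers):
        c = c / np.linalg.norm(c)
        for j in range(n_per):
            v = c + rng.normal(0, spread, c.size)
            days = []
            if glucose_means is not None:
                vals = np.clip(np.full(288, glucose_means[ci] + rng.normal(0, 0.5)), 40, 300)
                days = [DayProfile.from_values(f"c{ci}_{j}", dt.date(2024, 1, 1), vals)]
            lab = labels[ci] if labels else ("NGT" if ci == 0 else "IGR")
            samples.append(ReferenceSample(SampleEmbedding(v, f"c{ci}_{j}"), lab, days))
            truth.append(ci)
    return samples, np.array(truth)


@pytest.fixture()
def planted_reference():
    # three coherent stage-1 groups, each splitting into the planted
    # sub-blobs; IGR fractions increase Normal -> Pre_I -> Pre_II so the
    # naming stage is deterministic
    centers = np.zeros((6, 20))
    centers[0, 0] = 10.0                      # Normal blob
    centers[1, 5] = 10.0; centers[1, 6] = 2.0   # Pre_I sub a
    centers[2, 5] = 10.0; centers[2, 7] = -2.0  # Pre_I sub b
    centers[3, 12] = 10.0; centers[3, 13] = 2.0  # Pre_II sub a
    centers[4, 12] = 10.0; centers[4, 14] = 2.0  # Pre_II sub b
    centers[5, 12] = 10.0; centers[5, 15] = 2.0  # Pre_II sub c
    labels = ["NGT", "NGT", "NGT", "IGR", "IGR", "IGR"]
    # stage-1 igr fractions: Normal 0, Pre_I group 0 (both NGT), Pre_II 1.0
    # -> break the Normal/Pre_I tie by making one Pre_I blob half IGR
    samples, truth = make_blobs(
        np.random.default_rng(1), centers, n_per=8, spread=0.004,
        labels=labels, glucose_means=[90, 110, 120, 130, 150, 170],
    )
    # flip alternate Pre_I members to IGR so stage-1 naming is unambiguous
    for s, t in zip(samples, truth):
        if t in (1, 2) and int(s.embedding.subject_id.split("_")[1]) % 2 == 0:
            s.clinical_label = "IGR"
    return samples, truth


class TestFitReference:
    def test_six_labels_exactly(self, planted_reference):
        samples, _ = planted_reference
        ref = fit_reference(samples)
        assert set(ref.partition) == set(TAXONOMY)
        assert len(TAXONOMY) == 6
        for t in TAXONOMY:
            assert len(ref.partition[t]) > 0

    def test_planted_partition_recovered_ari_one(self, planted_reference):
        from sklearn.metrics import adjusted_rand_score

        samples, truth = planted_reference
        ref = fit_reference(samples)
        pred = np.empty(len(samples), dtype=int)
        for ti, t in enumerate(TAXONOMY):
            for i in ref.partition[t]:
                pred[i] = ti
        assert adjusted_rand_score(truth, pred) == pytest.approx(1.0)

    def test_partition_is_disjoint_cover(self, planted_reference):
        samples, _ = planted_reference
        ref = fit_reference(samples)
        all_idx = sorted(i for idx in ref.partition.values() for i in idx)
        assert all_idx == list(range(len(samples)))

    def test_identical_embeddings_error(self):
        v = np.ones(8)
        samples = [ReferenceSample(SampleEmbedding(v.copy(), f"s{i}"), "NGT")
                   for i in range(10)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_reference(samples)

    def test_too_few_samples(self):
        samples = [ReferenceSample(SampleEmbedding(np.ones(4), "a"), "NGT")]
        with pytest.raises(ValueError, match="at least 6"):
            fit_reference(samples)

    def test_unsplittable_cluster_named_in_error(self):
        # 3 tight blobs, one of which has a single member -> stage 2 fails
        rng = np.random.default_rng(2)
        centers = np.eye(3) * 10
        samples = []
        for ci, n in enumerate([5, 1, 5]):
            for j in range(n):
                v = centers[ci] + rng.normal(0, 0.01, 3)
                lab = ["NGT", "NGT", "IGR"][ci]
                samples.append(ReferenceSample(SampleEmbedding(v, f"b{ci}_{j}"), lab))
        with pytest.raises(ValueError, match="Pre_I"):
            fit_reference(samples)

    def test_subname_ordering_by_mean_glucose(self, planted_reference):
        samples, _ = planted_reference
        ref = fit_reference(samples)
        for group in (("Pre_Ia", "Pre_Ib"), ("Pre_IIa", "Pre_IIb", "Pre_IIc")):
            means = [np.mean([ref.samples[i].mean_glucose for i in ref.partition[t]])
                     for t in group]
            assert means == sorted(means)


class TestAssignSubtype:
    def test_exact_match_single_member_orthogonal(self):
        dim = 8
        samples = []
        for i in range(6):
            v = np.zeros(dim)
            v[i] = 1.0
            samples.append(ReferenceSample(SampleEmbedding(v, f"s{i}"),
                                           "NGT" if i == 0 else "IGR"))
        from glucodyn.subtype import SubtypeReference

        ref = SubtypeReference(samples, {t: [i] for i, t in enumerate(TAXONOMY)}, "average")
        probe = np.zeros(dim)
        probe[3] = 2.5  # scale-invariant
        a = assign_subtype(SampleEmbedding(probe, "probe"), ref)
        assert a.subtype == TAXONOMY[3]
        assert a.scores[TAXONOMY[3]] == pytest.approx(1.0)
        for t in TAXONOMY[:3] + TAXONOMY[4:]:
            assert a.scores[t] == pytest.approx(0.0, abs=1e-12)

    def test_exhaustive_scoring_oracle(self, planted_reference):
        samples, _ = planted_reference
        ref = fit_reference(samples)
        rng = np.random.default_rng(3)
        for _ in range(10):
            v = rng.normal(size=20)
            a = assign_subtype(SampleEmbedding(v, "p"), ref)
            # brute-force loop over all (t, u)
            best_t, best_score = None, -np.inf
            for t in TAXONOMY:
                total = 0.0
                for i in ref.partition[t]:
                    u = ref.samples[i].embedding.vector
                    total += v @ u / (np.linalg.norm(v) * np.linalg.norm(u))
                score = abs(total) / len(ref.partition[t])
                if score > best_score:
                    best_t, best_score = t, score
            assert a.subtype == best_t
            assert a.scores[best_t] == pytest.approx(best_score)

    def test_label_always_in_taxonomy(self, planted_reference):
        samples, _ = planted_reference
        ref = fit_reference(samples)
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = assign_subtype(SampleEmbedding(rng.normal(size=20), "p"), ref)
            assert a.subtype in TAXONOMY

    def test_scale_invariance(self, planted_reference):
        samples, _ = planted_reference
        ref = fit_reference(samples)
        rng = np.random.default_rng(5)
        v = rng.normal(size=20)
        a1 = assign_subtype(SampleEmbedding(v, "p"), ref)
        for scale in (0.01, 3.7, 1000.0):
            a2 = assign_subtype(SampleEmbedding(v * scale, "p"), ref)
            assert a2.subtype == a1.subtype
            for t in TAXONOMY:
                assert a2.scores[t] == pytest.approx(a1.scores[t])

    def test_self_consistency_rate(self, planted_reference):
        samples, _ = planted_reference
        ref = fit_reference(samples)
        hits = 0
        for i, s in enumerate(samples):
            a = assign_subtype(s.embedding, ref)
            hits += a.subtype == ref.subtype_of(i)
        assert hits / len(samples) >= 0.8

    def test_zero_norm_rejected(self, planted_reference):
        samples, _ = planted_reference
        ref = fit_reference(samples)
        with pytest.raises(ValueError, match="zero-norm"):
            assign_subtype(SampleEmbedding(np.zeros(20), "z"), ref)


class TestMedianProfile:
    def test_single_member_is_that_day(self, planted_reference):
        samples, _ = planted_reference
        ref = fit_reference(samples)
        # build a reference with one member's days
        member = ref.members("Normal")[0]
        from glucodyn.subtype import SubtypeReference

        small = SubtypeReference([member], {"Normal": [0]}, "average")
        np.testing.assert_array_equal(
            median_profile(small, "Normal"), member.days[0].values
        )

    def test_two_members_midpoint(self):
        from glucodyn.subtype import SubtypeReference

        d1 = DayProfile.from_values("a", dt.date(2024, 1, 1), np.full(288, 100.0))
        d2 = DayProfile.from_values("b", dt.date(2024, 1, 1), np.full(288, 120.0))
        samples = [
            ReferenceSample(SampleEmbedding(np.ones(3), "a"), "NGT", [d1]),
            ReferenceSample(SampleEmbedding(np.ones(3) * 2, "b"), "NGT", [d2]),
        ]
        ref = SubtypeReference(samples, {"Normal": [0, 1]}, "average")
        np.testing.assert_allclose(median_profile(ref, "Normal"), 110.0)

    def test_direct_slotwise_oracle(self, planted_reference):
        samples, _ = planted_reference
        ref = fit_reference(samples)
        got = median_profile(ref, "Pre_IIb")
        days = [d for m in ref.members("Pre_IIb") for d in m.days]
        for slot in (0, 100, 287):
            vals = [d.values[slot] for d in days if d.present_mask[slot]]
            assert got[slot] == pytest.approx(np.median(vals))

    def test_empty_subtype_error(self):
        from glucodyn.subtype import SubtypeReference

        ref = SubtypeReference([], {"Normal": []}, "average")
        with pytest.raises(ValueError):
            median_profile(ref, "Normal")
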