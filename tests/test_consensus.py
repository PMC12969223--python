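"""k-means, consensus accumulation, PAC and model selection."""

import numpy as np
import pytest

import capdyn as cd
from capdyn.consensus import ConsensusResult
from capdyn.errors import DegenerateInputError, InputError


def test_separable_one_dimensional_clusters():
    frames = np.array([[0.], [0.], [0.], [10.], [10.], [10.]])
    caps = cd.kmeans_frames(frames, k=2, n_restarts=5, seed=0)
    assert caps.inertia == pytest.approx(0.0)
    assert sorted(caps.centroids.ravel()) == [0.0, 10.0]
    assert len(set(caps.assignments[:3])) == 1
    assert len(set(caps.assignments[3:])) == 1


def test_kmeans_matches_exhaustive_minimum_inertia_search():
    """Brute-force oracle: enumerate all 3^8 labelings of 8 frames and
    compare the partition and inertia of the best one with k-means."""
    from itertools import product
    rng = np.random.default_rng(12)
    X = rng.normal(size=(8, 2))
    best_inertia, best_labels = np.inf, None
    for labels in product(range(3), repeat=8):
        labels = np.array(labels)
        if len(set(labels.tolist())) < 3:
            continue
        inertia = sum(((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum()
                      for c in range(3))
        if inertia < best_inertia:
            best_inertia, best_labels = inertia, labels
    caps = cd.kmeans_frames(X, k=3, n_restarts=30, seed=1)
    assert caps.inertia == pytest.approx(best_inertia, rel=1e-9)
    assert {frozenset(np.flatnonzero(caps.assignments == c)) for c in range(3)} == \
           {frozenset(np.flatnonzero(best_labels == c)) for c in range(3)}


def test_centroids_are_member_means_and_sizes_conserve(small_frames):
    caps = cd.kmeans_frames(small_frames, k=5, n_restarts=2, seed=3)
    assert caps.cluster_sizes().sum() == small_frames.n_frames
    for c in range(caps.k):
        members = small_frames.data[caps.assignments == c]
        assert np.allclose(caps.centroids[c], members.mean(axis=0))


def test_degenerate_inputs_rejected():
    X = np.zeros((5, 3))
    with pytest.raises(DegenerateInputError):
        cd.kmeans_frames(X, k=2, seed=0)
    with pytest.raises(DegenerateInputError):
        cd.kmeans_frames(np.ones((2, 3)), k=3, seed=0)
    with pytest.raises(InputError):
        cd.kmeans_frames(np.ones((9, 3)), k=1, seed=0)


def test_pac_of_unambiguous_two_blob_data_is_zero():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.05, (20, 3)), rng.normal(8, 0.05, (20, 3))])
    res = cd.consensus_cluster(X, k_range=[2], n_runs=10, seed=0)
    assert res[0].pac == 0.0
    vals = res[0].consensus[np.triu_indices(40, 1)]
    vals = vals[~np.isnan(vals)]
    assert set(np.unique(vals)) <= {0.0, 1.0}


def test_pac_is_one_when_all_pairs_are_maximally_ambiguous():
    consensus = np.full((6, 6), 0.5)
    np.fill_diagonal(consensus, 1.0)
    assert cd.pac_from_consensus(consensus) == 1.0


def test_pac_thresholds_are_strict():
    consensus = np.full((4, 4), 0.1)
    np.fill_diagonal(consensus, 1.0)
    assert cd.pac_from_consensus(consensus) == 0.0
    consensus[consensus == 0.1] = 0.9
    assert cd.pac_from_consensus(consensus) == 0.0


def test_streaming_pac_matches_brute_force_pair_counting():
    """Oracle: store every run's label vector and count pairs directly."""
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 4)) + rng.integers(0, 3, size=30)[:, None] * 2.0
    res = cd.consensus_cluster(X, k_range=[3], n_runs=5, subsample_fraction=0.8,
                               seed=7, keep_runs=True)[0]
    n = 30
    co_sampled = np.zeros((n, n))
    co_assigned = np.zeros((n, n))
    for idx, labels in res.runs:
        for a in range(len(idx)):
            for b in range(len(idx)):
                i, j = idx[a], idx[b]
                co_sampled[i, j] += 1
                if labels[a] == labels[b]:
                    co_assigned[i, j] += 1
    lo, hi = 0.1, 0.9
    num = den = 0
    for i in range(n):
        for j in range(i + 1, n):
            if co_sampled[i, j] == 0:
                continue
            den += 1
            c = co_assigned[i, j] / co_sampled[i, j]
            if lo < c < hi:
                num += 1
    assert res.pac == pytest.approx(num / den)
    iu = np.triu_indices(n, 1)
    expected_undefined = int((co_sampled[iu] == 0).sum())
    assert res.n_undefined_pairs == expected_undefined


def test_pac_invariant_to_cluster_relabeling():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(25, 3)) + rng.integers(0, 2, size=25)[:, None] * 3
    res = cd.consensus_cluster(X, k_range=[2], n_runs=6, seed=2, keep_runs=True)[0]
    n = 25
    co_sampled = np.zeros((n, n), np.float32)
    co_assigned = np.zeros((n, n), np.float32)
    rng2 = np.random.default_rng(0)
    for idx, labels in res.runs:
        perm = rng2.permutation(2)
        labels = perm[labels]            # relabel clusters arbitrarily
        co_sampled[np.ix_(idx, idx)] += 1
        for c in range(2):
            m = idx[labels == c]
            co_assigned[np.ix_(m, m)] += 1
    with np.errstate(invalid="ignore"):
        consensus = co_assigned / co_sampled
    consensus[co_sampled == 0] = np.nan
    assert cd.pac_from_consensus(consensus) == pytest.approx(res.pac)


@pytest.mark.parametrize("pacs,expected", [
    ({4: 0.30, 5: 0.05, 6: 0.20}, 5),
    ({4: 0.10, 5: 0.10}, 4),           # tie broken toward smaller k
])
def test_select_k(pacs, expected):
    results = [ConsensusResult(k=k, consensus=np.empty(0), pac=p, n_runs=1,
                               subsample_fraction=0.8) for k, p in pacs.items()]
    assert cd.select_k(results) == expected


def test_finalize_reduces_to_single_restart_and_improves_inertia(small_frames):
    X = small_frames.data[:200]
    single = cd.finalize_caps(X, k=4, n_folds=1, seed=9)
    direct = cd.kmeans_frames(X, k=4, n_restarts=1, seed=9)
    assert np.array_equal(single.assignments, direct.assignments)
    assert single.inertia == pytest.approx(direct.inertia)
    many = cd.finalize_caps(X, k=4, n_folds=20, seed=9)
    assert many.inertia <= single.inertia + 1e-9


def test_pac_rises_with_observation_noise():
    """Median PAC at the true k must respond monotonically (non-strictly)
    to the generator's noise level."""
    medians = []
    for noise in (0.5, 1.5, 3.0):
        pacs = []
        for seed in range(10):
            cfg = cd.StudyConfig(seed=100 + seed, noise_sd=noise, n_subjects=4,
                                 frames_per_block=30, grid=(11, 11, 9))
            study = cd.simulate_study(cfg)
            fm = cd.extract_blocks(study.images, study.timing, study.mask_img)
            res = cd.consensus_cluster(fm, k_range=[5], n_runs=15, seed=seed)
            pacs.append(res[0].pac)
        medians.append(np.median(pacs))
    assert medians[0] <= medians[1] + 1e-12
    assert medians[1] <= medians[2] + 1e-12


def test_consensus_matrix_is_symmetric_with_unit_diagonal(small_frames):
    X = small_frames.data[:120]
    res = cd.consensus_cluster(X, k_range=[4], n_runs=8, seed=4)[0]
    c = res.consensus
    mask = ~np.isnan(c)
    assert np.allclose(c[mask], c.T[mask.T])
    diag = np.diag(c)
    assert np.allclose(diag[~np.isnan(diag)], 1.0)
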