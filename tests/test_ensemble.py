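"""Consensus machinery: Rand index, co-association, CSPA, stabilization."""

import numpy as np
import pytest

import erpconsensus as ec
from erpconsensus.clusterers import MethodParams
from erpconsensus.ensemble import (
    choose_k,
    coassociation,
    cspa,
    group_consensus,
    rand_index,
    select_methods,
    stabilize_method,
    subject_consensus,
)


def _pairwise_rand(a, b):
    """O(n^2) pair-enumeration oracle for the Rand index."""
    n = len(a)
    agree = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            together_a = a[i] == a[j]
            together_b = b[i] == b[j]
            agree += together_a == together_b
    return agree / total


def test_rand_index_examples():
    assert rand_index([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0  # relabeling
    assert rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(1 / 3)
    assert rand_index([1, 1], [1, 2]) == 0.0
    with pytest.raises(ValueError):
        rand_index([1, 2, 3], [1, 2])


@pytest.mark.parametrize("trial", range(10))
def test_rand_index_matches_pair_enumeration(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(5, 200))
    a = rng.integers(1, 6, size=n)
    b = rng.integers(1, 4, size=n)
    assert rand_index(a, b) == pytest.approx(_pairwise_rand(a, b))
    assert rand_index(a, b) == pytest.approx(rand_index(b, a))


def test_coassociation_single_partition_is_block_binary():
    ca = coassociation([np.array([1, 1, 2, 2, 2])])
    expected = np.array([1, 1, 0, 0, 0], dtype=float)
    np.testing.assert_array_equal(ca.matrix[0], expected)
    np.testing.assert_array_equal(np.diag(ca.matrix), np.ones(5))


def test_coassociation_counts_fractions():
    parts = [np.array([1, 1, 2]), np.array([1, 1, 1]), np.array([1, 2, 2])]
    ca = coassociation(parts)
    assert ca.matrix[0, 1] == pytest.approx(2 / 3)
    assert ca.matrix[0, 2] == pytest.approx(1 / 3)


def test_cspa_idempotent_on_unanimous_ensembles():
    L = np.array([1, 1, 1, 2, 2, 2, 3, 3])
    out = cspa([L, L, L, L], 3)
    assert rand_index(out.labels, L) == 1.0


def test_cspa_label_invariance():
    L = np.array([1, 1, 2, 2])
    flipped = np.array([2, 2, 1, 1])
    out = cspa([L, L, flipped], 2)
    assert rand_index(out.labels, L) == 1.0


def test_cspa_majority_structure_with_one_dissenter():
    majority = np.array([1, 1, 1, 2, 2, 2])
    dissent = np.array([1, 1, 2, 2, 2, 2])
    out = cspa([majority] * 4 + [dissent], 2)
    assert rand_index(out.labels, majority) == 1.0


def test_cspa_rejects_bad_k():
    with pytest.raises(ValueError):
        cspa([np.array([1, 2, 1])], 4)


def test_stabilize_deterministic_method_degenerates():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((30, 8))
    res = stabilize_method("aahc", X, 3, Mr=6, seed=0)
    assert all(v == pytest.approx(1.0) for v in res.R_series.values())
    assert res.r_opt == 3 and res.converged


def test_stabilize_impossible_threshold_does_not_converge(planted_blocks):
    X, _, _ = planted_blocks
    res = stabilize_method(MethodParams(method="kmeans", restarts=1), X, 3,
                           Mr=6, tau=1.01, seed=0)
    assert not res.converged
    assert res.r_opt == 6


def test_stabilized_consensus_is_reproducible_across_stabilizations(planted_blocks):
    """Separated data: two independent stabilizations agree almost exactly."""
    X, labels, _ = planted_blocks
    a = stabilize_method(MethodParams(method="kmeans", restarts=2), X, 3, Mr=8, seed=1)
    b = stabilize_method(MethodParams(method="kmeans", restarts=2), X, 3, Mr=8, seed=2)
    assert a.converged and b.converged
    assert rand_index(a.consensus, b.consensus) >= 0.95
    assert rand_index(a.consensus.labels, labels) == 1.0


def test_subject_consensus_single_method_passthrough(planted_blocks):
    X, labels, _ = planted_blocks
    single = subject_consensus(X, ["aahc"], 3, seed=0)
    direct = ec.run_base("aahc", X, 3)
    assert rand_index(single, direct) == 1.0


def test_subject_consensus_of_agreeing_methods(planted_blocks):
    X, labels, _ = planted_blocks
    part = subject_consensus(X, ["kmeans", "hierarchical_corr", "aahc"], 3, seed=0)
    assert rand_index(part.labels, labels) == 1.0


def test_group_consensus_majority_and_identity():
    L = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
    same = group_consensus([L] * 5, 3)
    assert rand_index(same.labels, L) == 1.0
    rng = np.random.default_rng(3)
    adversary = rng.integers(1, 4, size=L.size)
    mixed = group_consensus([L] * 5 + [adversary], 3)
    assert rand_index(mixed.labels, L) == 1.0


def test_select_methods_on_structured_study(small_study):
    """On clean block-structured data agreeing methods are selected."""
    report = select_methods(
        small_study, 7, ["hierarchical_corr", "aahc"], sim_threshold=0.8, seed=0, Mr=6
    )
    assert report.benchmark == "modified_kmeans"
    assert "modified_kmeans" in report.selected
    assert report.counts["aahc"] >= small_study.n_subjects // 2
    assert set(report.counts) == {"hierarchical_corr", "aahc"}


def test_choose_k_singleton_range(small_study):
    intervals = {"N2": (175.0, 292.0)}
    k, trace = choose_k(small_study, [7], intervals, ["aahc", "modified_kmeans"], seed=0)
    assert k == 7
    assert set(trace) == {7}
    assert 0.0 <= trace[7] <= 1.0
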