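"""Frequency tables, AMOVA F_ST, permutation testing, affinity filter and
the Mann-Whitney comparison."""

import numpy as np
import pandas as pd
import pytest

from helpers import amova_fst_bruteforce, mwu_exact_pvalue

from haplotrace.diversity import (
    FrequencyTable,
    build_frequency_table,
    find_sample_size,
    fst_matrix,
    fst_permutation_test,
    infer_counts_from_frequencies,
    lower_quartile_affinity,
    mann_whitney_u,
    pairwise_fst,
)
from haplotrace.errors import InputError, ReconstructionError


def _table(rows):
    return FrequencyTable(pd.DataFrame(rows).T)


# ------------------------------------------------------- frequency table --

def test_build_frequency_table_basic():
    t = build_frequency_table(
        [("s1", "A", "X"), ("s2", "A", "X"), ("s3", "A", "Y"), ("s4", "B", "Y")]
    )
    assert t.frequencies.loc["A", "X"] == pytest.approx(2 / 3)
    assert t.frequencies.loc["B", "X"] == 0  # zero-filled union
    assert t.n.to_dict() == {"A": 3, "B": 1}


def test_single_population_single_haplogroup():
    t = build_frequency_table([("s1", "A", "X")])
    assert t.frequencies.loc["A", "X"] == 1.0


def test_empty_assignments_rejected():
    with pytest.raises(InputError):
        build_frequency_table([])


def test_fixture_frequencies_match_printed_values(fixture_tables):
    y, mt = fixture_tables
    assert round(y.frequencies.loc["Maanyan", "C"], 4) == 0.5222
    assert round(mt.frequencies.loc["Bajo", "B4a1a1"], 4) == 0.0370


def test_pool_and_collapse():
    t = _table({"A": {"X": 2, "Y": 2}, "B": {"X": 1, "Y": 3}})
    pooled = t.pool(["A", "B"], "AB")
    assert pooled.counts.loc["AB"].to_dict() == {"X": 3, "Y": 5}
    collapsed = t.collapse({"Y": "X"})
    assert collapsed.counts.loc["A"].to_dict() == {"X": 4}


# -------------------------------------------------- count reconstruction --

def test_infer_counts_maanyan_column():
    freqs = pd.Series(
        {"C": 0.5222, "K-M526": 0.0222, "O1a": 0.0222, "O1a1": 0.1000,
         "O2a1": 0.0778, "O3": 0.0111, "O1a2": 0.0222, "O2a1a": 0.0111,
         "O3a2": 0.1778, "P": 0.0222, "R1a": 0.0111}
    )
    counts = infer_counts_from_frequencies(freqs, 90)
    assert counts.sum() == 90
    assert sorted(counts.values) == sorted([47, 2, 2, 9, 7, 1, 2, 1, 16, 2, 1])


def test_infer_counts_simple_and_error():
    assert list(infer_counts_from_frequencies([0.5, 0.5], 4)) == [2, 2]
    with pytest.raises(ReconstructionError):
        infer_counts_from_frequencies([0.3, 0.7], 7)


def test_find_sample_size_recovers_male_counts():
    lebbo = pd.Series([0.1333, 0.0667, 0.1333, 0.3333, 0.2667, 0.0667])
    assert find_sample_size(lebbo) == 15


# ------------------------------------------------------------------ F_ST --

def test_fst_fixed_cases():
    identical = _table({"A": {"X": 3, "Y": 1}, "B": {"X": 3, "Y": 1}})
    assert pairwise_fst(identical, "A", "B")[0] == 0.0
    assert pairwise_fst(identical, "A", "B")[1].fst_raw < 0  # raw kept

    disjoint = _table({"A": {"X": 5, "Y": 0}, "B": {"X": 0, "Y": 5}})
    assert pairwise_fst(disjoint, "A", "B")[0] == pytest.approx(1.0)

    worked = _table({"A": {"X": 3, "Y": 1}, "B": {"X": 1, "Y": 3}})
    fst, comp = pairwise_fst(worked, "A", "B")
    assert fst == pytest.approx(0.2, abs=1e-12)
    assert comp.ssd_among == pytest.approx(comp.ssd_total - comp.ssd_within)


def test_fst_equals_bruteforce_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(100):
        k = rng.integers(2, 6)
        c_a = rng.multinomial(int(rng.integers(2, 21)), rng.dirichlet(np.ones(k)))
        c_b = rng.multinomial(int(rng.integers(2, 21)), rng.dirichlet(np.ones(k)))
        t = _table({"A": dict(enumerate(c_a)), "B": dict(enumerate(c_b))})
        got = pairwise_fst(t, "A", "B", clip=False)[1].fst_raw
        want = amova_fst_bruteforce(c_a, c_b)
        assert got == pytest.approx(want, abs=1e-12)


def test_fst_symmetry_and_small_n_rejected():
    t = _table({"A": {"X": 3, "Y": 2}, "B": {"X": 1, "Y": 4}})
    assert pairwise_fst(t, "A", "B")[0] == pairwise_fst(t, "B", "A")[0]
    tiny = _table({"A": {"X": 1}, "B": {"X": 3, "Y": 2}})
    with pytest.raises(InputError):
        pairwise_fst(tiny, "A", "B")


def test_merging_columns_absent_from_both_pops_leaves_fst_unchanged():
    """Collapsing two haplogroups carried only by a third population does
    not increase the F_ST between two populations that both lack them."""
    rng = np.random.default_rng(7)
    for _ in range(30):
        c_a = [int(rng.integers(1, 10)), int(rng.integers(1, 10)), 0, 0]
        c_b = [int(rng.integers(1, 10)), int(rng.integers(1, 10)), 0, 0]
        c_c = list(rng.multinomial(20, rng.dirichlet(np.ones(4))))
        t = _table({"A": dict(enumerate(c_a)), "B": dict(enumerate(c_b)),
                    "C": dict(enumerate(c_c))})
        before = pairwise_fst(t, "A", "B")[0]
        after = pairwise_fst(t.collapse({3: 2}), "A", "B")[0]
        assert after <= before + 1e-12


# ------------------------------------------------------ permutation test --

def test_permutation_test_deterministic_under_seed():
    t = _table({"A": {"X": 6, "Y": 4}, "B": {"X": 2, "Y": 8}})
    p1 = fst_permutation_test(t, "A", "B", n_perm=500, seed=11)
    p2 = fst_permutation_test(t, "A", "B", n_perm=500, seed=11)
    assert p1 == p2
    assert 0 <= p1 <= 1


def test_permutation_test_identical_pops_p_near_one():
    t = _table({"A": {"X": 5, "Y": 5}, "B": {"X": 5, "Y": 5}})
    p = fst_permutation_test(t, "A", "B", n_perm=2000, seed=3)
    assert p > 0.9


def test_permutation_test_disjoint_matches_enumeration():
    """Fully fixed disjoint populations: only 2 of C(10,5)=252 label splits
    reach F_ST = 1, so p ~= 2/252."""
    t = _table({"A": {"X": 5, "Y": 0}, "B": {"X": 0, "Y": 5}})
    p = fst_permutation_test(t, "A", "B", n_perm=5040, seed=5)
    expected = 2 / 252
    # 4 sigma binomial tolerance at 5040 replicates
    assert abs(p - expected) < 4 * np.sqrt(expected * (1 - expected) / 5040)


def test_plus_one_convention_and_bad_nperm():
    t = _table({"A": {"X": 5, "Y": 0}, "B": {"X": 0, "Y": 5}})
    p = fst_permutation_test(t, "A", "B", n_perm=100, seed=1, plus_one=True)
    assert p >= 1 / 101
    with pytest.raises(InputError):
        fst_permutation_test(t, "A", "B", n_perm=0)


def test_fst_matrix_structure():
    t = _table({
        "A": {"X": 5, "Y": 5}, "B": {"X": 2, "Y": 8}, "C": {"X": 9, "Y": 1}
    })
    m = fst_matrix(t, n_perm=100, seed=0)
    assert np.allclose(m.fst.values, m.fst.values.T)
    assert np.allclose(np.diag(m.fst.values), 0)
    assert ((m.p.values >= 0) & (m.p.values <= 1)).all()
    assert set(m.row("A").index) == {"B", "C"}


# ------------------------------------------------------- affinity filter --

def test_lower_quartile_of_range_examples():
    row = pd.Series({"a": 0.0, "b": 0.1, "c": 0.2, "d": 0.4})
    assert lower_quartile_affinity(row) == {"a", "b"}
    with pytest.warns(UserWarning):
        assert lower_quartile_affinity(
            pd.Series({"a": 0.3, "b": 0.3, "c": 0.3, "d": 0.3})
        ) == {"a", "b", "c", "d"}
    with pytest.raises(InputError):
        lower_quartile_affinity(pd.Series({"a": 0.1, "b": 0.2}))


def test_lower_quartile_matches_bruteforce():
    rng = np.random.default_rng(9)
    values = pd.Series(rng.random(20), index=[f"p{i}" for i in range(20)])
    got = lower_quartile_affinity(values)
    thr = values.min() + 0.25 * (values.max() - values.min())
    want = {i for i, v in values.items() if v <= thr}
    assert got == want


# ----------------------------------------------------------- Mann-Whitney --

def test_mwu_exact_small_sample():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0
    assert p == pytest.approx(0.1)
    assert p == pytest.approx(mwu_exact_pvalue([1, 2, 3], [4, 5, 6]))


def test_mwu_identical_groups_symmetric():
    u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert u == pytest.approx(4.5)  # n_a * n_b / 2 with tie handling
    assert p > 0.9


def test_mwu_empty_group_rejected():
    with pytest.raises(InputError):
        mann_whitney_u([], [1.0])
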