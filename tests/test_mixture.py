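"""Simplex-constrained least-squares mixture decomposition and bootstrap."""

import numpy as np
import pandas as pd
import pytest

from helpers import simplex_grid_minimum

from haplotrace.diversity import FrequencyTable
from haplotrace.errors import InputError
from haplotrace.mixture import (
    SourceProfileMatrix,
    TargetProfile,
    bootstrap_mixture,
    build_profile_matrix,
    solve_mixture,
)


def _matrix(a, names=None):
    a = np.asarray(a, float)
    names = names or [f"s{i}" for i in range(a.shape[1])]
    return SourceProfileMatrix(a, names, [f"h{i}" for i in range(a.shape[0])])


def _target(b):
    return TargetProfile(np.asarray(b, float), 100)


def _random_profile_matrix(rng, n_h, n_s):
    a = rng.dirichlet(np.ones(n_h), size=n_s).T
    return a


# ------------------------------------------------------------- solve ----

def test_column_target_recovers_unit_vector():
    rng = np.random.default_rng(0)
    a = _random_profile_matrix(rng, 6, 3)
    sol = solve_mixture(_matrix(a), _target(a[:, 1]))
    assert np.allclose(sol.x, [0, 1, 0], atol=1e-6)
    assert sol.residual_norm < 1e-6


def test_interior_blend_recovered_exactly():
    a = np.array([[0.8, 0.1], [0.2, 0.9]])
    b = 0.3 * a[:, 0] + 0.7 * a[:, 1]
    sol = solve_mixture(_matrix(a), _target(b))
    assert np.allclose(sol.x, [0.3, 0.7], atol=1e-6)


def test_solution_constraints_hold():
    rng = np.random.default_rng(1)
    for _ in range(20):
        a = _random_profile_matrix(rng, 8, 4)
        b = rng.dirichlet(np.ones(8))
        sol = solve_mixture(_matrix(a), _target(b))
        assert sol.x.sum() == pytest.approx(1.0, abs=1e-9)
        assert (sol.x >= 0).all()


def test_matches_simplex_grid_search():
    """Off-span targets: the active-set solution matches an exhaustive
    0.001-step simplex grid search for 3-source problems."""
    rng = np.random.default_rng(2)
    for _ in range(3):
        a = _random_profile_matrix(rng, 8, 3)
        b = rng.dirichlet(np.ones(8))
        sol = solve_mixture(_matrix(a), _target(b))
        x_grid, obj_grid = simplex_grid_minimum(a, b, step=0.001)
        assert np.abs(sol.x - x_grid).max() < 1e-3 + 1e-9
        assert sol.objective <= obj_grid + 1e-9


def test_objective_never_above_feasible_probes():
    rng = np.random.default_rng(3)
    a = _random_profile_matrix(rng, 7, 4)
    b = rng.dirichlet(np.ones(7))
    sol = solve_mixture(_matrix(a), _target(b))
    for _ in range(200):
        probe = rng.dirichlet(np.ones(4))
        assert sol.objective <= ((a @ probe - b) ** 2).sum() + 1e-9


def test_duplicate_columns_split_mass_equally():
    a0 = np.array([[0.7, 0.2], [0.3, 0.8]])
    a = np.column_stack([a0[:, 0], a0[:, 0], a0[:, 1]])
    b = 0.6 * a0[:, 0] + 0.4 * a0[:, 1]
    sol = solve_mixture(_matrix(a), _target(b))
    assert sol.degenerate
    assert sol.x[0] == pytest.approx(sol.x[1])
    assert sol.x[0] + sol.x[1] == pytest.approx(0.6, abs=1e-6)
    assert sol.x[2] == pytest.approx(0.4, abs=1e-6)


def test_profile_validation():
    with pytest.raises(InputError):
        _matrix(np.array([[0.5, 0.2], [0.2, 0.2]]))  # columns not summing to 1
    with pytest.raises(InputError):
        TargetProfile(np.array([0.5, 0.4]), 10)


# ----------------------------------------------------- profile building --

def test_disjoint_sources_complementary_blocks():
    t = FrequencyTable(pd.DataFrame(
        {"X": [4, 0, 2], "Y": [0, 6, 1], "Z": [0, 0, 3]},
        index=["A", "B", "T"],
    ))
    m, prof = build_profile_matrix(t, "T", ["A", "B"])
    assert m.A.shape == (3, 2)
    assert np.allclose(m.A.sum(axis=0), 1.0)
    assert prof.b.sum() == pytest.approx(1.0)


def test_african_reference_pooled_by_counts():
    ref = FrequencyTable(pd.DataFrame(
        {"X": [10, 0], "Y": [0, 30]}, index=["r1", "r2"]
    ))
    t = FrequencyTable(pd.DataFrame(
        {"X": [5, 3], "Y": [5, 7]}, index=["S", "T"]
    ))
    m, _ = build_profile_matrix(t, "T", ["S"], ref)
    ref_col = m.A[:, m.sources.index("African reference")]
    got = dict(zip(m.haplogroups, ref_col))
    assert got == {"X": pytest.approx(0.25), "Y": pytest.approx(0.75)}


def test_fixture_union_rows(fixture_tables):
    y, _ = fixture_tables
    from haplotrace.simulate import synthetic_african_reference

    ref = synthetic_african_reference("y")
    augmented = FrequencyTable(
        pd.concat([y.counts, pd.DataFrame({"C": [10]}, index=["T"])]).fillna(0)
    )
    m, _ = build_profile_matrix(augmented, "T", y.populations, ref)
    expected = set(y.haplogroups) | set(ref.haplogroups) | {"C"}
    assert set(m.haplogroups) == expected


# ------------------------------------------------------------ bootstrap --

def test_single_source_bootstrap_is_degenerate_at_one():
    t = FrequencyTable(pd.DataFrame(
        {"X": [5, 4], "Y": [5, 6]}, index=["S", "T"]
    ))
    boot = bootstrap_mixture(t, "T", ["S"], n_rep=50, seed=0)
    assert np.allclose(boot.draws.values, 1.0)


def test_bootstrap_seed_reproducible():
    t = FrequencyTable(pd.DataFrame(
        {"X": [8, 2, 5], "Y": [2, 8, 5]}, index=["A", "B", "T"]
    ))
    b1 = bootstrap_mixture(t, "T", ["A", "B"], n_rep=200, seed=42)
    b2 = bootstrap_mixture(t, "T", ["A", "B"], n_rep=200, seed=42)
    assert b1.draws.equals(b2.draws)
    with pytest.raises(InputError):
        bootstrap_mixture(t, "T", ["A", "B"], n_rep=0)


def _recovery_setup(rng, n=2000):
    """Three well-separated sources and a target drawn from a known blend."""
    a = np.array([
        [0.70, 0.05, 0.05],
        [0.20, 0.10, 0.05],
        [0.05, 0.70, 0.10],
        [0.03, 0.10, 0.10],
        [0.01, 0.03, 0.50],
        [0.01, 0.02, 0.20],
    ])
    true_x = np.array([0.5, 0.3, 0.2])
    f = a @ true_x
    counts = {
        "s0": rng.multinomial(n, a[:, 0]),
        "s1": rng.multinomial(n, a[:, 1]),
        "s2": rng.multinomial(n, a[:, 2]),
        "T": rng.multinomial(n, f),
    }
    table = FrequencyTable(pd.DataFrame(counts, index=[f"h{i}" for i in range(6)]).T)
    return table, true_x


def test_parameter_recovery_mean_absolute_error():
    """Across synthetic replicates at n=2000 the mean absolute coefficient
    error stays below 0.05."""
    rng = np.random.default_rng(5)
    errors = []
    for _ in range(200):
        table, true_x = _recovery_setup(rng)
        m, t = build_profile_matrix(table, "T", ["s0", "s1", "s2"])
        sol = solve_mixture(m, t)
        errors.append(np.abs(sol.x - true_x).mean())
    assert np.mean(errors) < 0.05


def test_bootstrap_interval_covers_truth():
    """95% percentile intervals cover the true coefficient in >= 90% of
    replicates in the recovery setup."""
    rng = np.random.default_rng(6)
    covered = 0
    n_rep = 60
    for _ in range(n_rep):
        table, true_x = _recovery_setup(rng)
        boot = bootstrap_mixture(
            table, "T", ["s0", "s1", "s2"], n_rep=200,
            seed=int(rng.integers(2**31 - 1)),
        )
        lo = boot.summaries["p2.5"]["s0"]
        hi = boot.summaries["p97.5"]["s0"]
        covered += int(lo <= 0.5 <= hi)
    assert covered / n_rep >= 0.9
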