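"""Range-based SPC variance estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mrakit as mk
from mrakit.exceptions import DataError
from mrakit.spc import ColumnVariance, range_chart_d4

WORKED_SUBGROUPS = ((1.0, 2.0), (5.0, 7.0), (10.0, 13.0))  # ranges 1, 2, 3


def test_hartley_d2_subgroup_of_two():
    assert mk.hartley_d2(2) == 1.128


def test_hartley_d2_subgroup_of_three_matches_expected_range_of_normals():
    # E[range of 3 iid N(0,1)] = 3/sqrt(pi) ~ 1.6926, tabulated as 1.693
    assert mk.hartley_d2(3) == pytest.approx(3.0 / np.sqrt(np.pi), abs=5e-4)
    assert mk.hartley_d2(3) == 1.693


@pytest.mark.parametrize("bad", [1, 11, 0])
def test_hartley_d2_unsupported_sizes(bad):
    with pytest.raises(DataError, match="2..10"):
        mk.hartley_d2(bad)


def test_spc_intra_sd_worked_fixture():
    est = mk.spc_intra_sd(mk.SubgroupedSamples(WORKED_SUBGROUPS))
    assert est.mean_range == pytest.approx(2.0)
    assert est.s_intra == pytest.approx(6.0 / (3 * 1.128))
    assert (est.k_t, est.n_r, est.d2) == (3, 2, 1.128)


def test_spc_intra_sd_zero_for_constant_subgroups():
    est = mk.spc_intra_sd(mk.SubgroupedSamples(((4.0, 4.0), (9.0, 9.0))))
    assert est.s_intra == 0.0


def test_spc_intra_sd_unbiased_on_normal_data():
    """Monte-Carlo: 10,000 subgroups of 2 from N(0, sigma=2)."""
    rng = np.random.default_rng(42)
    draws = rng.normal(0.0, 2.0, size=(10_000, 2))
    est = mk.spc_intra_sd(mk.SubgroupedSamples(tuple(map(tuple, draws))))
    assert abs(est.s_intra - 2.0) / 2.0 <= 0.02


def test_spc_intra_sd_rejects_ragged_and_singleton_groups():
    with pytest.raises(DataError, match="ragged"):
        mk.SubgroupedSamples(((1.0, 2.0), (3.0,)))
    with pytest.raises(DataError, match="two members"):
        mk.SubgroupedSamples(((1.0,), (2.0,)))


@given(
    lam=st.floats(min_value=0.01, max_value=100),
    shift=st.floats(min_value=-50, max_value=50),
)
def test_spc_intra_sd_scale_equivariant_translation_invariant(lam, shift):
    base = mk.spc_intra_sd(mk.SubgroupedSamples(WORKED_SUBGROUPS))
    scaled = mk.spc_intra_sd(
        mk.SubgroupedSamples(tuple(tuple(lam * v + shift for v in g) for g in WORKED_SUBGROUPS))
    )
    assert scaled.s_intra == pytest.approx(lam * base.s_intra, rel=1e-9)


# ---------------------------------------------------------------------------
# Gene-population pooled estimator
# ---------------------------------------------------------------------------


def _clean_population(n_genes=200, sigma=0.3, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, sigma, size=(n_genes, 2))
    return pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)])


def _uniform_spread_population(n_genes=50, half_range=0.15, seed=0) -> pd.DataFrame:
    """Every gene's replicate pair has the identical spread: nothing is out
    of control under the range chart."""
    rng = np.random.default_rng(seed)
    means = rng.normal(0.0, 1.0, size=n_genes)
    values = np.column_stack([means - half_range, means + half_range])
    return pd.DataFrame(values, index=[f"g{i}" for i in range(n_genes)])


def test_population_sd_in_control_data_single_pass():
    pop = _uniform_spread_population()
    result = mk.estimate_population_column_sd(pop)
    assert result.n_iterations == 1
    assert not result.excluded_genes
    # matches the plain pooled mean-range estimate
    pooled = mk.spc_intra_sd(
        mk.SubgroupedSamples(tuple(map(tuple, pop.to_numpy())))
    ).s_intra
    assert result.sigma == pytest.approx(pooled)
    assert result.sigma == pytest.approx(0.3 / 1.128)


def test_population_sd_gaussian_data_near_truth():
    """On Gaussian replicate noise the pooled estimate tracks the true sd;
    the range chart may trim a few legitimate tail genes, biasing it only
    slightly low."""
    pop = _clean_population(n_genes=500, sigma=0.3, seed=9)
    plain = mk.estimate_population_column_sd(pop, rule="none")
    trimmed = mk.estimate_population_column_sd(pop, rule="range_chart")
    assert plain.sigma == pytest.approx(0.3, rel=0.05)
    assert trimmed.sigma <= plain.sigma
    assert trimmed.sigma == pytest.approx(plain.sigma, rel=0.15)


def test_population_sd_excludes_extreme_outlier_first_iteration():
    pop = _uniform_spread_population(seed=1)
    pop.loc["outlier"] = [0.0, 100.0 * 0.3]
    result = mk.estimate_population_column_sd(pop)
    assert ("outlier", 1) in result.excluded_genes
    assert "outlier" not in result.retained_genes
    clean = mk.estimate_population_column_sd(pop.drop(index="outlier"), rule="none")
    assert result.sigma == pytest.approx(clean.sigma)


def test_population_sd_rule_off_is_plain_pooled_estimate():
    pop = _clean_population(n_genes=30, seed=2)
    pop.loc["outlier"] = [0.0, 50.0]
    result = mk.estimate_population_column_sd(pop, rule="none")
    assert result.n_iterations == 1
    ranges = pop.max(axis=1) - pop.min(axis=1)
    assert result.sigma == pytest.approx(float(ranges.mean()) / 1.128)
    assert set(result.retained_genes) == set(pop.index)


def test_population_sd_terminates_and_partitions_genes():
    rng = np.random.default_rng(3)
    values = rng.normal(0.0, 0.1, size=(40, 2))
    values[::7] *= 30  # several out-of-control genes
    pop = pd.DataFrame(values, index=[f"g{i}" for i in range(40)])
    result = mk.estimate_population_column_sd(pop)
    retained = set(result.retained_genes)
    excluded = {g for g, _ in result.excluded_genes}
    assert retained | excluded == set(pop.index)
    assert not retained & excluded
    assert result.n_iterations <= len(pop.index)


def test_population_sd_degeneracy_error():
    # geometric range tiers: each iteration peels off the current maximum,
    # shrinking the retained set below the configured floor
    ranges = [4.0**k for k in range(12)]
    pop = pd.DataFrame(
        {"a": [0.0] * 12, "b": ranges}, index=[f"g{i}" for i in range(12)]
    )
    with pytest.raises(DataError, match="retained"):
        mk.estimate_population_column_sd(pop, min_retained=10)


def test_population_sd_requires_population():
    with pytest.raises(DataError, match=">= 10 genes"):
        mk.estimate_population_column_sd(_clean_population(n_genes=5))
    with pytest.raises(DataError, match="replicates"):
        mk.estimate_population_column_sd(np.ones((20, 1)))


def test_zscore_rule_excludes_shifted_gene():
    pop = _clean_population(n_genes=50, sigma=0.1, seed=5)
    pop.loc["shifted"] = [5.0, 5.0]  # tight replicates, wild mean
    ranged = mk.estimate_population_column_sd(pop, rule="range_chart")
    assert "shifted" in ranged.retained_genes  # range chart cannot see it
    zruled = mk.estimate_population_column_sd(pop, rule="zscore")
    assert "shifted" not in zruled.retained_genes


def test_d4_constant_table():
    assert range_chart_d4(2) == 3.267
    with pytest.raises(DataError):
        range_chart_d4(1)
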