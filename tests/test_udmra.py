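"""Unidirectional MRA: appended genes, weight optimization, baselines."""

import numpy as np
import pandas as pd
import pytest

import mrakit as mk
from mrakit.exceptions import DataError, SaturationError
from mrakit.synthetic import mixed_sign_gene_benchmark


def _gene(name, responses, basal=10.0):
    return mk.AppendedGene(gene=name, responses=np.asarray(responses), basal_abundance=basal)


def test_fit_row_reproduces_module_row(R3):
    """A gene responding exactly like module j gets weight 1 on module j."""
    row = mk.fit_udmra_row(R3, _gene("mimic", R3.values[1, :]))
    np.testing.assert_allclose(row.coefficients, [0.0, 1.0, 0.0], atol=1e-12)


def test_fit_row_zero_responses_zero_coefficients(R3):
    row = mk.fit_udmra_row(R3, _gene("flat", np.zeros(3)))
    np.testing.assert_allclose(row.coefficients, np.zeros(3), atol=1e-14)


def test_fit_row_recovers_random_weights(R3):
    rng = np.random.default_rng(5)
    for _ in range(10):
        w = rng.uniform(-0.8, 0.8, size=3)
        responses = w @ R3.values
        if np.any(np.abs(responses) >= 2):
            continue
        row = mk.fit_udmra_row(R3, _gene("g", responses))
        assert np.abs(row.coefficients - w).max() <= 1e-10


def test_fit_row_rejects_out_of_range_responses(R3):
    with pytest.raises(DataError, match="\\(-2, 2\\)"):
        _gene("bad", [2.5, 0.0, 0.0])


def test_predict_gene_elementary_consistency(R3, net3):
    """With an elementary perturbation the fitted gene reproduces its own
    training response (interpolation property of an exact solve)."""
    rng = np.random.default_rng(6)
    w = rng.uniform(-0.5, 0.5, size=3)
    responses = w @ R3.values
    row = mk.fit_udmra_row(R3, _gene("g", responses))
    for k in range(3):
        _, u = mk.predict_gene(
            row, net3, mk.CombinedPerturbation(np.eye(3)[k]), 10.0
        )
        assert u == pytest.approx(responses[k], abs=1e-10)


def test_predict_gene_zero_row_stays_at_basal(R3, net3):
    row = mk.fit_udmra_row(R3, _gene("flat", np.zeros(3)))
    x, u = mk.predict_gene(
        row, net3, mk.CombinedPerturbation(np.array([1.0, 1.0, 0.0])), 12.5
    )
    assert u == pytest.approx(0.0, abs=1e-12)
    assert x == pytest.approx(12.5)


def test_predict_gene_matches_generator_truth():
    """Noiseless double perturbation: the udMRA pipeline prediction equals
    the generator's ground-truth abundance."""
    truth, panel, c = mixed_sign_gene_benchmark(seed=21, n_genes=10)
    R = mk.GlobalResponseMatrix(truth.R_true, truth.modules)
    net = mk.infer_network(R)
    for gene in panel.genes:
        row = mk.fit_udmra_row(
            R, _gene(gene, panel.responses.loc[gene].to_numpy(), panel.basal[gene])
        )
        x, _ = mk.predict_gene(row, net, c, panel.basal[gene])
        expected = panel.true_abundance(gene, c)
        assert abs(x - expected) / expected <= 1e-9


def test_optimize_weights_recovers_synthetic_truth(net3):
    """Self-consistency: observations generated at weights (1, 0.4) are
    recovered by the grid + refinement search."""
    target = {"M2": 1.0, "M3": 0.4}
    c = mk.CombinedPerturbation.from_modules(net3.modules, target)
    observed = mk.predict_response(net3, c)
    fit = mk.optimize_weights(net3, observed, ["M2", "M3"])
    assert fit.weights["M2"] == pytest.approx(1.0, abs=1e-4)
    assert fit.weights["M3"] == pytest.approx(0.4, abs=1e-4)
    assert fit.objective_value <= 1e-10


def test_optimize_weights_all_ones_trivial(net3):
    c = mk.CombinedPerturbation(np.ones(3))
    observed = mk.predict_response(net3, c)
    fit = mk.optimize_weights(net3, observed, list(net3.modules))
    for m in net3.modules:
        assert fit.weights[m] == pytest.approx(1.0, abs=1e-4)


def test_optimize_weights_optimum_bounds_trace(net3):
    c = mk.CombinedPerturbation(np.array([1.0, 0.7, 0.0]))
    observed = mk.predict_response(net3, c) + 0.01
    fit = mk.optimize_weights(net3, observed, ["M1", "M2"])
    assert all(fit.objective_value <= obj for _, obj in fit.trace)


def test_optimize_weights_rejects_all_zero_observations(net3):
    with pytest.raises(DataError, match="absolute"):
        mk.optimize_weights(net3, np.zeros(3), ["M1"])


@pytest.mark.parametrize(
    "obs, expected",
    [
        ([4.0, 9.0], {"mean": 6.5, "gMean": 6.0, "max": 9.0}),
        ([5.0, 5.0], {"mean": 5.0, "gMean": 5.0, "max": 5.0}),
        ([7.0], {"mean": 7.0, "gMean": 7.0, "max": 7.0}),
    ],
)
def test_naive_predictors_arithmetic(obs, expected):
    result = mk.naive_predictors(obs, basal=10.0)
    for k, v in expected.items():
        assert result[k] == pytest.approx(v)


def test_naive_predictors_fold_change_space():
    result = mk.naive_predictors([4.0, 9.0], basal=2.0, space="fold_change")
    assert result["mean"] == pytest.approx((2.0 + 4.5) / 2 * 2.0)


def test_naive_predictors_reject_empty_and_nonpositive():
    with pytest.raises(DataError):
        mk.naive_predictors([], basal=1.0)
    with pytest.raises(DataError):
        mk.naive_predictors([1.0, -2.0], basal=1.0)


def test_benchmark_exact_method_dominates():
    observed = pd.Series({"g1": 5.0, "g2": 8.0, "g3": 2.0})
    predicted = pd.DataFrame(
        {"exact": [5.0, 8.0, 2.0], "off": [6.0, 7.0, 3.0]},
        index=["g1", "g2", "g3"],
    )
    result = mk.benchmark_predictions(predicted, observed)
    assert (result.errors["exact"] == 0).all()
    assert (result.errors["off"] > 0).all()


def test_benchmark_identical_methods_p_one():
    observed = pd.Series({"g1": 5.0, "g2": 8.0})
    predicted = pd.DataFrame({"a": [6.0, 7.0], "b": [6.0, 7.0]}, index=["g1", "g2"])
    result = mk.benchmark_predictions(predicted, observed)
    assert result.wilcoxon("a", "b") == 1.0


def test_mixed_sign_benchmark_udmra_beats_naive_baselines():
    """Genes depending on >= 2 modules with opposite signs: exact udMRA has
    median relative error 0 and strictly beats mean/gMean/max."""
    truth, panel, c = mixed_sign_gene_benchmark(seed=17, n_genes=30)
    R = mk.GlobalResponseMatrix(truth.R_true, truth.modules)
    net = mk.infer_network(R)
    perturbed = [m for m, w in zip(truth.modules, c.weights) if w]
    rows = {}
    observed = {}
    for gene in panel.genes:
        row = mk.fit_udmra_row(
            R, _gene(gene, panel.responses.loc[gene].to_numpy(), panel.basal[gene])
        )
        x, _ = mk.predict_gene(row, net, c, panel.basal[gene])
        singles = panel.single_perturbation_abundances(gene)
        naive = mk.naive_predictors([singles[m] for m in perturbed], panel.basal[gene])
        rows[gene] = {"udMRA": x, **naive}
        observed[gene] = panel.true_abundance(gene, c)
    result = mk.benchmark_predictions(pd.DataFrame(rows).T, pd.Series(observed))
    medians = result.median_errors
    assert medians["udMRA"] <= 1e-9
    for baseline in ("mean", "gMean", "max"):
        assert medians["udMRA"] < medians[baseline]
        assert result.wilcoxon("udMRA", baseline) < 0.01
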