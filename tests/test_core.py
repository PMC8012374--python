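"""MRA core: response construction, inversion, prediction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mrakit as mk
from mrakit.exceptions import DataError, DesignError, InferenceError, SaturationError

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


@pytest.mark.parametrize(
    "x_pert, x_basal, expected",
    [(5.0, 5.0, 0.0), (3.0, 1.0, 1.0), (1.0, 3.0, -1.0)],
)
def test_symmetric_relative_change_examples(x_pert, x_basal, expected):
    assert mk.symmetric_relative_change(x_pert, x_basal) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [(0.0, 1.0), (-2.0, 1.0), (1.0, float("nan")), (1.0, float("inf"))])
def test_symmetric_relative_change_rejects_nonpositive(bad):
    with pytest.raises(DataError):
        mk.symmetric_relative_change(*bad, label="Luc@siNRIP1")


@given(a=positive, b=positive)
def test_symmetric_relative_change_bounded_and_antisymmetric(a, b):
    v = mk.symmetric_relative_change(a, b)
    assert -2.0 < v < 2.0
    assert mk.symmetric_relative_change(b, a) == pytest.approx(-v)


def _two_module_design(k_t=1, n_r=1):
    return mk.ExperimentDesign(
        modules=("A", "B"),
        basal_condition="basal",
        perturbation_map={"pA": "A", "pB": "B"},
        replicates=(k_t, n_r),
    )


def test_build_global_response_hand_example():
    """Hand evaluation of the symmetric relative difference per cell."""
    design = _two_module_design()
    data = mk.AbundanceSet.from_records(
        [
            ("A", "basal", 1, 1, 10.0),
            ("B", "basal", 1, 1, 20.0),
            ("A", "pA", 1, 1, 5.0),
            ("B", "pA", 1, 1, 20.0),
            ("A", "pB", 1, 1, 10.0),
            ("B", "pB", 1, 1, 10.0),
        ]
    )
    R = mk.build_global_response(data, design, "pooled_mean")
    # column A: 2*(5-10)/15 = -2/3 on A, no change on B; column B likewise
    np.testing.assert_allclose(R.values, [[-2.0 / 3.0, 0.0], [0.0, -2.0 / 3.0]])


def test_build_global_response_identity_conditions_zero_matrix():
    design = _two_module_design()
    data = mk.AbundanceSet.from_records(
        [(m, c, 1, 1, 7.0) for m in ("A", "B") for c in ("basal", "pA", "pB")]
    )
    R = mk.build_global_response(data, design, "pooled_mean")
    np.testing.assert_array_equal(R.values, np.zeros((2, 2)))


def test_per_replicate_zero_noise_matrices_identical(truth3, design3, noiseless_data):
    mats = mk.build_global_response(noiseless_data, design3, "per_replicate")
    assert len(mats) == design3.k_t * design3.n_r == 6
    for m in mats[1:]:
        np.testing.assert_array_equal(m.values, mats[0].values)


def test_build_global_response_missing_cell_error(truth3, design3, noiseless_data):
    table = noiseless_data.table
    cond = design3.condition_for(truth3.modules[0])
    table = table[~((table["condition"] == cond) & (table["bio_rep"] == 2))]
    incomplete = mk.AbundanceSet(table)
    with pytest.raises(DataError, match="missing measurement cells"):
        mk.build_global_response(incomplete, design3, "per_replicate")


def test_infer_network_diagonal_case():
    d = np.array([-0.7, 0.9, -1.3])
    net = mk.infer_network(mk.GlobalResponseMatrix(np.diag(d), ("A", "B", "C")))
    np.testing.assert_allclose(net.r, -np.eye(3))
    np.testing.assert_allclose(net.P, d)


def test_infer_network_two_by_two_hand_oracle():
    """Oracle: explicit 2x2 inversion in plain arithmetic."""
    R = np.array([[-0.5, 0.2], [0.3, -0.8]])
    det = (-0.5) * (-0.8) - 0.2 * 0.3
    Rinv = [[-0.8 / det, -0.2 / det], [-0.3 / det, -0.5 / det]]
    expected_P = [1.0 / Rinv[0][0], 1.0 / Rinv[1][1]]
    expected_r01 = -Rinv[0][1] / Rinv[0][0]
    expected_r10 = -Rinv[1][0] / Rinv[1][1]
    net = mk.infer_network(mk.GlobalResponseMatrix(R, ("A", "B")))
    assert net.P == pytest.approx(expected_P)
    assert net.r[0, 1] == pytest.approx(expected_r01)
    assert net.r[1, 0] == pytest.approx(expected_r10)
    assert net.r[0, 0] == -1.0 and net.r[1, 1] == -1.0


@pytest.mark.parametrize("n", [2, 3, 4, 5])
def test_forward_compose_invert_round_trip(n):
    """Compose R from a random truth, infer back, recover r and P exactly."""
    for seed in range(5):
        truth = mk.random_ground_truth(n, seed=100 * n + seed)
        R = mk.GlobalResponseMatrix(truth.R_true, truth.modules)
        net = mk.infer_network(R)
        assert np.abs(net.r - truth.r_true).max() <= 1e-10
        assert np.abs(net.P - truth.P_true).max() <= 1e-10
        np.testing.assert_allclose(net.reconstruct_global(), truth.R_true, atol=1e-10)


def test_infer_network_rejects_singular():
    R = mk.GlobalResponseMatrix(np.array([[0.5, 0.5], [0.5, 0.5]]), ("A", "B"))
    with pytest.raises(InferenceError, match="condition number"):
        mk.infer_network(R)


def test_predict_response_elementary_reproduces_columns(truth3, net3):
    R_true = truth3.R_true
    for k in range(3):
        c = mk.CombinedPerturbation(np.eye(3)[k])
        v = mk.predict_response(net3, c)
        assert np.abs(v - R_true[:, k]).max() <= 1e-12


def test_predict_response_rejects_zero_vector():
    with pytest.raises(DataError):
        mk.CombinedPerturbation(np.zeros(3))


def test_predict_response_linearity(net3):
    ei = mk.CombinedPerturbation(np.array([1.0, 0.0, 0.0]))
    ej = mk.CombinedPerturbation(np.array([0.0, 1.0, 0.0]))
    both = mk.CombinedPerturbation(np.array([1.0, 1.0, 0.0]))
    np.testing.assert_allclose(
        mk.predict_response(net3, both),
        mk.predict_response(net3, ei) + mk.predict_response(net3, ej),
        atol=1e-12,
    )


def test_predict_abundance_identity_and_examples():
    net = mk.infer_network(mk.GlobalResponseMatrix(np.diag([1.0, 0.5]), ("A", "B")))
    basal = np.array([10.0, 20.0])
    # elementary perturbation of A gives v = (1, 0): 10 * (2+1)/(2-1) = 30
    x = mk.predict_abundance(net, mk.CombinedPerturbation(np.array([1.0, 0.0])), basal)
    np.testing.assert_allclose(x, [30.0, 20.0])
    # round trip through the symmetric relative difference recovers v
    assert mk.symmetric_relative_change(x[0], basal[0]) == pytest.approx(1.0)


def test_predict_abundance_saturation_error():
    net = mk.infer_network(mk.GlobalResponseMatrix(np.diag([0.5, 0.5]), ("A", "B")))
    big = mk.CombinedPerturbation(np.array([10.0, 0.0]))
    with pytest.raises(SaturationError, match="'A'"):
        mk.predict_abundance(net, big, np.array([10.0, 10.0]))


def test_diagonal_of_r_is_exactly_minus_one(net3):
    assert np.all(np.diag(net3.r) == -1.0)


def test_design_invariants():
    with pytest.raises(DesignError):  # module targeted twice
        mk.ExperimentDesign(
            modules=("A",),
            basal_condition="b",
            perturbation_map={"p1": "A", "p2": "A"},
        )
    with pytest.raises(DesignError):  # basal must not perturb
        mk.ExperimentDesign(
            modules=("A",), basal_condition="p", perturbation_map={"p": "A"}
        )
    with pytest.raises(DesignError):  # untargeted module
        mk.ExperimentDesign(
            modules=("A", "B"), basal_condition="b", perturbation_map={"p": "A"}
        )
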