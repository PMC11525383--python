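import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcuncert.distributions import (
    DegenerateDispersionError,
    DistributionSpec,
    InputQuantity,
    InsufficientReplicatesError,
    InvalidParameterError,
    QuantitySet,
    ReplicateSet,
    gaussian_from_estimate,
    gaussian_from_expanded,
    load_quantities,
    quantities_from_records,
    quantity_rng,
    rectangular_from_limits,
    sample,
    save_quantities,
    type_a_from_replicates,
)


class TestConstructors:
    @pytest.mark.parametrize(
        "x, u",
        [(1.1419, 0.01759), (0.0, 1.0), (0.949, 0.0095)],
    )
    def test_gaussian_from_estimate(self, x, u):
        spec = gaussian_from_estimate(x, u)
        assert spec.kind == "gaussian"
        assert spec.expectation == x
        assert spec.standard_uncertainty == u

    @pytest.mark.parametrize("bad_u", [0.0, -0.1])
    def test_gaussian_rejects_nonpositive_u(self, bad_u):
        with pytest.raises(InvalidParameterError):
            gaussian_from_estimate(1.0, bad_u)

    @pytest.mark.parametrize(
        "a, b, expect, u",
        [
            (1.022, 1.026, 1.024, 0.004 / (2 * math.sqrt(3))),
            (-1.0, 1.0, 0.0, 1 / math.sqrt(3)),
            (0.0, 1.0, 0.5, 0.288675),
        ],
    )
    def test_rectangular_from_limits(self, a, b, expect, u):
        spec = rectangular_from_limits(a, b)
        assert spec.kind == "rectangular"
        assert spec.expectation == pytest.approx(expect)
        assert spec.standard_uncertainty == pytest.approx(u, abs=1e-6)

    def test_sample_density_uncertainty_rounds_to_published_value(self):
        u = rectangular_from_limits(1.022, 1.026).standard_uncertainty
        assert round(u, 4) == 0.0012

    @pytest.mark.parametrize("a, b", [(1.0, 1.0), (2.0, 1.0)])
    def test_rectangular_rejects_bad_limits(self, a, b):
        with pytest.raises(InvalidParameterError):
            rectangular_from_limits(a, b)

    def test_gaussian_from_expanded_certificate(self):
        # purity certificate: 94.9 % with expanded uncertainty 1.9 %, k = 2
        spec = gaussian_from_expanded(94.9, 1.9, 2.0)
        assert spec.expectation == 94.9
        assert spec.standard_uncertainty == pytest.approx(0.95)

    def test_gaussian_from_expanded_k1_identity(self):
        spec = gaussian_from_expanded(5.0, 0.3, 1.0)
        assert spec.standard_uncertainty == pytest.approx(0.3)

    @pytest.mark.parametrize("U, k", [(0.0, 2.0), (1.0, 0.0), (-1.0, 2.0)])
    def test_gaussian_from_expanded_guards(self, U, k):
        with pytest.raises(InvalidParameterError):
            gaussian_from_expanded(1.0, U, k)

    @given(
        x=st.floats(-1e3, 1e3),
        U=st.floats(1e-6, 1e3),
        k=st.floats(0.1, 10),
    )
    @settings(derandomize=True, max_examples=50)
    def test_expanded_equals_estimate_with_scaled_u(self, x, U, k):
        a = gaussian_from_expanded(x, U, k)
        b = gaussian_from_estimate(x, U / k)
        assert a == b


class TestTypeA:
    def test_two_observations_hand_case(self):
        spec = type_a_from_replicates(ReplicateSet((0.0, 2.0)))
        assert spec.expectation == 1.0
        # sample SD = sqrt(2); SD of the mean = sqrt(2)/sqrt(2) = 1
        assert spec.standard_uncertainty == pytest.approx(1.0)

    def test_recovers_generating_parameters_at_n10(self):
        u_target = 0.01185
        rng = np.random.default_rng(42)
        obs = rng.normal(1.00815, u_target * math.sqrt(10), 10)
        spec = type_a_from_replicates(ReplicateSet(tuple(obs)))
        assert spec.expectation == pytest.approx(1.00815, abs=3 * u_target)
        # SD estimated from n=10 is itself noisy; accept a 50% band
        assert abs(spec.standard_uncertainty - u_target) < 0.5 * u_target

    def test_zero_dispersion_rejected(self):
        with pytest.raises(DegenerateDispersionError):
            type_a_from_replicates(ReplicateSet((3.0, 3.0, 3.0)))

    def test_single_observation_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            ReplicateSet((1.0,))

    @given(st.permutations(list(range(8))))
    @settings(derandomize=True, max_examples=30)
    def test_permutation_invariance(self, order):
        base = [0.1, 0.5, 0.2, 0.9, 0.3, 0.7, 0.4, 0.6]
        shuffled = tuple(base[i] for i in order)
        a = type_a_from_replicates(ReplicateSet(tuple(base)))
        b = type_a_from_replicates(ReplicateSet(shuffled))
        assert a.expectation == pytest.approx(b.expectation)
        assert a.standard_uncertainty == pytest.approx(b.standard_uncertainty)


class TestSampling:
    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec("gaussian", 0.0, 1.0),
            DistributionSpec("gaussian", 16.0, 0.3),
            DistributionSpec("rectangular", 1.022, 1.026),
        ],
        ids=["std-normal", "shifted-normal", "rectangular"],
    )
    def test_moments_converge(self, spec):
        n = 10**6
        draws = sample(spec, n, np.random.default_rng(7))
        tol = 5 * spec.standard_uncertainty / math.sqrt(n)
        assert abs(draws.mean() - spec.expectation) < tol
        assert abs(draws.std(ddof=1) - spec.standard_uncertainty) < tol

    def test_rectangular_support_bound(self):
        spec = DistributionSpec("rectangular", 1.022, 1.026)
        draws = sample(spec, 5000, np.random.default_rng(0))
        assert draws.min() >= 1.022 and draws.max() <= 1.026

    def test_same_seed_bitwise_identical(self):
        spec = DistributionSpec("gaussian", 0.0, 1.0)
        a = sample(spec, 1000, quantity_rng(3, "R_S"))
        b = sample(spec, 1000, quantity_rng(3, "R_S"))
        assert np.array_equal(a, b)

    def test_streams_keyed_by_symbol_and_block(self):
        spec = DistributionSpec("gaussian", 0.0, 1.0)
        base = sample(spec, 100, quantity_rng(3, "R_S", 0))
        assert not np.array_equal(base, sample(spec, 100, quantity_rng(3, "R_L", 0)))
        assert not np.array_equal(base, sample(spec, 100, quantity_rng(3, "R_S", 1)))

    def test_adding_a_quantity_leaves_other_draws_unchanged(self):
        q1 = InputQuantity("A", "", 0.0, "", DistributionSpec("gaussian", 0.0, 1.0))
        q2 = InputQuantity("B", "", 5.0, "", DistributionSpec("gaussian", 5.0, 2.0))
        small = QuantitySet([q1]).sample_all(50, root_seed=11)
        large = QuantitySet([q1, q2]).sample_all(50, root_seed=11)
        assert np.array_equal(small["A"], large["A"])


class TestQuantitySet:
    def test_duplicate_symbols_rejected(self):
        q = InputQuantity("X", "", 0.0, "", DistributionSpec("gaussian", 0.0, 1.0))
        with pytest.raises(InvalidParameterError):
            QuantitySet([q, q])

    def test_value_must_match_expectation(self):
        with pytest.raises(InvalidParameterError):
            InputQuantity("X", "", 2.0, "", DistributionSpec("gaussian", 1.0, 0.1))

    def test_percent_unit_normalized_for_model(self):
        q = InputQuantity("P", "purity", 94.9, "%", DistributionSpec("gaussian", 94.9, 0.95))
        assert q.model_value() == pytest.approx(0.949)
        dist = q.model_distribution()
        assert dist.expectation == pytest.approx(0.949)
        assert dist.standard_uncertainty == pytest.approx(0.0095)

    def test_constant_quantity_passes_through(self):
        q = InputQuantity("M_W", "", 288.4, "g/mol", None)
        assert not q.is_stochastic
        draws = QuantitySet([q]).sample_all(10, root_seed=0)
        assert draws["M_W"] == 288.4

    def test_save_load_round_trip(self, tmp_path):
        records = [
            {"symbol": "X", "description": "d", "value": 1.0, "unit": "mg",
             "distribution": {"type": "gaussian", "parameters": [1.0, 0.1]}},
            {"symbol": "C", "description": "", "value": 2.0, "unit": "",
             "distribution": None},
        ]
        qset = quantities_from_records(records)
        path = tmp_path / "q.json"
        save_quantities(qset, path)
        reloaded = load_quantities(path)
        assert list(reloaded) == list(qset)
        save_quantities(reloaded, tmp_path / "q2.json")
        assert json.loads((tmp_path / "q.json").read_text()) == json.loads(
            (tmp_path / "q2.json").read_text()
        )
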