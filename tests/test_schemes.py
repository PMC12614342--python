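"""Reaction-network simulation and the closed-form kinetic models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from hdokin.errors import (
    ConfigurationError,
    InputError,
    UnsupportedSchemeError,
)
from hdokin.models import (
    DEGENERATE_RTOL,
    RiseDecayParams,
    SingleExpParams,
    eval_rise_decay,
    eval_single_exp,
)
from hdokin.schemes import (
    FirstOrderReaction,
    KineticScheme,
    Species,
    peroxo_fraction_at,
    simulate_scheme,
)


def ode_oracle(scheme, times):
    """Independent brute-force oracle: generic stiff integration."""
    k = scheme.rate_matrix()
    sol = solve_ivp(
        lambda t, c: k @ c, (0.0, float(times[-1])), scheme.initial_vector(),
        t_eval=times, method="LSODA", rtol=1e-12, atol=1e-14,
    )
    return sol.y.T


def random_dag_scheme(n_species, edge_bits, rates, initials):
    species = [
        Species(f"s{i}", "intermediate", initials[i]) for i in range(n_species)
    ]
    reactions = []
    idx = 0
    for i in range(n_species):
        for j in range(i + 1, n_species):
            if edge_bits[idx % len(edge_bits)]:
                reactions.append(
                    FirstOrderReaction(f"s{i}", f"s{j}", f"k{i}_{j}",
                                       rates[idx % len(rates)])
                )
            idx += 1
    return KineticScheme(species, reactions)


class TestSimulateScheme:
    def test_no_reactions_leaves_amounts_constant(self):
        scheme = KineticScheme(
            [Species("S", "substrate", 10.0), Species("P", "product", 2.0)], []
        )
        tc = simulate_scheme(scheme, [0.0, 1.0, 5.0])
        assert np.allclose(tc.observables["S"], 10.0)
        assert np.allclose(tc.observables["P"], 2.0)

    def test_half_life_identity(self):
        scheme = KineticScheme(
            [Species("A", "substrate", 1.0), Species("B", "product")],
            [FirstOrderReaction("A", "B", "k", np.log(2.0))],
        )
        tc = simulate_scheme(scheme, [1.0])
        assert tc.observables["A"][0] == pytest.approx(0.5, abs=1e-12)
        assert tc.observables["B"][0] == pytest.approx(0.5, abs=1e-12)

    def test_branch_fractions_and_oracle(self, branching_scheme):
        """Long-time product fractions equal k_i / sum(k); full agreement
        with the independent integrator to 1e-8."""
        times = np.geomspace(0.01, 500.0, 40)
        tc = simulate_scheme(branching_scheme, times)
        rates = {r.target: r.rate_value for r in branching_scheme.reactions}
        k_sum = sum(rates.values())
        total = sum(tc.observables[p][-1] for p in rates)
        for product, k in rates.items():
            assert tc.observables[product][-1] / total == pytest.approx(
                k / k_sum, abs=1e-10
            )
        oracle = ode_oracle(branching_scheme, times)
        ours = np.column_stack(
            [tc.observables[n] for n in branching_scheme.names]
        )
        assert np.max(np.abs(ours - oracle)) < 1e-8

    def test_cyclic_scheme_rejected(self):
        with pytest.raises(UnsupportedSchemeError):
            KineticScheme(
                [Species("A", "intermediate", 1.0), Species("B", "intermediate")],
                [FirstOrderReaction("A", "B", "k1", 1.0),
                 FirstOrderReaction("B", "A", "k2", 1.0)],
            )

    def test_negative_time_rejected(self, branching_scheme):
        with pytest.raises(InputError):
            simulate_scheme(branching_scheme, [-1.0, 1.0])

    def test_undeclared_species_rejected(self):
        with pytest.raises(ConfigurationError):
            KineticScheme(
                [Species("A", "substrate", 1.0)],
                [FirstOrderReaction("A", "ghost", "k", 1.0)],
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 6),
        edge_bits=st.lists(st.booleans(), min_size=15, max_size=15),
        rates=st.lists(st.floats(0.01, 10.0), min_size=15, max_size=15),
        initials=st.lists(st.floats(0.0, 10.0), min_size=6, max_size=6),
    )
    def test_mass_conservation_and_nonnegativity(self, n, edge_bits, rates,
                                                 initials):
        scheme = random_dag_scheme(n, edge_bits, rates, initials)
        times = np.array([0.01, 0.1, 1.0, 10.0, 100.0])
        tc = simulate_scheme(scheme, times)
        conc = np.column_stack([tc.observables[s] for s in scheme.names])
        totals = conc.sum(axis=1)
        expected = sum(initials[:n])
        assert np.allclose(totals, expected, rtol=1e-9, atol=1e-9)
        assert np.all(conc >= -1e-12)

    def test_defective_rate_matrix_falls_back_exactly(self):
        """Sequential steps with equal rates (non-diagonalizable matrix)."""
        scheme = KineticScheme(
            [Species("A", "substrate", 1.0), Species("B", "intermediate"),
             Species("C", "product")],
            [FirstOrderReaction("A", "B", "k1", 1.0),
             FirstOrderReaction("B", "C", "k2", 1.0)],
        )
        tc = simulate_scheme(scheme, [1.0])
        # B(t) = k t exp(-k t) for equal rates
        assert tc.observables["B"][0] == pytest.approx(np.exp(-1.0), abs=1e-10)


class TestSingleExp:
    @pytest.mark.parametrize(
        "params, t, expected",
        [
            (SingleExpParams(1.0, 1.0, 0.7), 0.0, 0.0),
            (SingleExpParams(1.0, 1.0, 0.23), 1e6, 1.0),
            (SingleExpParams(2.0, 1.0, 0.5), 2.0, 2.0 - np.exp(-1.0)),
        ],
    )
    def test_values(self, params, t, expected):
        assert eval_single_exp(params, t) == pytest.approx(expected, abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(InputError):
            eval_single_exp(SingleExpParams(1.0, 1.0, 1.0), -0.5)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(InputError):
            SingleExpParams(1.0, 1.0, 0.0)


class TestRiseDecay:
    def test_baseline_at_t0(self):
        p = RiseDecayParams(0.05, 0.3, 0.1, 0.5, 0.08, 0.01)
        assert eval_rise_decay(p, 0.0) == pytest.approx(0.05, abs=1e-12)

    def test_degenerate_equal_rates(self):
        p = RiseDecayParams(0.0, 1.0, 0.0, 1.0, 0.123, 1.0)
        assert eval_rise_decay(p, 1.0) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_single_channel_matches_sequential_scheme(self):
        """With one channel the model is the Bateman intermediate of an
        A -> B -> C scheme, up to the amplitude scale."""
        k1, k2 = 0.4, 0.03
        p = RiseDecayParams(0.0, 1.0, 0.0, k1, 0.05, k2)
        scheme = KineticScheme(
            [Species("A", "substrate", 1.0), Species("B", "intermediate"),
             Species("C", "product")],
            [FirstOrderReaction("A", "B", "kf", k1),
             FirstOrderReaction("B", "C", "kd", k2)],
        )
        t = np.geomspace(0.01, 200.0, 60)
        model = eval_rise_decay(p, t)
        sim = simulate_scheme(scheme, t).observables["B"]
        assert np.max(np.abs(model - sim)) < 1e-8

    def test_continuous_across_degenerate_switch(self):
        """No jump in the model value where the degenerate limit takes over."""
        k1 = 1.0
        p_lo = RiseDecayParams(0.0, 1.0, 0.0, k1, 0.1,
                               k1 * (1 + 0.5 * DEGENERATE_RTOL))
        p_hi = RiseDecayParams(0.0, 1.0, 0.0, k1, 0.1,
                               k1 * (1 + 2.0 * DEGENERATE_RTOL))
        t = np.linspace(0.1, 10.0, 50)
        assert np.max(np.abs(eval_rise_decay(p_lo, t)
                             - eval_rise_decay(p_hi, t))) < 1e-6


class TestPeroxoFraction:
    def _scheme(self, kf, kd):
        return KineticScheme(
            [Species("Fe2", "cluster-state", 1.0),
             Species("peroxo", "cluster-state", 0.0),
             Species("done", "cluster-state", 0.0)],
            [FirstOrderReaction("Fe2", "peroxo", "kf", kf),
             FirstOrderReaction("peroxo", "done", "kd", kd)],
        )

    def test_zero_at_t0(self):
        frac = peroxo_fraction_at(self._scheme(1.0, 0.1), [0.0], "peroxo")
        assert frac[0] == 0.0

    def test_fast_formation_limit(self):
        """With formation >> decay the fraction is ~exp(-kd t): 1/2 at the
        decay half-life."""
        kd = 0.1
        t_half = np.log(2.0) / kd
        frac = peroxo_fraction_at(self._scheme(1000.0, kd), [t_half], "peroxo")
        assert frac[0] == pytest.approx(0.5, rel=1e-3)

    def test_fractions_sum_to_one(self):
        scheme = self._scheme(2.0, 0.3)
        times = [0.5, 1.0, 5.0]
        total = sum(
            peroxo_fraction_at(scheme, times, name)
            for name in ("Fe2", "peroxo", "done")
        )
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_missing_state_rejected(self):
        with pytest.raises(ConfigurationError):
            peroxo_fraction_at(self._scheme(1.0, 0.1), [1.0], "nothere")
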