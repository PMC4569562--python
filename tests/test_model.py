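"""Core dynamics: initialisation, victim choice, collapse, saturation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from numpy.testing import assert_allclose, assert_array_equal
from scipy import stats
from scipy.integrate import solve_ivp

from divwaves import (
    CommunityState,
    ModelParams,
    apply_collapse,
    diversity,
    equalize_populations,
    init_community,
    saturate,
    select_victim,
    simulate,
    step,
)
from divwaves.model import SpeciesParams
from divwaves.recorders import EventLogRecorder, Recorder

from reference_impl import reference_run


def make_state(populations, **kwargs):
    p = np.asarray(populations, dtype=float)
    n = p.size
    return CommunityState(
        populations=p,
        species_id=np.arange(n, dtype=np.int64),
        birth_step=np.zeros(n, dtype=np.int64),
        n_substantial_at_birth=np.zeros(n, dtype=np.int64),
        next_species_id=n,
        **kwargs,
    )


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"N": 1, "gamma": 0.1},
            {"N": 10, "gamma": 0.0},
            {"N": 10, "gamma": 1.5},
            {"N": 10, "gamma": 0.1, "variant": "nope"},
            {"N": 10, "gamma": 0.1, "variant": "basic", "variant_params": {"sigma": 1}},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_wave_threshold_defaults_to_dominance(self):
        assert ModelParams(N=20, gamma=1e-4).wave_threshold == pytest.approx(0.95)


class TestInit:
    def test_uniform_start(self):
        state = init_community(ModelParams(N=4, gamma=0.01))
        assert_allclose(state.populations, [0.25, 0.25, 0.25, 0.25])
        assert state.populations.sum() == 1.0
        assert set(state.species_id) == {0, 1, 2, 3}

    def test_initial_diversity_is_N(self):
        state = init_community(ModelParams(N=17, gamma=1e-6))
        assert diversity(state.populations) == pytest.approx(17)


class TestSelectVictim:
    def test_uniform_frequencies(self, rng):
        p = np.array([0.2, 0.5, 0.3])
        counts = np.zeros(3)
        for _ in range(30_000):
            counts[select_victim(p, "uniform", rng)] += 1
        chi2 = stats.chisquare(counts).pvalue
        assert chi2 > 1e-4

    def test_size_proportional_selection(self, rng):
        # victim 0 with probability 0.9 when weights are the sizes themselves
        p = np.array([0.9, 0.1])
        hits = sum(
            select_victim(p, "power_weighted", rng, sigma=1.0) == 0
            for _ in range(20_000)
        )
        assert hits / 20_000 == pytest.approx(0.9, abs=0.01)

    def test_sigma_zero_is_uniform(self, rng):
        p = np.array([0.99, 0.005, 0.005])
        r1 = np.random.default_rng(5)
        r2 = np.random.default_rng(5)
        for _ in range(200):
            assert select_victim(p, "power_weighted", r1, sigma=0.0) == select_victim(
                p, "uniform", r2
            )

    def test_negative_exponent_matches_enumerated_weights(self, rng):
        # brute-force oracle: frequencies must match P^sigma / sum(P^sigma)
        p = np.array([0.64, 0.32, 0.04])
        sigma = -0.2
        expected = p**sigma / np.sum(p**sigma)
        counts = np.zeros(3)
        n_draws = 100_000
        for _ in range(n_draws):
            counts[select_victim(p, "power_weighted", rng, sigma=sigma)] += 1
        assert stats.chisquare(counts, expected * n_draws).pvalue > 1e-4

    def test_negative_exponent_rejects_zero_population(self, rng):
        with pytest.raises(ValueError, match="sigma < 0"):
            select_victim(np.array([0.0, 1.0]), "power_weighted", rng, sigma=-0.2)


class TestCollapseAndSaturation:
    def test_replace_leaves_unsaturated_gamma(self):
        state = make_state([0.5, 0.5])
        apply_collapse(state, 0, "replace_with_newcomer", gamma=0.1)
        assert_allclose(state.populations, [0.1, 0.5])
        assert state.species_id[0] == 2  # fresh id, never used before

    def test_shrink_keeps_species(self):
        state = make_state([0.9, 0.1])
        state.params_ref = SpeciesParams(gamma_i=np.array([0.01, 0.01]))
        apply_collapse(state, 0, "shrink_by_gamma_i")
        assert_allclose(state.populations, [0.009, 0.1])
        assert_array_equal(state.species_id, [0, 1])

    def test_common_rate_rescale(self):
        state = make_state([0.1, 0.5])
        factor = saturate(state)
        assert factor == pytest.approx(1 / 0.6)
        assert_allclose(state.populations, [1 / 6, 5 / 6])

    def test_saturated_input_is_identity(self):
        state = make_state([0.25, 0.75])
        assert saturate(state) == 1.0
        assert_allclose(state.populations, [0.25, 0.75])

    def test_oversaturated_rejected(self):
        with pytest.raises(ValueError, match="carrying capacity"):
            saturate(make_state([0.8, 0.8]))

    def test_per_species_equal_rates_match_common(self):
        s1 = make_state([0.1, 0.1])
        s2 = make_state([0.1, 0.1])
        saturate(s1)
        saturate(s2, omega=np.array([1.0, 1.0]))
        assert_allclose(s2.populations, s1.populations, atol=1e-10)
        assert_allclose(s2.populations, [0.5, 0.5], atol=1e-10)

    def test_per_species_closed_form_quadratic(self):
        # P = [0.1, 0.1], omega = [1, 2]: with x = e^A, 0.1 x + 0.1 x^2 = 1,
        # so x = (-1 + sqrt(41)) / 2 — the closed form is the oracle.
        state = make_state([0.1, 0.1])
        saturate(state, omega=np.array([1.0, 2.0]))
        x = (-1.0 + math.sqrt(41.0)) / 2.0
        assert_allclose(state.populations, [0.1 * x, 0.1 * x * x], rtol=1e-10)
        assert state.populations.sum() == pytest.approx(1.0, abs=1e-12)

    def test_per_species_matches_ode_integration(self):
        # independent cross-check: integrate dP_i/dt = w_i P_i (1 - sum P)
        p0 = np.array([0.05, 0.2, 0.01])
        omega = np.array([0.3, 1.0, 2.5])
        sol = solve_ivp(
            lambda t, p: omega * p * (1.0 - p.sum()),
            (0.0, 2000.0),
            p0,
            rtol=1e-11,
            atol=1e-14,
            dense_output=False,
        )
        state = make_state(p0.copy())
        saturate(state, omega=omega)
        assert_allclose(state.populations, sol.y[:, -1], rtol=1e-6)

    @given(
        scale=st.floats(0.05, 0.99),
        raw=st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=12),
    )
    def test_common_saturation_preserves_ratios(self, scale, raw):
        p = np.asarray(raw)
        p = p / p.sum() * scale
        state = make_state(p.copy())
        saturate(state)
        assert state.populations.sum() == pytest.approx(1.0, abs=1e-9)
        assert_allclose(state.populations, p / p.sum(), rtol=1e-12)

    def test_equalize(self):
        state = make_state([0.5, 0.2, 0.1, 0.1, 0.1])
        equalize_populations(state)
        assert_allclose(state.populations, [0.2] * 5)
        assert diversity(state.populations) == pytest.approx(5)


class TestStep:
    def test_single_step_composition(self):
        # forced victim 0 of [0.5, 0.5] at gamma=0.1: unsaturated [0.1, 0.5],
        # rescaled by 1/0.6 to [1/6, 5/6]
        params = ModelParams(N=2, gamma=0.1, seed=0)
        state = make_state([0.5, 0.5])
        # populations are symmetric, so either victim gives the same result
        state, event = step(state, params, np.random.default_rng(3), None)
        assert event.pre_collapse_size == pytest.approx(0.5)
        assert state.populations.sum() == pytest.approx(1.0, abs=1e-12)
        assert sorted(state.populations) == pytest.approx([1 / 6, 5 / 6])

    def test_dominant_collapse_rescales_by_inverse_gap(self):
        # survivors of a P=0.99 collapse grow by ~1/(1-0.99) = 100
        params = ModelParams(N=3, gamma=1e-8, seed=1)
        state = make_state([0.99, 0.005, 0.005])
        state, event = step(state, params, np.random.default_rng(11))
        if event.victim_index == 0:
            assert event.rescale_factor == pytest.approx(100.0, rel=0.01)

    def test_simulate_contracts(self):
        params = ModelParams(N=4, gamma=0.01, seed=42)
        rec = EventLogRecorder()
        summary = simulate(params, 10, recorders=[rec])
        assert [e.step for e in rec.events] == list(range(1, 11))
        assert summary.final_state.populations.sum() == pytest.approx(1, abs=1e-9)

    def test_normalization_every_step(self):
        class SumCheck(Recorder):
            def __init__(self):
                self.max_dev = 0.0

            def on_step(self, state, event):
                self.max_dev = max(
                    self.max_dev, abs(state.populations.sum() - 1.0)
                )

        chk = SumCheck()
        simulate(ModelParams(N=50, gamma=1e-6, seed=3), 5000, recorders=[chk])
        assert chk.max_dev <= 1e-9

    def test_same_seed_bit_identical(self):
        params = ModelParams(N=10, gamma=1e-4, seed=99)
        logs = []
        for _ in range(2):
            rec = EventLogRecorder()
            simulate(params, 500, recorders=[rec])
            logs.append([(e.victim_index, e.pre_collapse_size) for e in rec.events])
        assert logs[0] == logs[1]

    def test_newcomer_ids_never_reused(self):
        rec = EventLogRecorder()
        simulate(ModelParams(N=5, gamma=0.01, seed=7), 2000, recorders=[rec])
        # each step mints exactly one id; the victim's id was minted earlier
        minted = [e.victim_species_id for e in rec.events]
        assert all(sid < 5 + e.step for sid, e in zip(minted, rec.events))

    def test_dominant_collapse_lands_newcomer_near_gamma_N(self):
        # P_max = 1 - 1/N with gamma << 1/N: rescale factor ~ N, so the
        # newcomer ends near gamma * N
        N, gamma = 50, 1e-8
        params = ModelParams(N=N, gamma=gamma, seed=1)
        p = np.full(N, (1 / N) * (1 / (N - 1)) * 1.0)
        p[0] = 1 - 1 / N
        p[1:] = (1 / N) / (N - 1)
        state = make_state(p)
        for trial_seed in range(40):
            trial = state.copy()
            trial, event = step(trial, params, np.random.default_rng(trial_seed))
            if event.victim_index == 0:
                newcomer = trial.populations[np.argmin(trial.populations)]
                assert newcomer == pytest.approx(gamma * N, rel=0.01)
                break
        else:
            pytest.fail("no trial collapsed the dominant species")


class TestReferenceOracle:
    """The optimised stepper must reproduce a naive per-element stepper."""

    @pytest.mark.parametrize("equalize", [False, True])
    def test_basic_trajectory_identity(self, equalize):
        N, gamma, n_steps, seed = 6, 0.01, 1000, 1234
        traj, events = reference_run(
            N, gamma, n_steps, seed, equalize_at_wave_start=equalize
        )

        class Tracker(Recorder):
            def __init__(self):
                self.pops = []

            def on_step(self, state, event):
                self.pops.append(state.populations.copy())

        params = ModelParams(
            N=N, gamma=gamma, seed=seed, equalize_at_wave_start=equalize
        )
        trk = Tracker()
        rec = EventLogRecorder()
        simulate(params, n_steps, recorders=[trk, rec])
        for t in range(n_steps):
            assert_array_equal(trk.pops[t], np.array(traj[t + 1]))
        for ev, ref in zip(rec.events, events):
            assert (ev.step, ev.victim_index) == (ref[0], ref[1])
            assert ev.pre_collapse_size == ref[2]
            assert ev.is_wave_boundary == ref[3]
            assert ev.rescale_factor == ref[4]

    def test_size_weighted_trajectory_identity(self):
        N, gamma, n_steps, seed = 6, 0.01, 500, 77
        traj, _ = reference_run(
            N, gamma, n_steps, seed, victim_policy="size_proportional"
        )

        class Tracker(Recorder):
            def __init__(self):
                self.pops = []

            def on_step(self, state, event):
                self.pops.append(state.populations.copy())

        params = ModelParams(
            N=N, gamma=gamma, seed=seed, variant="ktw", variant_params={"sigma": 1.0}
        )
        trk = Tracker()
        simulate(params, n_steps, recorders=[trk])
        for t in range(n_steps):
            assert_array_equal(trk.pops[t], np.array(traj[t + 1]))
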