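"""Engine mechanics: placement, diffusion, boundaries, dimer events and
the phosphorylation state machine, tested on crafted states."""

import math

import numpy as np
import pytest
from scipy import stats

from erbbsim import _kernel
from erbbsim.engine import (
    SimulationInvariantError,
    advance,
    initialize,
    simulate,
)
from erbbsim.landscape import (
    build_empty_landscape,
    build_fixture_landscape,
)
from erbbsim.parameters import ParameterSet


def _quiet_params(**overrides):
    """Parameters with all reactions switched off unless overridden."""
    base = dict(
        k_on=0.0,
        k_off={"ErbB2/ErbB3": (0.0, 0.0), "ErbB3/ErbB3": (0.0, 0.0, 0.0),
               "ErbB2/ErbB2": (0.0,)},
        k_phos={"ErbB2": 0.0, "ErbB3": 0.0},
        k_phos_basal={"ErbB2": 0.0, "ErbB3": 0.0},
        k_dephos={"ErbB2": {"PY": 0.0}, "ErbB3": {"PY1197": 0.0, "PY1289": 0.0}},
        p_open=0.0,
    )
    base.update(overrides)
    return ParameterSet(**base)


def _make_dimer(state, i, j, x, y, activator):
    state.partner[i] = j
    state.partner[j] = i
    state.role[i] = 1 if activator == i else 2
    state.role[j] = 1 if activator == j else 2
    state.pos[i] = (x, y)
    state.pos[j] = (x, y)


class TestInitialize:
    def test_counts_and_initial_state(self):
        state = initialize(build_empty_landscape(), seed=0)
        assert state.n_species(0) == 31 and state.n_species(1) == 31
        assert np.all(state.partner == -1)
        assert not state.phos.any()

    @pytest.mark.parametrize("frac, expected", [(0.0, 0), (1.0, 31), (0.5, 16)])
    def test_ligand_fraction_rounding(self, frac, expected):
        state = initialize(build_empty_landscape(), ligand_fraction=frac, seed=1)
        assert state.liganded.sum() == expected
        assert not state.liganded[state.species == 0].any()

    def test_placement_avoids_other_species_domains(self):
        ls = build_fixture_landscape(0.0, seed=6)
        for seed in range(3):
            state = initialize(ls, seed=seed)
            for i in range(state.n):
                own = "ErbB2" if state.species[i] == 0 else "ErbB3"
                hits = ls.locate(state.pos[i, 0], state.pos[i, 1])
                # either free area or at least one domain of its own species
                assert not hits or any(d.species == own for d in hits)

    def test_receptors_do_populate_their_domains(self):
        ls = build_fixture_landscape(0.0, seed=6)
        state = initialize(ls, seed=3)
        in_own = 0
        for i in range(state.n):
            own = "ErbB2" if state.species[i] == 0 else "ErbB3"
            if any(d.species == own for d in ls.locate(*state.pos[i])):
                in_own += 1
        assert in_own > 0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            initialize(build_empty_landscape(), n_erbb2=0)
        with pytest.raises(ValueError):
            initialize(build_empty_landscape(), ligand_fraction=1.5)


class TestRandomness:
    def test_gaussian_step_generator(self):
        # the ziggurat sampler drives every Brownian displacement
        rng = _kernel.seed_rng(7)
        xs = np.array(
            [_kernel.normal01(rng, _kernel._ZIG_X, _kernel._ZIG_RATIO)
             for _ in range(100_000)]
        )
        assert abs(xs.mean()) < 0.02
        assert xs.std() == pytest.approx(1.0, abs=0.02)
        assert stats.kstest(xs, "norm").pvalue > 0.01

    def test_mean_squared_displacement_follows_brownian_law(self):
        # with reactions off, the net displacement over t has per-axis
        # variance 2*D*t for each species
        params = _quiet_params()
        t_tot = 0.05
        disp = {0: [], 1: []}
        for seed in range(5):
            state = initialize(build_empty_landscape(), seed=seed)
            p0 = state.pos.copy()
            advance(state, params, duration=t_tot, dt=1e-5, seed=seed + 50)
            d = state.pos - p0
            L = state.landscape.width
            d -= L * np.round(d / L)  # minimum-image displacement
            for s in (0, 1):
                disp[s].append(d[state.species == s])
        for s, D in ((0, 0.0272), (1, 0.013)):
            d = np.concatenate(disp[s]).ravel()  # both axes
            expected = 2 * D * t_tot
            assert d.var() == pytest.approx(expected, rel=0.15)
            assert abs(d.mean()) < 3 * math.sqrt(expected / d.size)

    def test_axes_uncorrelated(self):
        params = _quiet_params()
        dx, dy = [], []
        for seed in range(5):
            state = initialize(build_empty_landscape(), seed=seed)
            p0 = state.pos.copy()
            advance(state, params, duration=0.05, dt=1e-5, seed=seed)
            d = state.pos - p0
            L = state.landscape.width
            d -= L * np.round(d / L)
            dx.append(d[:, 0])
            dy.append(d[:, 1])
        r = np.corrcoef(np.concatenate(dx), np.concatenate(dy))[0, 1]
        assert abs(r) < 3.0 / math.sqrt(310)

    def test_same_seed_reproduces_run_exactly(self):
        ls = build_fixture_landscape(0.5, seed=1)
        a = simulate(ls, duration=0.5, dt=1e-5, seed=9)
        b = simulate(ls, duration=0.5, dt=1e-5, seed=9)
        c = simulate(ls, duration=0.5, dt=1e-5, seed=10)
        assert a.equals(b)
        assert not a.equals(c)


class TestConformation:
    def test_open_fraction_matches_flat_per_step_probability(self):
        # unliganded ErbB3 monomers are dimer-competent with probability
        # 1e-4 per step, independent of dt
        params = _quiet_params(p_open=1e-4)
        state = initialize(build_empty_landscape(), ligand_fraction=0.0, seed=2)
        df = advance(
            state, params, duration=40.0, dt=1e-3, obs_interval=1e-3, seed=3
        )
        samples = df["erbb3_open_monomers"].iloc[1:]
        n_draws = len(samples) * 31
        expected = 1e-4
        se = math.sqrt(expected * (1 - expected) / n_draws)
        assert samples.sum() / n_draws == pytest.approx(expected, abs=3 * se)

    def test_liganded_and_erbb2_always_open(self):
        state = initialize(build_empty_landscape(), ligand_fraction=1.0, seed=2)
        advance(state, _quiet_params(), duration=0.01, dt=1e-5, seed=3)
        assert state.open_[state.species == 0].all()
        assert state.open_[state.liganded].all()


class TestDomainBoundary:
    def _resolve(self, x0, y0, dx, dy, rect, p_esc, seed=1):
        rects = np.array([rect])
        idx = np.array([0], dtype=np.int64)
        rng = _kernel.seed_rng(seed)
        x, y, _, _ = _kernel.resolve_confinement(
            x0, y0, dx, dy, rects, idx, 1, p_esc, rng[0], rng[1]
        )
        return x, y

    def test_certain_escape_leaves_endpoint_unchanged(self):
        x, y = self._resolve(0.15, 0.15, 0.08, 0.0, (0.1, 0.1, 0.2, 0.2), 1.0)
        assert x == pytest.approx(0.23, abs=1e-9)
        assert y == pytest.approx(0.15)

    def test_zero_escape_reflects_specularly(self):
        # overshoot d past the right edge at x_b = 0.2 -> final x = x_b - d
        x, y = self._resolve(0.15, 0.15, 0.08, 0.0, (0.1, 0.1, 0.2, 0.2), 0.0)
        assert x == pytest.approx(0.2 - 0.03, abs=1e-9)
        assert y == pytest.approx(0.15)

    def test_zero_escape_reflects_on_lower_edge(self):
        x, y = self._resolve(0.15, 0.12, 0.0, -0.05, (0.1, 0.1, 0.2, 0.2), 0.0)
        assert y == pytest.approx(0.1 + 0.03, abs=1e-9)
        assert x == pytest.approx(0.15)

    def test_inbound_crossing_is_free(self):
        # entry takes no draw and does not alter the jump
        x, y = self._resolve(0.05, 0.15, 0.08, 0.0, (0.1, 0.1, 0.2, 0.2), 0.0)
        assert x == pytest.approx(0.13, abs=1e-9)

    def test_segment_missing_domain_unaffected(self):
        x, y = self._resolve(0.3, 0.3, 0.01, 0.01, (0.1, 0.1, 0.2, 0.2), 0.0)
        assert (x, y) == pytest.approx((0.31, 0.31))

    def test_confined_particle_never_leaks_at_zero_escape(self):
        # many successive reflections keep the particle inside its domain
        rects = np.array([(0.1, 0.1, 0.2, 0.2)])
        idx = np.array([0], dtype=np.int64)
        rng = _kernel.seed_rng(123)
        s0, s1 = rng[0], rng[1]
        x, y = 0.15, 0.15
        for _ in range(20_000):
            dx = _kernel.normal01(rng, _kernel._ZIG_X, _kernel._ZIG_RATIO) * 5e-3
            dy = _kernel.normal01(rng, _kernel._ZIG_X, _kernel._ZIG_RATIO) * 5e-3
            x, y, s0, s1 = _kernel.resolve_confinement(
                x, y, dx, dy, rects, idx, 1, 0.0, np.uint64(s0), np.uint64(s1)
            )
            assert 0.1 <= x < 0.2 and 0.1 <= y < 0.2


class TestPeriodicBoundary:
    @pytest.mark.parametrize(
        "v, L, expected",
        [
            (0.4466 + 0.003, 0.4466, 0.003),
            (-0.002, 0.4466, 0.4466 - 0.002),
            (0.25, 0.4466, 0.25),
        ],
    )
    def test_wrap_arithmetic(self, v, L, expected):
        assert _kernel.wrap_coordinate(v, L) == pytest.approx(expected)

    def test_positions_stay_in_box(self):
        df = simulate(build_empty_landscape(), duration=1.0, dt=1e-4, seed=5)
        assert len(df) == 21  # 0.05 s grid


class TestDimerization:
    def _state_with_pair(self, d, open3=True):
        # a liganded ErbB3 is constitutively open; an unliganded one stays
        # closed under p_open = 0
        ls = build_empty_landscape()
        state = initialize(
            ls, n_erbb2=1, n_erbb3=1,
            ligand_fraction=1.0 if open3 else 0.0, seed=0,
        )
        state.pos[0] = (0.2, 0.2)
        state.pos[1] = (0.2 + d, 0.2)
        return state

    def test_pair_within_radius_forms_dimer(self):
        r_b = np.array([1e-3, 1e-3, 1e-3])
        state = self._state_with_pair(0.5e-3)
        params = _quiet_params(D_monomer={"ErbB2": 0.0, "ErbB3": 0.0})
        advance(state, params, duration=1e-5, dt=1e-5, seed=1, r_b=r_b)
        assert state.partner[0] == 1 and state.partner[1] == 0
        assert sorted(state.role[:2]) == [1, 2]
        # dimer sits at the pair midpoint
        assert state.pos[0, 0] == pytest.approx(0.2 + 0.25e-3)
        assert np.array_equal(state.pos[0], state.pos[1])

    def test_pair_outside_radius_stays_monomeric(self):
        r_b = np.array([1e-3, 1e-3, 1e-3])
        state = self._state_with_pair(2e-3)
        params = _quiet_params(D_monomer={"ErbB2": 0.0, "ErbB3": 0.0})
        advance(state, params, duration=1e-5, dt=1e-5, seed=1, r_b=r_b)
        assert state.partner[0] == -1

    def test_closed_receptor_cannot_dimerize(self):
        r_b = np.array([1e-3, 1e-3, 1e-3])
        state = self._state_with_pair(0.5e-3, open3=False)
        params = _quiet_params(D_monomer={"ErbB2": 0.0, "ErbB3": 0.0})
        advance(state, params, duration=1e-5, dt=1e-5, seed=1, r_b=r_b)
        assert state.partner[0] == -1

    def test_closest_pair_wins_conflicts(self):
        # three open ErbB2 in a row: the closer pair binds, one is left out
        ls = build_empty_landscape()
        state = initialize(ls, n_erbb2=3, n_erbb3=1, ligand_fraction=0.0, seed=0)
        state.pos[0] = (0.2, 0.2)
        state.pos[1] = (0.2 + 0.3e-3, 0.2)
        state.pos[2] = (0.2 + 0.9e-3, 0.2)
        state.pos[3] = (0.4, 0.4)
        params = _quiet_params(
            D_monomer={"ErbB2": 0.0, "ErbB3": 0.0},
            erbb2_homodimer_on_multiplier=1.0,
        )
        advance(state, params, duration=1e-5, dt=1e-5, seed=1,
                r_b=np.array([1e-3, 1e-3, 1e-3]))
        assert state.partner[0] == 1 and state.partner[1] == 0
        assert state.partner[2] == -1

    def test_erbb2_homodimer_on_multiplier_zero_blocks_2_2(self):
        ls = build_empty_landscape()
        state = initialize(ls, n_erbb2=2, n_erbb3=1, ligand_fraction=0.0, seed=0)
        state.pos[0] = (0.2, 0.2)
        state.pos[1] = (0.2005, 0.2)
        state.pos[2] = (0.4, 0.4)
        params = _quiet_params(
            D_monomer={"ErbB2": 0.0, "ErbB3": 0.0},
            erbb2_homodimer_on_multiplier=0.0,
        )
        advance(state, params, duration=1e-4, dt=1e-5, seed=1,
                r_b=np.array([1e-3, 1e-3, 1e-3]))
        assert state.partner[0] == -1


class TestDissociation:
    def test_zero_off_rate_never_dissociates(self):
        ls = build_empty_landscape()
        state = initialize(ls, n_erbb2=1, n_erbb3=1, ligand_fraction=1.0, seed=0)
        _make_dimer(state, 0, 1, 0.2, 0.2, activator=0)
        params = _quiet_params(D_monomer={"ErbB2": 0.0, "ErbB3": 0.0})
        advance(state, params, duration=0.01, dt=1e-5, seed=4,
                r_b=np.array([0.0, 0.0, 0.0]))
        assert state.partner[0] == 1

    def test_separation_is_five_binding_radii_and_state_reset(self):
        ls = build_empty_landscape()
        state = initialize(ls, n_erbb2=1, n_erbb3=1, ligand_fraction=1.0, seed=0)
        _make_dimer(state, 0, 1, 0.2, 0.2, activator=0)
        state.phos[0, 0] = True  # phosphorylation must survive dissociation
        r_b = 1e-3
        params = _quiet_params(
            D_monomer={"ErbB2": 0.0, "ErbB3": 0.0},
            k_off={"ErbB2/ErbB3": (1e9, 1e9), "ErbB3/ErbB3": (1e9, 1e9, 1e9),
                   "ErbB2/ErbB2": (1e9,)},
        )
        advance(state, params, duration=1e-5, dt=1e-5, seed=4,
                r_b=np.array([r_b, r_b, r_b]))
        assert state.partner[0] == -1 and state.partner[1] == -1
        assert state.role[0] == 0 and state.role[1] == 0
        assert state.phos[0, 0]
        d = state.pos[1] - state.pos[0]
        L = ls.width
        d -= L * np.round(d / L)
        assert math.hypot(*d) == pytest.approx(5 * r_b, rel=1e-9)


class TestPhosphorylation:
    def _hetero_state(self, activator):
        ls = build_empty_landscape()
        state = initialize(ls, n_erbb2=1, n_erbb3=1, ligand_fraction=0.0, seed=0)
        _make_dimer(state, 0, 1, 0.2, 0.2, activator=activator)
        return state

    def test_erbb3_activator_with_erbb2_receiver_uses_full_rate(self):
        # k = 0.078/s: after 100 s each site is phosphorylated with
        # probability 1 - exp(-7.8) ~ 0.9996
        hits = 0
        for seed in range(10):
            state = self._hetero_state(activator=1)
            params = _quiet_params(
                D_monomer={"ErbB2": 0.0, "ErbB3": 0.0},
                k_phos={"ErbB2": 0.146, "ErbB3": 0.078},
            )
            advance(state, params, duration=100.0, dt=1e-2, seed=seed,
                    r_b=np.array([0.0, 0.0, 0.0]))
            if state.phos[1].any():
                hits += 1
            # the receiver is never phosphorylated by its own kinase
            assert not state.phos[0, 0]
        assert hits >= 9

    def test_erbb3_activator_with_naive_erbb3_receiver_uses_basal_rate(self):
        # k = 7e-5/s: expected events over 100 s ~ 0.014 across both sites
        hits = 0
        for seed in range(10):
            ls = build_empty_landscape()
            state = initialize(ls, n_erbb2=1, n_erbb3=2, ligand_fraction=0.0, seed=0)
            _make_dimer(state, 1, 2, 0.2, 0.2, activator=1)
            state.pos[0] = (0.4, 0.4)
            params = _quiet_params(
                D_monomer={"ErbB2": 0.0, "ErbB3": 0.0},
                k_phos={"ErbB2": 0.146, "ErbB3": 0.078},
                k_phos_basal={"ErbB2": 0.073, "ErbB3": 0.00007},
            )
            advance(state, params, duration=100.0, dt=1e-2, seed=seed,
                    r_b=np.array([0.0, 0.0, 0.0]))
            if state.phos[1].any():
                hits += 1
        assert hits <= 2

    def test_phosphorylated_erbb3_receiver_enables_full_rate(self):
        hits = 0
        for seed in range(10):
            ls = build_empty_landscape()
            state = initialize(ls, n_erbb2=1, n_erbb3=2, ligand_fraction=0.0, seed=0)
            _make_dimer(state, 1, 2, 0.2, 0.2, activator=1)
            state.phos[2, 0] = True  # receiver previously activated
            state.pos[0] = (0.4, 0.4)
            params = _quiet_params(
                D_monomer={"ErbB2": 0.0, "ErbB3": 0.0},
                k_phos={"ErbB2": 0.146, "ErbB3": 0.078},
            )
            advance(state, params, duration=100.0, dt=1e-2, seed=seed,
                    r_b=np.array([0.0, 0.0, 0.0]))
            if state.phos[1].any():
                hits += 1
        assert hits >= 9

    def test_isolated_phosphorylated_monomer_decays_to_zero(self):
        # no kinase source for monomers: dephosphorylation wins
        ls = build_empty_landscape()
        state = initialize(ls, n_erbb2=1, n_erbb3=1, ligand_fraction=0.0, seed=0)
        state.phos[0, 0] = True
        params = _quiet_params(
            D_monomer={"ErbB2": 0.0, "ErbB3": 0.0},
            k_dephos={"ErbB2": {"PY": 0.2},
                      "ErbB3": {"PY1197": 0.013, "PY1289": 0.06}},
        )
        df = advance(state, params, duration=100.0, dt=1e-2, seed=8,
                     r_b=np.array([0.0, 0.0, 0.0]))
        assert not state.phos[0, 0]
        assert df["erbb2_phos"].iloc[-1] == 0


class TestStepInvariants:
    def test_species_conservation_on_every_row(self):
        ls = build_fixture_landscape(0.5, seed=3)
        df = simulate(ls, duration=2.0, dt=1e-5, seed=6)
        tot2 = df.erbb2_monomers + df.heterodimers + 2 * df.erbb2_homodimers
        tot3 = df.erbb3_monomers + df.heterodimers + 2 * df.erbb3_homodimers
        assert (tot2 == 31).all() and (tot3 == 31).all()

    def test_initial_observation_row(self):
        df = simulate(build_empty_landscape(), duration=0.05, dt=1e-4, seed=0)
        first = df.iloc[0]
        assert first.erbb2_monomers == 31 and first.erbb3_monomers == 31
        assert first.heterodimers == 0 and first.erbb2_phos == 0

    def test_partner_symmetry_checker_catches_corruption(self):
        state = initialize(build_empty_landscape(), seed=0)
        state.partner[0] = 5  # one-sided link
        with pytest.raises(SimulationInvariantError):
            state.check_invariants()
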