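import numpy as np
import pytest

from pggsim import (
    ExtinctPopulationError,
    PopulationState,
    build_config,
    contribution_rates,
    draw_offspring,
    harvest_phase,
    init_population,
    mutate_probabilities,
    offspring_count,
    offspring_counts,
    public_goods_phase,
    reproduction_matrix,
)


def make_state(n_selfish, n_generous, t=0, phi=0.1, gamma=0.01, omega=0.01, prev=None):
    n = n_selfish + n_generous
    selfish = np.zeros(n, bool)
    selfish[:n_selfish] = True
    return PopulationState(
        t=t,
        selfish=selfish,
        phi=np.full(n, float(phi)),
        gamma=np.full(n, float(gamma)),
        omega=np.full(n, float(omega)),
        prev_mean_contribution=prev,
    )


class TestHarvestPhase:
    def test_harvest_fractions_of_per_capita_share(self, default_config, rng):
        # 250 agents on e_tot = 1125: share 4.5, below the cap for G, at it for S
        state = make_state(25, 225)
        cfg = default_config.with_updates(m_S=0.0)
        out = harvest_phase(state, cfg, rng)
        assert out.e_t == pytest.approx(4.5)
        assert out.harvest[state.selfish] == pytest.approx(3.6)
        assert out.harvest[~state.selfish] == pytest.approx(2.25)

    def test_cap_binds_when_population_halves(self, default_config, rng):
        # 125 agents on e_tot = 1125: share 9, both phenotypes capped at 4.5
        state = make_state(13, 112)
        cfg = default_config.with_updates(m_S=0.0)
        out = harvest_phase(state, cfg, rng)
        assert out.e_t == pytest.approx(9.0)
        assert out.harvest == pytest.approx(4.5)

    def test_zero_mortality_kills_nobody(self, default_config, rng):
        state = make_state(50, 50)
        out = harvest_phase(state, default_config.with_updates(m_S=0.0), rng)
        assert out.alive.all()

    def test_certain_mortality_kills_all_selfish_only(self, default_config, rng):
        state = make_state(50, 50)
        out = harvest_phase(state, default_config.with_updates(m_S=1.0), rng)
        assert not out.alive[state.selfish].any()
        assert out.alive[~state.selfish].all()
        assert out.harvest[state.selfish] == pytest.approx(0.0)

    def test_share_uses_premortality_headcount(self, default_config, rng):
        # all selfish die, yet survivors' share is still e_tot / 100
        state = make_state(50, 50)
        cfg = default_config.with_updates(m_S=1.0, e_tot=450.0)
        out = harvest_phase(state, cfg, rng)
        assert out.e_t == pytest.approx(4.5)
        assert out.harvest[~state.selfish] == pytest.approx(2.25)

    def test_empty_population_signals_extinction(self, default_config, rng):
        with pytest.raises(ExtinctPopulationError):
            harvest_phase(PopulationState.empty(3), default_config, rng)


class TestContributionRates:
    def test_unconditional_rates(self, default_config):
        state = make_state(2, 3)
        c = contribution_rates(state, default_config)
        assert c[state.selfish] == pytest.approx(0.2)
        assert c[~state.selfish] == pytest.approx(1.0)

    def test_conditional_cooperators_start_fully_cooperative(self, default_config):
        cfg = default_config.with_updates(conditional_cooperation=True)
        c = contribution_rates(make_state(1, 1, t=0), cfg)
        assert c[1] == pytest.approx(1.0)

    def test_conditional_cooperators_copy_previous_mean(self, default_config):
        cfg = default_config.with_updates(conditional_cooperation=True)
        # previous rates (1, 1, 0.2, 0.2) -> mean 0.6
        c = contribution_rates(make_state(1, 1, t=1, prev=0.6), cfg)
        assert c[1] == pytest.approx(0.6)
        assert c[0] == pytest.approx(0.2)
        # an all-selfish previous generation propagates 0.2
        c2 = contribution_rates(make_state(1, 1, t=5, prev=0.2), cfg)
        assert c2[1] == pytest.approx(0.2)

    def test_missing_previous_mean_is_an_error(self, default_config):
        cfg = default_config.with_updates(conditional_cooperation=True)
        with pytest.raises(ValueError, match="previous"):
            contribution_rates(make_state(1, 1, t=1, prev=None), cfg)


class TestPublicGoodsPhase:
    """Worked two-agent example: S harvests 3.6 and contributes 20%,
    G harvests 2.25 and contributes all."""

    harvests = np.array([3.6, 2.25])
    selfish = np.array([True, False])
    rates = np.array([0.2, 1.0])

    def test_pot_and_fitness(self, default_config):
        cfg = default_config.with_updates(lam=0.0)
        out = public_goods_phase(self.harvests, self.selfish, self.rates, cfg)
        assert out.pot == pytest.approx(2.97)
        assert out.payout == pytest.approx(1.5 * 2.97 / 2)
        assert out.fitness[0] == pytest.approx(5.1075)
        assert out.fitness[1] == pytest.approx(2.2275)

    def test_community_cost_reduces_pot_per_selfish_agent(self, default_config):
        cfg = default_config.with_updates(lam=50.0)
        out = public_goods_phase(self.harvests, self.selfish, self.rates, cfg)
        assert out.pot == pytest.approx(2.97 - 0.5)

    def test_pot_floored_at_zero(self, default_config):
        cfg = default_config.with_updates(lam=100.0)
        out = public_goods_phase(
            np.array([0.4, 0.4]), np.array([True, True]), np.array([0.2, 0.2]), cfg
        )
        assert out.pot == 0.0
        assert (out.fitness >= 0).all()

    def test_individual_cost_charged_to_selfish_only(self, default_config):
        base = public_goods_phase(
            self.harvests, self.selfish, self.rates, default_config
        )
        cfg = default_config.with_updates(individual_cost=True, alpha=0.1)
        out = public_goods_phase(self.harvests, self.selfish, self.rates, cfg)
        assert out.fitness[0] == pytest.approx(base.fitness[0] - 0.1)
        assert out.fitness[1] == pytest.approx(base.fitness[1])

    def test_single_agent_receives_own_multiplied_contribution(self, default_config):
        out = public_goods_phase(
            np.array([2.25]), np.array([False]), np.array([1.0]), default_config
        )
        assert out.fitness[0] == pytest.approx(1.5 * 2.25)

    def test_conservation_without_costs(self, default_config, rng):
        n = 40
        harvests = rng.uniform(0, 4.5, n)
        selfish = rng.random(n) < 0.5
        rates = np.where(selfish, 0.2, 1.0)
        out = public_goods_phase(harvests, selfish, rates, default_config)
        retained = (harvests * (1 - rates)).sum()
        assert out.fitness.sum() == pytest.approx(
            1.5 * out.pot + retained, rel=1e-12
        )


class TestOffspringCount:
    @pytest.mark.parametrize(
        "f,expected",
        [
            (1.0, 0),      # at the survival threshold
            (0.5, 0),
            (-2.0, 0),     # negative fitness allowed, no offspring
            (11.0, 10),    # at saturation
            (50.0, 10),
            (5.1075, 5),   # ceil(4.1075)
            (1.0001, 1),
            (2.0, 1),      # ceil(1.0) exactly
            (2.0001, 2),
        ],
    )
    def test_piecewise_rule(self, default_config, f, expected):
        assert offspring_count(f, default_config) == expected

    def test_vectorized_matches_scalar(self, default_config, rng):
        fs = rng.uniform(-1, 13, 200)
        vec = offspring_counts(fs, default_config)
        assert all(vec[i] == offspring_count(f, default_config) for i, f in enumerate(fs))


class TestReproductionMatrix:
    def test_published_initial_rates(self):
        mat = reproduction_matrix(0.1, 0.01, 0.01)
        assert mat.phi_GG == pytest.approx(0.91)
        assert mat.phi_GS == pytest.approx(0.09)
        assert mat.phi_SS == pytest.approx(0.11)
        assert mat.phi_SG == pytest.approx(0.89)

    def test_neutral_symmetric_point(self):
        mat = reproduction_matrix(0.5, 0.0, 0.0)
        assert mat.phi_GS == mat.phi_SS == 0.5

    def test_rows_sum_to_one_exactly(self, rng):
        phi = rng.random(100)
        gamma = rng.random(100) * (1 - phi)
        omega = rng.random(100) * phi
        mat = reproduction_matrix(phi, gamma, omega)
        np.testing.assert_allclose(mat.phi_GG + mat.phi_GS, 1.0, rtol=0, atol=1e-12)
        np.testing.assert_allclose(mat.phi_SS + mat.phi_SG, 1.0, rtol=0, atol=1e-12)


class TestDrawOffspring:
    def test_zero_counts_give_empty_cohort(self, default_config, rng):
        state = make_state(1, 1)
        sel, phi, gamma, omega = draw_offspring(
            state.selfish, state.phi, state.gamma, state.omega,
            np.zeros(2, int), default_config, rng,
        )
        assert sel.size == 0

    def test_offspring_inherit_parent_traits_verbatim(self, default_config, rng):
        state = make_state(1, 1, phi=0.3, gamma=0.2, omega=0.25)
        sel, phi, gamma, omega = draw_offspring(
            state.selfish, state.phi, state.gamma, state.omega,
            np.array([2, 3]), default_config, rng,
        )
        assert sel.size == 5
        assert (phi == 0.3).all() and (gamma == 0.2).all() and (omega == 0.25).all()

    def test_perfect_transmission_copies_phenotype(self, rng):
        cfg = build_config(perfect_transmission=True)
        state = make_state(1, 0)
        sel, *_ = draw_offspring(
            state.selfish, state.phi, state.gamma, state.omega,
            np.array([10]), cfg, rng,
        )
        assert sel.all()

    def test_generous_parent_selfish_rate_matches_matrix(self, default_config, rng):
        # phi - omega = 0.09; binomial check over 10^4 draws, 3 SE band
        state = make_state(0, 1)
        n = 10_000
        sel, *_ = draw_offspring(
            state.selfish, state.phi, state.gamma, state.omega,
            np.array([n]), default_config, rng,
        )
        p = 0.09
        se = np.sqrt(p * (1 - p) / n)
        assert abs(sel.mean() - p) < 3 * se


class _FixedNoise:
    """Stub generator returning preset normal draws (in call order)."""

    def __init__(self, *vectors):
        self._vectors = list(vectors)

    def normal(self, loc, scale, size):
        v = np.asarray(self._vectors.pop(0), dtype=float)
        assert v.size == size
        return v


class TestMutation:
    def test_disabled_mutation_is_identity(self, rng):
        cfg = build_config(mutation_enabled=False)
        phi, gamma, omega = np.array([0.3]), np.array([0.1]), np.array([0.2])
        out = mutate_probabilities(phi, gamma, omega, cfg, rng)
        assert out[0] == pytest.approx(0.3)
        assert out[1] == pytest.approx(0.1)
        assert out[2] == pytest.approx(0.2)

    def test_zero_variance_noise_leaves_valid_agent_unchanged(self, rng):
        cfg = build_config(sigma2_phi=0.0, sigma2_gamma=0.0, sigma2_omega=0.0)
        out = mutate_probabilities(
            np.array([0.4]), np.array([0.3]), np.array([0.2]), cfg, rng
        )
        assert out[0][0] == 0.4 and out[1][0] == 0.3 and out[2][0] == 0.2

    def test_clipping_order_phi_first(self, default_config):
        # phi 0.99 + 0.05 clips to 1, then gamma clips into [0, 1-phi] = {0}
        fake = _FixedNoise([0.05], [0.0], [0.0])
        phi, gamma, omega = mutate_probabilities(
            np.array([0.99]), np.array([0.05]), np.array([0.5]),
            default_config, fake,
        )
        assert phi[0] == 1.0
        assert gamma[0] == 0.0
        assert omega[0] == 0.5  # still within [0, phi] = [0, 1]

    def test_noise_is_mean_zero_away_from_boundaries(self, rng):
        cfg = build_config()
        n = 100_000
        phi = np.full(n, 0.5)
        gamma = np.full(n, 0.2)
        omega = np.full(n, 0.2)
        new_phi, _, _ = mutate_probabilities(phi, gamma, omega, cfg, rng)
        se = 0.1 / np.sqrt(n)
        assert abs(new_phi.mean() - 0.5) < 3 * se
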