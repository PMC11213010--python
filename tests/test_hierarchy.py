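"""Joint density of the hierarchical model and its control-guide constraint."""

import numpy as np
import pytest
from scipy import stats

from sortscreen.hierarchy import (
    Hyperparameters,
    ModelState,
    init_bins_from_controls,
    log_joint,
    sample_prior,
)
from sortscreen.marker import bin_masses, dirmult_logpmf
from sortscreen.screen_io import BinCountTable, GuideLibrary

HYPER = Hyperparameters()


def _random_state(library, rng, n_reps=2, n_bins=4) -> ModelState:
    gidx, genes = library.gene_index()
    G = len(genes)
    psi = rng.integers(0, 2, G)
    sigma, tau, pi = 0.8, 0.2, 0.15
    mu = np.where(psi == 1, rng.normal(0, sigma, G), 0.0)
    beta = np.zeros(library.n_guides)
    tg = ~library.is_control
    beta[tg] = mu[gidx[tg]] + rng.normal(0, tau, tg.sum())
    return ModelState(psi=psi, mu=mu, beta=beta,
                      w=rng.dirichlet(np.full(n_bins, 4.0), size=n_reps),
                      phi=rng.gamma(2.0, 50.0, n_reps),
                      sigma=sigma, tau=tau, pi=pi)


def _oracle_log_joint(state, data, library, hyper):
    """Independent term-by-term recomputation with scipy distributions."""
    hyper = hyper.resolved(data.n_bins)
    gidx, genes = library.gene_index()
    total = 0.0
    for n in range(data.n_replicates):
        t = np.concatenate([[0.0], np.cumsum(state.w[n])])
        t[-1] = 1.0
        from sortscreen.marker import BinScheme
        scheme = BinScheme(t)
        for h in range(data.n_guides):
            q = bin_masses(scheme, state.beta[h])
            total += stats.dirichlet_multinomial.logpmf(
                data.counts[n, h], state.phi[n] * q, int(data.totals[n, h]))
    for g in range(len(genes)):
        total += np.log(state.pi) if state.psi[g] else np.log1p(-state.pi)
        if state.psi[g]:
            total += stats.norm.logpdf(state.mu[g], 0, state.sigma)
    for h in range(library.n_guides):
        if not library.is_control[h]:
            total += stats.norm.logpdf(state.beta[h], state.mu[gidx[h]], state.tau)
    total += stats.halfcauchy.logpdf(state.sigma, scale=hyper.sigma_scale)
    total += stats.halfcauchy.logpdf(state.tau, scale=hyper.tau_scale)
    total += stats.beta.logpdf(state.pi, hyper.pi_a, hyper.pi_b)
    for n in range(data.n_replicates):
        total += stats.dirichlet.logpdf(state.w[n] / state.w[n].sum(),
                                        hyper.alpha_t * hyper.w0)
        total += stats.gamma.logpdf(state.phi[n], hyper.phi_shape,
                                    scale=1 / hyper.phi_rate)
    return total


class TestLogJoint:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_term_decomposition_oracle(self, small_library, small_table, seed):
        state = _random_state(small_library, np.random.default_rng(seed))
        assert np.isclose(
            log_joint(state, small_table, small_library, HYPER),
            _oracle_log_joint(state, small_table, small_library, HYPER),
            atol=1e-8,
        )

    def test_single_beta_change_is_local(self, small_library, small_table):
        rng = np.random.default_rng(3)
        state = _random_state(small_library, rng)
        state2 = ModelState(**{**state.__dict__})
        state2.beta = state.beta.copy()
        h = 1
        state2.beta[h] += 0.37
        gidx, _ = small_library.gene_index()
        delta = 0.0
        for n in range(small_table.n_replicates):
            t = np.concatenate([[0.0], np.cumsum(state.w[n])])
            t[-1] = 1.0
            from sortscreen.marker import BinScheme
            scheme = BinScheme(t)
            for b, st_ in ((state2.beta[h], 1), (state.beta[h], -1)):
                delta += st_ * dirmult_logpmf(small_table.counts[n, h],
                                              int(small_table.totals[n, h]),
                                              state.phi[n], bin_masses(scheme, b))
        delta += stats.norm.logpdf(state2.beta[h], state.mu[gidx[h]], state.tau) \
            - stats.norm.logpdf(state.beta[h], state.mu[gidx[h]], state.tau)
        assert np.isclose(
            log_joint(state2, small_table, small_library, HYPER)
            - log_joint(state, small_table, small_library, HYPER),
            delta, atol=1e-8)

    def test_null_state_likelihood_reduces_to_equal_bins(self, small_library, small_table):
        G = len(small_library.genes)
        state = ModelState(psi=np.zeros(G, int), mu=np.zeros(G),
                           beta=np.zeros(small_library.n_guides),
                           w=np.full((2, 4), 0.25), phi=np.array([50.0, 80.0]),
                           sigma=1.0, tau=0.2, pi=0.1)
        zero = BinCountTable(np.zeros_like(small_table.counts), small_table.guide_id,
                             small_table.replicate_labels, small_table.bin_labels)
        lik = log_joint(state, small_table, small_library, HYPER) \
            - log_joint(state, zero, small_library, HYPER)
        expected = sum(
            dirmult_logpmf(small_table.counts[n, h], int(small_table.totals[n, h]),
                           state.phi[n], np.full(4, 0.25))
            for n in range(2) for h in range(small_table.n_guides))
        assert np.isclose(lik, expected, atol=1e-8)

    def test_inclusion_impossible_at_pi_zero(self, small_library, small_table):
        state = _random_state(small_library, np.random.default_rng(5))
        state.psi[:] = 1
        state.pi = 0.0
        assert log_joint(state, small_table, small_library, HYPER) == -np.inf

    def test_malformed_state_raises_not_minus_inf(self, small_library, small_table):
        state = _random_state(small_library, np.random.default_rng(6))
        state.beta[-1] = 0.5  # control guide
        with pytest.raises(ValueError, match="control"):
            log_joint(state, small_table, small_library, HYPER)

    def test_invariant_to_guide_and_replicate_order(self, small_library, small_table):
        rng = np.random.default_rng(7)
        state = _random_state(small_library, rng)
        base = log_joint(state, small_table, small_library, HYPER)
        perm = rng.permutation(small_table.n_guides)
        table_p = BinCountTable(small_table.counts[::-1, perm, :],
                                small_table.guide_id[perm],
                                small_table.replicate_labels[::-1],
                                small_table.bin_labels)
        lib_p = GuideLibrary(small_library.guide_id[perm], small_library.gene_id[perm],
                             small_library.is_control[perm])
        state_p = ModelState(psi=state.psi, mu=state.mu, beta=state.beta[perm],
                             w=state.w[::-1], phi=state.phi[::-1],
                             sigma=state.sigma, tau=state.tau, pi=state.pi)
        # gene_index order may differ; map psi/mu through the permuted gene list
        gidx_p, genes_p = lib_p.gene_index()
        _, genes = small_library.gene_index()
        remap = [genes.index(g) for g in genes_p]
        state_p.psi, state_p.mu = state.psi[remap], state.mu[remap]
        assert np.isclose(log_joint(state_p, table_p, lib_p, HYPER), base, atol=1e-8)

    def test_all_controls_depends_only_on_bins_and_dispersion(self):
        ids = np.array([f"c{i}" for i in range(5)], object)
        lib = GuideLibrary(ids, np.array([""] * 5, object), np.ones(5, bool))
        rng = np.random.default_rng(8)
        counts = rng.multinomial(100, [0.25] * 4, size=(1, 5))
        table = BinCountTable(counts, ids, ["r1"], ["b1", "b2", "b3", "b4"])
        s1 = ModelState(psi=np.zeros(0, int), mu=np.zeros(0), beta=np.zeros(5),
                        w=np.full((1, 4), 0.25), phi=np.array([40.0]),
                        sigma=1.0, tau=0.2, pi=0.1)
        s2 = ModelState(psi=np.zeros(0, int), mu=np.zeros(0), beta=np.zeros(5),
                        w=np.full((1, 4), 0.25), phi=np.array([40.0]),
                        sigma=2.0, tau=0.7, pi=0.4)
        lj1 = log_joint(s1, table, lib, HYPER)
        lj2 = log_joint(s2, table, lib, HYPER)
        # differ only through hyperprior terms, not through any beta term
        hyper_delta = (stats.halfcauchy.logpdf(2.0, scale=1) - stats.halfcauchy.logpdf(1.0, scale=1)
                       + stats.halfcauchy.logpdf(0.7, scale=0.5) - stats.halfcauchy.logpdf(0.2, scale=0.5)
                       + stats.beta.logpdf(0.4, 1, 9) - stats.beta.logpdf(0.1, 1, 9))
        assert np.isclose(lj2 - lj1, hyper_delta, atol=1e-10)


class TestSamplePrior:
    def test_point_mass_pi_zero(self, small_library):
        hyper = Hyperparameters(pi_a=0.0)
        state = sample_prior(small_library, 2, 4, hyper, np.random.default_rng(0))
        assert not state.psi.any() and not state.mu.any()

    def test_inclusion_fraction_matches_beta_mean(self):
        # many genes, one guide each: fraction of psi=1 ~ E[pi] = 0.1
        n = 2000
        ids = np.array([f"g{i}" for i in range(n)] + ["c"], object)
        genes = np.array([f"x{i}" for i in range(n)] + [""], object)
        lib = GuideLibrary(ids, genes, np.array([False] * n + [True]))
        rng = np.random.default_rng(1)
        fracs = [sample_prior(lib, 1, 4, HYPER, rng).psi.mean() for _ in range(40)]
        se = np.sqrt(0.1 * 0.9 / (n * 40)) + np.std(fracs) / np.sqrt(40)
        assert abs(np.mean(fracs) - 0.1) < 3 * se

    def test_slab_draws_standardize_to_unit_normal(self, small_library):
        rng = np.random.default_rng(2)
        z = []
        for _ in range(4000):
            s = sample_prior(small_library, 1, 4, HYPER, rng)
            z.extend(s.mu[s.psi == 1] / s.sigma)
        z = np.asarray(z)
        assert abs(z.mean()) < 3 / np.sqrt(z.size)
        assert abs(z.std() - 1.0) < 0.05

    def test_controls_clamped_and_state_valid(self, small_library):
        state = sample_prior(small_library, 2, 4, HYPER, np.random.default_rng(3))
        state.validate(small_library)
        assert np.all(state.beta[small_library.is_control] == 0)


class TestInitBinsFromControls:
    def test_conjugate_posterior_mean_by_hand(self, small_library):
        counts = np.zeros((1, 8, 4), int)
        counts[0, 6] = [100, 200, 200, 100]   # ctrl_1
        counts[0, 7] = [50, 150, 150, 50]     # ctrl_2 -> pooled (150,350,350,150)
        table = BinCountTable(counts, small_library.guide_id, ["r1"],
                              ["b1", "b2", "b3", "b4"])
        [scheme] = init_bins_from_controls(table, small_library,
                                           Hyperparameters(alpha_t=4.0))
        assert np.allclose(scheme.masses, np.array([151, 351, 351, 151]) / 1004)

    def test_vanishing_prior_recovers_empirical_proportions(self, small_library):
        counts = np.zeros((1, 8, 4), int)
        counts[0, 6] = [10, 20, 30, 40]
        table = BinCountTable(counts, small_library.guide_id, ["r1"],
                              ["b1", "b2", "b3", "b4"])
        [scheme] = init_bins_from_controls(table, small_library,
                                           Hyperparameters(alpha_t=1e-9))
        assert np.allclose(scheme.masses, [0.1, 0.2, 0.3, 0.4], atol=1e-9)

    def test_replicates_are_independent(self, small_library):
        counts = np.zeros((2, 8, 4), int)
        counts[0, 6] = [100, 100, 100, 100]
        counts[1, 6] = [10, 20, 30, 40]
        table = BinCountTable(counts, small_library.guide_id, ["r1", "r2"],
                              ["b1", "b2", "b3", "b4"])
        s1, s2 = init_bins_from_controls(table, small_library)
        assert not np.allclose(s1.masses, s2.masses)

    def test_zero_controls_without_fallback_errors(self, small_library):
        counts = np.ones((1, 8, 4), int)
        counts[0, 6:] = 0
        table = BinCountTable(counts, small_library.guide_id, ["r1"],
                              ["b1", "b2", "b3", "b4"])
        with pytest.raises(ValueError, match="control"):
            init_bins_from_controls(table, small_library)
        schemes = init_bins_from_controls(table, small_library, fallback_all_guides=True)
        assert len(schemes) == 1

    def test_no_control_library_falls_back_to_median_composition(self):
        ids = np.array(["a", "b", "c"], object)
        lib = GuideLibrary(ids, np.array(["x", "y", "z"], object),
                           np.zeros(3, bool), allow_no_controls=True)
        counts = np.tile(np.array([[10, 20, 30, 40]]), (3, 1))[None, :, :]
        table = BinCountTable(counts, ids, ["r1"], ["b1", "b2", "b3", "b4"])
        [scheme] = init_bins_from_controls(table, lib, Hyperparameters(alpha_t=1e-9))
        assert np.allclose(scheme.masses, [0.1, 0.2, 0.3, 0.4], atol=1e-6)
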