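import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoinfer import AnalysisConfig, PeptideDataset, build_prior, run_mcmc
from isoinfer.data import ValidationError
from isoinfer.mcmc import (
    allocate_peptide,
    allocation_probabilities,
    sample_misdetection,
    sample_pi,
)
from isoinfer.prior import PriorSpec

from conftest import make_record


class TestMisdetection:
    def test_degenerate_probabilities(self, rng):
        eps = sample_misdetection(np.array([0.0, 1.0, 0.0, 1.0]), rng)
        assert eps.tolist() == [0, 1, 0, 1]

    def test_bernoulli_rate(self, rng):
        n = 10**5
        eps = sample_misdetection(np.full(n, 0.3), rng)
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(eps.mean() - 0.3) < 3 * se

    def test_missing_pep_is_an_error(self, rng):
        with pytest.raises(ValidationError, match="PEP"):
            sample_misdetection(np.array([0.1, np.nan]), rng)


class TestAllocationProbabilities:
    def test_hand_computed_weights(self):
        # weights pi/M = (0.6/2, 0.4/1) -> normalized (3/7, 4/7)
        got = allocation_probabilities(
            np.array([0.6, 0.4]), np.array([0, 1]), np.array([2, 1])
        )
        assert got == pytest.approx([3 / 7, 4 / 7])

    def test_unique_peptide_gets_everything(self):
        got = allocation_probabilities(
            np.array([0.2, 0.8]), np.array([0]), np.array([3, 1])
        )
        assert got.tolist() == [1.0, 0.0]

    def test_symmetric_case_is_uniform(self):
        got = allocation_probabilities(
            np.full(4, 0.25), np.arange(4), np.full(4, 2)
        )
        assert got == pytest.approx(np.full(4, 0.25))

    def test_underflow_falls_back_to_uniform(self):
        got = allocation_probabilities(
            np.array([0.0, 0.0, 1.0]), np.array([0, 1]), np.ones(3)
        )
        assert got == pytest.approx([0.5, 0.5, 0.0])

    @given(
        st.integers(min_value=2, max_value=8),
        st.integers(min_value=0, max_value=10**6),
    )
    @settings(max_examples=50, deadline=None)
    def test_simplex_support_property(self, p, seed):
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(np.ones(p))
        m = rng.integers(1, 6, size=p)
        k = int(rng.integers(1, p + 1))
        psi = rng.choice(p, size=k, replace=False)
        w = allocation_probabilities(pi, psi, m)
        assert w.sum() == pytest.approx(1.0)
        outside = np.setdiff1d(np.arange(p), psi)
        assert (w[outside] == 0).all() and (w[psi] > 0).all()


class TestAllocatePeptide:
    def test_misdetected_peptide_contributes_nothing(self, rng):
        out = allocate_peptide(7, 1, np.array([0.5, 0.5]), rng)
        assert out.tolist() == [0, 0]

    def test_unique_peptide_keeps_full_abundance(self, rng):
        out = allocate_peptide(5, 0, np.array([1.0, 0.0]), rng)
        assert out.tolist() == [5, 0]

    def test_multinomial_moments(self, rng):
        y = 10**4
        out = allocate_peptide(y, 0, np.array([3 / 7, 4 / 7]), rng)
        assert out.sum() == y
        sd = np.sqrt(y * (3 / 7) * (4 / 7))
        assert abs(out[0] - y * 3 / 7) < 3 * sd


class TestSamplePi:
    def test_conjugate_posterior_mean(self, rng):
        prior = PriorSpec(np.ones(2), informative=False, prior_mass=2.0)
        x = np.array([3, 0])
        draws = np.array([sample_pi(x, prior, rng)[0] for _ in range(10**5)])
        assert abs(draws.mean() - 0.8) < 0.005  # Dir(4,1) mean
    def test_prior_only_is_uniform_mean(self, rng):
        prior = PriorSpec(np.ones(4), informative=False, prior_mass=4.0)
        draws = np.array([sample_pi(np.zeros(4), prior, rng) for _ in range(20000)])
        assert draws.mean(axis=0) == pytest.approx(np.full(4, 0.25), abs=0.01)

    def test_single_isoform_is_degenerate(self, rng):
        prior = PriorSpec(np.ones(1), informative=False, prior_mass=1.0)
        assert sample_pi(np.array([5]), prior, rng).tolist() == [1.0]


class TestRunMcmc:
    def unique_dataset(self):
        return PeptideDataset.from_records(
            [
                make_record("p1", 4, ["A"]),
                make_record("p2", 3, ["A"]),
                make_record("p3", 2, ["B"]),
            ]
        )

    def test_unique_peptides_fix_the_latent_abundances(self):
        ds = self.unique_dataset()
        prior = build_prior(ds.catalog, use_mrna=False)
        cfg = AnalysisConfig(mcmc_iterations=400, burn_in=100, seed=1)
        chains = run_mcmc(ds, prior, cfg)
        assert (chains.x_draws == np.array([7, 2])).all()
        # pi draws are then iid Dir(x + delta)
        expected = (7 + 1) / (9 + 2)
        se = chains.pi_draws[:, 0].std(ddof=1) / np.sqrt(chains.kept_iterations)
        assert abs(chains.pi_draws[:, 0].mean() - expected) < 3 * se

    def test_same_seed_is_bit_identical(self, tiny_dataset):
        prior = build_prior(tiny_dataset.catalog, use_mrna=False)
        cfg = AnalysisConfig(mcmc_iterations=200, burn_in=50, seed=11)
        a = run_mcmc(tiny_dataset, prior, cfg)
        b = run_mcmc(tiny_dataset, prior, cfg)
        assert (a.x_draws == b.x_draws).all()
        assert (a.pi_draws == b.pi_draws).all()

    def test_prior_recovery_without_abundance(self):
        # all Y = 0: pi draws must follow the Dirichlet prior
        ds = PeptideDataset.from_records(
            [make_record("p1", 0, ["A"]), make_record("p2", 0, ["B", "C"])]
        )
        delta = np.array([2.0, 1.0, 1.0])
        prior = PriorSpec(delta, informative=True, prior_mass=4.0)
        cfg = AnalysisConfig(mcmc_iterations=21000, burn_in=1000, seed=4)
        chains = run_mcmc(ds, prior, cfg)
        assert (chains.x_draws == 0).all()
        k = chains.kept_iterations
        mean = delta / delta.sum()
        var = mean * (1 - mean) / (delta.sum() + 1)
        for p in range(3):
            se = np.sqrt(var[p] / k)
            assert abs(chains.pi_draws[:, p].mean() - mean[p]) < 4 * se
            assert chains.pi_draws[:, p].var() == pytest.approx(var[p], rel=0.1)

    def test_conservation_every_iteration_pep_mode(self):
        ds = PeptideDataset.from_records(
            [
                make_record("p1", 5, ["A"], pep=0.4),
                make_record("p2", 3, ["A", "B"], pep=0.2),
                make_record("p3", 7, ["B", "C"], pep=0.9),
            ]
        )
        prior = build_prior(ds.catalog, use_mrna=False)
        cfg = AnalysisConfig(mode="pep", mcmc_iterations=300, burn_in=100, seed=8)
        chains = run_mcmc(ds, prior, cfg)
        y = ds.abundances()
        retained = ((1 - chains.epsilon_draws) * y).sum(axis=1)
        assert (chains.x_draws.sum(axis=1) == retained).all()

    def test_pep_mode_requires_pep_values(self):
        ds = PeptideDataset.from_records(
            [make_record("p1", 5, ["A"], pep=None)]
        )
        prior = build_prior(ds.catalog, use_mrna=False)
        cfg = AnalysisConfig(mode="pep", mcmc_iterations=10, burn_in=1, seed=0)
        with pytest.raises(ValidationError, match="PEP"):
            run_mcmc(ds, prior, cfg)

    def test_prior_dimension_checked(self, tiny_dataset):
        prior = PriorSpec(np.ones(5), informative=False, prior_mass=5.0)
        cfg = AnalysisConfig(mcmc_iterations=10, burn_in=1)
        with pytest.raises(ValidationError, match="dimension"):
            run_mcmc(tiny_dataset, prior, cfg)

    def test_intensities_must_be_normalized_first(self):
        ds = PeptideDataset.from_records(
            [make_record("p1", 5.5, ["A"])], abundance_kind="intensities"
        )
        prior = build_prior(ds.catalog, use_mrna=False)
        cfg = AnalysisConfig(mcmc_iterations=10, burn_in=1)
        with pytest.raises(ValidationError, match="integer"):
            run_mcmc(ds, prior, cfg)
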