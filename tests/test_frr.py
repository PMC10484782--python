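"""FRR formula, mixture likelihood, empirical-Bayes fit."""

import numpy as np
import pytest
from scipy import integrate, stats

import rvburden as rv
from rvburden.errors import DomainError, ParameterError, ValidationError
from rvburden.frr import counts_from_scan, empirical_log_or
from rvburden.simulate import simulate_gene_counts


class TestGeneFrr:
    def test_null_effect_is_one(self):
        for p in (0.0, 0.001, 0.3):
            assert rv.gene_frr(p, 0.0) == 1.0

    def test_zero_frequency_is_one(self):
        for beta in (-1.0, 0.0, 2.0):
            assert rv.gene_frr(0.0, beta) == 1.0

    def test_known_value(self):
        # p=0.001, OR=3: 1 + 0.001*4 / (1.004)^2
        expected = 1 + 0.001 * 4 / (1 + 2 * 0.001 * 2) ** 2
        assert rv.gene_frr(0.001, np.log(3)) == pytest.approx(expected, rel=1e-12)

    def test_at_least_one_on_grid_with_equality_cases(self):
        ps = np.linspace(0, 0.5, 26)
        betas = np.linspace(-0.5, 3, 36)
        for p in ps:
            lam = rv.gene_frr(p, betas)
            assert (lam >= 1.0).all()
            equal = np.isclose(lam, 1.0, atol=1e-15)
            expected_equal = (p == 0) | np.isclose(betas, 0.0)
            assert np.array_equal(equal, expected_equal)

    def test_frequency_domain_enforced(self):
        # for p <= 0.5 the denominator 2p(e^b - 1) + 1 >= e^b > 0, so the
        # only reachable domain violation is an out-of-range frequency
        with pytest.raises(ParameterError):
            rv.gene_frr(0.7, 1.0)
        with pytest.raises(ParameterError):
            rv.gene_frr(-0.1, 1.0)

    def test_agrees_with_family_simulation(self):
        pairs = rv.simulate_proband_relative_pairs(0.004, np.log(2), 0.1, 1_000_000, 5)
        assert rv.empirical_frr(pairs) == pytest.approx(
            rv.gene_frr(0.002, np.log(2)), rel=0.05
        )


class TestTotalFrr:
    def test_arithmetic(self):
        assert rv.total_frr([1.02, 1.03]) == pytest.approx(1.05)
        assert rv.total_frr([1.0, 1.0]) == 1.0

    def test_permutation_invariant(self):
        lams = [1.01, 1.2, 1.005]
        assert rv.total_frr(lams) == pytest.approx(rv.total_frr(lams[::-1]))

    def test_below_one_rejected(self):
        with pytest.raises(ValidationError):
            rv.total_frr([0.9])


class TestAdjustedFrequency:
    def test_carrier_counts_to_allele_frequency(self):
        gc = rv.GeneCounts("G", a=5, b=15, n1=10_000, n0=90_000)
        assert rv.adjusted_frequency(gc) == pytest.approx(1.0e-4)

    def test_sv_adjustment_adds(self):
        gc = rv.GeneCounts("G", a=5, b=15, n1=10_000, n0=90_000, sv_freq=2e-5)
        assert rv.adjusted_frequency(gc) == pytest.approx(1.2e-4)

    def test_zero_carriers(self):
        assert rv.adjusted_frequency(rv.GeneCounts("G", 0, 0, 100, 100)) == 0.0

    def test_excess_frequency_rejected(self):
        with pytest.raises(DomainError):
            rv.adjusted_frequency(rv.GeneCounts("G", 100, 100, 100, 100, sv_freq=0.3))

    def test_count_invariants(self):
        with pytest.raises(ValidationError):
            rv.GeneCounts("G", a=11, b=0, n1=10, n0=10)


class TestEmpiricalLogOr:
    def test_plain_table(self):
        gc = rv.GeneCounts("G", a=30, b=10, n1=1000, n0=1000)
        bhat, se = empirical_log_or(gc)
        assert bhat == pytest.approx(np.log((30 * 990) / (10 * 970)))
        assert se == pytest.approx(np.sqrt(1 / 30 + 1 / 970 + 1 / 10 + 1 / 990))

    def test_zero_cell_continuity_correction(self):
        gc = rv.GeneCounts("G", a=5, b=0, n1=1000, n0=1000)
        bhat, se = empirical_log_or(gc)
        expected = np.log((5.5 * 1000.5) / (0.5 * 995.5))
        assert bhat == pytest.approx(expected)
        assert np.isfinite(se)

    def test_no_carriers_rejected(self):
        with pytest.raises(ValidationError):
            empirical_log_or(rv.GeneCounts("G", 0, 0, 10, 10))


class TestMarginalLoglik:
    def test_alpha_zero_reduces_to_null_density(self):
        gc = rv.GeneCounts("G", a=12, b=9, n1=5000, n0=5000)
        bhat, s = empirical_log_or(gc)
        got = rv.marginal_loglik(gc, rv.EBPrior(alpha=0.0, eta=2.0))
        assert got == pytest.approx(stats.norm.logpdf(bhat, 0, s), rel=1e-12)

    @pytest.mark.parametrize("bhat", [-1.0, 0.0, 0.5, 1.0, 2.5])
    @pytest.mark.parametrize("s", [0.05, 0.2, 0.8])
    @pytest.mark.parametrize("eta", [0.5, 2.0, 8.0])
    def test_closed_form_matches_adaptive_quadrature(self, bhat, s, eta):
        """The exponentially-modified-Gaussian tail integral vs scipy.quad."""
        from rvburden.frr import _log_assoc_marginal

        closed = np.exp(_log_assoc_marginal(bhat, s, eta))
        # finite window generously covering both the likelihood peak and the
        # prior mass, with breakpoints so the sharp peak is not missed
        upper = max(bhat + 12 * s, 12 / eta, 1.0)
        pts = sorted(
            x for x in (bhat - 5 * s, bhat, bhat + 5 * s) if 0 < x < upper
        )
        quad, _ = integrate.quad(
            lambda b: stats.norm.pdf(bhat, loc=b, scale=s) * eta * np.exp(-eta * b),
            0, upper, points=pts or None, limit=400,
            epsabs=1e-13, epsrel=1e-12,
        )
        assert closed == pytest.approx(quad, rel=1e-8)

    def test_strong_positive_evidence_prefers_nonzero_alpha(self):
        gc = rv.GeneCounts("G", a=200, b=40, n1=50_000, n0=50_000)
        l_null = rv.marginal_loglik(gc, rv.EBPrior(alpha=0.0, eta=2.0))
        l_mix = rv.marginal_loglik(gc, rv.EBPrior(alpha=0.05, eta=2.0))
        assert l_mix > l_null


class TestFitEb:
    def test_overwhelming_gene_has_high_posterior(self):
        # one gene with a huge, precise effect among many nulls
        rng = np.random.default_rng(4)
        counts = [
            rv.GeneCounts(f"N{i}", int(a), int(b), 50_000, 50_000)
            for i, (a, b) in enumerate(
                zip(rng.binomial(50_000, 1e-3, 300), rng.binomial(50_000, 1e-3, 300))
            )
            if a + b > 0
        ]
        counts.append(rv.GeneCounts("STRONG", a=400, b=60, n1=50_000, n0=50_000))
        fit = rv.fit_eb(counts)
        table = fit.genes.set_index("gene_id")
        assert table.loc["STRONG", "posterior_assoc"] > 0.99

    def test_posterior_monotone_in_effect_at_fixed_se(self):
        counts = [
            rv.GeneCounts("G1", 55, 50, 50_000, 50_000),
            rv.GeneCounts("G2", 75, 50, 50_000, 50_000),
            rv.GeneCounts("G3", 110, 50, 50_000, 50_000),
        ] + [
            rv.GeneCounts(f"N{i}", 50, 50, 50_000, 50_000) for i in range(200)
        ]
        import warnings

        fit = rv.fit_eb(counts)
        post = fit.genes.set_index("gene_id")["posterior_assoc"]
        assert post["G1"] <= post["G2"] <= post["G3"]

    def test_null_only_drives_alpha_to_boundary(self):
        counts, _ = simulate_gene_counts(
            1500, alpha=0.0, eta=2.0, n1=20_000, n0=20_000,
            carrier_freq=2e-3, seed=8,
        )
        fit = rv.fit_eb(counts)
        assert fit.prior.alpha < 0.02
        assert (fit.genes["posterior_assoc"] < 0.5).all()

    def test_recovers_mixture_parameters(self):
        counts, _ = simulate_gene_counts(
            2000, alpha=0.05, eta=2.0, n1=50_000, n0=50_000,
            carrier_freq=1e-3, seed=13,
        )
        fit = rv.fit_eb(counts)
        assert fit.converged
        assert fit.prior.alpha == pytest.approx(0.05, abs=0.02)
        assert fit.prior.eta == pytest.approx(2.0, rel=0.3)

    def test_binomial_likelihood_agrees_roughly(self):
        counts, _ = simulate_gene_counts(
            400, alpha=0.08, eta=2.0, n1=30_000, n0=30_000,
            carrier_freq=1e-3, seed=6,
        )
        normal = rv.fit_eb(counts, likelihood="normal")
        conditional = rv.fit_eb(counts, likelihood="binomial")
        assert conditional.prior.alpha == pytest.approx(normal.prior.alpha, abs=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            rv.fit_eb([])


class TestMedianOr:
    def test_known_values(self):
        assert rv.median_or(rv.EBPrior(0.1, np.log(2))) == pytest.approx(np.e)
        eta = np.log(2) / np.log(1.38)
        assert rv.median_or(rv.EBPrior(0.1, eta)) == pytest.approx(1.38)

    def test_monotone_decreasing_to_one(self):
        assert rv.median_or(rv.EBPrior(0.1, 100.0)) == pytest.approx(1.0, abs=0.01)


@pytest.fixture(scope="module")
def fit():
    counts, _ = simulate_gene_counts(
        600, alpha=0.05, eta=2.0, n1=30_000, n0=30_000,
        carrier_freq=1e-3, seed=3,
    )
    return rv.fit_eb(counts)


class TestFrrPercent:

    def test_partition_sums_to_total(self, fit):
        genes = fit.genes["gene_id"].tolist()
        half = len(genes) // 2
        total = rv.frr_percent(fit)
        part = rv.frr_percent(fit, genes[:half]) + rv.frr_percent(fit, genes[half:])
        assert part == pytest.approx(total, rel=1e-9)

    def test_empty_subset_is_zero(self, fit):
        assert rv.frr_percent(fit, subset=[]) == 0.0

    def test_order_invariant(self, fit):
        genes = fit.genes["gene_id"].tolist()[:10]
        assert rv.frr_percent(fit, genes) == pytest.approx(
            rv.frr_percent(fit, genes[::-1])
        )

    def test_unknown_gene_rejected(self, fit):
        with pytest.raises(ValidationError):
            rv.frr_percent(fit, subset=["NOPE"])

    def test_strong_gene_share_matches_truth(self):
        """Strong genes among nulls: their combined estimated share of a
        lambda=2 FRR approaches the truth-based value.  Population allele
        frequencies are taken from controls so case enrichment cannot
        inflate them."""
        rng = np.random.default_rng(17)
        n1 = n0 = 50_000
        q = 2e-3  # carrier frequency
        beta = float(np.log(4.0))
        q1 = q * np.exp(beta) / (1 - q + q * np.exp(beta))
        strong = [f"STRONG{k}" for k in range(5)]
        counts = [
            rv.GeneCounts(
                name, int(rng.binomial(n1, q1)), int(rng.binomial(n0, q)), n1, n0
            )
            for name in strong
        ]
        for i in range(800):
            a, b = rng.binomial(n1, 5e-4), rng.binomial(n0, 5e-4)
            if a + b:
                counts.append(rv.GeneCounts(f"N{i}", int(a), int(b), n1, n0))
        fit = rv.fit_eb(counts, controls_only_freq=True)
        est = rv.frr_percent(fit, subset=strong, lambda_obs=2.0)
        truth = 5 * 100 * (rv.gene_frr(q / 2, beta) - 1) / (2.0 - 1.0)
        # posterior shrinkage and sampling noise allow a generous band
        assert est == pytest.approx(truth, rel=0.35)


def test_counts_from_scan(small_cohort):
    ph = small_cohort.phenotypes
    counts = counts_from_scan(
        small_cohort.carriers.matrix, ph["d"].to_numpy(),
        small_cohort.carriers.genes, {"RISK1": 1e-4},
    )
    by_id = {c.gene_id: c for c in counts}
    cases = (ph["d"] == 1).to_numpy()
    col = small_cohort.carriers.column("RISK1")
    assert by_id["RISK1"].a == col[cases].sum()
    assert by_id["RISK1"].b == col[~cases].sum()
    assert by_id["RISK1"].sv_freq == 1e-4
    assert by_id["RISK1"].n1 == cases.sum()
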