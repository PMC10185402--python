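"""Cross-GWAS coherence and ratio tests: allele harmonization, product-normal
nulls, closed forms, and symmetry properties."""

import math

import numpy as np
import pytest

from genescore.cross import (
    HarmonizationError,
    HarmonizedPair,
    coherence_null,
    harmonize,
    ratio_null,
    score_coherence,
    score_ratio,
)
from genescore.genes import GeneDef, SnpAssignment, SnpStat, SummaryStats, transform_pvalue
from genescore.lincomb import sf_davies

GENE = GeneDef("G1", "G1", "1", 100, 200)


def stats_of(**kw):
    return SummaryStats.from_records((k, v) for k, v in kw.items())


def base_assignment(n=1, sigma=None, ref="A", alt="G"):
    sigma = np.eye(n) if sigma is None else np.asarray(sigma, float)
    return SnpAssignment(
        GENE,
        [f"v{i}" for i in range(n)],
        np.zeros(n),
        sigma,
        ref_alleles=[ref] * n,
        alt_alleles=[alt] * n,
    )


def pair_of(z, w, sigma=None):
    z = np.atleast_1d(np.asarray(z, float))
    n = len(z)
    return HarmonizedPair(
        GENE, [f"v{i}" for i in range(n)], z, np.atleast_1d(np.asarray(w, float)),
        np.eye(n) if sigma is None else np.asarray(sigma, float),
    )


class TestHarmonize:
    def test_matching_alleles_keep_sign(self):
        s1 = stats_of(v0=SnpStat(0.05, beta=0.2, a1="G", a2="A"))
        s2 = stats_of(v0=SnpStat(0.1, beta=-0.1, a1="G", a2="A"))
        pair = harmonize(s1, s2, base_assignment())
        assert pair.z[0] > 0 and pair.w[0] < 0

    def test_opposite_effect_allele_flips_sign(self):
        s1 = stats_of(v0=SnpStat(0.05, beta=0.2, a1="G", a2="A"))
        s2 = stats_of(v0=SnpStat(0.1, beta=0.1, a1="A", a2="G"))  # effect on ref
        pair = harmonize(s1, s2, base_assignment())
        assert pair.z[0] > 0 and pair.w[0] < 0
        assert abs(pair.w[0]) == pytest.approx(transform_pvalue(0.1))

    def test_palindromic_dropped_under_strict_policy(self):
        s1 = stats_of(v0=SnpStat(0.05, beta=0.2, a1="T", a2="A"))
        s2 = stats_of(v0=SnpStat(0.1, beta=0.1, a1="T", a2="A"))
        a = base_assignment(ref="A", alt="T")
        assert harmonize(s1, s2, a) is None
        pair = harmonize(s1, s2, a, drop_palindromic=False)
        assert pair is not None and pair.n_snps == 1

    def test_irreconcilable_alleles_dropped_and_counted(self):
        s1 = stats_of(
            v0=SnpStat(0.05, beta=0.2, a1="C", a2="T"),
            v1=SnpStat(0.5, beta=0.1, a1="G", a2="A"),
        )
        s2 = stats_of(
            v0=SnpStat(0.1, beta=0.1, a1="C", a2="T"),
            v1=SnpStat(0.5, beta=0.1, a1="G", a2="A"),
        )
        pair = harmonize(s1, s2, base_assignment(n=2))
        assert pair.n_snps == 1 and pair.n_dropped == 1
        assert pair.variant_ids == ["v1"]

    def test_unsigned_input_rejected(self):
        s1 = stats_of(v0=SnpStat(0.05, a1="G", a2="A"))
        s2 = stats_of(v0=SnpStat(0.1, beta=0.1, a1="G", a2="A"))
        with pytest.raises(HarmonizationError, match="signed"):
            harmonize(s1, s2, base_assignment())


class TestCoherenceNull:
    def test_single_snp_pair(self):
        spec = coherence_null(np.eye(1))
        assert sorted(spec.coefficients) == [-0.5, 0.5]

    def test_identity_two_snps(self):
        spec = coherence_null(np.eye(2))
        assert sorted(spec.coefficients) == [-0.5, -0.5, 0.5, 0.5]

    def test_correlated_sigma_eigenvalues(self):
        spec = coherence_null(np.array([[1.0, 0.6], [0.6, 1.0]]))
        assert sorted(spec.coefficients) == pytest.approx([-0.8, -0.2, 0.2, 0.8])

    def test_coefficients_sum_to_zero(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((5, 5))
        sigma = np.corrcoef(a @ a.T)
        assert sum(coherence_null(sigma).coefficients) == pytest.approx(0.0, abs=1e-12)

    def test_correlated_null_against_monte_carlo(self):
        sigma = np.array([[1.0, 0.6], [0.6, 1.0]])
        rng = np.random.default_rng(9)
        chol = np.linalg.cholesky(sigma)
        z = rng.standard_normal((2, 2_000_000))
        w = rng.standard_normal((2, 2_000_000))
        x = np.sum((chol @ z) * (chol @ w), axis=0)
        q = 1.7
        mc = float(np.mean(x > q))
        se = math.sqrt(mc * (1 - mc) / x.size)
        assert sf_davies(coherence_null(sigma), q) == pytest.approx(mc, abs=3 * se)


class TestCoherenceScore:
    def test_zero_statistic_gives_half(self):
        res = score_coherence(pair_of([0.0], [1.0]))
        assert res.p_coherent == pytest.approx(0.5, abs=1e-8)

    def test_coherent_and_anticoherent_sum_to_one(self):
        res = score_coherence(pair_of([1.2], [0.7]))
        assert res.p_coherent + res.p_anticoherent == pytest.approx(1.0, abs=1e-9)

    def test_swapping_gwas_leaves_p_unchanged(self):
        z, w = [1.1, -0.4], [0.3, 0.9]
        sigma = [[1.0, 0.2], [0.2, 1.0]]
        a = score_coherence(pair_of(z, w, sigma))
        b = score_coherence(pair_of(w, z, sigma))
        assert a.p_coherent == pytest.approx(b.p_coherent, rel=1e-10)

    def test_single_snp_product_normal_closed_form(self):
        # P(z*w > 1) via the Bessel-K0 representation of the product normal
        from scipy.integrate import quad
        from scipy.special import k0

        oracle = quad(k0, 1, np.inf)[0] / math.pi
        z = [math.sqrt(1.0)]  # z*w = 1
        res = score_coherence(pair_of(z, z))
        assert res.statistic == pytest.approx(1.0)
        assert res.p_coherent == pytest.approx(oracle, abs=1e-8)


class TestRatioNull:
    def test_r_zero_single_snp(self):
        spec = ratio_null(np.eye(1), 0.0)
        assert sorted(spec.coefficients) == pytest.approx([-0.5, 0.5])
        assert sf_davies(spec, 0.0) == pytest.approx(0.5, abs=1e-9)

    def test_r_one_single_snp_is_cauchy_quartile(self):
        # R = w/z is standard Cauchy; P(R > 1) = 1/4
        spec = ratio_null(np.eye(1), 1.0)
        assert sf_davies(spec, 0.0) == pytest.approx(0.25, abs=1e-9)

    def test_correlated_sigma_against_monte_carlo(self):
        sigma = np.array([[1.0, 0.5], [0.5, 1.0]])
        rng = np.random.default_rng(17)
        chol = np.linalg.cholesky(sigma)
        z = chol @ rng.standard_normal((2, 2_000_000))
        w = chol @ rng.standard_normal((2, 2_000_000))
        r = np.sum(z * w, axis=0) / np.sum(z * z, axis=0)
        mc = float(np.mean(r > 0.3))
        se = math.sqrt(mc * (1 - mc) / r.shape[0])
        p = sf_davies(ratio_null(sigma, 0.3), 0.0)
        assert p == pytest.approx(mc, abs=3 * se)


class TestRatioScore:
    def test_w_equals_z_gives_cauchy_quartile(self):
        z = [1.3]
        res = score_ratio(pair_of(z, z))
        assert res.statistic == pytest.approx(1.0)
        assert res.p_ratio == pytest.approx(0.25, abs=1e-8)

    def test_direction_swap_on_symmetric_input(self):
        z = [0.8, -0.5, 1.1]
        sigma = np.array([[1, 0.3, 0.1], [0.3, 1, 0.2], [0.1, 0.2, 1.0]])
        a = score_ratio(pair_of(z, z, sigma), direction="z_over")
        b = score_ratio(pair_of(z, z, sigma), direction="w_over")
        assert a.p_ratio == pytest.approx(b.p_ratio, rel=1e-10)

    def test_three_snp_fixture_against_monte_carlo(self):
        sigma = np.array([[1, 0.4, 0.2], [0.4, 1, 0.3], [0.2, 0.3, 1.0]])
        zobs = np.array([0.9, 0.2, -0.3])
        wobs = np.array([0.5, 1.0, 0.1])
        rstar = float(zobs @ wobs / (zobs @ zobs))
        rng = np.random.default_rng(23)
        chol = np.linalg.cholesky(sigma)
        z = chol @ rng.standard_normal((3, 2_000_000))
        w = chol @ rng.standard_normal((3, 2_000_000))
        r = np.sum(z * w, axis=0) / np.sum(z * z, axis=0)
        mc = float(np.mean(r > rstar))
        se = math.sqrt(mc * (1 - mc) / r.shape[1] if r.ndim > 1 else mc * (1 - mc) / r.size)
        res = score_ratio(pair_of(zobs, wobs, sigma))
        assert res.p_ratio == pytest.approx(mc, abs=3 * se)

    def test_zero_denominator_unscorable(self):
        res = score_ratio(pair_of([0.0], [1.0]))
        assert res.p_ratio is None
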