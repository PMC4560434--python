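"""Four-model Bayesian comparison: closed-form marginals against numerical
integration, decision rule, symmetry, and the summary statistics."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from isodiv.divergence import (
    CLASS_NAMES,
    DivergenceModelSpec,
    IsoformPairSummary,
    allelic_fractions,
    classify_divergence,
    classify_gene,
    classify_major_isoform,
    gene_deltas,
    isoform_logodds,
    isoform_proportion,
    model_log_marginals,
    rank_correlation,
)
from isodiv.synthetic_data import SimulationConfig, simulate_cohort, simulate_expression

from conftest import make_table


# ---------------------------------------------------------------------------
# Numerical-integration oracle for the marginal likelihoods
# ---------------------------------------------------------------------------

def numeric_log_marginals(d1, v1, d2, v2, sigma0):
    def like1(b):
        return norm.pdf(d1, b, math.sqrt(v1)) * norm.pdf(b, 0, sigma0)

    def like_cis(b):
        return (
            norm.pdf(d1, b, math.sqrt(v1))
            * norm.pdf(d2, b, math.sqrt(v2))
            * norm.pdf(b, 0, sigma0)
        )

    def like2(b):
        return norm.pdf(d2, b, math.sqrt(v2)) * norm.pdf(b, 0, sigma0)

    lim = 12 * sigma0
    pts = sorted({0.0, d1, d2})
    kw = dict(limit=500, points=pts, epsabs=0.0, epsrel=1e-11)
    cis = quad(like_cis, -lim, lim, **kw)[0]
    int1 = quad(like1, -lim, lim, **kw)[0]
    int2 = quad(like2, -lim, lim, **kw)[0]
    return {
        "conserved": norm.logpdf(d1, 0, math.sqrt(v1))
        + norm.logpdf(d2, 0, math.sqrt(v2)),
        "cis": math.log(cis),
        "trans": math.log(int1) + norm.logpdf(d2, 0, math.sqrt(v2)),
        "cis_trans": math.log(int1) + math.log(int2),
    }


class TestLogOdds:
    def test_symmetric_input_gives_zero(self):
        assert isoform_logodds(5, 5, 0.01) == 0.0

    def test_pseudocount_arithmetic(self):
        assert isoform_logodds(10, 0, 0.01) == pytest.approx(
            math.log(10.01 / 0.01), abs=1e-9
        )

    def test_both_zero_flagged_missing(self):
        assert math.isnan(isoform_logodds(0, 0, 0.01))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            isoform_logodds(-1, 1, 0.01)

    def test_proportion(self):
        assert isoform_proportion(3, 1) == 0.75
        assert math.isnan(isoform_proportion(0, 0))


class TestMarginals:
    def test_conserved_example(self):
        s = IsoformPairSummary("g", 0.0, 0.1, 0.0, 0.1)
        call = classify_divergence(s)
        assert call.posteriors["conserved"] == pytest.approx(0.77, abs=0.01)
        assert call.label == "conserved"

    def test_cis_example(self):
        s = IsoformPairSummary("g", 2.0, 0.01, 2.0, 0.01)
        call = classify_divergence(s)
        assert call.posteriors["cis"] == pytest.approx(0.96, abs=0.01)
        assert call.label == "cis"

    def test_trans_example(self):
        s = IsoformPairSummary("g", 2.0, 0.01, 0.0, 0.01)
        call = classify_divergence(s)
        assert call.posteriors["trans"] == pytest.approx(0.95, abs=0.01)
        assert call.label == "trans"

    def test_closed_form_matches_numerical_integration(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            d1, d2 = rng.normal(0, 2, size=2)
            v1, v2 = rng.uniform(0.005, 1.0, size=2)
            sigma0 = rng.uniform(0.5, 4.0)
            spec = DivergenceModelSpec(sigma0=sigma0)
            got = model_log_marginals(
                IsoformPairSummary("g", d1, v1, d2, v2), spec
            )
            want = numeric_log_marginals(d1, v1, d2, v2, sigma0)
            for k in CLASS_NAMES:
                assert got[k] == pytest.approx(want[k], abs=1e-3), k

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            IsoformPairSummary("g", 0, 0.0, 0, 0.1)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            s = IsoformPairSummary(
                "g", rng.normal(), rng.uniform(0.01, 1),
                rng.normal(), rng.uniform(0.01, 1),
            )
            call = classify_divergence(s)
            assert sum(call.posteriors.values()) == pytest.approx(1.0, abs=1e-9)

    def test_no_model_above_half_is_unclassified(self):
        # moderate evidence spread over models: nothing beats the rest pooled
        s = IsoformPairSummary("g", 0.6, 0.1, 0.3, 0.1)
        call = classify_divergence(s)
        assert max(call.posteriors.values()) <= 0.5
        assert call.label == "unclassified"

    def test_label_symmetry_under_isoform_swap(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            d1, d2 = rng.normal(0, 1.5, size=2)
            v1, v2 = rng.uniform(0.01, 0.5, size=2)
            a = classify_divergence(IsoformPairSummary("g", d1, v1, d2, v2))
            b = classify_divergence(IsoformPairSummary("g", -d1, v1, -d2, v2))
            for k in CLASS_NAMES:
                assert a.posteriors[k] == pytest.approx(b.posteriors[k], abs=1e-12)

    def test_cis_posterior_monotone_in_shared_effect(self):
        post = [
            classify_divergence(
                IsoformPairSummary("g", d, 0.05, d, 0.05)
            ).posteriors["cis"]
            for d in np.linspace(0, 3, 13)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(post, post[1:]))


class TestGeneDeltas:
    def _zero_noise_table(self, class_probs, effect, seed):
        cfg = SimulationConfig(
            n_genes=3, class_probs=class_probs, effect_size=effect,
            noise_sd=0.0, seed=seed,
        )
        genes, truth, _ = simulate_cohort(cfg)
        return genes, truth, simulate_expression(genes, truth, cfg)

    def test_zero_noise_cis_recovers_beta(self):
        genes, truth, table = self._zero_noise_table((0, 1.0, 0, 0), 2.0, 11)
        spec = DivergenceModelSpec(epsilon=1e-12)
        for g in genes:
            s = gene_deltas(table, g.gene_id, *g.transcript_ids, spec)
            beta = truth.genes.loc[g.gene_id, "beta_f0"]
            assert s.d1 == pytest.approx(beta, abs=1e-6)
            assert s.d2 == pytest.approx(beta, abs=1e-6)

    def test_zero_noise_trans_has_null_d2(self):
        genes, truth, table = self._zero_noise_table((0, 0, 1.0, 0), 2.0, 12)
        spec = DivergenceModelSpec(epsilon=1e-12)
        for g in genes:
            s = gene_deltas(table, g.gene_id, *g.transcript_ids, spec)
            assert abs(s.d1) == pytest.approx(2.0, abs=1e-6)
            assert s.d2 == pytest.approx(0.0, abs=1e-6)

    def test_all_equal_expression_gives_zero_deltas(self):
        table = make_table({"t1": [4.0] * 8, "t2": [4.0] * 8})
        s = gene_deltas(table, "g", "t1", "t2", DivergenceModelSpec(epsilon=0.01))
        assert s.d1 == 0.0 and s.d2 == 0.0


class TestMajorIsoform:
    def _three_isoform_table(self, cast_props):
        # BL6 side fixed at (60, 25, 15); CAST side configurable
        bl6 = [60.0, 25.0, 15.0]
        vals = {}
        for i, tid in enumerate(["tA", "tB", "tC"]):
            row = [bl6[i]] * 2 + [cast_props[i]] * 2
            for _ in range(2):  # F1 pairs: BL6 allele then CAST allele
                row += [bl6[i] / 2, cast_props[i] / 2]
            vals[tid] = row
        return make_table(vals, n_f0=2, n_f1=2, se=0.5)

    def test_conserved_proportions_classify_conserved(self):
        table = self._three_isoform_table([60.0, 25.0, 15.0])
        s, call = classify_major_isoform(table, "g", ["tA", "tB", "tC"])
        assert s.d1 == pytest.approx(0.0, abs=1e-9)
        assert call.label == "conserved"

    def test_cis_shift_of_major_isoform_detected(self):
        table = self._three_isoform_table([30.0, 45.0, 25.0])
        s, call = classify_major_isoform(
            table, "g", ["tA", "tB", "tC"], DivergenceModelSpec(epsilon=1e-9)
        )
        want = math.log(60 / 40) - math.log(30 / 70)
        assert s.d1 == pytest.approx(want, abs=1e-6)
        assert s.d2 == pytest.approx(want, abs=1e-6)
        assert call.label == "cis"

    def test_two_isoform_input_redirected(self):
        table = make_table({"t1": [1] * 8, "t2": [1] * 8})
        with pytest.raises(ValueError, match="classify_gene"):
            classify_major_isoform(table, "g", ["t1", "t2"])


class TestAllelicFractions:
    def test_balanced_alleles_give_half(self):
        table = make_table({"t1": [1, 1, 3, 3, 2, 2, 2, 2],
                            "t2": [1, 1, 3, 3, 2, 2, 2, 2]})
        res = allelic_fractions(table, "t1", "t2")
        assert res["S_mean"] == pytest.approx(0.5)
        assert res["U_mean"] == pytest.approx(0.5)

    def test_allele_specific_isoform_gives_unit_fraction(self):
        # BL6 allele expresses both isoforms; CAST allele only isoform 1:
        # the isoform-2 BL6 fraction U is 1
        vals = {
            "t1": [5, 5, 5, 5, 2.5, 2.5, 2.5, 2.5],
            "t2": [5, 5, 0, 0, 2.5, 0.0, 2.5, 0.0],
        }
        table = make_table(vals)
        res = allelic_fractions(table, "t1", "t2", assay_transcript="t2")
        assert res["U_mean"] == pytest.approx(1.0)
        # BL6 allele carries 5 of the replicate's 7.5 total units
        assert res["S_mean"] == pytest.approx(2 / 3)

    def test_zero_denominator_flagged_missing(self):
        vals = {"t1": [1, 1, 1, 1, 0, 0, 1, 1], "t2": [1, 1, 1, 1, 0, 0, 1, 1]}
        table = make_table(vals)
        res = allelic_fractions(table, "t1", "t2")
        assert math.isnan(res["S"][0])
        assert res["S"][1] == pytest.approx(0.5)

    def test_rank_correlation_of_self_is_one(self):
        x = [0.2, 0.5, 0.9, 0.1, 0.7]
        rho, _ = rank_correlation(x, x)
        assert rho == pytest.approx(1.0)


class TestParameterRecovery:
    def test_recovery_on_mixed_cohort(self):
        cfg = SimulationConfig(n_genes=400, seed=77)
        genes, truth, _ = simulate_cohort(cfg)
        table = simulate_expression(genes, truth, cfg)
        spec = DivergenceModelSpec()
        correct = called = 0
        for g in genes:
            _, call = classify_gene(table, g.gene_id, *g.transcript_ids, spec)
            if call.label != "unclassified":
                called += 1
                correct += call.label == truth.genes.loc[g.gene_id, "true_class"]
        assert called > 350
        assert correct / called >= 0.9
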