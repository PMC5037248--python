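"""Sequential / average / case-based attributable fractions: identities
and oracle checks."""

import itertools

import numpy as np
import pytest

from attribfrac.levin import levin_par
from attribfrac.multifactor import (
    average_paf,
    average_paf_bruteforce,
    build_attribution_report,
    case_based_paf,
    sequential_paf,
)
from attribfrac.simulate import (
    PopulationSample,
    ScenarioConfig,
    generate_population,
    true_paf,
)


def _scenario(k, prevalences=None, rr=None, corr=None, n=20_000, seed=13, baseline=None):
    prevalences = prevalences or (0.3,) * k
    rr = rr or (1.8,) * k
    if baseline is None:
        baseline = min(0.08, 0.9 / np.prod(rr))
    return ScenarioConfig(
        n_individuals=n,
        factors=tuple("f%d" % j for j in range(k)),
        prevalences=prevalences,
        rr_true=rr,
        latent_correlation=np.eye(k) if corr is None else corr,
        baseline_risk=baseline,
        seed=seed,
    )


class TestCaseBased:
    def test_null_rr_gives_zero(self, demo_sample):
        assert case_based_paf(demo_sample, "smoking", 1.0) == 0.0

    def test_equals_levin_without_confounding(self):
        # single factor: p_c*(rr-1)/rr estimates the same quantity as
        # Levin's formula; at large n they agree to sampling error
        sample = generate_population(_scenario(1, prevalences=(0.5,), rr=(2.0,), n=400_000))
        got = case_based_paf(sample, "f0", 2.0)
        assert got == pytest.approx(levin_par(0.5, 2.0), abs=0.01)

    def test_reduced_attribution_under_positive_confounding(self, demo_sample):
        """With positively correlated factors, attribution at the true
        (adjusted) RR is smaller than the crude Levin PAR."""
        from attribfrac.simulate import estimate_crude_rr

        cfg = demo_sample.config
        j = cfg.factors.index("excess body weight")
        crude = estimate_crude_rr(demo_sample, "excess body weight")
        pe_hat = demo_sample.exposures[:, j].mean()
        crude_levin = levin_par(pe_hat, crude.rr)
        adjusted = case_based_paf(demo_sample, "excess body weight", cfg.rr_true[j])
        assert adjusted < crude_levin

    def test_no_cases_raises(self):
        cfg = _scenario(1, n=10)
        sample = PopulationSample(
            exposures=np.zeros((10, 1), dtype=np.int8),
            outcome=np.zeros(10, dtype=np.int8),
            model_risk=np.full(10, 0.01),
            config=cfg,
        )
        with pytest.raises(ValueError, match="no cases"):
            case_based_paf(sample, "f0", 2.0)


class TestSequential:
    def test_telescoping_identity_every_ordering(self, demo_sample):
        joint = true_paf(demo_sample, demo_sample.config.factors)
        rng = np.random.default_rng(0)
        factors = list(demo_sample.config.factors)
        for _ in range(10):
            ordering = list(rng.permutation(factors))
            seq = sequential_paf(demo_sample, ordering)
            assert seq.sum() == pytest.approx(joint, abs=1e-10)

    def test_single_factor_equals_true_paf(self):
        sample = generate_population(_scenario(1))
        seq = sequential_paf(sample, ["f0"])
        assert seq[0] == pytest.approx(true_paf(sample, ["f0"]), abs=1e-14)

    def test_first_position_not_smaller_than_second(self):
        sample = generate_population(_scenario(2, rr=(1.8, 2.5), n=50_000))
        first = sequential_paf(sample, ["f0", "f1"])[0]
        second = sequential_paf(sample, ["f1", "f0"])[1]
        assert first >= second

    def test_invalid_permutation(self, demo_sample):
        with pytest.raises(ValueError):
            sequential_paf(demo_sample, ["smoking", "smoking"])


class TestAverage:
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_shapley_matches_permutation_bruteforce(self, k):
        corr = np.full((k, k), 0.25)
        np.fill_diagonal(corr, 1.0)
        rng = np.random.default_rng(k)
        sample = generate_population(
            _scenario(
                k,
                prevalences=tuple(rng.uniform(0.1, 0.6, k)),
                rr=tuple(rng.uniform(1.2, 2.5, k)),
                corr=corr,
                n=5000,
            )
        )
        assert np.allclose(average_paf(sample), average_paf_bruteforce(sample), atol=1e-12)

    def test_sums_to_joint(self, demo_sample):
        joint = true_paf(demo_sample, demo_sample.config.factors)
        assert average_paf(demo_sample).sum() == pytest.approx(joint, abs=1e-10)

    def test_symmetry(self):
        corr = np.full((3, 3), 0.4)
        np.fill_diagonal(corr, 1.0)
        sample = generate_population(
            _scenario(3, prevalences=(0.3, 0.3, 0.3), rr=(1.7, 1.7, 1.7), corr=corr)
        )
        avg = average_paf(sample)
        # exchangeable factors need not have identical *sampled*
        # exposures, but the estimands coincide; check to sampling error
        assert np.ptp(avg) < 0.01

    def test_k1_equals_true_paf(self):
        sample = generate_population(_scenario(1))
        assert average_paf(sample)[0] == pytest.approx(
            true_paf(sample, ["f0"]), abs=1e-14
        )

    def test_enumeration_limit(self):
        sample = generate_population(_scenario(7, n=100, rr=(1.1,) * 7))
        with pytest.raises(ValueError, match="limit"):
            average_paf(sample)

    def test_average_between_sequential_extremes(self):
        sample = generate_population(_scenario(3, rr=(1.5, 2.0, 2.5), n=10_000))
        avg = average_paf(sample)
        factors = list(sample.config.factors)
        seq_by_factor = {f: [] for f in factors}
        for perm in itertools.permutations(factors):
            seq = sequential_paf(sample, perm)
            for pos, f in enumerate(perm):
                seq_by_factor[f].append(seq[pos])
        for j, f in enumerate(factors):
            assert min(seq_by_factor[f]) - 1e-12 <= avg[j] <= max(seq_by_factor[f]) + 1e-12


class TestReport:
    def test_positive_correlation_overestimation(self, demo_sample):
        report = build_attribution_report(demo_sample)
        assert report.sum_crude_levin > report.joint_paf
        assert report.overestimation_gap > 0
        assert report.sum_average_paf == pytest.approx(report.joint_paf, abs=1e-10)

    def test_independence_crude_matches_single_removal(self, independent_sample):
        """Under independent factors the crude Levin PAR is consistent
        for each factor's own counterfactual PAF."""
        report = build_attribution_report(independent_sample)
        diffs = (
            report.table["crude_levin_par"] - report.table["single_removal_paf"]
        ).abs()
        assert diffs.max() < 0.02

    def test_empty_factor_list_all_zero(self):
        cfg = ScenarioConfig(
            n_individuals=10, factors=(), prevalences=(), rr_true=(),
            latent_correlation=np.zeros((0, 0)), baseline_risk=0.1,
        )
        sample = PopulationSample(
            exposures=np.zeros((10, 0), dtype=np.int8),
            outcome=np.zeros(10, dtype=np.int8),
            model_risk=np.full(10, 0.1),
            config=cfg,
        )
        report = build_attribution_report(sample)
        assert report.joint_paf == 0.0
        assert report.sum_crude_levin == 0.0
        assert report.table.empty

    def test_text_rendering(self, demo_sample):
        text = build_attribution_report(demo_sample).to_text()
        assert "joint PAF" in text and "overestimation gap" in text
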