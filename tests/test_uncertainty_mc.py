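"""Parameter sampling, paired evaluation, distribution fitting, separation."""

import math

import numpy as np
import pytest
from scipy import integrate

from voxear.core_models import InvalidInputError, load_tissue_library
from voxear.uncertainty_mc import (
    DistributionSummary,
    MCStudy,
    paired_evaluate,
    sample_parameters,
    separation_significance,
    summarize,
    symmetrize_sigma,
)


class TestSymmetrize:
    @pytest.mark.parametrize(
        "minus,plus,expected", [(1.05, 1.4, 1.4), (0.0, 0.0, 0.0), (0.7, 0.7, 0.7)]
    )
    def test_examples(self, minus, plus, expected):
        assert symmetrize_sigma(minus, plus) == expected

    def test_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            symmetrize_sigma(-0.1, 0.2)


class TestSampling:
    def test_thyroid_R_degenerate(self, library):
        draws = sample_parameters(library, 500, seed=3)
        assert np.all(draws.R["thyroid"] == 0.0)

    def test_zero_sigma_library_reproduces_means(self, library):
        import dataclasses

        degenerate = {
            name: dataclasses.replace(
                p, alpha_sigma=0.0, R_sigma=0.0, beta_sigma_minus=0.0, beta_sigma_plus=0.0
            )
            for name, p in library.items()
        }
        draws = sample_parameters(degenerate, 50, seed=1)
        for organ in draws.organs:
            assert np.all(draws.alpha[organ] == library[organ].alpha)
            assert np.all(draws.beta[organ] == library[organ].beta_ear)

    def test_reproducible_under_seed(self, library):
        a = sample_parameters(library, 100, seed=42)
        b = sample_parameters(library, 100, seed=42)
        for organ in a.organs:
            assert np.array_equal(a.alpha[organ], b.alpha[organ])
            assert np.array_equal(a.beta[organ], b.beta[organ])

    def test_sample_means_converge(self, library):
        # law-of-large-numbers check on parameters far from their domain
        # boundary (so clipping bias is negligible against 3 sigma/sqrt(n))
        n = 10_000
        draws = sample_parameters(library, n, seed=11)
        checks = [
            ("stomach", "alpha", library["stomach"].alpha, library["stomach"].alpha_sigma),
            ("lungs", "R", library["lungs"].repopulation_R, library["lungs"].R_sigma),
            ("breast", "beta_ear", library["breast"].beta_ear, library["breast"].beta_sigma),
        ]
        arrays = {"alpha": draws.alpha, "R": draws.R, "beta_ear": draws.beta}
        for organ, param, mean, sigma in checks:
            sample_mean = arrays[param][organ].mean()
            assert abs(sample_mean - mean) < 3 * sigma / math.sqrt(n)

    def test_liver_alpha_heavily_clipped_but_valid(self, library):
        # sigma (0.905) far exceeds the mean (0.323): a third of draws clip
        draws = sample_parameters(library, 2000, seed=5)
        frac = draws.clip_fraction("liver", "alpha")
        assert 0.25 < frac < 0.45
        assert np.all(draws.alpha["liver"] >= 0.0)

    def test_domains_respected(self, library):
        draws = sample_parameters(library, 2000, seed=9)
        for organ in draws.organs:
            assert np.all(draws.alpha[organ] >= 0)
            assert np.all((draws.R[organ] >= 0) & (draws.R[organ] <= 1))
            assert np.all(draws.beta[organ] >= 0)

    def test_indexing_yields_single_draw(self, library):
        draws = sample_parameters(library, 10, seed=0)
        one = draws[3]
        assert one.draw_index == 3
        assert one.values["lungs"][0] == draws.alpha["lungs"][3]


class TestPairedEvaluation:
    def test_identical_cubes_indistinguishable(self, library, ctx, small_plans):
        plan = small_plans["IMRT"]
        study = MCStudy(patients=("p",), modalities=("A", "B"), n_replicates=50, master_seed=2)
        res = paired_evaluate(study, {"p": {"A": plan, "B": plan}}, library, ctx)
        assert np.array_equal(res.total_ear[("p", "A")], res.total_ear[("p", "B")])
        rel = res.relative_total("p", "A", "B")
        assert np.all(rel == 1.0)

    def test_evaluation_bookkeeping(self, library, ctx, small_plans):
        study = MCStudy(
            patients=("p",), modalities=tuple(small_plans), n_replicates=20, master_seed=2
        )
        res = paired_evaluate(study, {"p": small_plans}, library, ctx)
        assert res.evaluation_count == study.n_evaluations == 20 * 1 * 4 * 13

    def test_draw_permutation_invariance(self, library, ctx, small_plans):
        plan = {"IMRT": small_plans["IMRT"], "VMAT": small_plans["VMAT"]}
        study = MCStudy(patients=("p",), modalities=("IMRT", "VMAT"),
                        n_replicates=64, master_seed=4)
        res = paired_evaluate(study, {"p": plan}, library, ctx)
        draws = res.draws["p"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(64)
        shuffled = type(draws)(
            {o: v[perm] for o, v in draws.alpha.items()},
            {o: v[perm] for o, v in draws.R.items()},
            {o: v[perm] for o, v in draws.beta.items()},
            seed=draws.seed,
        )
        res2 = paired_evaluate(study, {"p": plan}, library, ctx, draws={"p": shuffled})
        for m in ("IMRT", "VMAT"):
            s1 = summarize(res.total_ear[("p", m)])
            s2 = summarize(res2.total_ear[("p", m)])
            assert s1.mean == pytest.approx(s2.mean, rel=1e-12)
            assert s1.sigma == pytest.approx(s2.sigma, rel=1e-9)

    def test_mismatched_anatomy_rejected(self, library, ctx, small_plans):
        import dataclasses

        vmat = small_plans["VMAT"]
        altered_labels = vmat.labels.copy()
        altered_labels[vmat.organ_mask("thyroid")] = 0  # drop an organ
        altered = dataclasses.replace(vmat, labels=altered_labels)
        study = MCStudy(patients=("p",), modalities=("IMRT", "VMAT"),
                        n_replicates=5, master_seed=0)
        mixed = {"IMRT": small_plans["IMRT"], "VMAT": altered}
        with pytest.raises(InvalidInputError):
            paired_evaluate(study, {"p": mixed}, library, ctx)

    def test_excluded_and_zero_risk_organs(self, library, ctx, small_plans):
        study = MCStudy(patients=("p",), modalities=("IMRT",), n_replicates=10, master_seed=1)
        res = paired_evaluate(study, {"p": {"IMRT": small_plans["IMRT"]}}, library, ctx)
        assert res.organ_ear[("p", "IMRT", "spleen")] is None  # excluded
        assert np.all(res.organ_ear[("p", "IMRT", "heart")] == 0.0)  # zero risk


class TestSummarize:
    def test_constant_sequence(self):
        s = summarize([4.2] * 10)
        assert s.sigma == 0.0 and s.cv == 0.0

    def test_two_values_hand_calc(self):
        s = summarize([1.0, 3.0])
        assert s.mean == 2.0
        assert s.sigma == pytest.approx(math.sqrt(2.0))
        assert s.cv == pytest.approx(math.sqrt(2.0) / 2.0)

    def test_zero_mean_cv_undefined(self):
        s = summarize([-1.0, 1.0])
        assert math.isnan(s.cv)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize([])


class TestSeparation:
    def test_identical_distributions(self):
        s = DistributionSummary(1.0, 0.1, 0.1, 100)
        sep = separation_significance(s, s)
        assert sep.z_separation == 0.0 and not sep.significant

    def test_degenerate_sigmas(self):
        a = DistributionSummary(1.0, 0.0, 0.0, 100)
        b = DistributionSummary(1.4, 0.0, 0.0, 100)
        sep = separation_significance(a, b)
        assert sep.significant and sep.p_value == 0.0
        same = separation_significance(a, a)
        assert same.z_separation == 0.0 and same.p_value == 1.0

    def test_table_style_inputs(self):
        # relative-to-self convention: reference has sigma exactly 0
        ref = DistributionSummary(1.0, 0.0, 0.0, 1000)
        impt = DistributionSummary(1.38, 1.38 * 0.05, 0.05, 1000)
        sep = separation_significance(impt, ref)
        assert sep.z_separation == pytest.approx(0.38 / (1.38 * 0.05), rel=1e-9)
        assert sep.significant

    def test_p_value_against_numerical_integration(self):
        # brute-force two-sided tail mass of the standard normal
        z = 3.2905
        pdf = lambda x: math.exp(-x * x / 2) / math.sqrt(2 * math.pi)
        tail, _ = integrate.quad(pdf, z, 40)
        a = DistributionSummary(0.0, 1.0, 0.0, 10)
        b = DistributionSummary(z, 0.0, 0.0, 10)
        sep = separation_significance(a, b)
        assert sep.p_value == pytest.approx(2 * tail, rel=1e-6)
        assert sep.p_value == pytest.approx(0.001, rel=1e-2)


class TestVarianceReduction:
    def test_pairing_tightens_relative_distributions(self, library, ctx, small_plans):
        # similar-topology photon pair: correlated parameter uncertainty
        # cancels in the ratio
        study = MCStudy(patients=("p",), modalities=("IMRT", "VMAT"),
                        n_replicates=300, master_seed=13)
        plans = {"IMRT": small_plans["IMRT"], "VMAT": small_plans["VMAT"]}
        res = paired_evaluate(study, {"p": plans}, library, ctx)
        abs_cv = summarize(res.total_ear[("p", "IMRT")]).cv
        rel_cv = summarize(res.relative_total("p", "IMRT", "VMAT")).cv
        assert rel_cv < abs_cv

    def test_linear_model_organ_relative_variance_is_zero(self, library, ctx, small_plans):
        study = MCStudy(patients=("p",), modalities=("IMRT", "VMAT"),
                        n_replicates=100, master_seed=13)
        plans = {"IMRT": small_plans["IMRT"], "VMAT": small_plans["VMAT"]}
        res = paired_evaluate(study, {"p": plans}, library, ctx, dose_response="linear")
        rel = res.relative_organ("p", "IMRT", "VMAT", "lungs")
        assert np.all(rel == rel[0])
        assert summarize(rel).sigma == 0.0
        # total-level relative EAR still varies (beta weights differ by organ)
        rel_tot = res.relative_total("p", "IMRT", "VMAT")
        assert summarize(rel_tot).sigma > 0.0
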