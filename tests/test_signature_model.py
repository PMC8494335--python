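"""Hierarchical signature model: z-tests, BH, MCMC recovery, divergence."""

from dataclasses import replace
from itertools import permutations

import numpy as np
import pytest
from scipy import optimize

from irmut.io_formats import SampleMeta
from irmut.signature_model import (
    SamplerSettings,
    bh_adjust,
    class_fold_change,
    compare_to_wildtype,
    cosine_similarity_draws,
    fit_signature_model,
    fold_change,
    profile_divergence,
    z_test,
)
from irmut.spectra import SCHEME, MutationSpectrum, count_spectrum
from irmut.synthetic_data import default_wildtype_config, simulate_experiment

FAST = SamplerSettings(chains=2, warmup=600, draws=500, seed=17)


def _simulate_spectra(cfg):
    records, metas, genome = simulate_experiment(cfg)
    by_sample: dict[str, list] = {m.sample_id: [] for m in metas}
    for r in records:
        by_sample[r.sample_id].append(r)
    spectra = [count_spectrum(by_sample[m.sample_id], genome, m.sample_id) for m in metas]
    return spectra, metas


class TestZTest:
    def test_equal_rates(self):
        z, p = z_test(5.0, 1.0, 5.0, 1.0)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_printed_formula(self):
        z, p = z_test(10.0, 1.0, 5.0, 1.0)
        assert z == pytest.approx(5 / np.sqrt(2), abs=1e-4)
        assert p == pytest.approx(4.07e-4, rel=0.01)

    def test_zero_se_is_error(self):
        with pytest.raises(ValueError):
            z_test(1.0, 0.0, 2.0, 0.0)


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_stepup_oracle_on_all_orderings(self):
        def stepup(ps):
            """Textbook BH step-up adjusted p-values."""
            ps = np.asarray(ps, float)
            m = len(ps)
            order = np.argsort(ps)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, ps[i] * m / rank)
                adj[i] = running
            return adj

        base = [0.001, 0.008, 0.039, 0.041, 0.27, 0.74]
        for perm in permutations(base):
            assert np.allclose(bh_adjust(list(perm)), stepup(list(perm)))

    def test_empty_family(self):
        assert bh_adjust([]).size == 0


def _mutant_config(seed, fold=2.0, replicates=2):
    cfg = default_wildtype_config(seed=seed)
    lfc = np.zeros(119)
    lfc[:96] = np.log(fold)
    return replace(cfg.with_genotype("xpf-1", lfc), replicates_per_dose=replicates)


class TestModelFit:
    def test_requires_wildtype_and_replicates(self):
        metas = [SampleMeta("a", "xpf-1", 0.0, 1), SampleMeta("b", "xpf-1", 80.0, 1)]
        spectra = [MutationSpectrum("a", np.zeros(119, int)),
                   MutationSpectrum("b", np.zeros(119, int))]
        with pytest.raises(ValueError, match="wild-type"):
            fit_signature_model(spectra, metas)

    def test_wildtype_only_recovers_planted_signature(self):
        cfg = default_wildtype_config(seed=21)
        spectra, metas = _simulate_spectra(cfg)
        fit = fit_signature_model(spectra, metas, FAST)
        assert not fit.flagged
        ci = SCHEME.class_indices()
        for c, idx in [(0, np.flatnonzero(ci == 0)), (3, np.flatnonzero(ci == 3))]:
            truth = cfg.ir_rate_per_80gy[idx].sum()
            draws = fit.ir_draws[:, :, idx].sum(axis=2).ravel()
            assert abs(draws.mean() - truth) < 3 * draws.std()

    def test_null_genotype_class_folds_near_one(self):
        cfg = default_wildtype_config(seed=22)
        cfg = replace(cfg.with_genotype("null-g", np.zeros(119)), replicates_per_dose=2)
        spectra, metas = _simulate_spectra(cfg)
        fit = fit_signature_model(spectra, metas, replace(FAST, warmup=800, draws=800))
        assert not fit.flagged
        # SNV class: ~370 informative counts, tight recovery expected
        snv = class_fold_change(fit, "null-g", "snv")
        assert 0.8 < snv.mean < 1.25
        # indel class: ~20 counts per genotype, only a 3-sigma band is meaningful
        indel = class_fold_change(fit, "null-g", "indel")
        assert 0.3 < indel.mean < 3.0
        fc = fold_change(fit, "null-g")
        assert 0.8 < fc.mean < 1.25

    def test_planted_twofold_recovered(self):
        spectra, metas = _simulate_spectra(_mutant_config(seed=3))
        fit = fit_signature_model(spectra, metas, FAST)
        assert not fit.flagged
        fc = fold_change(fit, "xpf-1")
        assert 1.5 < fc.mean < 2.7
        assert fc.covers(2.0)

    def test_large_count_toy_matches_mle_oracle(self):
        """Two active channels, huge counts: posterior ~ likelihood peak."""
        rng = np.random.default_rng(5)
        k1, k2 = 10, 40
        ir_true = np.zeros(119)
        ir_true[k1], ir_true[k2] = 400.0, 200.0
        fold = 3.0
        doses = [0.0, 80.0]
        metas, spectra = [], []
        for g, scale in (("wild-type", 1.0), ("mut", fold)):
            for d in doses:
                for rep in (1, 2, 3):
                    sid = f"{g}_{d}_{rep}"
                    metas.append(SampleMeta(sid, g, d, rep))
                    lam = (d / 80.0) * ir_true * (scale if g == "mut" else 1.0)
                    counts = rng.poisson(lam)
                    spectra.append(MutationSpectrum(sid, counts))
        fit = fit_signature_model(spectra, metas, replace(FAST, tau=0.5))
        # independent MLE per channel: rate = mean count at 80 Gy (3 samples)
        for k in (k1, k2):
            wt80 = np.mean([s.counts[k] for s, m in zip(spectra, metas)
                            if m.genotype == "wild-type" and m.dose_gy == 80])
            mut80 = np.mean([s.counts[k] for s, m in zip(spectra, metas)
                             if m.genotype == "mut" and m.dose_gy == 80])
            assert fit.ir_mean[k] == pytest.approx(wt80, rel=0.05)
            post_fold = fit.ir_mean[k] * np.exp(fit.lfc_mean("mut")[k]) / fit.ir_mean[k]
            assert post_fold == pytest.approx(mut80 / wt80, rel=0.05)

    def test_deterministic_given_seed(self):
        spectra, metas = _simulate_spectra(default_wildtype_config(seed=30))
        tiny = SamplerSettings(chains=1, warmup=150, draws=100, seed=9)
        f1 = fit_signature_model(spectra, metas, tiny)
        f2 = fit_signature_model(spectra, metas, tiny)
        assert np.array_equal(f1.ir_draws, f2.ir_draws)


class TestCompare:
    def test_posterior_comparison_flags_planted_effect(self):
        spectra, metas = _simulate_spectra(_mutant_config(seed=3))
        fit = fit_signature_model(spectra, metas, FAST)
        res = {(c.genotype, c.class_label): c for c in compare_to_wildtype(fit)}
        snv = res[("xpf-1", "snv")]
        assert snv.direction == "up" and snv.q < 0.05

    def test_rate_estimate_route(self):
        from irmut.dose_response import RateEstimate

        rates = {
            "wild-type": {"substitutions": RateEstimate("wild-type", "substitutions", 1, 0.45, 0.03)},
            "mut": {"substitutions": RateEstimate("mut", "substitutions", 1, 0.45, 0.03)},
        }
        res = compare_to_wildtype(rates)
        assert len(res) == 1 and res[0].z == 0.0 and res[0].p == pytest.approx(1.0)


class TestProfileDivergence:
    def test_wildtype_distance_is_zero(self):
        spectra, metas = _simulate_spectra(default_wildtype_config(seed=21))
        fit = fit_signature_model(spectra, metas, FAST)
        d = profile_divergence(fit, "wild-type")
        assert d.cosine_distance == 0.0 and not d.significant

    def test_hand_computed_cosine(self):
        a = np.array([[1.0, 1.0, 0.0]])
        b = np.array([[1.0, 0.0, 1.0]])
        assert cosine_similarity_draws(a, b)[0] == pytest.approx(0.5)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity_draws(np.zeros((1, 3)), np.ones((1, 3)))

    def test_planted_shift_increases_distance(self):
        # a genotype whose SNV signature is tilted (half the channels silenced)
        cfg = default_wildtype_config(seed=25)
        tilt = np.zeros(119)
        tilt[:48] = np.log(4.0)
        cfg = replace(
            cfg.with_genotype("null-g", np.zeros(119)).with_genotype("tilted", tilt),
            replicates_per_dose=2,
        )
        spectra, metas = _simulate_spectra(cfg)
        fit = fit_signature_model(spectra, metas, replace(FAST, warmup=800, draws=800))
        comparisons = compare_to_wildtype(fit)
        d_null = profile_divergence(fit, "null-g", comparisons=comparisons)
        d_tilt = profile_divergence(fit, "tilted", comparisons=comparisons)
        assert d_tilt.cosine_distance > d_null.cosine_distance


class TestCalibration:
    def test_ztest_type_i_error_on_null_rate_pairs(self):
        """Two genotypes simulated from identical rates: rejection ~ alpha."""
        from irmut.dose_response import fit_rate

        rng = np.random.default_rng(202)
        doses = np.repeat([0.0, 20, 40, 60, 80], 3)
        b, r = 1.0, 36.63 / 80
        rejections = 0
        n_sim = 250
        for _ in range(n_sim):
            e1 = fit_rate(list(zip(doses, rng.poisson(b + r * doses))))
            e2 = fit_rate(list(zip(doses, rng.poisson(b + r * doses))))
            _, p = z_test(e1.rate_per_gy, e1.se_rate, e2.rate_per_gy, e2.se_rate)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_null_lfc_interval_coverage(self):
        """exp(LFC) 95% interval covers 1 for a null genotype in >= 9/10 runs."""
        tiny = SamplerSettings(chains=2, warmup=500, draws=400, seed=3)
        covered = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = default_wildtype_config(seed=300 + rep)
            cfg = replace(cfg.with_genotype("null-g", np.zeros(119)), replicates_per_dose=2)
            spectra, metas = _simulate_spectra(cfg)
            fit = fit_signature_model(spectra, metas, tiny)
            covered += fold_change(fit, "null-g").covers(1.0)
        assert covered >= 9
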