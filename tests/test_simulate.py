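"""Synthetic-cohort generator: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scnadriver import preprocess, simulate, survival
from conftest import small_config


class TestDeterminism:
    def test_same_seed_identical_bundle(self):
        c1, t1 = simulate.simulate_cohort(small_config(seed=5))
        c2, t2 = simulate.simulate_cohort(small_config(seed=5))
        pd.testing.assert_frame_equal(c1.expression_pt, c2.expression_pt)
        pd.testing.assert_frame_equal(c1.dcn_pt, c2.dcn_pt)
        pd.testing.assert_frame_equal(c1.clinical, c2.clinical)
        pd.testing.assert_series_equal(t1.subclass, t2.subclass)

    def test_different_seeds_differ(self):
        c1, _ = simulate.simulate_cohort(small_config(seed=5))
        c2, _ = simulate.simulate_cohort(small_config(seed=6))
        assert not c1.expression_pt.equals(c2.expression_pt)

    def test_survival_params_do_not_perturb_copy_number(self):
        # named substreams: changing one component's parameters leaves others intact
        c1, _ = simulate.simulate_cohort(small_config(seed=5))
        c2, _ = simulate.simulate_cohort(small_config(seed=5, gamma=-2.0, h0=0.1))
        pd.testing.assert_frame_equal(c1.dcn_pt, c2.dcn_pt)
        pd.testing.assert_frame_equal(c1.expression_pt, c2.expression_pt)


class TestCopyNumber:
    def test_cohort_dimensions(self, small_cohort):
        cohort, _ = small_cohort
        cfg = small_config()
        assert cohort.expression_pt.shape[1] == cfg.n_pt_expression
        assert cohort.expression_nt.shape[1] == cfg.n_nt_expression
        assert cohort.dcn_pt["sample"].nunique() == cfg.n_pt_dcn
        assert cohort.dcn_nt["sample"].nunique() == cfg.n_pt_dcn
        assert len(cohort.intersection_samples) == cfg.n_intersection

    def test_every_tumor_has_paired_normal(self, small_cohort):
        cohort, _ = small_cohort
        assert set(cohort.pairing) == set(cohort.dcn_pt["sample"])
        assert set(cohort.pairing.values()) == set(cohort.dcn_nt["sample"])

    def test_zero_penetrance_means_no_carriers(self):
        cfg = small_config(seed=2)
        cfg.scna_events = tuple(
            simulate.ScnaEvent(e.name, e.chromosome, e.start, e.end, e.kind, 0.0, e.mu)
            for e in cfg.scna_events)
        _, truth = simulate.simulate_cohort(cfg)
        assert not truth.carriers.any().any()

    def test_full_penetrance_no_noise_gives_exact_ratio(self):
        # pi=1, mu=-1, sigma_c -> 0: every tumor's in-region value is 2^-1
        cfg = small_config(seed=3, sigma_c=1e-12, seg_drop_rate=0.0)
        ev = cfg.scna_events[0]
        cfg.scna_events = (simulate.ScnaEvent(ev.name, ev.chromosome, ev.start, ev.end,
                                              "loss", 1.0, -1.0),)
        cohort, truth = simulate.simulate_cohort(cfg)
        gene_dcn = preprocess.map_segments_to_genes(cohort.dcn_pt, cohort.annotation)
        region = truth.event_genes[ev.name]
        np.testing.assert_allclose(gene_dcn.loc[region].to_numpy(), 0.5, rtol=1e-9)

    def test_event_fraction_within_binomial_bounds(self):
        cfg = small_config(seed=7, n_pt_dcn=500, n_pt_expression=500,
                           n_intersection=500, n_nt_expression=5)
        _, truth = simulate.simulate_cohort(cfg)
        count = int(truth.carriers["del_13q"].sum())
        lo = stats.binom.ppf(0.005, 500, 0.4)
        hi = stats.binom.ppf(0.995, 500, 0.4)
        assert lo <= count <= hi

    def test_event_outside_genome_rejected(self):
        cfg = small_config()
        cfg.scna_events = (simulate.ScnaEvent("bad", "13", 0, 10**9, "loss", 0.4, -0.7),)
        with pytest.raises(ValueError, match="outside"):
            cfg.validate()


class TestExpression:
    def test_closed_form_dosage_correlation(self):
        # empirical DE-SCNA correlation of dosage genes approaches
        # rho = beta sd(c) / sqrt(beta^2 var(c) + sigma_e^2) at n = 1000
        cfg = small_config(seed=13, n_pt_dcn=1000, n_pt_expression=1000,
                           n_intersection=1000, n_nt_expression=30)
        cohort, truth = simulate.simulate_cohort(cfg)
        dcn_pt = preprocess.map_segments_to_genes(cohort.dcn_pt, cohort.annotation)
        dcn_nt = preprocess.map_segments_to_genes(cohort.dcn_nt, cohort.annotation)
        de = np.log2(cohort.expression_pt)  # no pseudocount: isolate the planted model
        scna = preprocess.compute_scna_matrix(dcn_pt, dcn_nt)
        rho = simulate.theoretical_dosage_correlation(cfg, cfg.scna_events[0])
        rs = []
        for g in truth.dosage_genes:
            x = de.loc[g, cohort.intersection_samples]
            y = scna.loc[g, cohort.intersection_samples]
            ok = x.notna() & y.notna()
            rs.append(stats.pearsonr(x[ok], y[ok])[0])
        assert abs(np.mean(rs) - rho) < 0.05

    def test_uncoupled_genes_have_no_dosage_correlation(self):
        cfg = small_config(seed=21, n_pt_dcn=300, n_pt_expression=300,
                           n_intersection=300, n_nt_expression=10, dosage_genes=())
        cohort, truth = simulate.simulate_cohort(cfg)
        dcn_pt = preprocess.map_segments_to_genes(cohort.dcn_pt, cohort.annotation)
        arm_gene = truth.event_genes["del_13q"][0]
        x = np.log2(cohort.expression_pt.loc[arm_gene, cohort.intersection_samples])
        y = np.log2(dcn_pt.loc[arm_gene, cohort.intersection_samples])
        ok = x.notna() & y.notna()
        assert abs(stats.pearsonr(x[ok], y[ok])[0]) < 0.1

    def test_expression_nonnegative(self, small_cohort):
        cohort, _ = small_cohort
        assert (cohort.expression_pt.to_numpy() >= 0).all()
        assert (cohort.expression_nt.to_numpy() >= 0).all()

    def test_template_shift_planted(self, small_cohort):
        cohort, truth = small_cohort
        cfg = small_config()
        spec = cfg.templates[0]
        members = truth.subclass.index[truth.subclass == "S1"]
        others = truth.subclass.index[truth.subclass == "none"]
        log2 = np.log2(cohort.expression_pt + 1)
        up = [g for g, d in zip(spec.genes, spec.directions) if d == 1]
        shift = (log2.loc[up, members].mean(axis=1) - log2.loc[up, others].mean(axis=1)).mean()
        assert shift == pytest.approx(spec.delta, abs=0.4)


class TestSurvival:
    def test_protective_driver_shortens_low_stratum_survival(self):
        # gamma = -1: low driver expression -> higher hazard; n large enough
        # that the median-survival ordering is stable
        cfg = small_config(seed=11, n_pt_dcn=300, n_pt_expression=300,
                           n_intersection=300, gamma=-1.0)
        cohort, _ = simulate.simulate_cohort(cfg)
        z = cohort.clinical["driver_z"]
        low = cohort.clinical[z < z.median()]
        high = cohort.clinical[z >= z.median()]
        km_low = survival.km_estimate(low["os_time"], low["os_event"])
        km_high = survival.km_estimate(high["os_time"], high["os_event"])
        assert km_low.median < km_high.median

    def test_zero_horizon_censors_everything(self):
        cfg = small_config(seed=4, censor_horizon=1e-9)
        cohort, _ = simulate.simulate_cohort(cfg)
        assert cohort.clinical["os_event"].sum() == 0

    def test_null_hazard_gives_uniform_logrank_p(self):
        # gamma = 0: two-group log-rank p over replicates is ~ Uniform(0, 1)
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(200):
            t = rng.exponential(30.0, size=120)
            c = rng.uniform(0, 120, size=120)
            times, events = np.minimum(t, c), (t <= c).astype(int)
            res = survival.logrank_test(times[:60], events[:60], times[60:], events[60:])
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_cox_recovers_gamma_from_driver_zscore(self):
        cfg = small_config(seed=17, n_pt_dcn=500, n_pt_expression=500,
                           n_intersection=500, n_nt_expression=10)
        cohort, truth = simulate.simulate_cohort(cfg)
        res = survival.cox_univariate(cohort.clinical["os_time"], cohort.clinical["os_event"],
                                      cohort.clinical["driver_z"])
        assert res.coef == pytest.approx(truth.gamma, abs=0.15)
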