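"""Power engine: combination weights, analytic power, empirical estimator."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from seqimpower import (
    DiseaseModel,
    SignificanceSpec,
    StudyDesign,
    analytic_power,
    effect_size_eta,
    effective_fraction,
    estimate_power,
    is_imputable,
    maf_weight,
    power_curve,
    ps_weight,
)
from seqimpower.disease_model import sample_mac_mean
from seqimpower.quality_data import MafBin

from conftest import make_record, make_table


class TestEffectiveFraction:
    def test_sequencing_only(self):
        assert effective_fraction(100, 0, 0.3) == 1.0

    def test_perfect_imputation(self):
        assert effective_fraction(100, 900, 1.0) == pytest.approx(0.1)

    def test_partial(self):
        assert effective_fraction(100, 900, 0.5) == pytest.approx(100 / 550)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            effective_fraction(0, 0, 0.5)


class TestAnalyticPower:
    def test_null_equals_alpha(self):
        for alpha in (0.05, 1e-4, 5e-8):
            sig = SignificanceSpec(alpha)
            assert analytic_power(0.0, 1000, 5000, 0.7, sig) == pytest.approx(
                alpha, rel=1e-9
            )

    def test_lambda_at_critical_value_gives_half(self, genome_wide):
        ess = 10000.0
        eta = genome_wide.z_crit / math.sqrt(ess)
        # second term Phi(-2 z_crit) < 1e-27 at genome-wide alpha
        assert analytic_power(eta, ess, 0, 0.0, genome_wide) == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_value(self, genome_wide):
        # Phi(4 - 5.45131) + Phi(-4 - 5.45131), frozen from normal CDF evaluation
        assert analytic_power(0.04, 10000, 0, 0.0, genome_wide) == pytest.approx(
            0.0733467, abs=1e-6
        )

    def test_matches_numerical_integration(self):
        """1 - integral of phi(u - lambda) over the acceptance region."""
        for alpha in (0.05, 1e-4, 5e-8):
            sig = SignificanceSpec(alpha)
            z = sig.z_crit
            for lam in (0.0, 1.0, 4.0, 6.0, 9.0):
                eta = lam / 100.0
                got = analytic_power(eta, 10000, 0, 0.0, sig)
                integral, _ = integrate.quad(
                    lambda u: stats.norm.pdf(u - lam), -z, z, epsabs=1e-13, limit=200
                )
                assert got == pytest.approx(1.0 - integral, abs=1e-9)


class TestImputability:
    @pytest.mark.parametrize(
        "mac_panel,r2,expected",
        [
            (5, 0.30, True),  # both thresholds are inclusive
            (4, 0.90, False),  # panel MAC rule
            (1000, None, False),  # absent from panel
            (5, 0.29, False),
        ],
    )
    def test_indicator(self, mac_panel, r2, expected):
        rec = make_record(mac_panel=mac_panel, r2=r2)
        assert is_imputable(rec) is expected

    def test_strict_flag_flips_boundary(self):
        rec = make_record(mac_panel=5, r2=0.30)
        assert is_imputable(rec)
        assert not is_imputable(rec, r2_strict=True)


class TestMafWeight:
    def test_self_weighting(self, worked_model):
        """Empirical histogram equal to the (renormalized) Poisson pmf
        gives identical weights for all records."""
        N = 3412
        mu = sample_mac_mean(worked_model, N)
        macs = [60, 80, 100]
        probs = stats.poisson.pmf(macs, mu)
        hist = {m: p / probs.sum() for m, p in zip(macs, probs)}
        weights = [
            maf_weight(make_record(str(m), m / (2 * N), N=N), worked_model, N, hist)
            for m in macs
        ]
        assert np.allclose(weights, probs.sum())

    def test_division(self, worked_model):
        N = 3412
        mu = sample_mac_mean(worked_model, N)
        hist = {10: 0.5, 20: 0.5}
        w10 = maf_weight(make_record("a", 10 / (2 * N), N=N), worked_model, N, hist)
        assert w10 == pytest.approx(stats.poisson.pmf(10, mu) / 0.5)

    def test_tail_suppression(self):
        model = DiseaseModel(p=1e-5, gamma=1.0, K=0.01)
        N = 3412
        hist = {50: 1.0}
        w = maf_weight(make_record("a", 50 / (2 * N), N=N), model, N, hist)
        assert w < 1e-20

    def test_missing_mac_in_hist(self, worked_model):
        with pytest.raises(ValueError, match="absent"):
            maf_weight(make_record("a", 0.01), worked_model, 3412, {5: 1.0})


class TestPsWeight:
    BINS = [MafBin(0.0, 0.01), MafBin(0.01, 0.5)]

    def test_same_bin_gives_unit_weight(self):
        frac = {self.BINS[0]: 0.4, self.BINS[1]: 0.1}
        for flag in (True, False):
            rec = make_record("a", 0.005, pop_specific=flag)
            assert ps_weight(rec, 0.002, frac, bins=self.BINS) == pytest.approx(1.0)

    def test_ps_ratio(self):
        frac = {self.BINS[0]: 0.6, self.BINS[1]: 0.3}
        rec = make_record("a", 0.02, pop_specific=True)
        assert ps_weight(rec, 0.005, frac, bins=self.BINS) == pytest.approx(2.0)

    def test_non_ps_ratio(self):
        frac = {self.BINS[0]: 0.6, self.BINS[1]: 0.2}
        rec = make_record("a", 0.02, pop_specific=False)
        assert ps_weight(rec, 0.005, frac, bins=self.BINS) == pytest.approx(0.5)

    def test_impossible_flag_zeroed(self):
        frac = {self.BINS[0]: 0.5, self.BINS[1]: 0.0}
        rec = make_record("a", 0.02, pop_specific=True)
        assert ps_weight(rec, 0.005, frac, bins=self.BINS) == 0.0


class TestEstimatePower:
    def test_nothing_imputable_gives_zero(self, worked_model, genome_wide):
        recs = [make_record(str(i), 0.01, mac_panel=0, r2=None) for i in range(4)]
        est = estimate_power(
            StudyDesign(0, 10000), make_table(recs), worked_model, genome_wide
        )
        assert est.power == 0.0
        assert est.p_imputable == 0.0

    def test_single_record_reduces_to_analytic(self, worked_model, genome_wide):
        rec = make_record("a", 0.01, mac_panel=50, r2=0.7)
        est = estimate_power(
            StudyDesign(0, 10000), make_table(rec for rec in [rec]),
            worked_model, genome_wide,
        )
        eta = effect_size_eta(worked_model).eta
        assert est.power == pytest.approx(analytic_power(eta, 0, 10000, 0.7, genome_wide))
        assert est.p_imputable == 1.0

    def test_weighted_mixture_of_imputable_and_not(self, worked_model, genome_wide):
        """Weights 1:3, second record not imputable: power = p1/4, bound 1/4."""
        recs = [
            make_record("a", 0.01, mac_panel=50, r2=1.0, weight=1.0),
            make_record("b", 0.01, mac_panel=0, r2=None, weight=3.0),
        ]
        est = estimate_power(
            StudyDesign(0, 10000), make_table(recs), worked_model, genome_wide
        )
        eta = effect_size_eta(worked_model).eta
        p1 = analytic_power(eta, 0, 10000, 1.0, genome_wide)
        assert est.power == pytest.approx(p1 / 4.0)
        assert est.p_imputable == pytest.approx(0.25)

    def test_null_calibration_exact(self, genome_wide, synth_tables):
        """Under gamma=1 every imputable variant contributes exactly alpha."""
        _, tables = synth_tables
        table = tables[("core", 500)]
        null = DiseaseModel(p=0.005, gamma=1.0, K=0.01)
        est = estimate_power(StudyDesign(500, 5000), table, null, genome_wide)
        assert est.power == pytest.approx(
            genome_wide.alpha * est.p_imputable, abs=1e-10
        )

    def test_panel_mismatch_rejected(self, worked_model, genome_wide):
        table = make_table([make_record("a", 0.01)], panel_n=0)
        with pytest.raises(ValueError, match="panel_n"):
            estimate_power(StudyDesign(500, 1000), table, worked_model, genome_wide)

    def test_monotone_in_m_and_n(self, worked_model, genome_wide, synth_tables):
        _, tables = synth_tables
        powers_m = [
            estimate_power(
                StudyDesign(500, m, "core"), tables[("core", 500)], worked_model, genome_wide
            ).power
            for m in (1000, 5000, 20000, 80000)
        ]
        assert all(b >= a for a, b in zip(powers_m, powers_m[1:]))
        powers_n = [
            estimate_power(
                StudyDesign(n, 10000, "core"), tables[("core", n)], worked_model, genome_wide
            ).power
            for n in (0, 200, 500, 1000, 2000)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(powers_n, powers_n[1:]))

    def test_monotone_in_r2(self, worked_model, genome_wide):
        """Record-wise r2 perturbation never lowers power."""
        lo = make_table([make_record("a", 0.01, mac_panel=50, r2=0.5)])
        hi = make_table([make_record("a", 0.01, mac_panel=50, r2=0.9)])
        d = StudyDesign(0, 8000)
        assert (
            estimate_power(d, hi, worked_model, genome_wide).power
            >= estimate_power(d, lo, worked_model, genome_wide).power
        )


class TestPowerCurve:
    def test_single_design_matches_estimate(self, worked_model, genome_wide, synth_tables):
        cfg, tables = synth_tables
        pool = [tables[("core", n)] for n in cfg.panel_sizes]
        d = StudyDesign(500, 4000, "core")
        df = power_curve([d], pool, worked_model, genome_wide)
        est = estimate_power(d, tables[("core", 500)], worked_model, genome_wide)
        assert len(df) == 1
        assert df["power"].iloc[0] == pytest.approx(est.power)

    def test_sorted_and_monotone_in_m(self, worked_model, genome_wide, synth_tables):
        cfg, tables = synth_tables
        pool = [tables[("core", n)] for n in cfg.panel_sizes]
        designs = [StudyDesign(500, m, "core") for m in (8000, 2000, 4000)]
        df = power_curve(designs, pool, worked_model, genome_wide)
        assert list(df["m_imp"]) == [2000, 4000, 8000]
        assert df["power"].is_monotonic_increasing

    def test_asymptote_at_imputable_probability(self, worked_model, genome_wide, synth_tables):
        """As m grows power plateaus at the probability of being imputable."""
        _, tables = synth_tables
        table = tables[("core", 500)]
        est = estimate_power(StudyDesign(500, 10**9, "core"), table, worked_model, genome_wide)
        assert est.power == pytest.approx(est.p_imputable, abs=1e-12)
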