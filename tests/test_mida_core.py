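"""The labeling model, mixtures, lookup table and inversions.

Expected values come from three sources: closed forms of the binomial site
model, exhaustive enumeration over site-label x isotope assignments for tiny
systems, and the published lookup-table cells (compared at the tolerances the
table's provenance supports).
"""

import itertools

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import binom

from conftest import BASELINE_RATIO
from gngmida.isotopes import IsotopePattern, IsotopeTable, natural_isotope_pattern
from gngmida.mida_core import (
    GGL,
    GLYCEROL_GNG,
    PEPCK_GNG,
    TOTAL_GNG,
    PathwayLabelModel,
    composite_gng,
    equivalent_n,
    excess_enrichments,
    excess_numerators,
    fractional_abundances,
    generate_table,
    invert_fgng,
    invert_fgng_tabular,
    invert_subpathway,
    label_site_distribution,
    labeled_pattern,
    mixture_excess,
    mixture_ratio,
    pathway_ratio,
    subpathway_mixture_ratio,
    table_to_long,
)


class TestSiteDistribution:
    def test_no_label_is_delta(self):
        for n in (0, 3, 7):
            pat = label_site_distribution(n, 0.0)
            assert pat[0] == pytest.approx(1.0)

    def test_fair_binomial(self):
        pat = label_site_distribution(2, 0.5)
        np.testing.assert_allclose(pat.abundances[:3], [0.25, 0.5, 0.25])

    def test_closed_form_single_label(self):
        pat = label_site_distribution(6, 0.08)
        assert pat[1] == pytest.approx(6 * 0.08 * 0.92**5, rel=1e-12)

    @pytest.mark.parametrize("bad_p", [-0.01, 0.6, 1.5])
    def test_rejects_out_of_range_enrichment(self, bad_p):
        with pytest.raises(ValueError):
            label_site_distribution(2, bad_p)

    def test_rejects_absurd_site_count(self):
        with pytest.raises(ValueError):
            PathwayLabelModel("custom", 11)


class TestLabeledPattern:
    def test_zero_sites_leaves_baseline(self, default_baseline):
        pat = labeled_pattern(0, 0.05, default_baseline)
        np.testing.assert_allclose(pat.abundances, default_baseline.abundances, atol=1e-15)

    @pytest.mark.parametrize("p", [0.005, 0.08])
    def test_single_site_ratio_is_p_independent(self, p, default_baseline):
        # excess = p * (shifted - baseline), so the ratio collapses to the
        # baseline signature (A1-A2)/(A0-A1) at any p (full window)
        b = default_baseline.abundances
        expected = (b[1] - b[2]) / (b[0] - b[1])
        pat = labeled_pattern(GGL, p, default_baseline)
        e = excess_enrichments(pat, default_baseline, window="full")
        assert e.ratio == pytest.approx(expected, abs=1e-12)

    def test_single_site_ratio_p_independent_three_ion(self, default_baseline):
        ratios = []
        for p in (0.002, 0.01, 0.045, 0.08):
            pat = labeled_pattern(1, p, default_baseline)
            ratios.append(excess_enrichments(pat, default_baseline).ratio)
        assert max(ratios) - min(ratios) < 1e-9

    def test_total_gng_ratio_matches_published_cell(self, calibrated_baseline):
        # published row p=1.5%, f(GNG)=100% cell
        pat = labeled_pattern(TOTAL_GNG, 0.015, calibrated_baseline)
        e = excess_enrichments(pat, calibrated_baseline)
        assert e.ratio == pytest.approx(0.219303, rel=0.02)

    def test_matches_exhaustive_site_and_isotope_enumeration(self):
        """Brute force: every site-label pattern x isotope assignment, n<=3."""
        table = IsotopeTable()
        comp = {"C": 2, "O": 1}
        p = 0.07
        for n in (1, 2, 3):
            base = natural_isotope_pattern(comp, max_shift=4, table=table)
            model = labeled_pattern(n, p, base)
            atoms = [table.abundances[el] for el, c in comp.items() for _ in range(c)]
            sites = [[(0, 1 - p), (1, p)]] * n
            brute = np.zeros(5)
            for combo in itertools.product(*(atoms + sites)):
                shift = sum(s for s, _ in combo)
                if shift <= 4:
                    prob = 1.0
                    for _, a in combo:
                        prob *= a
                    brute[shift] += prob
            np.testing.assert_allclose(model.abundances, brute, atol=1e-12)


class TestExcessEnrichments:
    def test_unlabeled_sample_has_no_excess(self, default_baseline):
        e = excess_enrichments(default_baseline, default_baseline)
        assert e.em1 == pytest.approx(0.0, abs=1e-15)
        assert e.em2 == pytest.approx(0.0, abs=1e-15)
        assert not e.ratio_defined
        with pytest.raises(ValueError):
            _ = e.ratio

    def test_window_fractions_normalized(self, default_baseline):
        f = fractional_abundances(default_baseline, "three-ion")
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        assert f.size == 3

    def test_single_site_em1_closed_form(self, default_baseline):
        # full-window EM1 of an n=1 population is p*(A0 - A1)
        p = 0.04
        b = default_baseline.abundances
        pat = labeled_pattern(1, p, default_baseline)
        e = excess_enrichments(pat, default_baseline, window="full")
        assert e.em1 == pytest.approx(p * (b[0] - b[1]), abs=1e-12)


class TestMixture:
    def test_baseline_ratio_at_zero_gng(self, calibrated_table):
        for p in (0.005, 0.04):
            r = mixture_ratio(0.0, p, table=calibrated_table)
            assert r == pytest.approx(BASELINE_RATIO, rel=0.03)

    def test_published_cells(self, calibrated_table):
        assert mixture_ratio(1.0, 0.08, table=calibrated_table) == pytest.approx(0.445287, rel=0.02)
        assert mixture_ratio(0.5, 0.04, table=calibrated_table) == pytest.approx(0.279059, rel=0.02)

    def test_monotone_in_f(self, calibrated_table):
        rs = [mixture_ratio(f, 0.03, table=calibrated_table) for f in np.linspace(0, 1, 21)]
        assert np.all(np.diff(rs) > 0)

    def test_excess_linearity_in_weights(self, calibrated_table):
        """Mixture N_x must equal the weight-weighted sum of end-member N_x."""
        p = 0.045
        for window in ("three-ion", "full"):
            g = mixture_excess(1.0, p, window=window, table=calibrated_table)
            l = mixture_excess(0.0, p, window=window, table=calibrated_table)
            for f in (0.25, 0.5, 0.9):
                m = mixture_excess(f, p, window=window, table=calibrated_table)
                assert m.em1 == pytest.approx(f * g.em1 + (1 - f) * l.em1, abs=1e-12)
                assert m.em2 == pytest.approx(f * g.em2 + (1 - f) * l.em2, abs=1e-12)

    def test_pattern_mixing_equals_physically_mixed_spectrum(self, calibrated_baseline, calibrated_table):
        """The model's mixture ratio must match a spectrum mixed at the pattern level."""
        p, f = 0.06, 0.37
        gng = labeled_pattern(6, p, calibrated_baseline)
        ggl = labeled_pattern(1, p, calibrated_baseline)
        mixed = IsotopePattern(f * gng.abundances + (1 - f) * ggl.abundances)
        observed = excess_enrichments(mixed, calibrated_baseline).ratio
        assert mixture_ratio(f, p, table=calibrated_table) == pytest.approx(observed, abs=1e-12)

    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            mixture_ratio(1.2, 0.04)


class TestSubpathwayMixture:
    def test_degenerate_endpoints(self, calibrated_table):
        p = 0.05
        assert subpathway_mixture_ratio(1.0, p, table=calibrated_table) == pytest.approx(
            pathway_ratio(PEPCK_GNG.n, p, table=calibrated_table), abs=1e-14
        )
        assert subpathway_mixture_ratio(0.0, p, table=calibrated_table) == pytest.approx(
            pathway_ratio(GLYCEROL_GNG.n, p, table=calibrated_table), abs=1e-14
        )

    def test_enrichment_weighting_pulls_toward_heavier_arm(self, calibrated_table):
        """The n=7 arm carries more EM1, so the mixture ratio exceeds the naive mean."""
        p = 0.05
        r7 = pathway_ratio(7, p, table=calibrated_table)
        r2 = pathway_ratio(2, p, table=calibrated_table)
        r_mix = subpathway_mixture_ratio(2 / 3, p, table=calibrated_table)
        naive = 2 / 3 * r7 + 1 / 3 * r2
        assert r2 < r_mix < r7
        assert r_mix > naive


class TestEquivalentN:
    def test_integer_round_trip_within_fit_residual(self, calibrated_table):
        p = 0.045
        for n in range(2, 8):
            r = pathway_ratio(n, p, table=calibrated_table)
            assert equivalent_n(r, p, table=calibrated_table) == pytest.approx(n, abs=0.05)

    def test_two_thirds_mixture_matches_published_value(self, calibrated_table):
        for p in (0.045, 0.05):
            r = subpathway_mixture_ratio(2 / 3, p, table=calibrated_table)
            assert equivalent_n(r, p, table=calibrated_table) == pytest.approx(6.12, abs=0.2)

    def test_monotone_in_ratio(self, calibrated_table):
        p = 0.05
        r_lo = pathway_ratio(1, p, table=calibrated_table)
        r_hi = pathway_ratio(8, p, table=calibrated_table)
        grid = np.linspace(r_lo, r_hi, 30)
        ns = [equivalent_n(r, p, table=calibrated_table) for r in grid]
        assert np.all(np.diff(ns) > 0)

    def test_rejects_ratio_outside_calibration(self, calibrated_table):
        with pytest.raises(ValueError, match="interval"):
            equivalent_n(0.9, 0.045, table=calibrated_table)


class TestInversion:
    def test_round_trip_grid(self, calibrated_table):
        for f in np.linspace(0, 1, 11):
            for p in (0.005, 0.02, 0.045, 0.08):
                r = mixture_ratio(f, p, table=calibrated_table)
                inv = invert_fgng(r, p, table=calibrated_table)
                assert inv.f == pytest.approx(f, abs=1e-6)
                assert not inv.out_of_range

    def test_baseline_ratio_maps_to_zero(self, calibrated_table):
        for p in (0.01, 0.06):
            r0 = mixture_ratio(0.0, p, table=calibrated_table)
            assert invert_fgng(r0, p, table=calibrated_table).f == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_bracketing_root_finder(self, calibrated_table):
        """Independent route: solve mixture_ratio(f) = R numerically."""
        p = 0.035
        for f_true in (0.15, 0.5, 0.85):
            r = mixture_ratio(f_true, p, table=calibrated_table)
            f_root = brentq(
                lambda f: mixture_ratio(f, p, table=calibrated_table) - r, 0.0, 1.0, xtol=1e-12
            )
            assert invert_fgng(r, p, table=calibrated_table).f == pytest.approx(f_root, abs=1e-9)

    def test_tabular_agrees_with_exact(self, calibrated_table):
        ref = generate_table(table=calibrated_table)
        rng = np.random.default_rng(7)
        # p on the table's 0.5% row grid: the bracketing-row mean is then exact
        # and only the 10%-step interpolation in f limits agreement
        for p in np.arange(0.005, 0.0801, 0.004):
            p = round(round(p / 0.005) * 0.005, 6)
            f = float(rng.uniform(0.05, 0.95))
            r = mixture_ratio(f, p, table=calibrated_table)
            f_tab = invert_fgng_tabular(r, p, ref=ref)
            assert f_tab == pytest.approx(f, abs=0.01)

    def test_out_of_range_flagged_and_clamped(self, calibrated_table):
        p = 0.04
        r_hi = mixture_ratio(1.0, p, table=calibrated_table)
        inv = invert_fgng(r_hi * 1.05, p, table=calibrated_table)
        assert inv.out_of_range and inv.clamped and inv.f == 1.0
        inv2 = invert_fgng(r_hi * 1.0001, p, table=calibrated_table, slack=0.01)
        assert not inv2.out_of_range and inv2.f == 1.0

    def test_subpathway_round_trip(self, calibrated_table):
        p = 0.045
        for fp in (0.0, 0.3, 0.7, 1.0):
            r = subpathway_mixture_ratio(fp, p, table=calibrated_table)
            assert invert_subpathway(r, p, table=calibrated_table).f == pytest.approx(fp, abs=1e-6)


class TestGenerateTable:
    def test_layout_matches_published_grid(self, calibrated_table):
        df = generate_table(table=calibrated_table)
        assert df.shape == (16, 11)
        assert df.index[0] == 0.5 and df.index[-1] == 8.0
        assert df.columns[0] == 0.0 and df.columns[-1] == 100.0

    def test_first_column_p_independent(self, calibrated_table):
        col = generate_table(table=calibrated_table).iloc[:, 0].to_numpy()
        assert np.ptp(col) / col.mean() < 1e-9

    def test_rows_strictly_increasing(self, calibrated_table):
        df = generate_table(table=calibrated_table)
        assert (df.diff(axis=1).iloc[:, 1:] > 0).all().all()

    def test_full_grid_against_published_cells(self, calibrated_table, reference_cells):
        """Tabulated convention reproduces the published table to printed precision."""
        df = generate_table(table=calibrated_table, mixing="tabulated")
        dev = np.abs(df.to_numpy() - reference_cells) / reference_cells
        assert dev.max() < 0.02
        # and to ~5e-4 in fact, which pins the convention
        assert dev.max() < 5e-4

    def test_pattern_convention_close_to_published(self, calibrated_table, reference_cells):
        df = generate_table(table=calibrated_table, mixing="pattern")
        dev = np.abs(df.to_numpy() - reference_cells) / reference_cells
        assert dev.max() < 0.02

    def test_long_format(self, calibrated_table):
        df = generate_table(table=calibrated_table)
        long = table_to_long(df)
        assert list(long.columns) == ["p_percent", "f_gng_percent", "em2_em1"]
        assert len(long) == 16 * 11
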