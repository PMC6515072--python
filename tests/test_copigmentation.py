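import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copigment.colorimetry import ColorCoordinates, SampleMeta, Spectrum
from copigment.copigmentation import (
    DIRECTION_RULE,
    CpResult,
    EffectDirectionRule,
    RatioSeries,
    aggregate_family,
    best_copigment_count,
    classify_effects,
    estimate_cp,
    mass_ratio,
    subtract_blank,
)
from copigment.tables import (
    load_ethanol_cp_table,
    load_origin_table,
    load_ph_cp_table,
)


def _spec(absorbance, sample_id="s", **meta):
    wl = np.arange(400.0, 801.0, 5.0)
    return Spectrum(sample_id, wl, np.broadcast_to(absorbance, wl.shape).copy(),
                    SampleMeta(**meta))


def _series(points_by_rep, **kwargs):
    """Build a RatioSeries holding a single parameter (A520) per point."""
    defaults = dict(copigment="x", family="GT", ph=3.5, ethanol_pct=12.0,
                    pigment_mg_per_l=50.0)
    defaults.update(kwargs)
    series = RatioSeries(**defaults)
    for rep, points in points_by_rep.items():
        for ratio, value in points:
            series.add(rep, ratio, ColorCoordinates(
                a520=value, X=1, Y=1, Z=1, L=value, a=value, b=value,
                C=abs(value), hab=0.0,
            ))
    return series


class TestSubtractBlank:
    def test_zero_blank_is_identity(self):
        mix = _spec(0.4, "mix", role="mix", copigment="c", family="GT",
                    dose_g_per_l=0.2)
        blank = _spec(0.0, "blank", role="blank", copigment="c", family="GT",
                      dose_g_per_l=0.2)
        out = subtract_blank(mix, blank)
        np.testing.assert_array_equal(out.absorbance, mix.absorbance)
        assert out.meta.role == "corrected"

    def test_self_subtraction_is_zero(self):
        mix = _spec(0.4, "mix", role="mix", copigment="c", dose_g_per_l=0.2,
                    family="GT")
        out = subtract_blank(mix, mix)
        np.testing.assert_array_equal(out.absorbance, np.zeros_like(out.absorbance))

    def test_additive_round_trip(self, rng):
        wl = np.arange(400.0, 801.0, 2.0)
        pigment = 0.5 * np.exp(-((wl - 520.0) ** 2) / (2 * 35.0**2))
        tail = 0.2 * np.exp(-(wl - 400.0) / 60.0)
        meta = dict(copigment="c", family="GT", dose_g_per_l=0.4)
        mix = Spectrum("m", wl, pigment + tail, SampleMeta(role="mix", **meta))
        blank = Spectrum("b", wl, tail, SampleMeta(role="blank", **meta))
        out = subtract_blank(mix, blank)
        np.testing.assert_allclose(out.absorbance, pigment, atol=1e-12)

    def test_metadata_mismatch_rejected(self):
        mix = _spec(0.4, "mix", role="mix", copigment="c", dose_g_per_l=0.2,
                    family="GT")
        blank = _spec(0.0, "blank", role="blank", copigment="other",
                      dose_g_per_l=0.2, family="GT")
        with pytest.raises(ValueError, match="metadata mismatch"):
            subtract_blank(mix, blank)

    def test_negative_result_flagged(self):
        mix = _spec(0.1, "mix", role="mix", copigment="c", dose_g_per_l=0.2,
                    family="GT")
        blank = _spec(0.2, "blank", role="blank", copigment="c",
                      dose_g_per_l=0.2, family="GT")
        assert "negative_absorbance" in subtract_blank(mix, blank).flags


class TestMassRatio:
    @pytest.mark.parametrize(
        "dose,pigment,ratio", [(0.1, 50, 2.0), (0.2, 50, 4.0), (0.4, 50, 8.0), (0, 50, 0.0)]
    )
    def test_design_ratios(self, dose, pigment, ratio):
        assert mass_ratio(dose, pigment) == ratio

    def test_nonpositive_pigment_rejected(self):
        with pytest.raises(ValueError):
            mass_ratio(0.1, 0.0)


class TestEstimateCp:
    def test_exact_line(self):
        series = _series({1: [(0, 0.0), (2, 0.2), (4, 0.4), (8, 0.8)]})
        res = estimate_cp(series, "A520")
        assert res.cp == pytest.approx(0.1, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_degenerate(self):
        series = _series({1: [(0, 0.5), (2, 0.5), (4, 0.5), (8, 0.5)]})
        res = estimate_cp(series, "A520")
        assert res.cp == 0.0
        assert math.isnan(res.r2)
        assert "degenerate_r2" in res.flags

    def test_identical_ratios_rejected(self):
        series = _series({1: [(4, 0.1)], 2: [(4, 0.2)]})
        with pytest.raises(ValueError, match="distinct ratios"):
            estimate_cp(series, "A520")

    def test_noisy_line_matches_normal_equations_oracle(self, rng):
        ratios = np.array([0.0, 2.0, 4.0, 8.0])
        points, slopes_oracle = {}, []
        for rep in (1, 2, 3):
            y = 0.05 * ratios + rng.normal(0, 0.005, 4)
            points[rep] = list(zip(ratios, y))
            design = np.column_stack([np.ones(4), ratios])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            slopes_oracle.append(beta[1])
        res = estimate_cp(_series(points), "A520")
        assert res.cp == pytest.approx(np.mean(slopes_oracle), abs=1e-10)
        assert res.sd == pytest.approx(np.std(slopes_oracle, ddof=1), abs=1e-10)
        se = 0.005 / math.sqrt(np.sum((ratios - ratios.mean()) ** 2) * 3)
        assert abs(res.cp - 0.05) < 3 * se

    def test_undefined_hue_dropped_with_warning(self):
        series = RatioSeries("x", "GT", 3.5, 12.0, 50.0)
        for ratio, (a, b) in [(0, (0.0, 0.0)), (2, (1.0, -1.0)), (4, (2.0, -2.0)),
                              (8, (4.0, -4.0))]:
            c = math.hypot(a, b)
            series.add(1, ratio, ColorCoordinates(
                a520=0.1, X=1, Y=1, Z=1, L=50, a=a, b=b, C=c,
                hab=math.nan if c == 0 else math.degrees(math.atan2(b, a)),
            ))
        with pytest.warns(UserWarning, match="undefined hab"):
            res = estimate_cp(series, "hab")
        assert np.isfinite(res.cp)

    @given(offset=st.floats(-100, 100), scale=st.floats(0.1, 10))
    @settings(max_examples=20, deadline=None)
    def test_slope_invariance(self, offset, scale):
        base = [(0.0, 0.1), (2.0, 0.25), (4.0, 0.38), (8.0, 0.9)]
        cp0 = estimate_cp(_series({1: base}), "A520").cp
        shifted = [(r, v + offset) for r, v in base]
        assert estimate_cp(_series({1: shifted}), "A520").cp == pytest.approx(
            cp0, rel=1e-9, abs=1e-12
        )
        stretched = [(r * scale, v) for r, v in base]
        assert estimate_cp(_series({1: stretched}), "A520").cp == pytest.approx(
            cp0 / scale, rel=1e-9
        )


class TestClassifyEffects:
    def test_reference_gallotannin_row(self):
        # Cp values of the strongest copigment at standard conditions
        cp = {"A520": 0.31, "L*": -4.14, "a*": 5.62, "b*": -3.41,
              "hab": -16.75, "C*ab": 6.23}
        labels = classify_effects(cp)
        assert labels.hyperchromic and labels.bathochromic
        assert not labels.hypochromic and not labels.hypsochromic

    def test_all_zero_is_neither(self):
        cp = dict.fromkeys(["A520", "L*", "a*", "b*", "hab", "C*ab"], 0.0)
        labels = classify_effects(cp)
        assert not any(
            [labels.hyperchromic, labels.hypochromic, labels.bathochromic,
             labels.hypsochromic]
        )

    def test_sign_reversal_is_hypochromic(self):
        cp = {"A520": -0.1, "L*": 0.5, "a*": -0.2, "b*": 0.3, "hab": 1.0,
              "C*ab": -0.4}
        labels = classify_effects(cp)
        assert labels.hypochromic and not labels.hyperchromic

    def test_missing_parameter_rejected(self):
        with pytest.raises(KeyError, match="missing Cp"):
            classify_effects({"A520": 0.1})


class TestBestCopigmentCount:
    def test_single_copigment_wins_everywhere(self):
        rows = [
            {"condition": c, "copigment": "only", "parameter": p, "cp": 1.0}
            for c in ("c1", "c2")
            for p in ("A520", "L*", "a*", "b*", "hab", "C*ab")
        ]
        res = best_copigment_count(pd.DataFrame(rows), "only")
        assert res.wins == res.total == 12 and res.ties == 0

    def test_ties_break_against_focal(self):
        rows = []
        for cop in ("a", "b"):
            rows.append({"condition": "c", "copigment": cop,
                         "parameter": "A520", "cp": 1.0})
        for p in ("L*", "a*", "b*", "hab", "C*ab"):
            for cop, v in (("a", 1.0), ("b", 2.0)):
                rows.append({"condition": "c", "copigment": cop,
                             "parameter": p, "cp": v})
        res = best_copigment_count(pd.DataFrame(rows), "a")
        assert res.ties == 1
        assert res.wins == 3  # 'a' lower on L*, b*, hab

    def test_missing_cell_rejected(self):
        rows = [
            {"condition": "c", "copigment": "a", "parameter": "A520", "cp": 1.0},
            {"condition": "c", "copigment": "b", "parameter": "A520", "cp": 0.5},
            {"condition": "c", "copigment": "a", "parameter": "L*", "cp": -1.0},
        ]
        with pytest.raises(ValueError, match="missing copigment"):
            best_copigment_count(pd.DataFrame(rows), "a")

    def test_direction_rule_is_total(self):
        with pytest.raises(ValueError):
            EffectDirectionRule(frozenset({"A520"}), frozenset({"L*"}))
        assert DIRECTION_RULE.orientation("A520") == 1
        assert DIRECTION_RULE.orientation("hab") == -1


class TestAggregateFamily:
    def test_nut_gall_printed_values(self):
        df = pd.DataFrame(
            {
                "family": "GT",
                "origin": "nut galls",
                "product": [f"ng{i}" for i in range(4)],
                "value": [0.302, 0.517, 0.234, 0.467],
            }
        )
        agg = aggregate_family(df).set_index(["level", "name"])
        assert agg.loc[("origin", "nut galls"), "mean"] == pytest.approx(0.380, abs=5e-4)
        assert agg.loc[("origin", "nut galls"), "sd"] == pytest.approx(0.134, abs=5e-4)

    def test_gt_family_from_two_origins(self):
        df = pd.DataFrame(
            {
                "family": "GT",
                "origin": ["nut galls"] * 4 + ["tara"] * 4,
                "product": [f"p{i}" for i in range(8)],
                "value": [0.302, 0.517, 0.234, 0.467, 0.520, 0.409, 0.588, 0.512],
            }
        )
        agg = aggregate_family(df).set_index(["level", "name"])
        assert agg.loc[("family", "GT"), "mean"] == pytest.approx(0.4436, abs=1e-4)

    def test_singleton_flagged(self):
        df = pd.DataFrame(
            {"family": "GT", "origin": "tara", "product": ["only"], "value": [0.5]}
        )
        agg = aggregate_family(df).set_index(["level", "name"])
        assert agg.loc[("origin", "tara"), "sd"] == 0.0
        assert bool(agg.loc[("origin", "tara"), "singleton"])

    def test_two_level_equals_flat_for_balanced_origins(self):
        table = load_origin_table()
        gt = table[(table.family == "GT") & (table.parameter == "A520")]
        df = gt.rename(columns={"cp": "value"})
        agg = aggregate_family(df).set_index(["level", "name"])
        flat = df["value"].mean()
        assert agg.loc[("family", "GT"), "mean"] == pytest.approx(flat, abs=1e-12)

    def test_family_ordering_from_printed_products(self):
        table = load_origin_table()
        a520 = table[(table.parameter == "A520") & (table.family != "reference")]
        agg = aggregate_family(a520.rename(columns={"cp": "value"}))
        fam = agg[agg.level == "family"].set_index("name")["mean"]
        assert fam["GT"] > fam["ET"] > fam["PC/PD"] > fam["PF/PR"]


class TestFixtureIntegrity:
    def test_origin_table_shape(self):
        t = load_origin_table()
        assert t["product"].nunique() == 37  # 36 tannins + reference
        assert set(t["parameter"]) == {"A520", "L*", "a*", "b*", "hab", "C*ab"}

    @pytest.mark.parametrize(
        "loader,condition,n_levels",
        [(load_ph_cp_table, "ph", 3), (load_ethanol_cp_table, "ethanol_pct", 3)],
    )
    def test_condition_tables_complete(self, loader, condition, n_levels):
        t = loader()
        assert t[condition].nunique() == n_levels
        assert t["copigment"].nunique() == 6
        assert len(t) == n_levels * 6 * 6
        assert t["r2"].between(0, 1).all()

    def test_win_counts_bounded_by_cells(self):
        t = load_ph_cp_table()
        total_wins = sum(
            best_copigment_count(t, cop, condition="ph").wins
            for cop in t["copigment"].unique()
        )
        assert total_wins <= 18
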