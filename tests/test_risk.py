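"""Exposure and risk equations: EDI, THQ, HI, TR, classification, tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hmrisk.risk import (
    ExposureScenario,
    ToxProfile,
    build_risk_table,
    classify_tr,
    edi,
    flag_ptdi,
    hazard_index,
    thq,
    tr,
)

scenario_st = st.builds(
    ExposureScenario,
    label=st.just("s"),
    body_weight_kg=st.floats(5, 150),
    intake_rate_g_per_day=st.floats(1, 500),
    exposure_frequency_days_per_year=st.floats(1, 365),
    exposure_duration_years=st.floats(1, 90),
    averaging_time_days=st.floats(1, 40000),
)


class TestEdi:
    def test_zero_concentration(self, adult):
        assert edi(0.0, adult) == 0.0

    def test_reproduces_printed_adult_intake(self, adult):
        # pooled Cm back-solved from the published adult chromium intake
        assert edi(1.475, adult) == pytest.approx(1.66e-3, rel=5e-3)

    def test_child_is_four_times_adult(self, adult, child):
        # only BW differs between the two scenarios (60 vs 15 kg)
        assert edi(1.475, child) == pytest.approx(4 * edi(1.475, adult))

    @given(s=scenario_st, cm=st.floats(0, 100))
    def test_homogeneous_in_concentration(self, s, cm):
        assert edi(2 * cm, s) == pytest.approx(2 * edi(cm, s))

    @given(cm=st.floats(0.001, 100), bw=st.floats(5, 150), fir=st.floats(1, 500))
    def test_chronic_scenario_factor_cancels(self, cm, bw, fir):
        """When TA = EFr * ED the full equation collapses to FIR*Cm/BW*1e-3."""
        efr, ed = 365.0, 72.3
        s = ExposureScenario("s", bw, fir, efr, ed, efr * ed)
        assert s.is_chronic
        assert edi(cm, s) == pytest.approx(fir * cm / bw * 1e-3, rel=1e-12)

    def test_nonpositive_scenario_parameter_rejected(self):
        with pytest.raises(ValueError):
            ExposureScenario("bad", body_weight_kg=0, intake_rate_g_per_day=60)


class TestThqHi:
    def test_matches_printed_chromium_quotient(self, adult):
        assert thq(1.66e-3, 0.003) == pytest.approx(0.5533, abs=1e-3)

    def test_unity_at_threshold(self):
        assert thq(0.003, 0.003) == 1.0

    def test_zero(self):
        assert thq(0.0, 0.04) == 0.0

    def test_hi_matches_published_sum(self):
        assert hazard_index([0.554, 0.319, 0.044, 0.254, 0.001]) == pytest.approx(1.172)

    def test_hi_of_single_element_and_zeros(self):
        assert hazard_index([0.7]) == 0.7
        assert hazard_index([0.0, 0.0]) == 0.0

    def test_hi_empty_rejected(self):
        with pytest.raises(ValueError):
            hazard_index([])

    @given(st.lists(st.floats(0, 10), min_size=1, max_size=8))
    def test_hi_permutation_invariant_and_superadditive(self, qs):
        assert hazard_index(qs) == pytest.approx(hazard_index(qs[::-1]))
        assert hazard_index(qs) >= max(qs) - 1e-12
        if len(qs) > 1:
            parts = hazard_index(qs[:1]) + hazard_index(qs[1:])
            assert parts == pytest.approx(hazard_index(qs))

    @given(e=st.floats(0, 1), rfd=st.floats(1e-5, 1), csf=st.floats(1e-3, 10))
    def test_algebraic_round_trips(self, e, rfd, csf):
        assert thq(e, rfd) * rfd == pytest.approx(e, rel=1e-12, abs=1e-300)
        assert tr(e, csf) / csf == pytest.approx(e, rel=1e-12, abs=1e-300)


class TestTr:
    @pytest.mark.parametrize(
        "e,csf,expected",
        [(1.66e-3, 0.5, 8.30e-4), (1.28e-3, 0.0085, 1.088e-5), (0.0, 1.5, 0.0)],
    )
    def test_published_carcinogenic_risks(self, e, csf, expected):
        assert tr(e, csf) == pytest.approx(expected, rel=1e-3, abs=1e-12)


class TestClassifyTr:
    @pytest.mark.parametrize(
        "value,band",
        [
            (8.31e-4, "unacceptable"),
            (3.39e-7, "negligible"),
            (1e-6, "tolerable"),
            (1e-4, "tolerable"),
            (5e-5, "tolerable"),
            (0.0, "negligible"),
        ],
    )
    def test_bands(self, value, band):
        assert classify_tr(value) == band

    @given(st.floats(0, 1e-2), st.floats(0, 1e-2))
    def test_monotone(self, a, b):
        severity = {"negligible": 0, "tolerable": 1, "unacceptable": 2}
        lo, hi = sorted([a, b])
        assert severity[classify_tr(lo)] <= severity[classify_tr(hi)]


class TestPtdi:
    def test_lead_exceeds(self):
        exceeds, ratio = flag_ptdi(1.28e-3, 3.57e-4)
        assert exceeds and ratio > 3

    def test_chromium_within(self):
        exceeds, _ = flag_ptdi(1.66e-3, 3.00e-3)
        assert not exceeds

    def test_equality_compliant(self):
        exceeds, ratio = flag_ptdi(5e-4, 5e-4)
        assert not exceeds and ratio == 1.0


def pooled_summaries(config):
    """Exact pooled concentrations of the reproduction profile."""
    from hmrisk.synthetic import study_profile

    gen = study_profile(config=config)
    rows = [
        {"species_id": sid, "metal": metal, "season": "pooled",
         "mean_ww": cm, "n": 6, "substituted_fraction": 0.0}
        for (sid, metal), cm in gen.target_pooled_cm_ww.items()
    ]
    return pd.DataFrame(rows)


class TestRiskTable:
    def test_reproduction_profile_counts(self, config):
        """4 species x 5 metals x 2 scenarios; Cu carries no slope factor."""
        table = build_risk_table(
            pooled_summaries(config), list(config.scenarios.values()), config.tox
        )
        assert len(table.per_metal) == 40
        assert table.per_metal["edi"].notna().all()
        assert table.per_metal["thq"].notna().all()
        assert table.per_metal["tr"].notna().sum() == 32
        assert table.per_metal.loc[table.per_metal.metal == "Cu", "tr"].isna().all()
        assert len(table.hi) == 8

    def test_hi_equals_sum_of_group_thqs(self, config):
        table = build_risk_table(
            pooled_summaries(config), list(config.scenarios.values()), config.tox
        )
        for (sid, sc), grp in table.per_metal.groupby(["species_id", "scenario"]):
            hi = table.hi.query("species_id == @sid and scenario == @sc")["hi"].iloc[0]
            assert hi == pytest.approx(grp["thq"].sum(), rel=1e-12)

    def test_child_rows_are_four_times_adult(self, config):
        table = build_risk_table(
            pooled_summaries(config), list(config.scenarios.values()), config.tox
        ).per_metal
        merged = table[table.scenario == "child"].merge(
            table[table.scenario == "adult"],
            on=["species_id", "metal"],
            suffixes=("_c", "_a"),
        )
        for col in ("edi", "thq", "tr"):
            sub = merged.dropna(subset=[f"{col}_c"])
            assert np.allclose(sub[f"{col}_c"], 4 * sub[f"{col}_a"])

    def test_single_metal_hi_equals_thq(self, adult):
        summaries = pd.DataFrame(
            [{"species_id": "sp", "metal": "Cd", "season": "pooled",
              "mean_ww": 0.2, "n": 3, "substituted_fraction": 0.0}]
        )
        tox = {"Cd": ToxProfile("Cd", rfd=0.001, csf=0.38, ptdi=8.3e-4)}
        table = build_risk_table(summaries, [adult], tox)
        assert len(table.per_metal) == 1
        assert table.hi["hi"].iloc[0] == pytest.approx(table.per_metal["thq"].iloc[0])

    def test_missing_metal_rejected_not_zero_filled(self, config, adult):
        summaries = pooled_summaries(config)
        summaries = summaries[
            ~((summaries.species_id == "wallagu_attu") & (summaries.metal == "Cd"))
        ]
        with pytest.raises(ValueError, match="wallagu_attu.*Cd"):
            build_risk_table(summaries, [adult], config.tox)

    def test_trophic_ordering_of_intake(self, config):
        """Carnivore > omnivores > herbivore intake for Cr, Cu and Cd."""
        table = build_risk_table(
            pooled_summaries(config), list(config.scenarios.values()), config.tox
        ).per_metal
        habit = {sid: p.feeding_habit for sid, p in config.species.items()}
        adult_rows = table[table.scenario == "adult"]
        for metal in ("Cr", "Cu", "Cd"):
            sub = adult_rows[adult_rows.metal == metal].set_index("species_id")["edi"]
            carn = [v for s, v in sub.items() if habit[s] == "carnivore"]
            omni = [v for s, v in sub.items() if habit[s] == "omnivore"]
            herb = [v for s, v in sub.items() if habit[s] == "herbivore"]
            assert min(carn) > max(omni) > min(omni) > max(herb)
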