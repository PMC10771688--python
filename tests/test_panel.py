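"""Outcome operators, lagging, quartiles and panel assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pssnet import months, panel, pipeline, pss, synth
from pssnet.defaults import ConfigurationError

SIX_MONTHS = months.month_range("2020-03", "2020-08")


def brute_force_discontinuation(pss_months, study_months, gap=3):
    """Oracle: scan every month after the first dispensation for a full gap."""
    first = min(pss_months)
    for i, m in enumerate(study_months):
        if m <= first:
            continue
        window = study_months[i : i + gap]
        if len(window) == gap and all(w not in pss_months for w in window):
            return m
    return None


def test_discontinuation_all_patterns_over_six_months():
    """Exhaustive check of the 3-month-gap rule on every dispensation pattern."""
    for bits in itertools.product([0, 1], repeat=6):
        if not any(bits):
            continue
        pss_set = {m for m, b in zip(SIX_MONTHS, bits) if b}
        expected = brute_force_discontinuation(pss_set, SIX_MONTHS)
        assert panel.discontinuation_month(pss_set, SIX_MONTHS) == expected


def test_discontinuation_examples():
    study = months.month_range("2020-03", "2021-08")
    # dispensation in June only; July-September empty -> event July
    assert panel.discontinuation_month({"2020-06"}, study) == "2020-07"
    # dispensations every month -> no event
    assert panel.discontinuation_month(set(study), study) is None
    # June 2021 then nothing: only 2 observable empty months remain -> censored
    assert panel.discontinuation_month({"2021-06"}, study) is None


def test_discontinuation_outcome_and_preconditions():
    study = months.month_range("2020-03", "2021-08")
    assert panel.discontinuation_outcome({"2020-06"}, "2020-07", study) == 1
    assert panel.discontinuation_outcome({"2020-06"}, "2020-08", study) == 0
    with pytest.raises(ValueError):
        panel.discontinuation_outcome({"2020-06"}, "2020-05", study)
    with pytest.raises(ValueError):
        panel.discontinuation_month(set(), study)


def test_adoption_outcome():
    assert panel.adoption_outcome("2020-07", "2020-07") == 1
    assert panel.adoption_outcome("2020-07", "2020-06") == 0
    assert panel.adoption_outcome(None, "2020-06") == 0


def test_quartile_scheme_modes():
    s = panel.QuartileScheme("caseload", (2, 6, 13), "printed", closed="right")
    vals = pd.Series([1, 2, 3, 6, 7, 13, 14, 50])
    assert s.assign(vals).tolist() == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]
    e = panel.QuartileScheme("experience", (4.5, 10.9, 22.4), "printed", closed="left")
    vals = pd.Series([4.4, 4.5, 10.8, 10.9, 22.3, 22.4])
    assert e.assign(vals).tolist() == ["Q1", "Q2", "Q2", "Q3", "Q3", "Q4"]
    with pytest.raises(ConfigurationError):
        panel.QuartileScheme("x", (3, 2, 5))


def test_empirical_quartiles_balanced_on_distinct_values():
    for n in (100, 101, 102, 103):
        vals = pd.Series(np.arange(n, dtype=float))
        scheme = panel.empirical_scheme("x", vals)
        counts = scheme.assign(vals).value_counts()
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == n


def test_case_mix_aggregates_small_case():
    clients = pd.DataFrame(
        {
            "client_id": ["C1", "C2", "C3", "C4"],
            "birth_year": [1950, 1990, 1985, 1960],
            "cci": [2, 0, 0, 1],
            "social_assistance_months": [3, 0, 0, 0],
            "overdose_date": ["2020-05-10", None, None, "2018-01-01"],
            "covid_diagnosis_date": [None, None, "2020-06-20", None],
        }
    ).set_index("client_id")
    agg = panel.aggregate_case_mix(["C1", "C2", "C3", "C4"], clients, {"C2"}, "2020-06")
    assert agg["pct_social_assistance"] == pytest.approx(25.0)
    assert agg["pct_cci_gt1"] == pytest.approx(25.0)
    assert agg["pct_benzo"] == pytest.approx(25.0)
    assert agg["pct_age40"] == pytest.approx(50.0)  # born 1950, 1960
    assert agg["pct_overdose_12m"] == pytest.approx(25.0)  # 2018 overdose too old
    assert agg["covid_flag"] == 1
    empty = panel.aggregate_case_mix([], clients, set(), "2020-06")
    assert all(v == 0 for v in empty.values())


@pytest.fixture(scope="module")
def assembled(small_data_module):
    data, analysis = small_data_module
    cfg = panel.PanelConfig()
    adoption_panel = panel.assemble_panel(
        "adoption", data.dispensations, analysis.classification, analysis.cohort,
        data.prescribers, data.clients, cfg,
    )
    disc_panel = panel.assemble_panel(
        "discontinuation", data.dispensations, analysis.classification, analysis.cohort,
        data.prescribers, data.clients, cfg,
    )
    return data, analysis, adoption_panel, disc_panel


@pytest.fixture(scope="module")
def small_data_module():
    cfg = synth.SimulationConfig(n_prescribers=150, n_clients=600, seed=7)
    data = synth.simulate(cfg)
    analysis = pipeline.run_analysis(data.tables, build_panels=False)
    return data, analysis


def test_adoption_panel_structure(assembled):
    data, analysis, ap, _ = assembled
    adoption = analysis.adoption.set_index("prescriber_id")
    assert not ap.duplicated(["prescriber_id", "month"]).any()
    assert ap["month"].min() >= "2020-05"
    by = dict(list(ap.groupby("prescriber_id")))
    for pid, row in adoption.iterrows():
        fp = row["first_pss_month"]
        if row["status"] == "innovator":
            assert pid not in by  # events before panel start leave no rows
        elif row["status"] == "early adopter":
            sub = by[pid]
            assert sub["month"].max() == fp
            assert sub["outcome"].sum() == 1 and sub.iloc[-1]["outcome"] == 1
        else:
            sub = by[pid]
            assert sub["outcome"].sum() == 0 and sub["month"].max() == "2021-08"
    # total row count equals sum of months at risk
    expected_rows = 0
    panel_months = [m for m in months.month_range("2020-03", "2021-08") if m >= "2020-05"]
    for pid, row in adoption.iterrows():
        fp = row["first_pss_month"]
        if row["status"] == "innovator":
            continue
        expected_rows += sum(1 for m in panel_months if fp is None or m <= fp)
    assert len(ap) == expected_rows


def test_discontinuation_panel_structure(assembled):
    data, analysis, _, dp = assembled
    study = months.month_range("2020-03", "2021-08")
    pm = pss.pss_months_by_prescriber(data.dispensations, analysis.classification)
    for pid, sub in dp.groupby("prescriber_id"):
        event = panel.discontinuation_month(pm[pid], study)
        first = min(pm[pid])
        assert sub["month"].min() >= max(months.shift(first, 1), "2020-07")
        if event is not None and event >= "2020-07":
            assert sub["month"].max() == event
            assert sub["outcome"].sum() == 1
        else:
            assert sub["outcome"].sum() == 0


def test_exposure_category_consistency(assembled):
    _, _, ap, _ = assembled
    from pssnet.network import categorize_exposure

    assert (categorize_exposure(ap["exposure"]).to_numpy() == ap["exposure_category"].to_numpy()).all()
    assert ((ap["exposure"] >= 0) & (ap["exposure"] <= 1)).all()
    assert ((ap["clustering"] >= 0) & (ap["clustering"] <= 1)).all()


def test_panel_regressors_match_generator_trace(assembled):
    """The estimator's regressors are exactly the generator's hazard inputs."""
    data, _, ap, _ = assembled
    trace = data.truth.hazard_trace
    merged = ap.merge(trace, on=["month", "prescriber_id"], suffixes=("", "_truth"), how="inner")
    assert len(merged) == len(ap)
    assert np.allclose(merged["exposure"], merged["exposure_truth"])


def test_no_future_leakage(assembled):
    """Recomputing covariates from data truncated at m-1 changes nothing."""
    data, analysis, ap, _ = assembled
    month = "2020-09"
    lag = "2020-08"
    sub = ap[ap["month"] == month]
    cutoff = months.month_end(lag)
    disp = data.dispensations
    truncated = disp[pd.to_datetime(disp["date"]) <= cutoff]
    cfg = panel.PanelConfig()
    covars = panel._monthly_covariates(
        truncated, analysis.cohort, data.clients, analysis.adoption, [lag], cfg
    )[lag]
    check_cols = ["exposure", "clustering", "adjusted_strength", "caseload_month", "pct_social_assistance"]
    recomputed = covars.loc[sub["prescriber_id"], check_cols].reset_index(drop=True)
    original = sub[check_cols].reset_index(drop=True)
    pd.testing.assert_frame_equal(recomputed, original, check_dtype=False)


def test_two_degree_exposure_column_available(small_data_module):
    data, analysis = small_data_module
    cfg = panel.PanelConfig(include_case_mix=False, include_two_degree=True)
    ap = panel.assemble_panel(
        "adoption", data.dispensations, analysis.classification, analysis.cohort,
        data.prescribers, data.clients, cfg,
    )
    assert "exposure_two_degree" in ap.columns
    # the two-step neighbourhood can only enlarge the adopter pool's reach
    assert ((ap["exposure_two_degree"] > 0) | (ap["exposure"] == 0)).all()


def test_medication_subgroup_variant(small_data_module):
    data, analysis = small_data_module
    cfg = panel.PanelConfig(include_case_mix=False, med_classes=["opioid"])
    ap_sub = panel.assemble_panel(
        "adoption", data.dispensations, analysis.classification, analysis.cohort,
        data.prescribers, data.clients, cfg,
    )
    ap_all = panel.assemble_panel(
        "adoption", data.dispensations, analysis.classification, analysis.cohort,
        data.prescribers, data.clients, panel.PanelConfig(include_case_mix=False),
    )
    # restricting to one medication class can only delay or remove initiations,
    # so prescribers stay at risk at least as long
    assert len(ap_sub) >= len(ap_all)
    sub = pss.derive_adoption(
        data.dispensations, analysis.classification, analysis.cohort, med_classes=["opioid"]
    ).set_index("prescriber_id")["first_pss_month"]
    full = analysis.adoption.set_index("prescriber_id")["first_pss_month"]
    for pid in sub.index:
        if sub[pid] is not None:
            assert full[pid] is not None and sub[pid] >= full[pid]


def test_mid_month_scheme_changes_binning(small_data_module):
    data, analysis = small_data_module
    cfg = panel.PanelConfig(scheme="mid-month")
    ap = panel.assemble_panel(
        "adoption", data.dispensations, analysis.classification, analysis.cohort,
        data.prescribers, data.clients, cfg,
    )
    assert len(ap) > 0  # pipeline-wide month switch runs end to end


def test_unknown_kind_rejected(small_data_module):
    data, analysis = small_data_module
    with pytest.raises(ConfigurationError):
        panel.assemble_panel(
            "uptake", data.dispensations, analysis.classification, analysis.cohort,
            data.prescribers, data.clients,
        )
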