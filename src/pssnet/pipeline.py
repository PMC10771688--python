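"""End-to-end analysis: record tables in, panels and model results out."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cohort as cohort_mod
from . import gee, panel as panel_mod, pss as pss_mod
from .defaults import (
    DEFAULT_DRUG_CLASS_MAP,
    DEFAULT_KEYWORD_CONFIG,
    DEFAULT_OAT_DRUG_CODES,
    DEFAULT_SUD_DIAGNOSTIC_CODES,
)


@dataclass
class AnalysisResult:
    sud_flags: pd.DataFrame
    cohort: list
    attachments: pd.DataFrame
    classification: pd.DataFrame
    adoption: pd.DataFrame
    adoption_panel: pd.DataFrame | None = None
    discontinuation_panel: pd.DataFrame | None = None
    adoption_fit: gee.ModelResult | None = None
    discontinuation_fit: gee.ModelResult | None = None


def run_analysis(
    tables: dict,
    algorithm: str = "sensitive",
    panel_config: panel_mod.PanelConfig | None = None,
    sud_codes=None,
    oat_codes=None,
    keyword_config: dict | None = None,
    drug_class_map: dict | None = None,
    build_panels: bool = True,
    fit_models: bool = False,
    adoption_spec: gee.ModelSpec | None = None,
    discontinuation_spec: gee.ModelSpec | None = None,
    study_window: tuple[str, str] = cohort_mod.STUDY_WINDOW,
) -> AnalysisResult:
    """Run cohort definition, case-finding, panels and (optionally) the models."""
    panel_config = panel_config or panel_mod.PanelConfig()
    disp = tables["dispensations"]
    flags = cohort_mod.flag_sud_clients(
        disp,
        tables["visits"],
        tables["acute_visits"],
        cohort_mod.perinatal_records(tables["clients"]),
        sud_codes or DEFAULT_SUD_DIAGNOSTIC_CODES,
        oat_codes or DEFAULT_OAT_DRUG_CODES,
    )
    cohort_ids, attachments = cohort_mod.build_prescriber_cohort(disp, flags, study_window)
    classification = pss_mod.classify_dispensations(
        disp, keyword_config or DEFAULT_KEYWORD_CONFIG, drug_class_map or DEFAULT_DRUG_CLASS_MAP, algorithm
    )
    adoption = pss_mod.derive_adoption(disp, classification, cohort_ids, scheme=panel_config.scheme)
    result = AnalysisResult(
        sud_flags=flags,
        cohort=cohort_ids,
        attachments=attachments,
        classification=classification,
        adoption=adoption,
    )
    if not build_panels:
        return result
    result.adoption_panel = panel_mod.assemble_panel(
        "adoption", disp, classification, cohort_ids, tables["prescribers"], tables["clients"], panel_config
    )
    result.discontinuation_panel = panel_mod.assemble_panel(
        "discontinuation", disp, classification, cohort_ids, tables["prescribers"], tables["clients"], panel_config
    )
    if fit_models:
        result.adoption_fit = gee.fit_panel_model(
            result.adoption_panel, adoption_spec or gee.adoption_spec()
        )
        if result.discontinuation_panel["outcome"].nunique() > 1:
            result.discontinuation_fit = gee.fit_panel_model(
                result.discontinuation_panel, discontinuation_spec or gee.discontinuation_spec()
            )
    return result
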