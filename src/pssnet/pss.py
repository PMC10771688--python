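"""Keyword-based case-finding for prescribed safer supply and adoption timing.

Safer-supply dispensations carry no dedicated drug identifiers, so they are
recognized by case-insensitive keyword patterns over the free-text
directions-for-use, restricted to an eligible medication-class set. The
*specific* algorithm's patterns and classes are a subset of the *sensitive*
one's, so its positive set is contained in the sensitive positive set on any
input.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from . import months
from .defaults import (
    DEFAULT_DRUG_CLASS_MAP,
    DEFAULT_KEYWORD_CONFIG,
    ConfigurationError,
    validate_keyword_config,
)

logger = logging.getLogger(__name__)

ALGORITHMS = ("sensitive", "specific")
INNOVATION_WINDOW = ("2020-03-27", "2020-04-30")
STATUSES = ("innovator", "early adopter", "non-adopter")


def classify_dispensations(
    dispensations: pd.DataFrame,
    keyword_config: dict | None = None,
    drug_class_map: dict | None = None,
    algorithm: str = "sensitive",
) -> pd.DataFrame:
    """Classify each dispensation as safer supply or not.

    A record is positive iff its medication class (looked up from
    ``drug_class_map`` by drug code, defaulting to "other") is in the
    algorithm's eligible class set AND its directions text contains at least
    one of the algorithm's patterns, case-insensitively. Records with null
    directions are negative and counted in a logged tally. Deterministic and
    order-independent.
    """
    if algorithm not in ALGORITHMS:
        raise ConfigurationError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    config = validate_keyword_config(keyword_config or DEFAULT_KEYWORD_CONFIG)[algorithm]
    class_map = drug_class_map if drug_class_map is not None else DEFAULT_DRUG_CLASS_MAP

    med_class = dispensations["drug_code"].map(class_map).fillna("other")
    text = dispensations["directions"]
    null_mask = text.isna()
    n_null = int(null_mask.sum())
    if n_null:
        logger.info("classify_dispensations: %d records with null directions treated as not-PSS", n_null)
    pattern = "|".join(re.escape(p) for p in config["patterns"])
    matched = text.fillna("").str.contains(pattern, case=False, regex=True)
    is_pss = matched & med_class.isin(set(config["med_classes"]))
    return pd.DataFrame(
        {
            "dispensation_id": dispensations["dispensation_id"],
            "is_pss": is_pss.to_numpy(),
            "algorithm": algorithm,
            "med_class": med_class.to_numpy(),
        }
    )


def pss_dispensations(
    dispensations: pd.DataFrame,
    classification: pd.DataFrame,
    med_classes=None,
) -> pd.DataFrame:
    """Dispensation records classified as safer supply.

    ``med_classes`` restricts to a medication-class subgroup (e.g. only
    opioids), for the per-medication subgroup analyses.
    """
    pos = classification.loc[classification["is_pss"], ["dispensation_id", "med_class"]]
    if med_classes is not None:
        pos = pos[pos["med_class"].isin(set(med_classes))]
    return dispensations.drop(columns=["med_class"], errors="ignore").merge(
        pos, on="dispensation_id"
    )


def derive_adoption(
    dispensations: pd.DataFrame,
    classification: pd.DataFrame,
    cohort,
    innovation_window: tuple[str, str] = INNOVATION_WINDOW,
    scheme: str = "calendar",
    med_classes=None,
) -> pd.DataFrame:
    """Adoption status per cohort prescriber.

    ``first_pss_month`` is the measurement month of the earliest safer-supply
    dispensation attributed to the prescriber (the prescriber of record).
    Innovators initiated within the innovation window; prescribers whose
    first dispensation is after the window end are early adopters; cohort
    members with no safer-supply dispensation are non-adopters.
    """
    window_end = pd.Timestamp(innovation_window[1])
    pss = pss_dispensations(dispensations, classification, med_classes=med_classes)
    first = pd.to_datetime(pss["date"]).groupby(pss["prescriber_id"]).min()
    rows = []
    for pid in sorted(set(cohort)):
        d = first.get(pid)
        if d is None or pd.isna(d):
            rows.append((pid, None, None, "non-adopter"))
        else:
            key = months.month_key(pd.Series([d]), scheme=scheme).iloc[0]
            status = "innovator" if d <= window_end else "early adopter"
            rows.append((pid, str(d.date()), key, status))
    return pd.DataFrame(rows, columns=["prescriber_id", "first_pss_date", "first_pss_month", "status"])


def pss_months_by_prescriber(
    dispensations: pd.DataFrame,
    classification: pd.DataFrame,
    scheme: str = "calendar",
    med_classes=None,
) -> dict[str, set[str]]:
    """Set of measurement months with >=1 safer-supply dispensation, per prescriber."""
    pss = pss_dispensations(dispensations, classification, med_classes=med_classes)
    if not len(pss):
        return {}
    keys = months.month_key(pss["date"], scheme=scheme)
    return {p: set(g) for p, g in keys.groupby(pss["prescriber_id"])}
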