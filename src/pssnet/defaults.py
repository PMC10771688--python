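"""Default code sets and the safer-supply case-finding keyword configuration.

Safer-supply dispensations carry no dedicated drug identification numbers, so
they are found by matching keywords the prescriber wrote in the
directions-for-use text against a list of eligible medications. Two tiers are
defined: a *sensitive* algorithm (broad keyword list, catches more true
dispensations at the cost of specificity) and a *specific* one whose keywords
and eligible drugs are a subset of the sensitive tier. Every list below is a
configurable default — deployments replace them with their own lexicon via
YAML without touching code.
"""

from __future__ import annotations

from typing import Any

import yaml

# Diagnostic codes indicating a substance use disorder; matched by prefix
# against the code recorded on the visit (ICD-9 304/305.x and ICD-10 F1x).
DEFAULT_SUD_DIAGNOSTIC_CODES: list[str] = [
    "304", "305",
    "F10", "F11", "F12", "F13", "F14", "F15", "F16", "F18", "F19",
]

# Opioid agonist treatment drug codes (methadone, buprenorphine-naloxone).
DEFAULT_OAT_DRUG_CODES: list[str] = ["METHADONE", "BUP-NX", "SLOW-METHADONE"]

# Medication class per drug code for every drug the generator emits.
DEFAULT_DRUG_CLASS_MAP: dict[str, str] = {
    # safer-supply-eligible medications
    "HYDROMORPHONE-TAB": "opioid",
    "MORPHINE-SR": "opioid",
    "DEXTROAMPHETAMINE": "stimulant",
    "METHYLPHENIDATE": "stimulant",
    "DIAZEPAM": "benzodiazepine",
    "CLONAZEPAM": "benzodiazepine",
    # common background medications
    "METHADONE": "other",
    "BUP-NX": "other",
    "SLOW-METHADONE": "other",
    "AMOXICILLIN": "other",
    "RAMIPRIL": "other",
    "METFORMIN": "other",
    "SERTRALINE": "other",
    "LORAZEPAM": "benzodiazepine",
    "GABAPENTIN": "other",
}

PSS_MED_CLASSES = ("opioid", "stimulant", "benzodiazepine")

# Keyword patterns are matched case-insensitively as substrings of the
# directions-for-use text. The specific tier must be a subset of the
# sensitive tier (enforced by validate_keyword_config).
DEFAULT_KEYWORD_CONFIG: dict[str, Any] = {
    "sensitive": {
        "patterns": [
            "risk mitigation",
            "rmg",
            "safer supply",
            "safe supply",
            "pandemic",
            "covid",
            "witnessed daily",
        ],
        "med_classes": ["opioid", "stimulant", "benzodiazepine"],
    },
    "specific": {
        "patterns": ["risk mitigation", "rmg", "safer supply"],
        "med_classes": ["opioid", "stimulant", "benzodiazepine"],
    },
}


class ConfigurationError(ValueError):
    """Raised for invalid run-time configuration (bad vectors, windows, sets)."""


def validate_keyword_config(config: dict[str, Any]) -> dict[str, Any]:
    """Check structure and the specific-within-sensitive containment."""
    for algo in ("sensitive", "specific"):
        if algo not in config:
            raise ConfigurationError(f"keyword config missing {algo!r} section")
        section = config[algo]
        if not section.get("patterns"):
            raise ConfigurationError(f"keyword config {algo!r} has no patterns")
        if not section.get("med_classes"):
            raise ConfigurationError(f"keyword config {algo!r} has no med_classes")
    sens, spec = config["sensitive"], config["specific"]
    if not set(spec["patterns"]) <= set(sens["patterns"]):
        raise ConfigurationError("specific patterns must be a subset of sensitive patterns")
    if not set(spec["med_classes"]) <= set(sens["med_classes"]):
        raise ConfigurationError("specific med_classes must be a subset of sensitive med_classes")
    return config


def load_keyword_config(path: str) -> dict[str, Any]:
    with open(path) as fh:
        return validate_keyword_config(yaml.safe_load(fh))


def load_code_sets(path: str) -> dict[str, list[str]]:
    """Load YAML with ``sud_diagnostic_codes`` and ``oat_drug_codes`` lists."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("sud_diagnostic_codes", "oat_drug_codes"):
        if not raw.get(key):
            raise ConfigurationError(f"code set file missing non-empty {key!r}")
    return raw
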