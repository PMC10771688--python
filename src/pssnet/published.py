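"""Reference tallies from the province-wide BC safer-supply rollout.

These are the published cohort counts for the March 2020 - August 2021
study period in British Columbia (14,137 prescribers caring for clients with
a substance use disorder). They are inputs for replication arithmetic:
stratum percentages are recomputed from the counts with the package's own
rounding, never hard-coded. The two "stopped prescribing" tallies (653 and
734 of the 1,290 initiators; 673 of the early adopters) come from different
summary conventions and are each checked against their own denominator.
"""

from __future__ import annotations

from .report import percent

REFERENCE_COUNTS = {
    "prescribers_total": 14137,
    "innovators": 228,
    "early_adopters": 1062,
    "non_adopters": 12847,
    "early_adopters_stopped": 673,
    "innovators_stopped": 62,
    "initiators_stopped": 653,
    "initiators_lapsed_at_end": 734,
}

#: (numerator key, denominator key) per reported percentage.
PERCENTAGE_DEFINITIONS = {
    "pct_innovators": ("innovators", "prescribers_total"),
    "pct_early_adopters": ("early_adopters", "prescribers_total"),
    "pct_non_adopters": ("non_adopters", "prescribers_total"),
    "pct_early_adopters_stopped": ("early_adopters_stopped", "early_adopters"),
    "pct_innovators_stopped": ("innovators_stopped", "innovators"),
    "pct_initiators_stopped": ("initiators_stopped", "initiators_total"),
    "pct_initiators_lapsed_at_end": ("initiators_lapsed_at_end", "initiators_total"),
}


def reference_percentages() -> dict[str, float]:
    """Stratum percentages recomputed from the published counts."""
    counts = dict(REFERENCE_COUNTS)
    counts["initiators_total"] = counts["innovators"] + counts["early_adopters"]
    return {
        name: percent(counts[num], counts[den])
        for name, (num, den) in PERCENTAGE_DEFINITIONS.items()
    }
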