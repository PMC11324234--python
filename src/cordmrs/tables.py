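"""Published cohort characteristic counts and simple summary arithmetic.

The three NutriGen birth cohorts (CHILD and FAMILY, predominantly White
European; START, South Asian) report maternal smoking history with the
ordinal coding 0 = never smoked, 1 = quit before this pregnancy, 2 = quit
during this pregnancy, 3 = currently smoking. The counts below are the
published epigenetic-subsample characteristics and are used both as the
reference conditions for the synthetic cohort generator and for the
descriptive arithmetic reported by the acceptance script.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SMOKING_HISTORY_COUNTS",
    "COHORT_SIZES",
    "EUROPEAN_COHORTS",
    "smoking_history_table",
    "complete_pairs",
    "current_smoker_count",
    "current_smoker_percent",
]

#: per-cohort smoking-history counts (epigenetic subsample); "missing" is
#: the count of mothers without a recorded smoking history.
SMOKING_HISTORY_COUNTS: dict[str, dict[str, int]] = {
    "CHILD": {"never": 247, "quit_before": 72, "quit_during": 17, "current": 11,
              "missing": 5},
    "FAMILY": {"never": 253, "quit_before": 58, "quit_during": 57, "current": 29,
               "missing": 14},
    "START": {"never": 501, "quit_before": 1, "quit_during": 1, "current": 0,
              "missing": 1},
}

COHORT_SIZES = {"CHILD": 352, "FAMILY": 411, "START": 504}

EUROPEAN_COHORTS = ("CHILD", "FAMILY")

_CATEGORIES = ("never", "quit_before", "quit_during", "current")


def smoking_history_table() -> pd.DataFrame:
    """Smoking-history counts as a cohorts × categories DataFrame."""
    return pd.DataFrame(SMOKING_HISTORY_COUNTS).T


def complete_pairs(cohorts: tuple[str, ...] = EUROPEAN_COHORTS) -> int:
    """Mother–newborn pairs with non-missing smoking history."""
    return sum(
        sum(SMOKING_HISTORY_COUNTS[c][k] for k in _CATEGORIES) for c in cohorts
    )


def current_smoker_count(cohorts: tuple[str, ...] = EUROPEAN_COHORTS) -> int:
    """Newborns exposed to current maternal smoking."""
    return sum(SMOKING_HISTORY_COUNTS[c]["current"] for c in cohorts)


def current_smoker_percent(cohorts: tuple[str, ...] = EUROPEAN_COHORTS) -> float:
    """Current-smoker percentage among complete pairs."""
    return 100.0 * current_smoker_count(cohorts) / complete_pairs(cohorts)
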