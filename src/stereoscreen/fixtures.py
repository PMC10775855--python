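"""Reference tables from the source screening study, loaded read-only.

These small fixtures carry the study's published summary numbers: the
age-by-condition demographics, per-test participant counts, sensitivity /
specificity strings, worked perceptron input-output examples, and the
reconstructed 2x2 tables behind the sensitivity and specificity
comparisons. They feed tests and the evaluation report templates; none of
them contain subject-level raw data (which was never deposited).
"""

from __future__ import annotations

import numpy as np

from .evalstats import ContingencyTable


class UnknownFixtureError(KeyError):
    pass


# age band x (eye condition, control); 423 children in total
TABLE2_AGE = ContingencyTable(
    counts=np.array([
        [4, 1], [45, 59], [28, 24], [40, 27], [31, 22], [19, 21], [62, 40],
    ]),
    row_labels=["3.5-4", "4-5", "5-6", "6-7", "7-8", "8-9", "9-15"],
    col_labels=["eye_condition", "control"])

# participants examined with every test, by group
TABLE5_COMPLETE_CASES = {
    "amblyopia": 23, "amblyogenic": 23,
    "nonamblyogenic": 39, "control": 45, "total": 130}

TABLE5_GROUP_TOTALS = {
    "amblyopia": 46, "amblyogenic": 55,
    "nonamblyogenic": 128, "control": 194, "total": 423}

# merged with/without-correction training set size
MERGED_DATASET_SIZE = 182

# sensitivity (joint pathologic group) and specificity with exact 95% CIs,
# as printed; selected rows used by the tests
TABLE8_SELECTED = {
    "AI-aw WC": {"sens": (0.83, 0.69, 0.92), "sens_n": 46,
                 "sens_successes": 38,
                 "spec": (0.89, 0.76, 0.96), "spec_n": 45},
    "TNO": {"sens": (0.66, 0.55, 0.76), "sens_n": 88,
            "sens_successes": 58,
            "spec": (0.91, 0.86, 0.95), "spec_n": 183},
}

# worked perceptron examples: score vectors (S8, D1, D07, D1N) and the
# published logsig outputs. The outputs depend on unpublished trained
# weights and are reference metadata only, never asserted.
TABLE9_EXAMPLES = {
    "true_negatives": {
        "inputs": [(5, 4, 5, 4), (5, 3, 3, 2), (5, 4, 4, 4),
                   (5, 3, 4, 3), (5, 5, 5, 5)],
        "outputs": [0.788, 0.559, 0.751, 0.602, 0.881]},
    "false_positives": {
        "inputs": [(5, 1, 3, 1), (5, 3, 1, 1)],
        "outputs": [0.236, 0.464]},
    "true_positives": {
        "inputs": [(1, 1, 0, 1), (1, 2, 2, 3), (5, 2, 4, 1),
                   (5, 2, 1, 2), (5, 2, 2, 4)],
        "outputs": [0.001, 0.001, 0.438, 0.290, 0.321]},
    "false_negatives": {
        "inputs": [(5, 5, 5, 4), (5, 5, 4, 4), (5, 4, 4, 3),
                   (5, 5, 4, 4), (5, 3, 5, 3)],
        "outputs": [0.884, 0.861, 0.757, 0.861, 0.650]},
}

# 2x2 tables reconstructed from the printed sensitivities/specificities:
# rows = test (TNO, AI combination), columns = (detected, missed)
FISHER_SENSITIVITY = ContingencyTable(
    counts=np.array([[58, 30], [38, 8]]),
    row_labels=["TNO", "AI-aw WC"], col_labels=["detected", "missed"])

FISHER_SPECIFICITY = ContingencyTable(
    counts=np.array([[166, 17], [40, 5]]),
    row_labels=["TNO", "AI-aw WC"], col_labels=["correct", "false_positive"])

# exact-McNemar p-values for the AI combination against the four classic
# tests (Frisby, Lang II, Stereo Fly, TNO) on the joint pathologic group
MCNEMAR_PVALUES = [0.0117, 0.0129, 0.0129, 0.508]

_REGISTRY = {
    "table2_age": TABLE2_AGE,
    "table5_complete_cases": TABLE5_COMPLETE_CASES,
    "table5_group_totals": TABLE5_GROUP_TOTALS,
    "merged_dataset_size": MERGED_DATASET_SIZE,
    "table8_selected": TABLE8_SELECTED,
    "table9_examples": TABLE9_EXAMPLES,
    "table9_true_positives": TABLE9_EXAMPLES["true_positives"],
    "fisher_sensitivity": FISHER_SENSITIVITY,
    "fisher_specificity": FISHER_SPECIFICITY,
    "mcnemar_pvalues": MCNEMAR_PVALUES,
}


def available_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def load_fixtures(name: str):
    """Look up a reference fixture by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        ) from None
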