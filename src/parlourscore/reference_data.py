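"""Published summary counts from a two-farm field study of in-parlour lameness scoring.

The study observed two pasture-based New Zealand dairy herds monthly over one
lactation season (nine visits, August-April).  Whole-herd locomotion scoring on
the DairyNZ 0-3 scale was followed a day later by in-parlour scoring of every
third cow for four binary indicators: shifting weight (SW), abnormal weight
distribution (AWD), swollen heel or hock joint (SHH), and overgrown hoof (OH).
Only the published marginal tables are available (the joint record-level data
were never deposited); this module holds those counts verbatim.  They serve two
purposes:

* calibration targets and monthly visit sizes for the study-like simulation
  preset in :mod:`parlourscore.simulate`;
* inputs for worked examples that recompute the study's printed statistics
  (diagnostic metrics of the >=2-indicator composite, classifier metrics of the
  best cross-validation fold) from marginals alone.
"""

from __future__ import annotations

import numpy as np

from .diagnostics import ContingencyTable2x2

MONTH_NAMES = (
    "August", "September", "October", "November", "December",
    "January", "February", "March", "April",
)

#: Monthly locomotion-score counts (rows = visit month, cols = LS 0,1,2,3) for
#: cow-visits that also had an in-parlour score.  Farm totals: 3006 and 1119.
LS_MONTHLY_COUNTS = {
    "farm1": np.array(
        [
            [220, 82, 8, 0],
            [226, 95, 5, 0],
            [228, 101, 8, 1],
            [240, 85, 10, 1],
            [254, 86, 10, 0],
            [246, 81, 12, 2],
            [260, 63, 9, 0],
            [261, 66, 9, 0],
            [197, 122, 15, 3],
        ]
    ),
    "farm2": np.array(
        [
            [73, 31, 4, 0],
            [70, 43, 5, 0],
            [67, 50, 3, 1],
            [89, 32, 5, 0],
            [93, 24, 5, 0],
            [87, 36, 5, 1],
            [80, 39, 4, 1],
            [89, 42, 3, 0],
            [93, 41, 3, 0],
        ]
    ),
}

#: Published farm-level LS class shares (percent of observations per farm).
LS_CLASS_PCT = {
    "farm1": np.array([70.9, 26.0, 2.9, 0.2]),
    "farm2": np.array([66.2, 30.2, 3.3, 0.3]),
}

#: Counts of cow-visits with each indicator present, per farm.
INDICATOR_PRESENT_COUNTS = {
    "farm1": {"sw": 234, "awd": 257, "shh": 145, "oh": 416},
    "farm2": {"sw": 67, "awd": 95, "shh": 71, "oh": 237},
}

#: Distribution of the number of positive indicators per cow-visit
#: (0, 1, 2, 3 positives; no cow showed all four).
POSITIVE_COUNT_DISTRIBUTION = {
    "farm1": np.array([2094, 786, 115, 11]),
    "farm2": np.array([713, 351, 46, 9]),
}

#: Published sensitivity/specificity (proportions) of each indicator and of the
#: composite thresholds for detecting locomotion score >= 2, pooled farms.
SCREENING_SE_SP = {
    "sw": (0.421, 0.939),
    "awd": (0.474, 0.928),
    "shh": (0.767, 0.971),
    "oh": (0.429, 0.851),
    "ge1": (1.000, 0.703),
    "ge2": (0.932, 0.986),
    "eq3": (0.150, 1.000),
}

#: Confusion matrix of the best cross-validation fold's decision-tree
#: classifier on its 1030-observation test set.  Rows = true LS class
#: {0, 1, >=2}, columns = predicted class.
BEST_TREE_CONFUSION = np.array(
    [
        [697, 21, 0],
        [4, 274, 2],
        [0, 8, 24],
    ]
)


def ls_totals(farm: str) -> np.ndarray:
    """Total LS class counts for a farm (length-4 vector)."""
    return LS_MONTHLY_COUNTS[farm].sum(axis=0)


def pooled_ls_totals() -> np.ndarray:
    """LS class counts pooled over both farms."""
    return sum(ls_totals(f) for f in LS_MONTHLY_COUNTS)


def monthly_visit_totals(farm: str) -> np.ndarray:
    """Number of matched cow-visits per monthly visit for a farm."""
    return LS_MONTHLY_COUNTS[farm].sum(axis=1)


def n_lame() -> int:
    """Pooled number of lame reference observations (LS >= 2)."""
    return int(pooled_ls_totals()[2:].sum())


def pooled_indicator_positives(indicator: str) -> int:
    """Pooled count of cow-visits with a given indicator present."""
    return sum(INDICATOR_PRESENT_COUNTS[f][indicator] for f in INDICATOR_PRESENT_COUNTS)


def composite_ge2_positives() -> int:
    """Pooled count of cow-visits with two or more positive indicators."""
    return int(sum(POSITIVE_COUNT_DISTRIBUTION[f][2:].sum() for f in POSITIVE_COUNT_DISTRIBUTION))


def reconstruct_2x2(sensitivity: float, n_positive: int) -> ContingencyTable2x2:
    """Reconstruct a screening 2x2 table from published marginals.

    The study prints, for each test, its sensitivity against the LS >= 2
    reference and (via the indicator tables) the total number of test-positive
    cow-visits, but not the joint 2x2 table.  With the pooled number of lame
    observations known, ``tp = round(sensitivity * n_lame)`` recovers the only
    integer table consistent with the printed rounding, and the remaining
    cells follow from the margins.

    Parameters
    ----------
    sensitivity : float
        Published sensitivity of the test, as a proportion.
    n_positive : int
        Total number of test-positive observations (tp + fp).
    """
    lame = n_lame()
    total = int(pooled_ls_totals().sum())
    tp = int(round(sensitivity * lame))
    fn = lame - tp
    fp = n_positive - tp
    tn = total - tp - fn - fp
    return ContingencyTable2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def composite_ge2_table() -> ContingencyTable2x2:
    """Reconstructed 2x2 table of the >=2-indicator composite vs LS >= 2."""
    return reconstruct_2x2(SCREENING_SE_SP["ge2"][0], composite_ge2_positives())


def indicator_table(indicator: str) -> ContingencyTable2x2:
    """Reconstructed 2x2 table of a single indicator vs LS >= 2."""
    return reconstruct_2x2(
        SCREENING_SE_SP[indicator][0], pooled_indicator_positives(indicator)
    )
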