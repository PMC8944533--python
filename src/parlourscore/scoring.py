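"""Pairing of locomotion and in-parlour records, and composite classification.

The study design scores the whole herd's locomotion one day and every third
cow in the parlour the next; only cow-visits with both scores enter the
analysis.  This module performs that inner join, amalgamates locomotion
scores into the binary lame reference (LS >= 2) and the three-class outcome
{0, 1, >=2}, and classifies cow-visits by composite indicator-count
thresholds (at least k, or exactly k, positive indicators).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ValidationError

INDICATORS = ("sw", "awd", "shh", "oh")
JOIN_KEY = ["farm", "month", "cow_id"]

#: Display labels of the three-class locomotion outcome.
LS3_LABELS = ("0", "1", ">=2")


@dataclass
class MatchedDataset:
    """Inner-joined LS/IPS records plus the join accounting report."""

    data: pd.DataFrame
    report: dict

    @property
    def n(self) -> int:
        return len(self.data)


def _check_unique_keys(frame: pd.DataFrame, side: str) -> None:
    dup = frame.duplicated(subset=JOIN_KEY, keep=False)
    if dup.any():
        key = tuple(frame.loc[dup.idxmax(), JOIN_KEY])
        raise ValidationError(f"duplicate {side} record for key (farm, month, cow_id) = {key}")


def pair_records(ls_records: pd.DataFrame, ips_records: pd.DataFrame) -> MatchedDataset:
    """Inner-join locomotion and in-parlour records on (farm, month, cow_id).

    Unmatched records on either side are dropped and counted in the report
    (``matched``, ``ls_only``, ``ips_only``).  Duplicate keys within a side
    raise a validation error naming the offending key.
    """
    _check_unique_keys(ls_records, "locomotion")
    _check_unique_keys(ips_records, "in-parlour")
    merged = ls_records.merge(ips_records, on=JOIN_KEY, how="inner")
    report = {
        "matched": len(merged),
        "ls_only": len(ls_records) - len(merged),
        "ips_only": len(ips_records) - len(merged),
    }
    return MatchedDataset(data=merged, report=report)


def split_ls_ips(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split simulated cow-visit records into the two source tables.

    Convenience inverse of :func:`pair_records` for simulated data: the LS
    table keeps the locomotion score, the IPS table keeps the indicator flags.
    """
    ls = frame[JOIN_KEY + ["ls"]].copy()
    ips = frame[JOIN_KEY + [c for c in frame.columns if c not in JOIN_KEY + ["ls"]]].copy()
    return ls, ips


@dataclass(frozen=True)
class CompositeThreshold:
    """Composite rule over the indicator count: at least k, or exactly k."""

    k: int
    mode: str = "at_least"  # "at_least" or "exactly"

    def __post_init__(self) -> None:
        if self.k not in (1, 2, 3, 4):
            raise ValidationError(f"threshold k must be in 1..4, got {self.k}")
        if self.mode not in ("at_least", "exactly"):
            raise ValidationError(f"mode must be 'at_least' or 'exactly', got {self.mode!r}")


def indicator_count(obs):
    """Number of positive analysed indicators (0..4).

    Accepts a DataFrame (returns a Series) or a single record as a mapping/
    Series (returns an int).  Missing analysed flags are a validation error.
    """
    if isinstance(obs, pd.DataFrame):
        block = obs[list(INDICATORS)]
        if block.isna().any().any():
            raise ValidationError("analysed indicator flags must not be missing")
        values = block.to_numpy(dtype=int)
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("analysed indicator flags must be 0 or 1")
        return pd.Series(values.sum(axis=1), index=obs.index, name="indicator_count")
    total = 0
    for name in INDICATORS:
        v = obs[name]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValidationError(f"indicator {name} is missing")
        if v not in (0, 1):
            raise ValidationError(f"indicator {name} must be 0 or 1, got {v!r}")
        total += int(v)
    return total


def classify_composite(obs, threshold: CompositeThreshold):
    """Binary test-positive flag of the composite rule for one or many records."""
    count = indicator_count(obs)
    if threshold.mode == "at_least":
        positive = count >= threshold.k
    else:
        positive = count == threshold.k
    if isinstance(positive, pd.Series):
        return positive.astype(int)
    return int(positive)


def _validated_ls(ls):
    arr = np.asarray(ls)
    if not np.isin(arr, (0, 1, 2, 3)).all():
        bad = arr[~np.isin(arr, (0, 1, 2, 3))]
        raise ValidationError(f"locomotion score outside 0..3: {bad.flat[0]!r}")
    return arr


def amalgamate_ls(ls):
    """Binary lame flag: 1 iff locomotion score >= 2 (scores 2 and 3 pooled)."""
    arr = _validated_ls(ls)
    lame = (arr >= 2).astype(int)
    return lame if arr.ndim else int(lame)


def ls_class3(ls):
    """Three-class locomotion outcome {0, 1, >=2}, encoded 0/1/2."""
    arr = _validated_ls(ls)
    cls = np.minimum(arr, 2).astype(int)
    return cls if arr.ndim else int(cls)
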