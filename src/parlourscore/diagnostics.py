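"""Diagnostic-test evaluation of in-parlour scores against the lameness reference.

A cow-visit is reference-positive ("lame") when its locomotion score is >= 2.
For any binary test (a single indicator or a composite threshold) the module
builds the 2x2 contingency table against that reference and computes
sensitivity, specificity, and predictive values with 95% confidence intervals:
exact Clopper-Pearson intervals for Se/Sp, standard-logit intervals for
PPV/NPV.  It also provides the Phi-coefficient collinearity screen between
indicators and the lameness flag, and per-farm prevalence summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta, norm

from ._util import ValidationError, percent

INDICATORS = ("sw", "awd", "shh", "oh")

#: Fixed label order of the Phi screen: the four indicators then the lame flag.
PHI_LABELS = ("sw", "awd", "shh", "oh", "lame")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a binary test against the lame (LS >= 2) reference.

    ``tp``: test-positive & lame, ``fp``: test-positive & sound,
    ``fn``: test-negative & lame, ``tn``: test-negative & sound.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class TestMetrics:
    """Point estimates and CIs for Se/Sp/PPV/NPV; ``None`` marks an undefined
    metric (zero denominator) or a degenerate logit interval."""

    se: float | None
    sp: float | None
    ppv: float | None
    npv: float | None
    ci_se: tuple[float, float] | None
    ci_sp: tuple[float, float] | None
    ci_ppv: tuple[float, float] | None
    ci_npv: tuple[float, float] | None
    level: float = 0.95


def contingency(test_positive, lame) -> ContingencyTable2x2:
    """Tabulate a binary test sequence against the binary lame reference."""
    t = np.asarray(test_positive, dtype=int)
    r = np.asarray(lame, dtype=int)
    if t.shape != r.shape:
        raise ValidationError(
            f"length mismatch: test has {t.size} entries, reference has {r.size}"
        )
    for name, arr in (("test", t), ("reference", r)):
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError(f"{name} sequence must be binary")
    return ContingencyTable2x2(
        tp=int(((t == 1) & (r == 1)).sum()),
        fp=int(((t == 1) & (r == 0)).sum()),
        fn=int(((t == 0) & (r == 1)).sum()),
        tn=int(((t == 0) & (r == 0)).sum()),
    )


def clopper_pearson_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for x/n.

    Uses the beta-quantile form: lower = B(alpha/2; x, n-x+1), upper =
    B(1-alpha/2; x+1, n-x), with lower = 0 at x = 0 and upper = 1 at x = n.
    The exact interval is conservative: coverage is at least the nominal
    level for every true proportion.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n]; got x={x}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lower, upper


def logit_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float] | None:
    """Standard-logit confidence interval for a proportion x/n.

    The interval used for predictive values: a Wald interval on the logit
    scale with variance 1/x + 1/(n-x), back-transformed.  Degenerate
    proportions (x = 0 or x = n) have no logit interval and return ``None``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n]; got x={x}, n={n}")
    if x == 0 or x == n:
        return None
    z = float(norm.ppf(1.0 - (1.0 - level) / 2.0))
    p = x / n
    halfwidth = z * math.sqrt(1.0 / x + 1.0 / (n - x))
    lo = math.log(p / (1 - p)) - halfwidth
    hi = math.log(p / (1 - p)) + halfwidth
    return 1.0 / (1.0 + math.exp(-lo)), 1.0 / (1.0 + math.exp(-hi))


def test_metrics(table: ContingencyTable2x2, level: float = 0.95) -> TestMetrics:
    """Se/Sp/PPV/NPV with CIs from a 2x2 table.

    Se/Sp intervals are Clopper-Pearson; PPV/NPV intervals are standard-logit
    (so a predictive value of exactly 0 or 1 carries no interval).  A metric
    whose denominator is zero is returned as ``None``; the others are still
    computed.
    """
    if table.total == 0:
        raise ValueError("empty contingency table")

    def ratio(num: int, den: int):
        return None if den == 0 else num / den

    se = ratio(table.tp, table.tp + table.fn)
    sp = ratio(table.tn, table.tn + table.fp)
    ppv = ratio(table.tp, table.tp + table.fp)
    npv = ratio(table.tn, table.tn + table.fn)
    ci_se = None if se is None else clopper_pearson_ci(table.tp, table.tp + table.fn, level)
    ci_sp = None if sp is None else clopper_pearson_ci(table.tn, table.tn + table.fp, level)
    ci_ppv = None if ppv is None else logit_ci(table.tp, table.tp + table.fp, level)
    ci_npv = None if npv is None else logit_ci(table.tn, table.tn + table.fn, level)
    return TestMetrics(se, sp, ppv, npv, ci_se, ci_sp, ci_ppv, ci_npv, level)


def phi_coefficient(a: int, b: int, c: int, d: int) -> float:
    """Phi coefficient (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) of a 2x2 table.

    Equals the Pearson correlation of the two underlying binary variables.
    Raises on a zero margin (a constant variable has no defined association).
    """
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins) <= 0:
        raise ValueError("phi undefined: a table margin is zero")
    return (a * d - b * c) / math.sqrt(math.prod(float(m) for m in margins))


def _phi_from_columns(x: np.ndarray, y: np.ndarray) -> float:
    a = int(((x == 1) & (y == 1)).sum())
    b = int(((x == 1) & (y == 0)).sum())
    c = int(((x == 0) & (y == 1)).sum())
    d = int(((x == 0) & (y == 0)).sum())
    return phi_coefficient(a, b, c, d)


def phi_screen(data) -> pd.DataFrame:
    """Pairwise Phi among the four indicators and the lame flag.

    Parameters
    ----------
    data : DataFrame or MatchedDataset
        Matched cow-visit records with columns ``sw, awd, shh, oh, ls``.

    Returns
    -------
    DataFrame
        Symmetric 5x5 matrix with labels ``sw, awd, shh, oh, lame``; NaN on
        the diagonal and for any pair involving a constant column.
    """
    frame = getattr(data, "data", data)
    if len(frame) == 0:
        raise ValidationError("phi screen needs a non-empty matched dataset")
    cols = {name: frame[name].to_numpy(dtype=int) for name in INDICATORS}
    cols["lame"] = (frame["ls"].to_numpy(dtype=int) >= 2).astype(int)
    out = pd.DataFrame(np.nan, index=list(PHI_LABELS), columns=list(PHI_LABELS))
    for i, li in enumerate(PHI_LABELS):
        for lj in PHI_LABELS[i + 1 :]:
            try:
                val = _phi_from_columns(cols[li], cols[lj])
            except ValueError:
                val = np.nan
            out.loc[li, lj] = out.loc[lj, li] = val
    return out


def prevalence_summary(data) -> pd.DataFrame:
    """Per-farm and pooled LS-class shares and prevalence summaries.

    Columns: observation count, percent share of each LS class, lameness
    prevalence (LS >= 2), and prevalence of the >=2-indicator composite.
    Percentages are full precision; rendering rounds to one decimal.
    """
    frame = getattr(data, "data", data)
    rows = {}
    groups = [(farm, g) for farm, g in frame.groupby("farm", sort=True)]
    groups.append(("pooled", frame))
    for label, g in groups:
        n = len(g)
        ls = g["ls"].to_numpy(dtype=int)
        counts = np.bincount(ls, minlength=4)[:4]
        ge2_pos = (g[list(INDICATORS)].to_numpy(dtype=int).sum(axis=1) >= 2).mean() if n else np.nan
        rows[label] = {
            "n": n,
            **{f"ls{c}_pct": 100.0 * counts[c] / n for c in range(4)},
            "lame_pct": 100.0 * counts[2:].sum() / n,
            "ips_ge2_pct": 100.0 * ge2_pos,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def screening_table(data, level: float = 0.95, third_row: str = "exactly") -> pd.DataFrame:
    """Diagnostic report of each indicator and composite threshold vs LS >= 2.

    Rows: sw, awd, shh, oh, ge1 (>=1 indicator), ge2 (>=2), and a third
    composite row matching the study's "three positives" rule: exactly 3 by
    default (``third_row="exactly"``, the printed row label; identical to >=3
    whenever no cow shows all four indicators) or >=3 (``"at_least"``).
    Columns: se, sp, ppv, npv (proportions, NaN when undefined) plus CI bound
    columns ``*_lo``/``*_hi`` (NaN for degenerate logit intervals).
    """
    if third_row not in ("exactly", "at_least"):
        raise ValueError(f"third_row must be 'exactly' or 'at_least', got {third_row!r}")
    frame = getattr(data, "data", data)
    lame = (frame["ls"].to_numpy(dtype=int) >= 2).astype(int)
    flags = frame[list(INDICATORS)].to_numpy(dtype=int)
    count = flags.sum(axis=1)
    tests = {name: flags[:, i] for i, name in enumerate(INDICATORS)}
    tests["ge1"] = (count >= 1).astype(int)
    tests["ge2"] = (count >= 2).astype(int)
    tests["eq3" if third_row == "exactly" else "ge3"] = (
        (count == 3) if third_row == "exactly" else (count >= 3)
    ).astype(int)
    rows = {}
    for name, t in tests.items():
        m = test_metrics(contingency(t, lame), level)
        row = {}
        for metric in ("se", "sp", "ppv", "npv"):
            val = getattr(m, metric)
            ci = getattr(m, f"ci_{metric}")
            row[metric] = np.nan if val is None else val
            row[f"{metric}_lo"], row[f"{metric}_hi"] = ci if ci else (np.nan, np.nan)
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def render_percent_table(table: pd.DataFrame, ndigits: int = 1) -> pd.DataFrame:
    """Human-readable layer: proportions/percent columns to half-up percents."""
    out = table.copy()
    for col in out.columns:
        if col == "n":
            continue
        if col.endswith("_pct"):
            out[col] = [percent(v / 100.0, ndigits) if np.isfinite(v) else v for v in out[col]]
        else:
            out[col] = [percent(v, ndigits) if np.isfinite(v) else v for v in out[col]]
    return out
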