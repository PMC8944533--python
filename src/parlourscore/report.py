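"""Confusion matrices, classifier metrics, and the end-to-end report pipeline.

The pipeline mirrors the study's analysis sequence on a matched two-farm
dataset: LS class distribution per farm, Phi collinearity screen, diagnostic
table of the indicators and composite thresholds, stratified 4-fold
cross-validated decision-tree selection, and the selected classifier's
confusion matrix with per-class true-positive rate, false-positive rate and
precision.  Every table is kept at full precision in memory; rounding to one
decimal on the percent scale happens only in the rendered layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from ._util import ValidationError
from . import __version__
from .diagnostics import phi_screen, prevalence_summary, screening_table
from .scoring import LS3_LABELS, pair_records, split_ls_ips
from .simulate import HerdConfig, simulate_herd, simulate_study
from .tree import CVResult, PruningRule, cross_validate_select, tree_to_dict, tree_to_dot

CLASS_LABELS = LS3_LABELS


def confusion_matrix3(truth, predicted) -> np.ndarray:
    """3x3 confusion matrix; rows = true class {0,1,>=2}, cols = predicted."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValidationError("truth and prediction length mismatch")
    if not (np.isin(t, (0, 1, 2)).all() and np.isin(p, (0, 1, 2)).all()):
        raise ValidationError("classes must be encoded 0, 1, 2 (2 meaning LS >= 2)")
    return _sk_confusion(t, p, labels=[0, 1, 2])


def accuracy(cm: np.ndarray) -> float:
    """Proportion of observations on the confusion-matrix diagonal."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def per_class_metrics(cm: np.ndarray) -> pd.DataFrame:
    """One-vs-rest TPR, FPR and precision per class.

    TPR_c = tp / (tp + fn) over true class c; FPR_c = fp / (fp + tn) over
    the other classes; precision_c = tp / (tp + fp) over predictions of c.
    A metric with a zero denominator is NaN (undefined), the rest are still
    returned.  Values are full precision proportions.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    rows = {}
    for c, label in enumerate(CLASS_LABELS):
        tp = cm[c, c]
        row_sum = cm[c].sum()
        col_sum = cm[:, c].sum()
        fp = col_sum - tp
        rows[label] = {
            "tpr": tp / row_sum if row_sum else np.nan,
            "fpr": fp / (total - row_sum) if total - row_sum else np.nan,
            "precision": tp / col_sum if col_sum else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run, plus the manifest."""

    ls_distribution: pd.DataFrame
    phi: pd.DataFrame
    diagnostics: pd.DataFrame
    confusion: np.ndarray
    classifier_metrics: pd.DataFrame
    cv: CVResult
    join_report: dict
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        """Write the table-shaped CSV reports, tree exports, and manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.ls_distribution.to_csv(out / "table3_ls_distribution.csv")
        self.phi.to_csv(out / "table5_phi.csv")
        self.diagnostics.to_csv(out / "table6_diagnostics.csv")
        pd.DataFrame(
            self.confusion, index=CLASS_LABELS, columns=CLASS_LABELS
        ).to_csv(out / "table7_confusion.csv")
        self.classifier_metrics.to_csv(out / "table8_classifier_metrics.csv")
        (out / "tree.json").write_text(
            json.dumps(tree_to_dict(self.cv.best_model.tree_), indent=2) + "\n",
            encoding="utf-8",
        )
        (out / "tree.dot").write_text(tree_to_dot(self.cv.best_model.tree_) + "\n", encoding="utf-8")
        (out / "join_report.json").write_text(
            json.dumps(self.join_report, indent=2) + "\n", encoding="utf-8"
        )
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2) + "\n", encoding="utf-8"
        )


def run_pipeline(
    data: pd.DataFrame | None = None,
    *,
    config: HerdConfig | None = None,
    seed: int = 0,
    rule: PruningRule = PruningRule(),
    k: int = 4,
    composite_third_row: str = "exactly",
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Execute the full analysis and return (optionally write) the report.

    With no ``data`` and no ``config``, the two-farm study-like preset is
    simulated from ``seed``.  All randomness (simulation and fold assignment)
    derives from ``seed``; re-running with the same inputs reproduces the
    bundle exactly.
    """
    source = "provided data"
    if data is None:
        if config is not None:
            data = simulate_herd(config)
            source = f"simulated herd ({config.farm_label})"
        else:
            data = simulate_study(seed)
            source = "simulated two-farm study preset"
    ls, ips = split_ls_ips(data)
    matched = pair_records(ls, ips)
    cv_seed = int(np.random.SeedSequence(seed).generate_state(3)[2] % (2**31))
    cv = cross_validate_select(matched, rule=rule, k=k, seed=cv_seed)
    manifest = {
        "package": "parlourscore",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "cv_seed": cv_seed,
        "k": k,
        "pruning": {
            "min_node_size_to_split": rule.min_node_size_to_split,
            "min_gini_decrease": rule.min_gini_decrease,
        },
        "composite_third_row": composite_third_row,
        "source": source,
        "n_matched": matched.n,
        "config": config.to_dict() if config is not None else None,
    }
    bundle = ReportBundle(
        ls_distribution=prevalence_summary(matched),
        phi=phi_screen(matched),
        diagnostics=screening_table(matched, third_row=composite_third_row),
        confusion=cv.best_confusion,
        classifier_metrics=per_class_metrics(cv.best_confusion),
        cv=cv,
        join_report=matched.report,
        manifest=manifest,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
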