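"""Classification metrics and the two-way feature-by-classifier ANOVA.

The positive class is AD (1) throughout.  Accuracy, precision, recall
and F1 follow the standard confusion-matrix definitions; precision,
recall and F1 are reported as missing (NaN, with a warning) when their
denominator is zero rather than being coerced to 0, so run averages are
not silently biased.

The ANOVA asks whether the feature stream and the classifier each
affect run-level accuracy, and whether they interact; a significant
interaction triggers a Tukey HSD all-pairs comparison over the
feature-by-classifier cells to locate the best-performing combinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["ConfusionCounts", "MetricsReport", "AnovaResult", "confusion", "metrics", "two_way_anova"]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricsReport:
    """Accuracy, precision, recall and F1 in [0, 1] (NaN where undefined)."""

    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_percent(self) -> dict[str, float]:
        return {
            k: round(100.0 * v, 10) if np.isfinite(v) else float("nan")
            for k, v in vars(self).items()
        }


@dataclass
class AnovaResult:
    table: pd.DataFrame  # type-II ANOVA table (F, p per effect)
    cell_means: pd.DataFrame  # feature x classifier mean accuracy
    tukey: pd.DataFrame | None  # all-pairs cell comparison when interaction significant
    best_cell: tuple[str, str]  # (feature, classifier) with highest mean accuracy
    best_group: list[tuple[str, str]] = field(default_factory=list)  # cells not sig. below best


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Exact TP/FP/FN/TN counts with AD (1) as the positive class."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"label length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("need at least one label pair")
    if not (np.isin(t, [0, 1]).all() and np.isin(p, [0, 1]).all()):
        raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        TP=int(((t == 1) & (p == 1)).sum()),
        FP=int(((t == 0) & (p == 1)).sum()),
        FN=int(((t == 1) & (p == 0)).sum()),
        TN=int(((t == 0) & (p == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, F1 from confusion counts."""
    if c.total == 0:
        raise ValueError("confusion counts are all zero")

    def safe_div(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reported as NaN", stacklevel=3)
            return float("nan")
        return num / den

    accuracy = (c.TP + c.TN) / c.total
    precision = safe_div(c.TP, c.TP + c.FP, "precision")
    recall = safe_div(c.TP, c.TP + c.FN, "recall")
    if np.isfinite(precision) and np.isfinite(recall) and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = safe_div(np.nan, 0, "f1")
    return MetricsReport(accuracy, precision, recall, f1)


def two_way_anova(accuracy_table: pd.DataFrame, alpha: float = 0.05) -> AnovaResult:
    """Two-way ANOVA of accuracy on feature and classifier factors.

    ``accuracy_table`` needs columns ``feature, classifier, run,
    accuracy`` forming a balanced design with >= 2 levels per factor and
    >= 2 replicates per cell.  Type-II sums of squares are used (equal
    to type-I/III on balanced data).  If the interaction is significant
    at ``alpha``, an all-pairs Tukey HSD over the cells is run and the
    group of cells not significantly below the best cell is flagged.
    """
    df = accuracy_table.copy()
    required = {"feature", "classifier", "run", "accuracy"}
    if missing := required - set(df.columns):
        raise ValueError(f"accuracy table missing columns: {sorted(missing)}")

    counts = df.groupby(["feature", "classifier"], sort=True).size()
    n_features = df["feature"].nunique()
    n_classifiers = df["classifier"].nunique()
    if n_features < 2 or n_classifiers < 2:
        raise ValueError("need at least 2 levels per factor")
    expected_cells = n_features * n_classifiers
    if len(counts) != expected_cells or counts.nunique() != 1:
        deficient = counts[counts != counts.max()].index.tolist()
        raise ValueError(f"unbalanced design; deficient cells: {deficient}")
    if counts.iloc[0] < 2:
        raise ValueError("need at least 2 replicates per cell")

    model = ols("accuracy ~ C(feature) * C(classifier)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual designs emit RuntimeWarnings
        table = sm.stats.anova_lm(model, typ=2)
    # constant tables give 0/0 F ratios; report them as no effect
    zero_ss = table["sum_sq"] < 1e-15
    table.loc[zero_ss, "F"] = 0.0
    table.loc[zero_ss, "PR(>F)"] = 1.0

    cell_means = df.pivot_table(index="feature", columns="classifier", values="accuracy")
    stacked = cell_means.stack()
    best_cell = tuple(stacked.idxmax())

    interaction_row = [i for i in table.index if ":" in str(i)][0]
    interaction_p = float(table.loc[interaction_row, "PR(>F)"])

    tukey_df = None
    best_group = [best_cell]
    if np.isfinite(interaction_p) and interaction_p < alpha:
        cell_labels = df["feature"].astype(str) + "|" + df["classifier"].astype(str)
        res = pairwise_tukeyhsd(df["accuracy"].to_numpy(), cell_labels.to_numpy(), alpha=alpha)
        tukey_df = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        best_label = f"{best_cell[0]}|{best_cell[1]}"
        not_sig = set()
        for row in tukey_df.itertuples():
            pair = {row.group1, row.group2}
            if best_label in pair and not row.reject:
                not_sig |= pair - {best_label}
        best_group = [best_cell] + [tuple(lbl.split("|", 1)) for lbl in sorted(not_sig)]

    return AnovaResult(
        table=table,
        cell_means=cell_means,
        tukey=tukey_df,
        best_cell=best_cell,
        best_group=best_group,
    )
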