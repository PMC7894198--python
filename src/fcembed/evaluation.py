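"""Confusion-matrix metrics and repeated cross-validated evaluation.

The protocol mirrors careful connectome-classification practice: stratified
10-fold cross-validation, repeated (default 5 repetitions with re-drawn
folds), with *per-fold* feature standardization and feature ranking fit on
the training split only — the test fold never influences standardization,
ranking or training (no selection bias).  Classifiers are trained on the
top-k ranked features for k = 1..k_max and metrics are aggregated to
mean / std / max / min per k; the reported operating point is the k that
maximizes mean accuracy (ties -> smallest k), and the spread statistics are
taken across the (fold x repetition) values at that k.

Metrics: ACC = (TP+TN)/n, SEN = TP/(TP+FN), SPE = TN/(TN+FP), and
F1 = 2 PRE SEN / (PRE + SEN) with PRE = TP/(TP+FP).  Undefined ratios
(zero denominator) are reported as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._seeds import STAGE_CLASSIFIER, STAGE_CV, small_int_seed
from .classifiers import get_classifier
from .feature_selection import apply_standardization, get_ranker, standardize

__all__ = ["ConfusionCounts", "CVResult", "confusion", "metrics",
           "repeated_cv", "positive_label_for_pair"]

_SEVERITY = {"HC": 0, "MCI": 1, "AD": 2}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


def confusion(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Standard 2x2 counts with an explicit positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    allowed = set(np.unique(y_true).tolist()) | {positive_class}
    if len(allowed) > 2:
        raise ValueError(f"more than two classes present: {sorted(map(str, allowed))}")
    stray = set(np.unique(y_pred).tolist()) - allowed
    if stray:
        raise ValueError(f"prediction contains unseen label(s): {sorted(map(str, stray))}")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)), tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)), fn=int(np.sum(pos_t & ~pos_p)))


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """ACC / SEN / SPE / F from one confusion table (NaN when undefined)."""
    if c.n == 0:
        raise ValueError("empty confusion table")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    acc = (c.tp + c.tn) / c.n
    sen = ratio(c.tp, c.tp + c.fn)
    pre = ratio(c.tp, c.tp + c.fp)
    spe = ratio(c.tn, c.tn + c.fp)
    if not math.isnan(pre) and not math.isnan(sen) and (pre + sen) > 0:
        f1 = 2 * pre * sen / (pre + sen)
    else:
        f1 = math.nan
    return {"ACC": acc, "SEN": sen, "SPE": spe, "F": f1}


def positive_label_for_pair(labels) -> str:
    """Disease-ward positive class under the HC < MCI < AD progression."""
    uniq = sorted(set(map(str, labels)))
    if all(u in _SEVERITY for u in uniq):
        return max(uniq, key=lambda u: _SEVERITY[u])
    return uniq[-1]


@dataclass
class CVResult:
    """Fold-level records, per-k aggregates and the selected operating point."""

    records: pd.DataFrame          # one row per (rep, fold, k)
    per_k: pd.DataFrame            # mean accuracy etc. per k
    chosen_k: int
    summary: dict                  # mean/std/max/min for ACC/SEN/SPE, F at chosen k
    provenance: dict = field(default_factory=dict)

    def summary_table(self) -> pd.DataFrame:
        """Mean(%) / Standard deviation / Max(%) / Min(%) rows per metric."""
        rows = []
        for name in ("Accuracy", "Sensitivity", "Specificity"):
            key = {"Accuracy": "ACC", "Sensitivity": "SEN", "Specificity": "SPE"}[name]
            s = self.summary[key]
            rows.append({"Performance metrics": name,
                         "Mean (%)": round(100 * s["mean"], 3),
                         "Standard deviation": round(100 * s["std"], 3),
                         "Max (%)": round(100 * s["max"], 3),
                         "Min (%)": round(100 * s["min"], 3)})
        rows.append({"Performance metrics": "F-measure",
                     "Mean (%)": round(self.summary["F"], 4),
                     "Standard deviation": "", "Max (%)": "", "Min (%)": ""})
        return pd.DataFrame(rows)

    def to_tidy_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False, float_format="%.10g")


def repeated_cv(features: np.ndarray, labels: np.ndarray, fs_method,
                classifier, n_folds: int = 10, k_max: int = 50,
                n_reps: int = 5, seed: int = 0,
                positive_label: str | None = None,
                fs_kwargs: dict | None = None,
                clf_kwargs: dict | None = None) -> CVResult:
    """Repeated stratified k-fold CV with per-fold ranking and a top-k sweep.

    ``fs_method`` is a method name (see :mod:`fcembed.feature_selection`) or
    a callable ``(X_train_std, y_train) -> Ranking``; ``classifier`` is
    ``"relm"``/``"lsvm"`` or a ``(train, predict)`` pair.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("repeated_cv evaluates binary tasks; filter the cohort "
                         "to one label pair first")
    if counts.min() < n_folds:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has only {counts.min()} "
            f"subjects (< {n_folds} folds); use fewer folds")
    ranker = get_ranker(fs_method, **(fs_kwargs or {})) if isinstance(fs_method, str) else fs_method
    if isinstance(classifier, str):
        train_fn, predict_fn = get_classifier(classifier, **(clf_kwargs or {}))
        clf_name = classifier
    else:
        train_fn, predict_fn = classifier
        clf_name = getattr(train_fn, "__name__", "custom")
    if positive_label is None:
        positive_label = positive_label_for_pair(classes)
    k_max = min(k_max, x.shape[1])

    rows = []
    for rep in range(n_reps):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=small_int_seed(seed, STAGE_CV, rep))
        for fold, (tr, te) in enumerate(skf.split(x, y)):
            x_tr, mean, sd = standardize(x[tr])
            x_te = apply_standardization(x[te], mean, sd)
            ranking = ranker(x_tr, y[tr])
            clf_seed = small_int_seed(seed, STAGE_CLASSIFIER, rep * n_folds + fold)
            for k in range(1, k_max + 1):
                idx = ranking.top(k)
                model = train_fn(x_tr[:, idx], y[tr], seed=clf_seed)
                pred = predict_fn(model, x_te[:, idx])
                cc = confusion(y[te], pred, positive_label)
                m = metrics(cc)
                rows.append({"rep": rep, "fold": fold, "k": k,
                             "tp": cc.tp, "tn": cc.tn, "fp": cc.fp, "fn": cc.fn,
                             "ACC": m["ACC"], "SEN": m["SEN"],
                             "SPE": m["SPE"], "F": m["F"]})
    records = pd.DataFrame(rows)
    per_k = records.groupby("k")["ACC"].agg(["mean", "std", "max", "min"]).reset_index()
    best = per_k.loc[per_k["mean"].idxmax()]  # idxmax -> first (smallest k) on ties
    chosen_k = int(best["k"])
    at_k = records[records["k"] == chosen_k]
    summary: dict = {}
    for key in ("ACC", "SEN", "SPE"):
        vals = at_k[key].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        summary[key] = {"mean": float(np.mean(finite)),
                        "std": float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0,
                        "max": float(np.max(finite)),
                        "min": float(np.min(finite))}
    pooled = ConfusionCounts(int(at_k["tp"].sum()), int(at_k["tn"].sum()),
                             int(at_k["fp"].sum()), int(at_k["fn"].sum()))
    summary["F"] = metrics(pooled)["F"]
    summary["n_predictions"] = int(at_k["tp"].sum() + at_k["tn"].sum()
                                   + at_k["fp"].sum() + at_k["fn"].sum())
    prov = {"fs_method": getattr(ranker, "__name__", str(fs_method)),
            "classifier": clf_name, "n_folds": n_folds, "k_max": k_max,
            "n_reps": n_reps, "seed": seed, "positive_label": str(positive_label),
            "std_convention": "across (fold x repetition) values at chosen k, ddof=1"}
    return CVResult(records, per_k, chosen_k, summary, prov)
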