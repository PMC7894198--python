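"""Desk-scale study protocols: the frozen end-to-end evaluation conditions.

Two canonical synthetic experiments exercise the whole pipeline:

* **Null sentinel** — a zero-effect cohort (31 vs 31 subjects, 116 ROIs,
  130 time points).  Labels are exchangeable by construction, so the
  repeated-CV mean accuracy of every feature-selection x classifier
  combination must stay inside the two-sided 99% binomial interval around
  0.5.  Any excursion above the band is evidence of information leaking
  from test folds into standardization, ranking or training.

* **Signal recovery** — the same cohort geometry with a planted module of
  10 ROIs whose within-module correlation drops by 0.5 between groups.
  LASSO-ranked embeddings should classify well with either classifier.

The node2vec and CV settings here are scaled for a single workstation CPU
(8-dimensional embeddings, 20 walks per node, k swept to 20, 2 CV
repetitions, 256 hidden ELM nodes); they are the package's reference
operating point for synthetic-cohort studies, not the connectome-scale
defaults of :class:`~fcembed.embedding.Node2vecParams`.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .embedding import Node2vecParams
from .evaluation import repeated_cv
from .pipeline import RunConfig, compute_features
from .synthetic import CohortConfig, generate_cohort

__all__ = ["study_cohort_config", "study_embedding_params", "study_run_config",
           "study_features", "null_sentinel", "signal_recovery",
           "binomial_null_interval", "FS_COMBOS"]

#: per-method hyperparameters used in the desk-scale protocol
FS_COMBOS: dict[str, dict] = {
    "lasso": {},
    "svmrfe": {"step": 0.2},
    "fsasl": {"max_sweeps": 3},
    "llcfs": {},
    "cfs": {},
}

_CLASSIFIERS: dict[str, dict] = {
    "lsvm": {},
    "relm": {"n_hidden": 256},
}


def study_cohort_config(effect_size: float, seed: int) -> CohortConfig:
    """31 vs 31 HC/AD cohort at the 130 x 116 acquisition geometry."""
    return CohortConfig(n_per_group=31, n_rois=116, n_timepoints=130,
                        effect_size=effect_size, module_size=10,
                        base_correlation=0.45, labels=("HC", "AD"), seed=seed)


def study_embedding_params(seed: int) -> Node2vecParams:
    return Node2vecParams(p=0.1, q=1.6, walk_length=10, num_walks=20, dim=8,
                          window=4, epochs=3, seed=seed)


def study_run_config(effect_size: float, seed: int) -> RunConfig:
    return RunConfig(seed=seed, task_pair=("HC", "AD"),
                     cohort=study_cohort_config(effect_size, seed),
                     embedding=study_embedding_params(seed),
                     n_folds=10, k_max=20, n_reps=2)


def study_features(effect_size: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Generate the cohort and embed every subject."""
    config = study_run_config(effect_size, seed)
    subjects, labels = generate_cohort(config.cohort)
    return compute_features(subjects, config), labels


def binomial_null_interval(n: int, confidence: float = 0.99) -> tuple[float, float]:
    """Two-sided normal-approximation binomial band around chance (p = 0.5)."""
    half = norm.ppf(0.5 + confidence / 2) * np.sqrt(0.25 / n)
    return 0.5 - half, 0.5 + half


def _cv(features, labels, fs, clf, seed):
    return repeated_cv(features, labels, fs, clf, n_folds=10, k_max=20,
                       n_reps=2, seed=seed, fs_kwargs=FS_COMBOS[fs],
                       clf_kwargs=_CLASSIFIERS[clf])


def null_sentinel(seed: int, combos=None) -> dict[str, dict]:
    """Zero-effect pipeline accuracies per feature-selection x classifier.

    Returns ``{"<fs>+<clf>": {"accuracy": ..., "n_predictions": ...}, ...}``.
    """
    features, labels = study_features(0.0, seed)
    out = {}
    for fs in (combos or FS_COMBOS):
        for clf in _CLASSIFIERS:
            res = _cv(features, labels, fs, clf, seed)
            out[f"{fs}+{clf}"] = {
                "accuracy": res.summary["ACC"]["mean"],
                "n_predictions": res.summary["n_predictions"],
                "chosen_k": res.chosen_k,
            }
    return out


def signal_recovery(seeds) -> dict[str, dict]:
    """Planted-signal (effect 0.5, module 10) LASSO accuracies per seed."""
    out = {}
    for seed in seeds:
        features, labels = study_features(0.5, seed)
        for clf in _CLASSIFIERS:
            res = _cv(features, labels, "lasso", clf, seed)
            out[f"lasso+{clf}@seed{seed}"] = {
                "accuracy": res.summary["ACC"]["mean"],
                "chosen_k": res.chosen_k,
            }
    return out
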