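"""End-to-end orchestration: simulate -> connect -> embed -> select+classify -> evaluate.

A single :class:`RunConfig` (loadable from YAML, schema-validated, unknown
keys rejected) plus one global seed fully determines every artifact.  The
seed fans out to stages via a fixed counter scheme (see
:mod:`fcembed._seeds`); the embedding stage shares one stage seed across
subjects so identical graphs embed identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seeds import STAGE_WALKS, seed_sequence, small_int_seed
from .connectivity import pearson_connectivity, save_connectivity, to_weighted_graph
from .embedding import Node2vecParams, embed_subject
from .evaluation import CVResult, positive_label_for_pair, repeated_cv
from .synthetic import CohortConfig, TimeSeriesMatrix, generate_cohort, read_cohort, write_cohort

log = logging.getLogger("fcembed")

__all__ = ["RunConfig", "load_config", "compute_features", "run_pipeline",
           "write_run_manifest", "verify_run_manifest"]


def _from_mapping(cls, data: dict, context: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration."""

    seed: int = 0
    task_pair: tuple[str, str] = ("HC", "AD")
    negative_policy: str = "absolute"
    keep_fraction: float | None = None
    fs_method: str = "lasso"
    classifier: str = "relm"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    embedding: Node2vecParams = field(default_factory=Node2vecParams)
    n_folds: int = 10
    k_max: int = 50
    n_reps: int = 5
    fs_kwargs: dict = field(default_factory=dict)
    clf_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.negative_policy not in ("absolute", "clip"):
            raise ValueError(f"unknown negative_policy {self.negative_policy!r}")
        if len(self.task_pair) != 2 or self.task_pair[0] == self.task_pair[1]:
            raise ValueError("task_pair must name two distinct labels")
        for lbl in self.task_pair:
            if lbl not in self.cohort.labels:
                raise ValueError(f"task label {lbl!r} not among cohort labels "
                                 f"{self.cohort.labels}")


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    cohort_raw = dict(raw.pop("cohort", {}))
    if "labels" in cohort_raw:
        cohort_raw["labels"] = tuple(cohort_raw["labels"])
    emb_raw = dict(raw.pop("embedding", {}))
    if "task_pair" in raw:
        raw["task_pair"] = tuple(raw["task_pair"])
    cohort = _from_mapping(CohortConfig, cohort_raw, "cohort")
    embedding = _from_mapping(Node2vecParams, emb_raw, "embedding")
    return _from_mapping(RunConfig, {**raw, "cohort": cohort,
                                     "embedding": embedding}, "run config")


def compute_features(subjects: list[TimeSeriesMatrix], config: RunConfig,
                     outdir: Path | None = None) -> np.ndarray:
    """Connectivity + graph + embedding for each subject -> S x (V*dim)."""
    emb = dataclasses.replace(config.embedding,
                              seed=small_int_seed(config.seed, STAGE_WALKS))
    vecs = []
    for ts in subjects:
        log.info("stage=embed subject=%s seed=%d", ts.subject_id, emb.seed)
        cm = pearson_connectivity(ts)
        if outdir is not None:
            save_connectivity(cm, outdir / f"{ts.subject_id}_connectivity.tsv")
        g = to_weighted_graph(cm, config.negative_policy,
                              keep_fraction=config.keep_fraction)
        # fresh generator from the shared stage seed: identical graphs give
        # identical corpora, hence comparable embeddings across subjects
        walk_rng = np.random.default_rng(seed_sequence(emb.seed, STAGE_WALKS))
        vecs.append(embed_subject(g, emb, walk_rng=walk_rng))
    return np.vstack(vecs)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None,
                 cohort_manifest: str | Path | None = None) -> CVResult:
    """Execute the full pipeline; identical config + seed reproduce
    byte-identical summary tables."""
    stage = "simulate"
    try:
        if cohort_manifest is None:
            subjects, labels = generate_cohort(config.cohort)
        else:
            subjects, labels = read_cohort(cohort_manifest)
        keep = np.isin(labels, config.task_pair)
        subjects = [s for s, k in zip(subjects, keep) if k]
        labels = labels[keep]
        if labels.size == 0:
            raise ValueError(f"no subjects carry the task labels {config.task_pair}")

        out = Path(outdir) if outdir is not None else None
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
            write_cohort(subjects, out / "cohort", config.cohort)

        stage = "embed"
        features = compute_features(subjects, config, outdir=None)

        stage = "evaluate"
        result = repeated_cv(
            features, labels, config.fs_method, config.classifier,
            n_folds=config.n_folds, k_max=config.k_max, n_reps=config.n_reps,
            seed=config.seed,
            positive_label=positive_label_for_pair(config.task_pair),
            fs_kwargs=config.fs_kwargs, clf_kwargs=config.clf_kwargs)
        result.provenance["task_pair"] = list(config.task_pair)
        result.provenance["config_digest"] = config_digest(config)

        if out is not None:
            stage = "write"
            np.savetxt(out / "features.tsv", features, delimiter="\t", fmt="%.10g")
            result.to_tidy_tsv(out / "cv_records.tsv")
            result.summary_table().to_csv(out / "summary.tsv", sep="\t", index=False)
            with open(out / "provenance.json", "w") as fh:
                json.dump(result.provenance, fh, indent=2, sort_keys=True)
            write_run_manifest(out)
        return result
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err


def config_digest(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_run_manifest(outdir: Path) -> Path:
    """Record a sha256 digest for every artifact under the run directory."""
    rows = []
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "run_manifest.tsv":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            rows.append({"path": str(path.relative_to(outdir)), "sha256": digest})
    manifest = outdir / "run_manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def verify_run_manifest(outdir: str | Path) -> None:
    """Raise if any recorded artifact is missing or stale."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "run_manifest.tsv", sep="\t")
    for row in manifest.itertuples():
        path = outdir / row.path
        if not path.exists():
            raise FileNotFoundError(f"stale run: missing artifact {row.path}")
        if hashlib.sha256(path.read_bytes()).hexdigest() != row.sha256:
            raise ValueError(f"stale run: digest mismatch for {row.path}")
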