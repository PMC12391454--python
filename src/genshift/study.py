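"""End-to-end study orchestration.

``run_study`` wires the full experiment together: corpus generation (or
ingestion) → validation → preprocessing-level experiments → divergence
matrices → correlation → clustering/embedding/outliers → report bundle.
Every stage's status and elapsed time is written to ``stages.json`` as it
finishes (a failed run leaves the marker of where it stopped), and a manifest
of every artifact with its SHA-256 hash closes the run.

A study is reproducible bit-for-bit from its config: the global seed is the
single entropy source and per-stage seeds are derived from it by label.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed
from .corpus import Corpus, CorpusValidationError, read_corpus, validate_corpus
from .clustering import (correlate, elbow_select_k, flag_outliers,
                         intra_inter_summary, kmedoids_fit, mds_embed)
from .divergence import divergence_matrix
from .experiments import DESIGNS, ExperimentPlan, run_design, summarize_deltas
from .preprocess import PreprocessLevel, default_lexicons, institution_vocabulary
from .synthetic import GeneratorConfig, corpus_misspelling_stats, generate_corpus

__all__ = ["StudyConfig", "StudyConfigError", "StudyReport", "run_study",
           "demo_config"]


class StudyConfigError(ValueError):
    """Raised when a study configuration fails schema validation."""


@dataclass(frozen=True)
class StudyConfig:
    """Declarative description of one full study run."""

    out_dir: str
    generator: GeneratorConfig | None = None
    corpus_path: str | None = None
    levels: tuple[str, ...] = ("minimal", "spell")
    designs: tuple[str, ...] = ("pairwise", "pooled_8020", "loio_holdout")
    cv_folds: int = 5
    classifier: Mapping = field(default_factory=dict)
    divergence_epsilon: float = 1e-9
    divergence_direction: str = "b_given_a"
    composite_strategy: str = "product"
    primary_level: str = "minimal"
    cluster_k: int | str = "auto"
    cluster_k_range: tuple[int, int] = (2, 25)
    outlier_threshold_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.levels or not self.designs:
            raise StudyConfigError("at least one level and one design required")
        for d in self.designs:
            if d not in DESIGNS:
                raise StudyConfigError(f"unknown design {d!r}")
        for lev in list(self.levels) + [self.primary_level]:
            try:
                PreprocessLevel.parse(lev)
            except ValueError as exc:
                raise StudyConfigError(str(exc)) from exc
        if (self.generator is None) == (self.corpus_path is None):
            raise StudyConfigError(
                "exactly one of generator config or corpus_path required")
        if self.primary_level not in self.levels:
            raise StudyConfigError("primary_level must be one of levels")
        if isinstance(self.cluster_k, str) and self.cluster_k != "auto":
            raise StudyConfigError("cluster_k must be an int or 'auto'")

    @classmethod
    def from_dict(cls, data: Mapping) -> "StudyConfig":
        data = dict(data)
        gen = data.pop("generator", None)
        if gen is not None:
            try:
                gen = GeneratorConfig(**gen)
            except (TypeError, ValueError) as exc:
                raise StudyConfigError(f"bad generator config: {exc}") from exc
        for key in ("levels", "designs"):
            if key in data:
                data[key] = tuple(data[key])
        if "cluster_k_range" in data:
            data["cluster_k_range"] = tuple(data["cluster_k_range"])
        try:
            return cls(generator=gen, **data)
        except TypeError as exc:
            raise StudyConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise StudyConfigError("study config must be a mapping")
        return cls.from_dict(data)


@dataclass
class StudyReport:
    """What a run produced: artifact manifest, timings, headline summary."""

    out_dir: str
    manifest: dict[str, str]
    stage_seconds: dict[str, float]
    summary: dict

    def verify_manifest(self) -> bool:
        for name, digest in self.manifest.items():
            path = Path(self.out_dir) / name
            if not path.exists() or _sha256(path) != digest:
                return False
        return True


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True,
                               default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def demo_config(out_dir: str, scale: str = "full", seed: int = 0) -> StudyConfig:
    """Ready-made study configurations.

    ``full`` — the default shifted corpus (6 institutions × 1500 records),
    minimal+spell levels, all three designs.
    ``small`` — 4 institutions × 400 records, minimal level, pairwise only;
    used for quick end-to-end and determinism checks.
    """
    if scale == "full":
        return StudyConfig(
            out_dir=out_dir,
            generator=GeneratorConfig(seed=derive_seed(seed, "generator")),
            levels=("minimal", "spell"),
            designs=("pairwise", "pooled_8020", "loio_holdout"),
            seed=seed)
    if scale == "small":
        return StudyConfig(
            out_dir=out_dir,
            generator=GeneratorConfig(
                n_institutions=4, n_labels=8, records_per_institution=400,
                seed=derive_seed(seed, "generator")),
            levels=("minimal",),
            designs=("pairwise",),
            primary_level="minimal",
            seed=seed)
    raise StudyConfigError(f"unknown demo scale {scale!r}")


def run_study(config: StudyConfig) -> StudyReport:
    """Execute all stages in dependency order; see module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lexicons = default_lexicons()
    stages: dict[str, dict] = {}
    timings: dict[str, float] = {}
    summary: dict = {"config": {
        "levels": list(config.levels), "designs": list(config.designs),
        "seed": config.seed, "divergence": {
            "epsilon": config.divergence_epsilon,
            "direction": config.divergence_direction,
            "strategy": config.composite_strategy,
            "log_base": "e"}}}
    artifacts: list[str] = []

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                stages[name] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
                _write_json(out / "stages.json", stages)
                raise
            dt = time.perf_counter() - t0
            stages[name] = {"status": "ok", "seconds": round(dt, 3)}
            timings[name] = dt
            _write_json(out / "stages.json", stages)
            return result
        return wrap

    # -- corpus ----------------------------------------------------------
    def _corpus():
        if config.generator is not None:
            corpus, truth = generate_corpus(config.generator)
        else:
            corpus, truth = read_corpus(config.corpus_path), None
        corpus.to_jsonl(out / "corpus.jsonl")
        artifacts.append("corpus.jsonl")
        if truth is not None:
            _write_json(out / "ground_truth_labels.json", {
                "labels": list(truth.labels),
                "label_distributions": {k: v.tolist()
                                        for k, v in truth.label_distributions.items()}})
            artifacts.append("ground_truth_labels.json")
        return corpus, truth

    corpus, truth = stage("generate_or_load")(_corpus)

    def _validate():
        validated, report = validate_corpus(corpus)
        _write_json(out / "validation.json", report)
        artifacts.append("validation.json")
        summary["validation"] = report
        return validated

    corpus_v = stage("validate")(_validate)

    def _noise_stats():
        if corpus_v.noise is None:
            return None
        word_rate, record_rate = corpus_misspelling_stats(corpus_v)
        abbr_rate = float(np.mean([n.abbreviated for n in corpus_v.noise]))
        stats = {"misspelled_word_rate": word_rate,
                 "misspelled_record_rate": record_rate,
                 "abbreviated_record_rate": abbr_rate}
        summary["noise"] = stats
        return stats

    stage("noise_stats")(_noise_stats)

    def _vocabulary():
        sizes = {}
        raw_tokens = set()
        for text in corpus_v.df["text"]:
            raw_tokens.update(text.split())
        sizes["raw"] = len(raw_tokens)
        for lev in config.levels:
            tokens = set()
            for inst in corpus_v.institutions:
                tokens |= institution_vocabulary(corpus_v, inst, lev, lexicons).tokens
            sizes[str(PreprocessLevel.parse(lev).value)] = len(tokens)
        summary["vocabulary_sizes"] = sizes
        return sizes

    stage("vocabulary")(_vocabulary)

    def _experiments():
        plan = ExperimentPlan(designs=tuple(config.designs),
                              levels=tuple(config.levels),
                              cv_folds=config.cv_folds,
                              seed=derive_seed(config.seed, "experiments"),
                              classifier_params=dict(config.classifier))
        tables = [run_design(d, corpus_v, plan, lexicons) for d in config.designs]
        all_rows = pd.concat([t.df for t in tables], ignore_index=True)
        all_rows.sort_values(["design", "level", "train_id", "test_id"],
                             inplace=True)
        all_rows.to_csv(out / "results.csv", index=False, float_format="%.12g")
        artifacts.append("results.csv")
        summary["experiments"] = summarize_deltas(tables)
        _write_json(out / "summary_experiments.json", summary["experiments"])
        artifacts.append("summary_experiments.json")
        return tables, all_rows

    tables, results_df = stage("experiments")(_experiments)

    def _divergence():
        matrices = {}
        for metric in ("overlap", "jaccard", "kld_cpt", "kld_composite"):
            m = divergence_matrix(
                corpus_v, metric, level=config.primary_level, lexicons=lexicons,
                epsilon=config.divergence_epsilon,
                strategy=config.composite_strategy,
                direction=config.divergence_direction)
            m.to_csv(out / f"matrix_{metric}.csv")
            _write_json(out / f"matrix_{metric}.meta.json", m.metadata)
            artifacts.extend([f"matrix_{metric}.csv", f"matrix_{metric}.meta.json"])
            matrices[metric] = m
        return matrices

    matrices = stage("divergence")(_divergence)

    def _correlation():
        has_pairwise = "pairwise" in config.designs
        if not has_pairwise:
            return None
        reports = {}
        for metric, m in matrices.items():
            rep = correlate(m, results_df, performance_field="micro_f1",
                            level=config.primary_level)
            reports[metric] = {
                "pearson_r": rep.pearson_r, "r_squared": rep.r_squared,
                "n_pairs": rep.n_pairs,
                "per_institution": rep.per_institution,
                "per_institution_mean": (
                    float(np.nanmean(finite))
                    if (finite := [v for v in rep.per_institution.values()
                                   if v == v])
                    else float("nan")),
            }
        _write_json(out / "correlation.json", reports)
        artifacts.append("correlation.json")
        summary["correlation"] = {k: {kk: v[kk] for kk in
                                      ("pearson_r", "r_squared", "n_pairs")}
                                  for k, v in reports.items()}
        return reports

    stage("correlation")(_correlation)

    def _clustering():
        composite = matrices["kld_composite"]
        sym = composite.symmetrized()
        if isinstance(config.cluster_k, str):
            elbow = elbow_select_k(sym, k_range=config.cluster_k_range,
                                   seed=derive_seed(config.seed, "kmedoids"))
            k = elbow.k
            elbow_payload = {"ks": list(elbow.ks), "costs": list(elbow.costs),
                             "method": elbow.method}
        else:
            k = int(config.cluster_k)
            elbow_payload = None
        assignment = kmedoids_fit(sym, k, seed=derive_seed(config.seed, "kmedoids"))
        coords = mds_embed(sym)
        emb = coords.copy()
        emb["cluster"] = [assignment.labels[i] for i in emb.index]
        emb.index.name = "institution_id"
        emb.to_csv(out / "embedding.csv", float_format="%.12g")
        artifacts.append("embedding.csv")
        _write_json(out / "clusters.json", {
            "k": k, "medoid_ids": list(assignment.medoid_ids),
            "labels": assignment.labels,
            "total_within_dissimilarity": assignment.total_within_dissimilarity,
            "elbow": elbow_payload})
        artifacts.append("clusters.json")
        outliers = flag_outliers(sym, assignment,
                                 threshold_sd=config.outlier_threshold_sd)
        _write_json(out / "outliers.json", [dataclasses.asdict(f) for f in outliers])
        artifacts.append("outliers.json")
        summary["clustering"] = {
            "k": k, "medoid_ids": list(assignment.medoid_ids),
            "outliers": [f.institution for f in outliers]}
        if "pairwise" in config.designs:
            intra = intra_inter_summary(assignment, results_df,
                                        level=config.primary_level)
            intra.to_csv(out / "cluster_performance.csv", float_format="%.12g")
            artifacts.append("cluster_performance.csv")
            summary["clustering"]["intra_inter"] = json.loads(
                intra.to_json(orient="index"))
        return assignment

    stage("clustering")(_clustering)

    def _report():
        _write_json(out / "summary.json", summary)
        artifacts.append("summary.json")
        (out / "report.txt").write_text(render_report(summary))
        artifacts.append("report.txt")
        return None

    stage("report")(_report)

    manifest = {name: _sha256(out / name) for name in sorted(set(artifacts))}
    _write_json(out / "manifest.json", manifest)
    return StudyReport(out_dir=str(out), manifest=manifest,
                       stage_seconds=timings, summary=summary)


def render_report(summary: dict) -> str:
    """Plain-text report of self vs non-self performance by level/design."""
    lines = ["Model generalizability study", "=" * 60, ""]
    if "validation" in summary:
        v = summary["validation"]
        lines.append(f"Records: {v['n_output']} (of {v['n_input']}) | "
                     f"institutions: {v['n_institutions']} | labels: {v['n_labels']}")
    if "noise" in summary:
        nz = summary["noise"]
        lines.append(f"Misspelled words: {100 * nz['misspelled_word_rate']:.1f}% | "
                     f"records with a misspelling: {100 * nz['misspelled_record_rate']:.1f}%")
    if "vocabulary_sizes" in summary:
        vs = summary["vocabulary_sizes"]
        lines.append("Vocabulary size: " + " -> ".join(
            f"{k}={v}" for k, v in vs.items()))
    lines.append("")
    for design, per_level in summary.get("experiments", {}).get("designs", {}).items():
        lines.append(f"[{design}]")
        for lev, entry in sorted(per_level.items()):
            parts = [f"  level={lev:8s}"]
            for scope in ("self", "nonself"):
                if scope in entry:
                    acc = entry[scope]["accuracy"]
                    parts.append(f"{scope}: acc {100 * acc['mean']:.1f}%"
                                 + (f" [{100 * acc['sd']:.1f}%]"
                                    if acc["sd"] == acc["sd"] else ""))
            lines.append(" | ".join(parts))
    deltas = summary.get("experiments", {}).get("level_deltas", {})
    if deltas:
        lines.append("")
        lines.append("Level deltas (accuracy, non-self):")
        for key, entry in sorted(deltas.items()):
            if "nonself" in entry:
                acc = entry["nonself"]["accuracy"]
                lines.append(f"  {key}: {100 * acc['mean']:+.2f}% [{100 * acc['sd']:.2f}%]")
    if "correlation" in summary and summary["correlation"]:
        lines.append("")
        lines.append("Divergence vs micro-F1 (pooled non-self pairs):")
        for metric, rep in sorted(summary["correlation"].items()):
            lines.append(f"  {metric:14s} r={rep['pearson_r']:+.3f} "
                         f"R^2={rep['r_squared']:.3f} (n={rep['n_pairs']})")
    if "clustering" in summary:
        c = summary["clustering"]
        lines.append("")
        lines.append(f"k-medoids: k={c['k']}, medoids={', '.join(c['medoid_ids'])}")
        if c.get("outliers"):
            lines.append(f"Flagged outliers: {', '.join(c['outliers'])}")
        else:
            lines.append("Flagged outliers: none")
    return "\n".join(lines) + "\n"
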