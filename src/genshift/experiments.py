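"""Transfer-evaluation designs across preprocessing levels.

Three designs:

* ``pairwise`` — one model per (institution, level), trained on the entire
  institution and evaluated on every other institution's full data; the self
  cell is scored by stratified k-fold cross-validation (mean of fold metrics)
  so no record is ever scored by a model that saw it.
* ``pooled_8020`` — k folds, each holding out a stratified 20% within every
  institution; one combined model per fold, scored per institution on the
  held-out part; per-institution metrics are fold means.
* ``loio_holdout`` — leave-one-institution-out: one model per institution
  trained on all other institutions and scored on the held-out one.

All randomness (fold splits, network init) derives from one experiment seed
via labeled seed derivation, so a full run is reproducible bit-for-bit.
Every fitted model's training-record fingerprint and every cell's test-record
ids are kept in an audit log for leakage checks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._seeds import derive_seed
from .classifier import CptClassifier, EvalResult, evaluate as _evaluate_est
from .corpus import Corpus
from .preprocess import Lexicons, PreprocessLevel, TextPreprocessor, default_lexicons

__all__ = [
    "ExperimentPlan",
    "ResultTable",
    "run_pairwise",
    "run_pooled_8020",
    "run_loio_holdout",
    "run_design",
    "summarize_deltas",
    "PlanningError",
]

DESIGNS = ("pairwise", "pooled_8020", "loio_holdout")

ROW_COLUMNS = ["design", "train_id", "test_id", "level",
               "accuracy", "micro_f1", "n_test", "is_self"]


class PlanningError(ValueError):
    """Raised when a plan cannot be executed on the given corpus."""


@dataclass(frozen=True)
class ExperimentPlan:
    """What to run: designs × preprocessing levels, CV folds, seed."""

    designs: tuple[str, ...] = ("pairwise",)
    levels: tuple[str, ...] = ("minimal",)
    cv_folds: int = 5
    seed: int = 0
    classifier_params: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise PlanningError("cv_folds must be >= 2")
        if not self.designs or not self.levels:
            raise PlanningError("at least one design and one level required")
        for d in self.designs:
            if d not in DESIGNS:
                raise PlanningError(f"unknown design {d!r}")
        for lev in self.levels:
            PreprocessLevel.parse(lev)


@dataclass
class ResultTable:
    """Tidy table of evaluation cells plus the leakage-audit log."""

    df: pd.DataFrame
    design: str
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df[ROW_COLUMNS].reset_index(drop=True)

    def to_csv(self, path) -> None:
        out = self.df.sort_values(
            ["design", "level", "train_id", "test_id"]).reset_index(drop=True)
        out.to_csv(path, index=False, float_format="%.12g")

    def nonself(self) -> pd.DataFrame:
        return self.df[~self.df["is_self"].astype(bool)]

    def self_rows(self) -> pd.DataFrame:
        return self.df[self.df["is_self"].astype(bool)]


def _docs_by_level(corpus: Corpus, levels: Sequence[str],
                   lexicons: Lexicons) -> dict[str, np.ndarray]:
    out = {}
    texts = corpus.df["text"].tolist()
    for lev in levels:
        lev = PreprocessLevel.parse(lev).value
        pre = TextPreprocessor(level=lev, lexicons=lexicons).fit([])
        out[lev] = np.array(pre.transform(texts), dtype=object)
    return out


def _fit(docs, labels, seed: int, params: Mapping) -> CptClassifier:
    est = CptClassifier(**{**dict(params), "random_state": seed})
    return est.fit(docs, labels)


def _cell(est: CptClassifier, docs, labels, train_id, test_id, level,
          design) -> dict:
    from sklearn.metrics import accuracy_score, f1_score

    y_pred = est.predict(list(docs))
    acc = float(accuracy_score(labels, y_pred))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1 = float(f1_score(labels, y_pred, average="micro"))
    res = EvalResult(train_id=train_id, test_id=test_id, level=level,
                     accuracy=acc, micro_f1=f1, n_test=len(labels))
    return {"design": design, "train_id": res.train_id, "test_id": res.test_id,
            "level": res.level, "accuracy": res.accuracy,
            "micro_f1": res.micro_f1, "n_test": res.n_test, "is_self": False}


def _institution_indices(corpus: Corpus) -> dict[str, np.ndarray]:
    return {inst: corpus.df.index[corpus.df["institution_id"] == inst].to_numpy()
            for inst in corpus.institutions}


def _check_min_records(idx_by_inst, cv_folds: int) -> None:
    for inst, idx in idx_by_inst.items():
        if len(idx) < cv_folds:
            raise PlanningError(
                f"institution {inst} has {len(idx)} records < cv_folds={cv_folds}")


def _stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return list(skf.split(np.zeros(len(labels)), labels))


def run_pairwise(corpus: Corpus, plan: ExperimentPlan,
                 lexicons: Lexicons | None = None) -> ResultTable:
    """All-pairs single-institution transfer with cross-validated self cells."""
    lexicons = lexicons if lexicons is not None else default_lexicons()
    insts = corpus.institutions
    if len(insts) < 2:
        raise PlanningError("pairwise design needs >= 2 institutions")
    idx_by_inst = _institution_indices(corpus)
    _check_min_records(idx_by_inst, plan.cv_folds)
    docs = _docs_by_level(corpus, plan.levels, lexicons)
    labels_all = corpus.df["label"].to_numpy()
    rows, audit = [], {}
    for lev in [PreprocessLevel.parse(l).value for l in plan.levels]:
        for inst in insts:
            idx = idx_by_inst[inst]
            seed = derive_seed(plan.seed, "pairwise", lev, inst)
            est = _fit(docs[lev][idx], labels_all[idx], seed, plan.classifier_params)
            audit[("pairwise", lev, inst)] = {
                "train_fingerprint": corpus.fingerprint(idx),
                "train_indices": tuple(int(i) for i in idx),
                "test_indices": {}}
            for other in insts:
                if other == inst:
                    continue
                oidx = idx_by_inst[other]
                rows.append(_cell(est, docs[lev][oidx], labels_all[oidx],
                                  inst, other, lev, "pairwise"))
                audit[("pairwise", lev, inst)]["test_indices"][other] = \
                    tuple(int(i) for i in oidx)
            # self cell by stratified k-fold CV
            accs, f1s, fold_audit = [], [], []
            folds = _stratified_folds(labels_all[idx], plan.cv_folds,
                                      derive_seed(plan.seed, "selfcv", lev, inst))
            for fi, (tr, te) in enumerate(folds):
                fest = _fit(docs[lev][idx[tr]], labels_all[idx[tr]],
                            derive_seed(plan.seed, "selfcv", lev, inst, fi),
                            plan.classifier_params)
                cell = _cell(fest, docs[lev][idx[te]], labels_all[idx[te]],
                             inst, inst, lev, "pairwise")
                accs.append(cell["accuracy"])
                f1s.append(cell["micro_f1"])
                fold_audit.append({"train_indices": tuple(int(i) for i in idx[tr]),
                                   "test_indices": tuple(int(i) for i in idx[te])})
            rows.append({"design": "pairwise", "train_id": inst, "test_id": inst,
                         "level": lev, "accuracy": float(np.mean(accs)),
                         "micro_f1": float(np.mean(f1s)),
                         "n_test": int(len(idx)), "is_self": True})
            audit[("pairwise", lev, inst)]["self_cv"] = fold_audit
    return ResultTable(df=pd.DataFrame(rows), design="pairwise", audit=audit)


def run_pooled_8020(corpus: Corpus, plan: ExperimentPlan,
                    lexicons: Lexicons | None = None) -> ResultTable:
    """Combined model on a stratified 80% of every institution, scored on the
    remaining 20%, repeated over ``cv_folds`` disjoint folds."""
    lexicons = lexicons if lexicons is not None else default_lexicons()
    insts = corpus.institutions
    if len(insts) < 2:
        raise PlanningError("pooled design needs >= 2 institutions")
    idx_by_inst = _institution_indices(corpus)
    _check_min_records(idx_by_inst, plan.cv_folds)
    docs = _docs_by_level(corpus, plan.levels, lexicons)
    labels_all = corpus.df["label"].to_numpy()
    # per-institution stratified folds -> global fold memberships
    fold_test: dict[int, list[np.ndarray]] = {f: [] for f in range(plan.cv_folds)}
    for inst in insts:
        idx = idx_by_inst[inst]
        folds = _stratified_folds(labels_all[idx], plan.cv_folds,
                                  derive_seed(plan.seed, "pooled", inst))
        for f, (_, te) in enumerate(folds):
            fold_test[f].append(idx[te])
    rows, audit = [], {}
    per_cell: dict[tuple, list[dict]] = {}
    for lev in [PreprocessLevel.parse(l).value for l in plan.levels]:
        for f in range(plan.cv_folds):
            test_idx = np.concatenate(fold_test[f])
            mask = np.ones(len(corpus.df), dtype=bool)
            mask[test_idx] = False
            train_idx = corpus.df.index.to_numpy()[mask]
            est = _fit(docs[lev][train_idx], labels_all[train_idx],
                       derive_seed(plan.seed, "pooled", lev, f),
                       plan.classifier_params)
            audit[("pooled_8020", lev, f)] = {
                "train_fingerprint": corpus.fingerprint(train_idx),
                "train_indices": tuple(int(i) for i in train_idx),
                "test_indices": {}}
            for inst, te in zip(insts, fold_test[f]):
                cell = _cell(est, docs[lev][te], labels_all[te],
                             "pooled", inst, lev, "pooled_8020")
                per_cell.setdefault((lev, inst), []).append(cell)
                audit[("pooled_8020", lev, f)]["test_indices"][inst] = \
                    tuple(int(i) for i in te)
    for (lev, inst), cells in per_cell.items():
        rows.append({"design": "pooled_8020", "train_id": "pooled",
                     "test_id": inst, "level": lev,
                     "accuracy": float(np.mean([c["accuracy"] for c in cells])),
                     "micro_f1": float(np.mean([c["micro_f1"] for c in cells])),
                     "n_test": int(sum(c["n_test"] for c in cells)),
                     "is_self": False})
    return ResultTable(df=pd.DataFrame(rows), design="pooled_8020", audit=audit)


def run_loio_holdout(corpus: Corpus, plan: ExperimentPlan,
                     lexicons: Lexicons | None = None) -> ResultTable:
    """Leave-one-institution-out: train on all but one, test on the holdout."""
    lexicons = lexicons if lexicons is not None else default_lexicons()
    insts = corpus.institutions
    if len(insts) < 3:
        raise PlanningError("holdout design needs >= 3 institutions")
    idx_by_inst = _institution_indices(corpus)
    _check_min_records(idx_by_inst, plan.cv_folds)
    docs = _docs_by_level(corpus, plan.levels, lexicons)
    labels_all = corpus.df["label"].to_numpy()
    rows, audit = [], {}
    for lev in [PreprocessLevel.parse(l).value for l in plan.levels]:
        for inst in insts:
            te = idx_by_inst[inst]
            tr = np.concatenate([idx_by_inst[o] for o in insts if o != inst])
            est = _fit(docs[lev][tr], labels_all[tr],
                       derive_seed(plan.seed, "loio", lev, inst),
                       plan.classifier_params)
            cell = _cell(est, docs[lev][te], labels_all[te],
                         f"all-minus-{inst}", inst, lev, "loio_holdout")
            rows.append(cell)
            audit[("loio_holdout", lev, inst)] = {
                "train_fingerprint": corpus.fingerprint(tr),
                "train_indices": tuple(int(i) for i in tr),
                "test_indices": {inst: tuple(int(i) for i in te)}}
    return ResultTable(df=pd.DataFrame(rows), design="loio_holdout", audit=audit)


_RUNNERS = {"pairwise": run_pairwise, "pooled_8020": run_pooled_8020,
            "loio_holdout": run_loio_holdout}


def run_design(design: str, corpus: Corpus, plan: ExperimentPlan,
               lexicons: Lexicons | None = None) -> ResultTable:
    if design not in _RUNNERS:
        raise PlanningError(f"unknown design {design!r}")
    return _RUNNERS[design](corpus, plan, lexicons)


# ---------------------------------------------------------------------------
# summaries


def _mean_sd(values) -> dict:
    v = np.asarray(list(values), dtype=float)
    return {"mean": float(v.mean()) if len(v) else float("nan"),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
            "n": int(len(v))}


def summarize_deltas(tables: Sequence[ResultTable]) -> dict:
    """Self/non-self summaries per design and level, level-to-level paired
    deltas, and combined-vs-single comparisons.

    Summary SDs are taken over institution-level aggregates (each training
    institution's non-self mean counts once), mirroring how the pairwise
    matrix is usually reported.
    """
    frames = [t.df for t in tables]
    all_df = pd.concat(frames, ignore_index=True)
    inst_sets = []
    for t in tables:
        ids = set(t.df["test_id"])
        if t.design == "pairwise":
            ids |= set(t.df["train_id"])
        inst_sets.append(ids)
    base_insts = set.union(*[set(t.df["test_id"]) for t in tables])
    for t, ids in zip(tables, inst_sets):
        if set(t.df["test_id"]) - base_insts:
            raise ValueError("tables cover mismatched institution sets")

    out: dict = {"designs": {}, "level_deltas": {}, "combined_vs_single": {}}
    pairwise = all_df[all_df["design"] == "pairwise"]
    levels = sorted(all_df["level"].unique())

    for design, sub in all_df.groupby("design"):
        per_level = {}
        for lev, lsub in sub.groupby("level"):
            nonself = lsub[~lsub["is_self"].astype(bool)]
            selfr = lsub[lsub["is_self"].astype(bool)]
            entry = {}
            if len(nonself):
                by_train = nonself.groupby("train_id")[["accuracy", "micro_f1"]].mean()
                entry["nonself"] = {m: _mean_sd(by_train[m]) for m in ("accuracy", "micro_f1")}
            if len(selfr):
                entry["self"] = {m: _mean_sd(selfr[m]) for m in ("accuracy", "micro_f1")}
            per_level[lev] = entry
        out["designs"][design] = per_level

    # paired level deltas on the pairwise design
    if len(pairwise) and len(levels) > 1:
        for i, l1 in enumerate(levels):
            for l2 in levels[i + 1:]:
                key = f"{l2}-{l1}"
                deltas = {}
                for scope, mask in (("nonself", ~pairwise["is_self"].astype(bool)),
                                    ("self", pairwise["is_self"].astype(bool))):
                    p = pairwise[mask]
                    a = p[p["level"] == l1].groupby("train_id")[["accuracy", "micro_f1"]].mean()
                    b = p[p["level"] == l2].groupby("train_id")[["accuracy", "micro_f1"]].mean()
                    common = a.index.intersection(b.index)
                    if len(common):
                        diff = b.loc[common] - a.loc[common]
                        deltas[scope] = {m: _mean_sd(diff[m]) for m in ("accuracy", "micro_f1")}
                out["level_deltas"][key] = deltas

    # pooled / holdout vs single-institution baselines
    for design in ("pooled_8020", "loio_holdout"):
        sub = all_df[all_df["design"] == design]
        if not len(sub) or not len(pairwise):
            continue
        for lev, lsub in sub.groupby("level"):
            p = pairwise[pairwise["level"] == lev]
            if not len(p):
                continue
            transfer_into = (p[~p["is_self"].astype(bool)]
                             .groupby("test_id")[["accuracy", "micro_f1"]].mean())
            self_base = p[p["is_self"].astype(bool)].set_index("train_id")[
                ["accuracy", "micro_f1"]]
            gains, shortfalls = [], []
            n_improved = 0
            for row in lsub.itertuples():
                inst = row.test_id
                if inst in transfer_into.index:
                    gain = row.accuracy - float(transfer_into.loc[inst, "accuracy"])
                    gains.append(gain)
                    n_improved += int(gain > 0)
                if inst in self_base.index:
                    shortfalls.append(row.accuracy - float(self_base.loc[inst, "accuracy"]))
            out["combined_vs_single"][f"{design}/{lev}"] = {
                "nonself_accuracy_gain": _mean_sd(gains),
                "n_institutions_improved": n_improved,
                "n_institutions": len(gains),
                "self_accuracy_delta": _mean_sd(shortfalls),
            }
    return out
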