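"""Corpus container and I/O.

A corpus is a flat table of procedure records — one ``(institution_id, text,
label)`` triple per row — together with the global label set shared by every
institution. Records are stored in a :class:`pandas.DataFrame`; synthetic
corpora additionally carry per-record noise metadata (which tokens were
misspelled or abbreviated at generation time).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ProcedureRecord",
    "RecordNoise",
    "Corpus",
    "read_corpus",
    "validate_corpus",
    "CorpusValidationError",
]

COLUMNS = ("institution_id", "text", "label")


@dataclass(frozen=True)
class ProcedureRecord:
    """One labeled procedure: free text plus its billed procedure code."""

    institution_id: str
    text: str
    label: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("procedure text must be non-empty")


@dataclass(frozen=True)
class RecordNoise:
    """Generation-time noise bookkeeping for one synthetic record.

    ``misspellings`` maps token position -> (clean, corrupted);
    ``n_eligible`` counts word tokens that were candidates for misspelling.
    """

    misspellings: tuple[tuple[int, str, str], ...] = ()
    abbreviated: bool = False
    n_eligible: int = 0


class CorpusValidationError(ValueError):
    """Raised when a corpus fails the record-level admission rules."""


@dataclass
class Corpus:
    """Institution-grouped collection of labeled procedure records."""

    df: pd.DataFrame
    label_set: tuple[str, ...]
    noise: list[RecordNoise] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"corpus frame missing columns: {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)
        self.label_set = tuple(self.label_set)
        if self.noise is not None and len(self.noise) != len(self.df):
            raise ValueError("noise metadata length mismatch")

    # -- access ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def institutions(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["institution_id"].unique()))

    def records_for(self, institution_id: str) -> pd.DataFrame:
        if institution_id not in set(self.df["institution_id"]):
            raise KeyError(f"unknown institution: {institution_id!r}")
        return self.df[self.df["institution_id"] == institution_id]

    def texts(self) -> list[str]:
        return self.df["text"].tolist()

    def label_distribution(self, institution_id: str) -> pd.Series:
        """Empirical label frequencies on the global label set (sums to 1)."""
        sub = self.records_for(institution_id)
        counts = sub["label"].value_counts().reindex(self.label_set, fill_value=0)
        return counts / counts.sum()

    def fingerprint(self, indices: Iterable[int] | None = None) -> str:
        """Stable hash of a record subset, used for train/test leakage audits."""
        idx = sorted(indices) if indices is not None else list(self.df.index)
        h = hashlib.sha256()
        sub = self.df.loc[idx]
        for row in sub.itertuples(index=True):
            h.update(f"{row.Index}\x1f{row.institution_id}\x1f{row.text}\x1f{row.label}\n".encode())
        return h.hexdigest()

    # -- I/O ------------------------------------------------------------
    def to_jsonl(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for row in self.df.itertuples(index=False):
                fh.write(json.dumps(
                    {"institution_id": row.institution_id,
                     "text": row.text, "label": row.label}) + "\n")

    def to_csv(self, path: str | Path) -> None:
        self.df[list(COLUMNS)].to_csv(path, index=False)

    def noise_to_json(self, path: str | Path) -> None:
        if self.noise is None:
            raise ValueError("corpus carries no noise metadata")
        payload = [dataclasses.asdict(n) for n in self.noise]
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_records(cls, records: Sequence[ProcedureRecord],
                     label_set: Sequence[str] | None = None) -> "Corpus":
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        labels = tuple(label_set) if label_set is not None else tuple(sorted(df["label"].unique()))
        return cls(df=df, label_set=labels)

    @classmethod
    def from_jsonl(cls, path: str | Path,
                   label_set: Sequence[str] | None = None) -> "Corpus":
        rows = []
        with Path(path).open() as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        if not rows:
            raise CorpusValidationError(f"no records in {path}")
        df = pd.DataFrame(rows)[list(COLUMNS)]
        labels = tuple(label_set) if label_set is not None else tuple(sorted(df["label"].unique()))
        return cls(df=df, label_set=labels)

    @classmethod
    def from_csv(cls, path: str | Path,
                 label_set: Sequence[str] | None = None) -> "Corpus":
        df = pd.read_csv(path, dtype=str)
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise CorpusValidationError(f"missing columns in {path}: {sorted(missing)}")
        labels = tuple(label_set) if label_set is not None else tuple(sorted(df["label"].unique()))
        return cls(df=df[list(COLUMNS)], label_set=labels)


def read_corpus(path: str | Path) -> Corpus:
    """Read a corpus from JSONL or CSV, dispatching on the file suffix."""
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".ndjson", ".json"}:
        return Corpus.from_jsonl(path)
    return Corpus.from_csv(path)


def validate_corpus(corpus: Corpus) -> tuple[Corpus, dict]:
    """Apply the study admission rules and report what was dropped.

    Records with empty/missing text or label are removed, then labels are
    restricted to those present at *all* institutions. Because dropping
    records can itself un-share labels, the shared-label filter is iterated
    to a fixpoint.

    Returns the filtered corpus plus a report with per-rule drop counts.
    """
    df = corpus.df.copy()
    n0 = len(df)
    text_ok = df["text"].astype(str).str.strip().ne("") & df["text"].notna()
    label_ok = df["label"].astype(str).str.strip().ne("") & df["label"].notna()
    df = df[text_ok & label_ok]
    dropped_empty = n0 - len(df)

    dropped_unshared = 0
    while True:
        institutions = df["institution_id"].unique()
        if len(df) == 0:
            break
        per_inst = df.groupby("institution_id")["label"].agg(set)
        shared = set.intersection(*per_inst.tolist()) if len(per_inst) else set()
        keep = df["label"].isin(shared)
        if keep.all():
            break
        dropped_unshared += int((~keep).sum())
        df = df[keep]
    if len(df) == 0:
        raise CorpusValidationError("no records survive validation")

    shared_labels = tuple(sorted(df["label"].unique()))
    report = {
        "n_input": n0,
        "n_output": len(df),
        "dropped": {"empty_text_or_label": dropped_empty,
                    "unshared_label": dropped_unshared},
        "dropped_per_institution": (
            corpus.df.loc[corpus.df.index.difference(df.index), "institution_id"]
            .value_counts().to_dict()),
        "n_institutions": int(df["institution_id"].nunique()),
        "n_labels": len(shared_labels),
    }
    noise = None
    if corpus.noise is not None:
        noise = [corpus.noise[i] for i in df.index]
    return Corpus(df=df.reset_index(drop=True), label_set=shared_labels,
                  noise=noise), report
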