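"""Shared fixtures.

The expensive full-scale study (the default shifted corpus, 6 institutions ×
1500 records, both preprocessing levels, all three designs) is run once per
session and shared by every test that inspects its outputs.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pytest

import genshift as g

# small, fast-converging network for unit tests on small corpora
TINY_CLF = {"hidden_layer_sizes": (64,), "max_epochs": 60,
            "batch_size": 32, "learning_rate": 3e-3}

STUDY_SEED = 1  # the development seed for the directional full-scale study


@pytest.fixture(scope="session")
def lexicons() -> g.Lexicons:
    return g.default_lexicons()


@pytest.fixture(scope="session")
def small_corpus():
    """4 institutions x 200 records with default shift/noise settings."""
    cfg = g.GeneratorConfig(n_institutions=4, n_labels=8,
                            records_per_institution=200, seed=11)
    return g.generate_corpus(cfg)


@pytest.fixture(scope="session")
def full_study_dir(tmp_path_factory) -> Path:
    """One full-scale study run (shared; takes several minutes)."""
    out = tmp_path_factory.mktemp("full_study")
    cfg = g.demo_config(str(out), scale="full", seed=STUDY_SEED)
    g.run_study(cfg)
    return out


@pytest.fixture(scope="session")
def full_results(full_study_dir) -> pd.DataFrame:
    return pd.read_csv(full_study_dir / "results.csv")


@pytest.fixture(scope="session")
def full_summary(full_study_dir) -> dict:
    return json.loads((full_study_dir / "summary.json").read_text())
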