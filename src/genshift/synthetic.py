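"""Synthetic multi-institution procedure-text corpus generator.

The generator emulates a multi-center procedure registry: each institution has
its own mix over a shared set of procedure-code labels (label shift) and its
own writing habits (covariate shift) layered on shared phrase templates in the
style of real procedural free text ("Left total knee replacement", "R TKA
(arthroscopy repalcement total knee)", ...).

Mechanisms, all seeded and all recorded in :class:`GroundTruth`:

* label mixes follow a hierarchical model: a common case-mix base (drawn once
  per corpus) captures that popular procedures are popular nearly everywhere,
  and each institution's mix is a Dirichlet deviation around it whose
  concentration ``label_concentration`` controls per-institution skew; planted
  outlier institutions override their mix (e.g. mass concentrated on a
  pediatric-style label subset);
* each label's text is assembled from a template: optional laterality, a
  distinguishing modifier (sometimes dropped — real notes are underspecified),
  site tokens, an action synonym slot, optional boilerplate tail and a
  surgical-code digit group;
* institution-private vocabulary: with probability ``private_vocab_fraction``
  the modifier+action phrase is replaced by a local jargon word. Each label
  has a finite pool of plausible jargon variants and each institution commits
  to one, so distinct institutions occasionally coincide — the way local
  shorthand recurs across subsets of real sites. Each institution additionally
  carries a private boilerplate inventory whose size grows with
  ``private_vocab_fraction``, so vocabulary divergence is graded in the knob;
* noise: acronym substitution, per-word misspellings (single character
  substitution or adjacent transposition, recorded per record), mixed casing,
  inserted stop words, punctuation and digit groups.

Institutions also differ in style intensities (boilerplate and abbreviation
tendency), which perturbs their word *distributions* without changing the
shared support — so the zero-noise configuration yields identical
vocabularies across institutions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from ._seeds import rng_for
from .corpus import Corpus, RecordNoise

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_corpus",
    "corpus_misspelling_stats",
    "load_templates",
]

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"

# style constants shared by all institutions (support-neutral)
_P_LATERAL = 0.8
_P_BILATERAL = 0.10
_P_OF = 0.25
_P_DIGIT = 0.2
_P_UPPER = 0.10
_P_TITLE = 0.25
_P_ACRONYM_UPPER = 0.8
_MIN_MISSPELL_LEN = 4
_JARGON_POOL_SIZE = 6       # per-label plausible local-shorthand variants
_TAIL_INVENTORY_SCALE = 16  # private boilerplate tokens ~= pvf * scale


class GeneratorConfigError(ValueError):
    """Raised for invalid generator configurations."""


def load_templates() -> list[dict]:
    """The packaged per-label phrase templates (48 entries)."""
    path = resources.files("genshift") / "data" / "templates.json"
    return json.loads(path.read_text())


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs controlling label shift, vocabulary shift and noise."""

    n_institutions: int = 6
    n_labels: int = 16
    records_per_institution: int = 1500
    label_concentration: float = 1.0
    private_vocab_fraction: float = 0.5
    misspell_word_rate: float = 0.10
    abbreviation_rate: float = 0.15
    modifier_drop_rate: float = 0.20
    outlier_institutions: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_institutions < 1 or self.records_per_institution < 1:
            raise GeneratorConfigError("counts must be >= 1")
        if self.n_labels < 2:
            raise GeneratorConfigError("n_labels must be >= 2")
        if self.n_labels > 48:
            raise GeneratorConfigError("at most 48 label templates are available")
        for name in ("private_vocab_fraction", "misspell_word_rate",
                     "abbreviation_rate", "modifier_drop_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorConfigError(f"{name} must be in [0, 1], got {v}")
        if self.label_concentration <= 0:
            raise GeneratorConfigError("label_concentration must be positive")
        for item in self.outlier_institutions:
            idx, override = item
            if not 0 <= int(idx) < self.n_institutions:
                raise GeneratorConfigError(f"outlier index {idx} out of range")
            if not isinstance(override, (int, float)) and len(override) != self.n_labels:
                raise GeneratorConfigError(
                    "outlier override must be a scalar mass or a length-n_labels vector")


@dataclass
class GroundTruth:
    """The generating distributions and lexicons behind a synthetic corpus."""

    labels: tuple[str, ...]
    label_distributions: dict[str, np.ndarray]
    word_distributions: dict[tuple[str, str], dict[str, float]]
    misspelling_map: dict[str, str]
    abbreviation_map: dict[str, tuple[str, ...]]
    private_vocabulary: dict[str, frozenset[str]]
    outlier_label_subset: tuple[str, ...] = ()
    styles: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for inst, p in self.label_distributions.items():
            if abs(float(np.sum(p)) - 1.0) > 1e-9:
                raise ValueError(f"label distribution for {inst} does not sum to 1")
        for key, dist in self.word_distributions.items():
            if not dist:
                raise ValueError(f"empty word distribution for {key}")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"word distribution for {key} does not sum to 1")

    def analytic_label_kld(self, inst_a: str, inst_b: str,
                           epsilon: float = 1e-9) -> float:
        """KL divergence D(p_b || p_a) of the *generating* label mixes."""
        from .divergence import DistributionPair, kl_divergence
        pair = DistributionPair.from_counts(
            support=list(self.labels),
            counts_p=self.label_distributions[inst_b],
            counts_q=self.label_distributions[inst_a],
            smoothing_epsilon=epsilon)
        return kl_divergence(pair)


def _pseudo_word(rng: np.random.Generator, taken: set[str],
                 forbidden: frozenset[str]) -> str:
    while True:
        n_syll = int(rng.integers(2, 4))
        word = "".join(
            _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
            + _VOWELS[int(rng.integers(len(_VOWELS)))]
            for _ in range(n_syll))
        if len(word) >= _MIN_MISSPELL_LEN and word not in taken and word not in forbidden:
            taken.add(word)
            return word


def _institution_style(cfg: GeneratorConfig, idx: int) -> dict:
    rng = rng_for(cfg.seed, "style", idx)
    return {
        "p_tail": float(rng.uniform(0.3, 0.7)),
        "abbr_mult": float(rng.uniform(0.5, 1.5)),
    }


def _base_case_mix(cfg: GeneratorConfig) -> np.ndarray:
    """Common case-mix backbone shared by all institutions (drawn once)."""
    return rng_for(cfg.seed, "base_mix").dirichlet(np.full(cfg.n_labels, 2.0))


def _label_distribution(cfg: GeneratorConfig, idx: int, base: np.ndarray,
                        overrides: Mapping[int, object],
                        subset_size: int) -> np.ndarray:
    rng = rng_for(cfg.seed, "labels", idx)
    alpha = np.maximum(cfg.label_concentration * cfg.n_labels * base, 1e-6)
    p_inst = rng.dirichlet(alpha)
    if idx not in overrides:
        return p_inst
    override = overrides[idx]
    if isinstance(override, (int, float)):
        mass = float(override)
        if not 0.0 < mass < 1.0:
            raise GeneratorConfigError("outlier mass must be in (0, 1)")
        p = np.zeros(cfg.n_labels)
        inner = rng.dirichlet(alpha[:subset_size])
        p[:subset_size] = mass * inner
        rest = p_inst[subset_size:]
        p[subset_size:] = (1 - mass) * rest / rest.sum()
        return p
    p = np.asarray(override, dtype=float)
    if (p < 0).any():
        raise GeneratorConfigError("outlier override has negative entries")
    return p / p.sum()


def _expected_word_distribution(template: dict, style: dict,
                                cfg: GeneratorConfig,
                                jargon: str, tail_inventory: tuple[str, ...],
                                ) -> dict[str, float]:
    """Expected clean (noise-free, minimally preprocessed) token frequencies."""
    counts: dict[str, float] = {}

    def add(token: str, p: float) -> None:
        if p > 0:
            counts[token] = counts.get(token, 0.0) + p

    a = min(cfg.abbreviation_rate * style["abbr_mult"], 0.95) if template["acronym"] else 0.0
    pvf = cfg.private_vocab_fraction
    if template["lateral"]:
        half = _P_LATERAL * (1 - _P_BILATERAL) / 2
        add("left", half)
        add("right", half)
        add("bilateral", _P_LATERAL * _P_BILATERAL)
    if a:
        add(template["acronym"], a)
    for tok in template["site"]:
        add(tok, 1 - a)
    add(jargon, (1 - a) * pvf)
    shared = (1 - a) * (1 - pvf)
    for tok in template["variant"]:
        add(tok, shared * (1 - cfg.modifier_drop_rate))
    groups = template["actions"]
    for group in groups:
        for tok in group:
            add(tok, shared / len(groups))
    p_tail = style["p_tail"]
    for tail in template["tails"]:
        for tok in tail:
            add(tok, p_tail * (1 - 0.5 * pvf) / len(template["tails"]))
    if tail_inventory:
        # a private-boilerplate tail emits two uniform draws (with replacement)
        for tok in tail_inventory:
            add(tok, p_tail * 0.5 * pvf * 2.0 / len(tail_inventory))
    add(template["surgical_code"], _P_DIGIT)
    total = sum(counts.values())
    return {t: c / total for t, c in sorted(counts.items())}


def _misspell(token: str, rng: np.random.Generator) -> str:
    for _ in range(8):
        if rng.random() < 0.6:  # substitution
            pos = int(rng.integers(len(token)))
            ch = _VOWELS[int(rng.integers(len(_VOWELS)))] if rng.random() < 0.4 \
                else _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
            cand = token[:pos] + ch + token[pos + 1:]
        else:  # adjacent transposition
            pos = int(rng.integers(len(token) - 1))
            cand = token[:pos] + token[pos + 1] + token[pos] + token[pos + 2:]
        if cand != token:
            return cand
    return token


def _assemble_record(template: dict, style: dict, cfg: GeneratorConfig,
                     jargon: str, tail_inventory: tuple[str, ...],
                     rng: np.random.Generator,
                     misspelling_map: dict[str, str],
                     ) -> tuple[str, RecordNoise]:
    # clean token assembly -------------------------------------------------
    lead: list[str] = []
    lateral_tok = None
    if template["lateral"] and rng.random() < _P_LATERAL:
        r = rng.random()
        lateral_tok = "bilateral" if r < _P_BILATERAL else ("left" if r < (1 + _P_BILATERAL) / 2 else "right")

    abbr_eff = min(cfg.abbreviation_rate * style["abbr_mult"], 0.95) if template["acronym"] else 0.0
    abbreviated = rng.random() < abbr_eff
    acronym_positions: set[int] = set()
    if abbreviated:
        descriptor = [template["acronym"]]
        descriptor_kind = "acronym"
    elif rng.random() < cfg.private_vocab_fraction:
        descriptor = [jargon] + list(template["site"])
        descriptor_kind = "private"
    else:
        variant = [] if rng.random() < cfg.modifier_drop_rate else list(template["variant"])
        action = list(template["actions"][int(rng.integers(len(template["actions"])))])
        if rng.random() < _P_OF:  # "total replacement of left knee"
            descriptor = variant + action + ["of"] + \
                ([lateral_tok] if lateral_tok else []) + list(template["site"])
            lateral_tok = None
        else:
            descriptor = variant + list(template["site"]) + action
        descriptor_kind = "shared"

    if lateral_tok:
        lead.append(lateral_tok)
    tokens = lead + descriptor
    if descriptor_kind == "acronym":
        acronym_positions.add(len(tokens) - 1)

    tail: list[str] = []
    if rng.random() < style["p_tail"]:
        if tail_inventory and rng.random() < 0.5 * cfg.private_vocab_fraction:
            tail = [tail_inventory[int(rng.integers(len(tail_inventory)))],
                    tail_inventory[int(rng.integers(len(tail_inventory)))]]
        else:
            tail = list(template["tails"][int(rng.integers(len(template["tails"])))])
    digit_tok = None
    if rng.random() < _P_DIGIT:
        digit_tok = f"{int(template['surgical_code']):,}"

    # noise ---------------------------------------------------------------
    body = tokens + tail
    misspellings: list[tuple[int, str, str]] = []
    n_eligible = 0
    noised: list[str] = []
    for pos, tok in enumerate(body):
        eligible = (tok.isalpha() and len(tok) >= _MIN_MISSPELL_LEN
                    and pos not in acronym_positions)
        if eligible:
            n_eligible += 1
            if rng.random() < cfg.misspell_word_rate:
                bad = _misspell(tok, rng)
                if bad != tok:
                    misspellings.append((pos, tok, bad))
                    misspelling_map.setdefault(bad, tok)
                    noised.append(bad)
                    continue
        noised.append(tok)

    # casing and punctuation ----------------------------------------------
    r = rng.random()
    if r < _P_UPPER:
        cased = [t.upper() for t in noised]
    elif r < _P_UPPER + _P_TITLE:
        cased = [t.capitalize() for t in noised]
    else:
        cased = list(noised)
    for pos in acronym_positions:
        if rng.random() < _P_ACRONYM_UPPER:
            cased[pos] = cased[pos].upper()

    n_body = len(tokens)
    parts = cased[:n_body]
    tail_cased = cased[n_body:]
    if tail_cased:
        if rng.random() < 0.4:
            parts = parts + [f"({' '.join(tail_cased)})"]
        elif rng.random() < 0.5:
            parts = parts + [","] + tail_cased
        else:
            parts = parts + tail_cased
    if digit_tok is not None:
        parts = [digit_tok + ","] + parts
    text = " ".join(parts).replace(" ,", ",")
    return text, RecordNoise(misspellings=tuple(misspellings),
                             abbreviated=abbreviated, n_eligible=n_eligible)


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a labeled multi-institution corpus plus its ground truth.

    Deterministic given ``config`` (including its seed): two calls with the
    same config produce byte-identical corpora.
    """
    from .preprocess import default_lexicons

    templates = load_templates()[: config.n_labels]
    labels = tuple(t["code"] for t in templates)
    subset_size = max(2, config.n_labels // 6)
    overrides = {int(i): o for i, o in config.outlier_institutions}
    reference = default_lexicons().reference_words

    inst_ids = [f"inst{idx:02d}" for idx in range(config.n_institutions)]
    taken: set[str] = set()
    # per-label pools of plausible jargon variants; institutions commit to one
    pool_rng = rng_for(config.seed, "jargon")
    jargon_pools = {t["code"]: [_pseudo_word(pool_rng, taken, reference)
                                for _ in range(_JARGON_POOL_SIZE)]
                    for t in templates}
    n_inventory = int(round(config.private_vocab_fraction * _TAIL_INVENTORY_SCALE))
    if config.private_vocab_fraction > 0:
        n_inventory = max(2, n_inventory)
    label_dists: dict[str, np.ndarray] = {}
    word_dists: dict[tuple[str, str], dict[str, float]] = {}
    styles: dict[str, dict] = {}
    private_vocab: dict[str, frozenset[str]] = {}
    misspelling_map: dict[str, str] = {}

    rows_inst: list[str] = []
    rows_text: list[str] = []
    rows_label: list[str] = []
    noise_meta: list[RecordNoise] = []

    base_mix = _base_case_mix(config)
    for idx, inst in enumerate(inst_ids):
        style = _institution_style(config, idx)
        styles[inst] = style
        p = _label_distribution(config, idx, base_mix, overrides, subset_size)
        label_dists[inst] = p

        wrng = rng_for(config.seed, "private", idx)
        jargon = {code: pool[int(wrng.integers(_JARGON_POOL_SIZE))]
                  for code, pool in jargon_pools.items()}
        tail_inventory = tuple(_pseudo_word(wrng, taken, reference)
                               for _ in range(n_inventory))
        private_vocab[inst] = frozenset(jargon.values()) | frozenset(tail_inventory)
        for t in templates:
            word_dists[(inst, t["code"])] = _expected_word_distribution(
                t, style, config, jargon[t["code"]], tail_inventory)

        rng = rng_for(config.seed, "records", idx)
        label_idx = rng.choice(config.n_labels, size=config.records_per_institution, p=p)
        for li in label_idx:
            t = templates[int(li)]
            text, noise = _assemble_record(
                t, style, config, jargon[t["code"]], tail_inventory, rng,
                misspelling_map)
            rows_inst.append(inst)
            rows_text.append(text)
            rows_label.append(t["code"])
            noise_meta.append(noise)

    import pandas as pd

    corpus = Corpus(
        df=pd.DataFrame({"institution_id": rows_inst, "text": rows_text,
                         "label": rows_label}),
        label_set=labels,
        noise=noise_meta)
    truth = GroundTruth(
        labels=labels,
        label_distributions=label_dists,
        word_distributions=word_dists,
        misspelling_map=misspelling_map,
        abbreviation_map={t["acronym"]: tuple(t["expansion"])
                          for t in templates if t["acronym"]},
        private_vocabulary=private_vocab,
        outlier_label_subset=labels[:subset_size] if overrides else (),
        styles=styles)
    return corpus, truth


def corpus_misspelling_stats(corpus: Corpus,
                             truth: GroundTruth | None = None,
                             ) -> tuple[float, float]:
    """(fraction of eligible word tokens misspelled, fraction of records
    containing at least one misspelling), from generation metadata."""
    if corpus.noise is None:
        raise ValueError("corpus has no generation metadata; "
                         "misspelling stats require a synthetic corpus")
    n_eligible = sum(n.n_eligible for n in corpus.noise)
    n_bad = sum(len(n.misspellings) for n in corpus.noise)
    n_records_bad = sum(1 for n in corpus.noise if n.misspellings)
    word_rate = n_bad / n_eligible if n_eligible else 0.0
    record_rate = n_records_bad / len(corpus.noise) if corpus.noise else 0.0
    return word_rate, record_rate


def expected_record_misspell_rate(corpus: Corpus, rate: float) -> float:
    """Closed-form record-level misspelling probability implied by per-token
    rate ``rate`` and the corpus' eligible-token length distribution."""
    if corpus.noise is None:
        raise ValueError("corpus has no generation metadata")
    return float(np.mean([1 - (1 - rate) ** n.n_eligible for n in corpus.noise]))
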