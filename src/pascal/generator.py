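"""Synthetic mixed-script clinical corpus generator.

Real chemotherapy-regimen mentions in Chinese EHR narratives are rich in
author idiosyncrasies: cycle multipliers ("EC ×4-TH ×4"), Chinese
connectives standing in for the hyphen ("EC 序贯 TH"), component-letter
permutations ("CEF ×3-P ×3" for FEC-P) and stray whitespace.  This module
emulates those surface phenomena inside short bilingual narrative
templates, emitting character-level gold labels (every character of a
mention carries its canonical regimen name; everything else is "O") plus
BIO recognition tags and a gold span table, so the whole pipeline can be
trained and evaluated without access to any hospital data.

Generation is fully deterministic given a config and seed: the same
inputs produce byte-identical corpora.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .corpus import (
    MAX_SENTENCE_LEN,
    OUTSIDE,
    Corpus,
    CorpusError,
    LabeledSentence,
    RegimenVocabulary,
    VocabularyError,
)
from .metrics import EntitySpan

#: Canonical regimen inventory used by default: adjuvant breast-cancer
#: chemotherapy acronyms (anthracycline/taxane combinations).  Deliberately
#: includes confusable pairs such as EC-T vs FEC-T.
DEFAULT_REGIMENS = ("AC", "EC", "TH", "EC-TH", "AC-T", "FEC-P", "FEC-T", "EC-T", "TC", "TAC")

#: Fixed component-letter permutation table (surface form ↔ canonical).
PERMUTATIONS = {"FEC": "CEF", "TAC": "TCA"}

_CONNECTIVES = ("序贯", " 序贯 ", "序贯 ")
_CYCLES = (2, 3, 4, 6)


@dataclass(frozen=True)
class VariantRule:
    """A named, reproducible string transformation of a canonical name."""

    name: str
    transform: Callable[[str, np.random.Generator], str]

    def apply(self, regimen: str, rng: np.random.Generator) -> str:
        out = self.transform(regimen, rng)
        if not out:
            raise ValueError(f"rule {self.name!r} produced an empty surface form")
        return out


def _components(regimen: str) -> list[str]:
    return regimen.split("-")


def _permute(comp: str) -> str:
    return PERMUTATIONS.get(comp, comp)


def _with_multiplier(comps: Sequence[str], k: int, sep: str) -> str:
    return sep.join(f"{c} ×{k}" for c in comps)


def _rule_multiplier(reg: str, rng: np.random.Generator) -> str:
    k = int(rng.choice(_CYCLES))
    return _with_multiplier(_components(reg), k, "-")


def _rule_connective(reg: str, rng: np.random.Generator) -> str:
    sep = str(rng.choice(_CONNECTIVES))
    return sep.join(_components(reg))


def _rule_permutation(reg: str, rng: np.random.Generator) -> str:
    return "-".join(_permute(c) for c in _components(reg))


def _rule_permutation_multiplier(reg: str, rng: np.random.Generator) -> str:
    k = int(rng.choice(_CYCLES))
    return _with_multiplier([_permute(c) for c in _components(reg)], k, "-")


def _rule_spaced(reg: str, rng: np.random.Generator) -> str:
    sep = str(rng.choice((" - ", " -", "- ")))
    comps = _components(reg)
    return sep.join(comps) if len(comps) > 1 else comps[0]


def _rule_multiplier_connective(reg: str, rng: np.random.Generator) -> str:
    k = int(rng.choice(_CYCLES))
    sep = str(rng.choice(_CONNECTIVES))
    return _with_multiplier(_components(reg), k, sep)


DEFAULT_RULES: tuple[VariantRule, ...] = (
    VariantRule("multiplier", _rule_multiplier),
    VariantRule("connective", _rule_connective),
    VariantRule("permutation", _rule_permutation),
    VariantRule("permutation_multiplier", _rule_permutation_multiplier),
    VariantRule("spaced", _rule_spaced),
    VariantRule("multiplier_connective", _rule_multiplier_connective),
)


def surface_variants(
    regimen: str,
    rules: Sequence[VariantRule],
    n: int,
    seed: int,
    vocabulary: RegimenVocabulary | None = None,
) -> list[str]:
    """Produce ``n`` surface strings for a canonical regimen.

    Variant 0 is always the canonical form itself; the remaining variants
    cycle through ``rules`` with per-variant sub-seeds, so every surface
    form maps unambiguously back to its canonical regimen and the list is
    reproducible for a fixed ``(regimen, rules, n, seed)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if vocabulary is not None and regimen not in vocabulary:
        raise VocabularyError(f"unknown regimen: {regimen!r}")
    out = [regimen]
    i = 1
    while len(out) < n:
        rule = rules[(i - 1) % len(rules)]
        rng = np.random.default_rng([seed % (2**31), i])
        out.append(rule.apply(regimen, rng))
        i += 1
    return out


def load_default_templates() -> list[str]:
    """Load the packaged bilingual narrative templates."""
    text = (importlib.resources.files("pascal") / "data" / "templates.txt").read_text(encoding="utf-8")
    return [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``split_ratio`` partitions *patients* 8:2 into train and test pools;
    10% of the training sentences are held out for validation.  Explicit
    per-split sentence ``counts`` (train, valid, test) may override the
    ratio-derived sentence counts; patient disjointness is preserved
    either way.
    """

    regimens: RegimenVocabulary = field(
        default_factory=lambda: RegimenVocabulary(DEFAULT_REGIMENS)
    )
    n_sentences: int = 1000
    n_patients: int = 100
    templates: tuple[str, ...] | None = None
    variant_rules: tuple[VariantRule, ...] = DEFAULT_RULES
    mention_rate: float = 1.2
    noise_rate: float = 0.1
    seed: int = 0
    max_len: int = MAX_SENTENCE_LEN
    split_ratio: tuple[float, float] = (0.8, 0.2)
    valid_fraction: float = 0.1
    counts: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_sentences <= 0:
            raise ValueError("n_sentences must be positive")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        if not 0.0 <= self.mention_rate <= 2.0:
            raise ValueError("mention_rate must lie in [0, 2] (templates carry at most 2 slots)")
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split_ratio fractions must sum to 1")


class _TemplatePool:
    def __init__(self, templates: Sequence[str], mention_rate: float):
        self.by_slots: dict[int, list[str]] = {0: [], 1: [], 2: []}
        for t in templates:
            k = t.count("{M}")
            if k > 2:
                raise ValueError(f"template has {k} slots; at most 2 supported: {t!r}")
            self.by_slots[k].append(t)
        self.mention_rate = mention_rate
        if mention_rate > 0 and not self.by_slots[1]:
            raise ValueError("need at least one single-slot template")

    def draw(self, rng: np.random.Generator) -> tuple[str, int]:
        # n_mentions ~ Binomial(2, rate/2): mean = mention_rate, support {0,1,2}
        k = int(rng.binomial(2, self.mention_rate / 2.0))
        while not self.by_slots[k]:
            k = 1 if k != 1 else 0
        pool = self.by_slots[k]
        return pool[int(rng.integers(len(pool)))], k


_NOISE_CONNECTIVES = set("，。、；：,")
_SIMILAR = {"，": ",", "。": ".", "；": ";", "：": ":", "０": "0", "１": "1"}


def render_sentence(
    template: str,
    mentions: Sequence[tuple[str, str]],
    sentence_id: str = "",
    patient_id: str = "",
    max_len: int = MAX_SENTENCE_LEN,
) -> tuple[LabeledSentence, list[EntitySpan]]:
    """Fill a template's ``{M}`` slots and emit aligned gold labels.

    Every character of an inserted surface string is labeled with the
    mention's canonical regimen (TER tags B then I...); every other
    character is "O".  Returns the sentence plus its recorded gold spans.
    """
    parts = template.split("{M}")
    if len(parts) - 1 != len(mentions):
        raise ValueError(f"template has {len(parts) - 1} slots but {len(mentions)} mentions given")
    chars: list[str] = []
    tags: list[str] = []
    labels: list[str] = []
    spans: list[EntitySpan] = []
    for part, (canonical, surface) in zip(parts, mentions):
        for ch in part:
            chars.append(ch), tags.append(OUTSIDE), labels.append(OUTSIDE)
        start = len(chars)
        for j, ch in enumerate(surface):
            chars.append(ch)
            tags.append("B" if j == 0 else "I")
            labels.append(canonical)
        spans.append(EntitySpan(sentence_id, canonical, start, len(chars)))
    for ch in parts[-1]:
        chars.append(ch), tags.append(OUTSIDE), labels.append(OUTSIDE)
    if len(chars) > max_len:
        raise CorpusError(f"rendered sentence has {len(chars)} characters > max_len {max_len}")
    sent = LabeledSentence(tuple(chars), tuple(tags), tuple(labels), sentence_id, patient_id)
    return sent, spans


def _apply_noise(
    sent: LabeledSentence, spans: list[EntitySpan], rng: np.random.Generator
) -> tuple[LabeledSentence, list[EntitySpan]]:
    """One typographic perturbation outside gold spans; labels stay exact."""
    chars, tags, labels = list(sent.chars), list(sent.ter_tags), list(sent.ten_labels)
    in_span = [lab != OUTSIDE for lab in labels]
    op = int(rng.integers(3))
    candidates: list[int]
    if op == 0:  # drop a connective / punctuation character
        candidates = [i for i, c in enumerate(chars) if c in _NOISE_CONNECTIVES and not in_span[i]]
    elif op == 1:  # duplicate a space
        candidates = [i for i, c in enumerate(chars) if c == " " and not in_span[i]]
    else:  # substitute a visually similar ASCII character
        candidates = [i for i, c in enumerate(chars) if c in _SIMILAR and not in_span[i]]
    if not candidates:
        return sent, spans
    i = int(candidates[int(rng.integers(len(candidates)))])
    if op == 0:
        del chars[i], tags[i], labels[i]
        shift = -1
    elif op == 1:
        chars.insert(i, " "), tags.insert(i, OUTSIDE), labels.insert(i, OUTSIDE)
        shift = 1
    else:
        chars[i] = _SIMILAR[chars[i]]
        shift = 0
    if shift:
        spans = [
            replace(s, start=s.start + (shift if s.start > i else 0), end=s.end + (shift if s.end > i else 0))
            for s in spans
        ]
    if not chars:
        return sent, spans
    new = LabeledSentence(tuple(chars), tuple(tags), tuple(labels), sent.sentence_id, sent.patient_id)
    return new, spans


def _make_sentence(
    cfg: GeneratorConfig,
    pool: _TemplatePool,
    sentence_id: str,
    patient_id: str,
    rng: np.random.Generator,
    forced_regimen: str | None = None,
) -> tuple[LabeledSentence, list[EntitySpan]]:
    regs = cfg.regimens.regimens
    for _attempt in range(32):
        if forced_regimen is None:
            template, k = pool.draw(rng)
        else:
            template, k = pool.by_slots[1][int(rng.integers(len(pool.by_slots[1])))], 1
        mentions = []
        for slot in range(k):
            canonical = forced_regimen if forced_regimen else str(regs[int(rng.integers(len(regs)))])
            n_var = 1 + int(rng.integers(8))
            variants = surface_variants(
                canonical, cfg.variant_rules, n_var, int(rng.integers(2**31)), cfg.regimens
            )
            mentions.append((canonical, variants[-1]))
        try:
            sent, spans = render_sentence(template, mentions, sentence_id, patient_id, cfg.max_len)
        except CorpusError:
            continue
        if rng.random() < cfg.noise_rate:
            sent, spans = _apply_noise(sent, spans, rng)
        return sent, spans
    raise CorpusError("could not render a sentence within max_len after bounded retries")


def generate_corpus(
    cfg: GeneratorConfig,
) -> tuple[Corpus, Corpus, Corpus, list[EntitySpan]]:
    """Generate (train, valid, test) corpora plus the gold span table.

    Patients are split 8:2 between the train and test pools before any
    sentence is drawn, so no patient contributes to both; validation
    sentences are sampled from the training pool only.  A coverage guard
    re-renders sentences until every regimen occurs at least once in
    train (only relevant for very small corpora).
    """
    if cfg.n_patients < 2:
        raise CorpusError("need at least 2 patients to split train/test")
    rng = np.random.default_rng(cfg.seed)
    templates = tuple(cfg.templates) if cfg.templates else tuple(load_default_templates())
    pool = _TemplatePool(templates, cfg.mention_rate)

    patients = [f"p{i:04d}" for i in range(cfg.n_patients)]
    order = rng.permutation(cfg.n_patients)
    n_test_p = max(1, round(cfg.split_ratio[1] * cfg.n_patients))
    test_patients = [patients[i] for i in order[:n_test_p]]
    train_patients = [patients[i] for i in order[n_test_p:]]

    if cfg.counts is not None:
        n_train, n_valid, n_test = cfg.counts
    else:
        n_test = round(cfg.split_ratio[1] * cfg.n_sentences)
        n_pool = cfg.n_sentences - n_test
        n_valid = round(cfg.valid_fraction * n_pool)
        n_train = n_pool - n_valid

    all_spans: list[EntitySpan] = []
    counter = 0

    def batch(n: int, pts: list[str]) -> list[LabeledSentence]:
        nonlocal counter
        out = []
        for _ in range(n):
            sid = f"s{counter:06d}"
            counter += 1
            pid = pts[int(rng.integers(len(pts)))]
            sent, spans = _make_sentence(cfg, pool, sid, pid, rng)
            out.append(sent)
            all_spans.extend(spans)
        return out

    pool_sents = batch(n_train + n_valid, train_patients)
    valid_idx = set(rng.choice(len(pool_sents), size=n_valid, replace=False).tolist())
    train_sents = [s for i, s in enumerate(pool_sents) if i not in valid_idx]
    valid_sents = [s for i, s in enumerate(pool_sents) if i in valid_idx]
    test_sents = batch(n_test, test_patients)

    # coverage guard: every regimen appears at least once in train
    seen = {lab for s in train_sents for lab in s.ten_labels if lab != OUTSIDE}
    missing = [r for r in cfg.regimens.regimens if r not in seen]
    for j, reg in enumerate(missing):
        victim = j % len(train_sents)
        old = train_sents[victim]
        all_spans = [sp for sp in all_spans if sp.sentence_id != old.sentence_id]
        sent, spans = _make_sentence(cfg, pool, old.sentence_id, old.patient_id, rng, forced_regimen=reg)
        train_sents[victim] = sent
        all_spans.extend(spans)

    return (
        Corpus(train_sents, "train"),
        Corpus(valid_sents, "valid"),
        Corpus(test_sents, "test"),
        all_spans,
    )


def write_gold_spans(spans: Sequence[EntitySpan], path: str | Path) -> Path:
    """Write the gold span table as JSONL (sentence_id, regimen, start, end)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in spans:
            fh.write(
                json.dumps(
                    {"sentence_id": s.sentence_id, "regimen": s.label, "start": s.start, "end": s.end},
                    ensure_ascii=False,
                )
                + "\n"
            )
    return path
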