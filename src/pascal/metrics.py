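"""Entity-level exact-match evaluation.

A predicted regimen mention counts as correct only when its canonical
label, start index and end index all equal a gold span's (character
coordinates, 0-based, half-open).  Precision, recall and F1 are
micro-averaged over the corpus; multi-run evaluation reports per-run
values plus mean ± standard deviation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import OUTSIDE


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A normalized mention: (sentence, canonical regimen, [start, end))."""

    sentence_id: str
    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.label == OUTSIDE:
            raise ValueError('span label may not be "O"')


def extract_entities(
    ten_labels: Sequence[str],
    ter_tags: Sequence[str] | None = None,
    sentence_id: str = "",
) -> list[EntitySpan]:
    """Spans are maximal runs of identical non-"O" TEN labels.

    When TER tags are supplied, a run is additionally split at every
    position tagged ``B``, so two adjacent mentions of the same regimen
    stay separate.
    """
    if ter_tags is not None and len(ter_tags) != len(ten_labels):
        raise ValueError("ten_labels and ter_tags must be aligned")
    spans: list[EntitySpan] = []
    start = None
    current = OUTSIDE
    for i, lab in enumerate(ten_labels):
        boundary = lab != current or (ter_tags is not None and ter_tags[i] == "B")
        if start is not None and boundary:
            spans.append(EntitySpan(sentence_id, current, start, i))
            start = None
        if lab != OUTSIDE and (start is None or boundary):
            start = i
        current = lab
    if start is not None:
        spans.append(EntitySpan(sentence_id, current, start, len(ten_labels)))
    return spans


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class MetricsReport:
    """Exact-match micro-averaged counts and derived scores."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "MetricsReport":
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        return cls(tp, fp, fn, p, r, f1_score(p, r))

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def prf(gold: Iterable[EntitySpan], pred: Iterable[EntitySpan]) -> MetricsReport:
    """Exact-match micro P/R/F1: a hit requires identical
    (sentence_id, label, start, end)."""
    gold_list, pred_list = list(gold), list(pred)
    gold_set, pred_set = set(gold_list), set(pred_list)
    if len(pred_set) != len(pred_list):
        warnings.warn("duplicate identical predicted spans counted once", stacklevel=2)
    if len(gold_set) != len(gold_list):
        warnings.warn("duplicate identical gold spans counted once", stacklevel=2)
    tp = len(gold_set & pred_set)
    return MetricsReport.from_counts(tp, len(pred_set) - tp, len(gold_set) - tp)


@dataclass
class AggregateReport:
    """Per-run metrics plus mean ± std over repeated runs."""

    runs: list[MetricsReport]
    mean: dict[str, float] = field(init=False)
    std: dict[str, float] | None = field(init=False)

    def __post_init__(self) -> None:
        keys = ("precision", "recall", "f1")
        n = len(self.runs)
        if n == 0:
            raise ValueError("no runs to aggregate")
        self.mean = {k: sum(getattr(r, k) for r in self.runs) / n for k in keys}
        if n == 1:
            self.std = None
        else:
            self.std = {
                k: math.sqrt(
                    sum((getattr(r, k) - self.mean[k]) ** 2 for r in self.runs) / (n - 1)
                )
                for k in keys
            }

    def format_cell(self, key: str = "f1", digits: int = 4) -> str:
        """Render like a results-table cell, e.g. ``0.9535±0.0094``."""
        m = f"{self.mean[key]:.{digits}f}"
        if self.std is None:
            return m
        return f"{m}±{self.std[key]:.{digits}f}"

    def as_dict(self) -> dict:
        first = self.runs[0]
        out = first.as_dict()
        out["runs"] = [r.as_dict() for r in self.runs]
        out["mean"] = self.mean
        if self.std is not None:
            out["std"] = self.std
        return out

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.as_dict(), indent=2) + "\n", encoding="utf-8")
        return path


def read_spans_jsonl(path: str | Path) -> list[EntitySpan]:
    """Read spans from JSONL lines of {sentence_id, label, start, end}.

    Prediction files may carry extra keys (ten_labels, viterbi_score ...);
    a line with a ``spans`` list contributes every span in it.
    """
    spans: list[EntitySpan] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if "spans" in rec:
                for s in rec["spans"]:
                    spans.append(EntitySpan(rec["sentence_id"], s["label"], s["start"], s["end"]))
            else:
                spans.append(
                    EntitySpan(rec["sentence_id"], rec.get("label", rec.get("regimen")), rec["start"], rec["end"])
                )
    return spans


def sentence_ids(spans: Iterable[EntitySpan]) -> set[str]:
    return {s.sentence_id for s in spans}


def evaluate_predictions(
    pred_runs: Sequence[Sequence[EntitySpan]],
    gold: Sequence[EntitySpan],
    covered_ids: Sequence[set[str]] | None = None,
) -> AggregateReport:
    """Score each run against the gold spans and aggregate.

    ``covered_ids``, when given, holds the full sentence set each run
    predicted over (spans alone cannot witness all-"O" sentences); runs
    must cover identical sentence sets.
    """
    if covered_ids is not None:
        ref = covered_ids[0]
        for i, ids in enumerate(covered_ids[1:], start=2):
            if ids != ref:
                missing = sorted((ref ^ ids))[:10]
                raise ValueError(f"run {i} covers a different sentence set; e.g. {missing}")
    return AggregateReport([prf(gold, run) for run in pred_runs])
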