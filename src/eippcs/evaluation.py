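"""Evaluation measures and post-hoc analyses.

Covers confusion accounting, recall, two precision conventions, Cohen's
kappa for inter-annotator agreement, method-overlap counting over true
positives, PT frequency profiling of retrieved sets, and differential
n-gram mining of false-positive pools.

Two precision variants are reported side by side and never silently
merged:

* ``precision_testset`` — tp / (tp + fp) inside the annotated universe
  (textbook positive predictive value);
* ``precision_paper`` — confirmed test-set true positives divided by the
  method's *total* retrieval from the full corpus. Published
  surveillance-comparison studies quote this ratio (e.g. 37/1104,
  38/2042, 33/2019); it understates PPV because its numerator is
  restricted to the annotated sample.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus_model import AnnotationSet, CorpusError, ICSRRecord, MedDRAHierarchy, MethodResult
from .meddra import PTFilterSpec, record_pt_names
from .text_engine import Sentence, segment_sentences

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "TermDiffRow",
    "UndefinedMetricError",
    "confusion",
    "recall",
    "precision_testset",
    "precision_paper",
    "cohens_kappa",
    "overlap_analysis",
    "pt_frequency",
    "ngram_counts",
    "fp_only_terms",
    "combine_term_diffs",
    "percent_round",
    "percent_trunc",
    "evaluate_method",
]

COMPOSITE_KEY = "Composite PTs"


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (e.g. recall with no gold positives)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise CorpusError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Per-method metrics; proportions kept at full precision."""

    method_name: str
    counts: ConfusionCounts
    retrieved_total: int
    recall: float
    precision_testset: float
    precision_paper: float | None

    def __post_init__(self) -> None:
        for value in (self.recall, self.precision_testset):
            if not 0.0 <= value <= 1.0:
                raise CorpusError(f"proportion out of [0,1]: {value}")
        if self.precision_paper is not None and not 0.0 <= self.precision_paper <= 1.0:
            raise CorpusError(f"proportion out of [0,1]: {self.precision_paper}")


@dataclass(frozen=True)
class TermDiffRow:
    """One FP-only n-gram with per-method counts; None marks absence."""

    term: str
    counts: Mapping[str, int | None]


def percent_round(p: float, decimals: int = 1) -> float:
    """Proportion -> percentage, half-up at ``decimals`` (88.095% -> 88.1)."""
    scale = 10 ** decimals
    return math.floor(p * 100 * scale + 0.5) / scale


def percent_trunc(p: float, decimals: int = 1) -> float:
    """Proportion -> percentage, truncated at ``decimals`` (90.476% -> 90.4).

    Both renderings exist because published one-decimal figures mix the
    two conventions; reports emit full precision plus both renderings.
    """
    scale = 10 ** decimals
    return math.floor(p * 100 * scale) / scale


def confusion(
    result: MethodResult, annotations: AnnotationSet, universe: Iterable[str]
) -> ConfusionCounts:
    """TP/FP/FN/TN of a retrieval against gold labels over ``universe``.

    Every id of the universe must be annotated; counts sum to |universe|.
    """
    universe = frozenset(universe)
    missing = universe - annotations.ids
    if missing:
        raise CorpusError(f"unannotated ids in universe: {sorted(missing)[:5]}")
    positives = annotations.positives & universe
    retrieved = result.retrieved_ids & universe
    tp = len(retrieved & positives)
    fp = len(retrieved - positives)
    fn = len(positives - retrieved)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def recall(c: ConfusionCounts) -> float:
    """Sensitivity: tp / (tp + fn)."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no gold positives")
    return c.tp / (c.tp + c.fn)


def precision_testset(c: ConfusionCounts) -> float:
    """Textbook PPV within the annotated universe: tp / (tp + fp)."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: nothing retrieved")
    return c.tp / (c.tp + c.fp)


def precision_paper(tp: int, retrieved_total: int) -> float:
    """Test-set TPs over the method's total retrieval from the full corpus."""
    if retrieved_total <= 0:
        raise UndefinedMetricError("precision undefined: retrieved_total is 0")
    if tp > retrieved_total or tp < 0:
        raise CorpusError("tp must satisfy 0 <= tp <= retrieved_total")
    return tp / retrieved_total


def cohens_kappa(labels_a: AnnotationSet, labels_b: AnnotationSet) -> float:
    """Chance-corrected agreement between two annotators on the same ids.

    kappa = (p_o - p_e) / (1 - p_e), with p_e from the marginal label
    frequencies of each annotator. The degenerate case p_e = 1 (both
    annotators constant with the same label) returns 1.0.
    """
    if labels_a.ids != labels_b.ids or not labels_a.ids:
        raise CorpusError("kappa requires identical non-empty id sets")
    n = len(labels_a)
    ids = sorted(labels_a.ids)
    a = [labels_a.labels[i] for i in ids]
    b = [labels_b.labels[i] for i in ids]
    p_o = sum(x == y for x, y in zip(a, b)) / n
    classes = set(a) | set(b)
    p_e = sum(
        (a.count(c) / n) * (b.count(c) / n) for c in classes
    )
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def overlap_analysis(
    results: Sequence[MethodResult], positives: Iterable[str]
) -> dict[tuple[str, ...], int]:
    """True positives captured by exactly each method subset.

    Keys are sorted method-name tuples over all 2^k - 1 non-empty subsets
    plus the empty tuple () for positives no method captured; values sum
    to |positives|.
    """
    if len(results) < 2:
        raise CorpusError("overlap analysis requires >= 2 method results")
    names = [r.method_name for r in results]
    if len(set(names)) != len(names):
        raise CorpusError("method names must be distinct")
    counts: dict[tuple[str, ...], int] = {}
    # pre-fill every region so absent regions read as 0
    for mask in range(2 ** len(names)):
        key = tuple(sorted(names[i] for i in range(len(names)) if mask >> i & 1))
        counts[key] = 0
    for pid in set(positives):
        key = tuple(sorted(r.method_name for r in results if pid in r.retrieved_ids))
        counts[key] += 1
    return counts


def pt_frequency(
    ids: Iterable[str],
    corpus: Sequence[ICSRRecord],
    pt_spec: PTFilterSpec,
    hierarchy: MedDRAHierarchy,
    group_threshold: int = 10,
) -> dict[str, int]:
    """Which spec PTs captured the given records.

    A record matching exactly one spec PT counts under that PT; a record
    matching more than one counts once under "Composite PTs"; PTs whose
    individual count falls below ``group_threshold`` are merged into a
    "PTs < N" bucket. Records carrying no spec PT are not counted.
    """
    ids = frozenset(ids)
    per_pt: Counter[str] = Counter()
    composite = 0
    for record in corpus:
        if record.id not in ids:
            continue
        matched = sorted(
            n for n in record_pt_names(record, hierarchy) if pt_spec.matches(n)
        )
        if not matched:
            continue
        if len(matched) > 1:
            composite += 1
        else:
            per_pt[matched[0]] += 1
    table: dict[str, int] = {}
    grouped = 0
    for pt, count in per_pt.most_common():
        if count < group_threshold:
            grouped += count
        else:
            table[pt] = count
    if composite:
        table[COMPOSITE_KEY] = composite
    if grouped:
        table[f"PTs < {group_threshold}"] = grouped
    return table


def _sentences_of_texts(texts: Iterable[str]) -> list[Sentence]:
    sentences: list[Sentence] = []
    for i, text in enumerate(texts):
        sentences.extend(segment_sentences(text, record_id=str(i)))
    return sentences


def ngram_counts(texts: Iterable[str], max_n: int = 5) -> Counter[str]:
    """Occurrence counts of word n-grams (1..max_n) within sentences.

    Uses the shared tokenizer/segmenter, case-folded; n-grams never cross
    sentence boundaries. Stop-words are kept: published FP-only term
    lists contain function-word-bearing phrases.
    """
    counts: Counter[str] = Counter()
    for sentence in _sentences_of_texts(texts):
        folded = sentence.folded_tokens()
        for n in range(1, max_n + 1):
            for i in range(len(folded) - n + 1):
                counts[" ".join(folded[i:i + n])] += 1
    return counts


def fp_only_terms(
    fp_texts: Iterable[str],
    tp_texts: Iterable[str],
    max_n: int = 5,
    top_k: int = 25,
) -> list[tuple[str, int]]:
    """N-grams present in the FP pool and absent from the TP pool.

    Ranked by descending FP count, ties broken lexicographically,
    truncated to ``top_k``.
    """
    fp_counts = ngram_counts(fp_texts, max_n)
    tp_counts = ngram_counts(tp_texts, max_n)
    only = [(term, cnt) for term, cnt in fp_counts.items() if term not in tp_counts]
    only.sort(key=lambda item: (-item[1], item[0]))
    return only[:top_k]


def combine_term_diffs(
    per_method: Mapping[str, Sequence[tuple[str, int]]]
) -> list[TermDiffRow]:
    """Merge per-method FP-only term lists into one table.

    Terms present in several methods share a row; a method where the term
    was not found gets None (rendered '-'). Rows are ordered by the count
    in the first method when present, then by the remaining methods'
    counts, mirroring the published layout.
    """
    methods = list(per_method)
    by_term: dict[str, dict[str, int]] = {}
    for method, terms in per_method.items():
        for term, count in terms:
            by_term.setdefault(term, {})[method] = count

    def sort_key(term: str) -> tuple:
        counts = by_term[term]
        return tuple(
            -(counts.get(m) if counts.get(m) is not None else -1) for m in methods
        ) + (term,)

    rows = []
    for term in sorted(by_term, key=sort_key):
        rows.append(
            TermDiffRow(term, {m: by_term[term].get(m) for m in methods})
        )
    return rows


def evaluate_method(
    result: MethodResult,
    annotations: AnnotationSet,
    universe: Iterable[str],
    retrieved_total: int | None = None,
) -> MetricsReport:
    """Full metrics for one method.

    ``retrieved_total`` is the method's retrieval count from the *full*
    corpus (the denominator of the survey-style precision); when
    omitted, the method's total retrieved set size is used.
    """
    counts = confusion(result, annotations, universe)
    total = len(result.retrieved_ids) if retrieved_total is None else retrieved_total
    return MetricsReport(
        method_name=result.method_name,
        counts=counts,
        retrieved_total=total,
        recall=recall(counts),
        precision_testset=precision_testset(counts) if counts.tp + counts.fp else 0.0,
        precision_paper=precision_paper(counts.tp, total) if total else None,
    )
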