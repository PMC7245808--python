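"""The three EIPPCS detection methods.

* ``run_ssa`` — the traditional safety-surveillance cascade: a narrative
  keyword filter ("syringe", token-prefix match so "syringes" counts)
  followed by a curated 12-PT code filter.
* ``run_cpr`` — an NER-tagger pipeline: section isolation, dictionary
  tagging (anchor / EIPPCS cues / products), negative filters (negation
  cues, inhaled-insulin context, "prefilled" immediately before the
  anchor) and finally a same-sentence <= 8-word proximity requirement
  between anchor and cue.
* ``run_i2e`` — a configurable sentence-scope rule cascade; the shipped
  default ruleset requires the anchor, an action-verb co-occurrence and a
  product mention, and excludes inhaled-insulin reports.

Each detector returns a :class:`~eippcs.corpus_model.MethodResult` whose
trace records, per record, the ordered rule decisions — so every miss can
be attributed to the exact rule that dropped it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus_model import (
    CorpusError,
    ICSRRecord,
    Lexicon,
    MedDRAHierarchy,
    MethodResult,
    fold,
)
from .meddra import PTFilterSpec, record_pt_names
from .text_engine import (
    Sentence,
    TagSpan,
    proximity_match,
    sentences_of_record,
    tag,
    tokenize_words,
)

__all__ = [
    "PatternRule",
    "RuleSet",
    "run_ssa",
    "run_cpr",
    "run_i2e",
    "default_i2e_ruleset",
    "DEFAULT_EXCLUDED_SECTIONS",
]

#: Section-name patterns the CPR pipeline drops before any tagging:
#: sections describing subsequent physical/chemical analyses of returned
#: product, not consumer mishandling.
DEFAULT_EXCLUDED_SECTIONS = frozenset({"analysis"})

_RULE_KINDS = (
    "require_phrase_in_sentence",
    "require_cooccurrence",
    "require_product_mention",
    "exclude_phrase",
    "exclude_section",
)
_INCLUDE_KINDS = frozenset(
    {"require_phrase_in_sentence", "require_cooccurrence", "require_product_mention"}
)


@dataclass(frozen=True)
class PatternRule:
    """One sentence-scope pattern rule of a rule cascade."""

    rule_id: str
    kind: str
    lexicons: tuple[Lexicon, ...] = ()
    max_gap: int | None = None
    section_patterns: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in _RULE_KINDS:
            raise CorpusError(f"rule {self.rule_id!r}: unknown kind {self.kind!r}")
        needs = {"require_cooccurrence": 2}.get(self.kind)
        if needs is not None and len(self.lexicons) != needs:
            raise CorpusError(f"rule {self.rule_id!r}: needs {needs} lexicons")
        if self.kind in ("require_phrase_in_sentence", "require_product_mention",
                         "exclude_phrase") and len(self.lexicons) != 1:
            raise CorpusError(f"rule {self.rule_id!r}: needs exactly 1 lexicon")
        if self.kind == "exclude_section" and not self.section_patterns:
            raise CorpusError(f"rule {self.rule_id!r}: needs section patterns")


@dataclass(frozen=True)
class RuleSet:
    """Ordered rules; all include-rules must pass AND no exclude-rule may fire."""

    rules: tuple[PatternRule, ...]

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise CorpusError("duplicate rule_id in ruleset")
        if not any(r.kind in _INCLUDE_KINDS for r in self.rules):
            raise CorpusError("ruleset needs at least one include-kind rule")

    @property
    def excluded_sections(self) -> frozenset[str]:
        patterns: set[str] = set()
        for rule in self.rules:
            if rule.kind == "exclude_section":
                patterns |= rule.section_patterns
        return frozenset(patterns)


# ---------------------------------------------------------------------------
# SSA


def run_ssa(
    corpus: Sequence[ICSRRecord],
    hierarchy: MedDRAHierarchy,
    pt_spec: PTFilterSpec,
    keyword: str = "syringe",
    prefix_match: bool = True,
) -> MethodResult:
    """Keyword filter over raw narratives, then the curated PT filter.

    With ``prefix_match`` (default) a token counts if its folded form
    starts with the keyword, so "syringes" matches "syringe"; the
    exact-token alternative is available as a config switch.
    """
    folded_kw = fold(keyword)
    retrieved: set[str] = set()
    trace: dict[str, tuple[tuple[str, str], ...]] = {}
    for record in corpus:
        steps: list[tuple[str, str]] = []
        tokens = tokenize_words(record.full_text)
        if prefix_match:
            hit = any(t.folded.startswith(folded_kw) for t in tokens)
        else:
            hit = any(t.folded == folded_kw for t in tokens)
        if not hit:
            steps.append(("ssa_keyword_filter", "exclude"))
            trace[record.id] = tuple(steps)
            continue
        steps.append(("ssa_keyword_filter", "pass"))
        names = record_pt_names(record, hierarchy)
        if any(pt_spec.matches(n) for n in names):
            steps.append(("ssa_pt_filter", "include"))
            retrieved.add(record.id)
        else:
            steps.append(("ssa_pt_filter", "exclude"))
        trace[record.id] = tuple(steps)
    return MethodResult("ssa", frozenset(retrieved), trace)


# ---------------------------------------------------------------------------
# CPR


def _spans_by_sentence(spans: Iterable[TagSpan]) -> set[tuple[str, str, int]]:
    return {span.sentence_key for span in spans}


def run_cpr(
    corpus: Sequence[ICSRRecord],
    lexicons: Mapping[str, Lexicon],
    max_gap: int = 8,
    exclude_sections: Iterable[str] = DEFAULT_EXCLUDED_SECTIONS,
) -> MethodResult:
    """The NER/proximity pipeline.

    Rule ids (used by the miss-attribution bookkeeping):

    * ``cpr_rule_2`` — section isolation: a record whose retained sections
      hold no text is dropped here.
    * ``cpr_rule_1`` — anchor ("syringe(s)") must be tagged somewhere in
      the retained text.
    * ``cpr_rule_3`` — negation cue sharing a sentence with an anchor or
      cue span disqualifies the record.
    * ``cpr_rule_4`` — context exclusions: inhaled-insulin vocabulary
      anywhere in retained text, or "prefilled" as the token immediately
      preceding an anchor.
    * ``cpr_rule_5`` — anchor and EIPPCS cue within ``max_gap`` words in
      the same sentence.

    ``lexicons`` must supply keys anchor, positive, product, negation,
    exclusion. Product spans are tagged for the trace/term-mining layers
    but do not gate retrieval.
    """
    for key in ("anchor", "positive", "product", "negation", "exclusion"):
        if key not in lexicons:
            raise CorpusError(f"run_cpr: missing lexicon {key!r}")
    exclude_sections = frozenset(exclude_sections)
    retrieved: set[str] = set()
    trace: dict[str, tuple[tuple[str, str], ...]] = {}

    for record in corpus:
        steps: list[tuple[str, str]] = []
        sentences = sentences_of_record(record, exclude_sections)
        if not sentences:
            steps.append(("cpr_rule_2", "exclude"))
            trace[record.id] = tuple(steps)
            continue
        steps.append(("cpr_rule_2", "pass"))

        anchor_spans = tag(sentences, lexicons["anchor"])
        positive_spans = tag(sentences, lexicons["positive"])
        negation_spans = tag(sentences, lexicons["negation"])
        exclusion_spans = tag(sentences, lexicons["exclusion"])
        tag(sentences, lexicons["product"])  # tagged for bookkeeping only

        if not anchor_spans:
            steps.append(("cpr_rule_1", "exclude"))
            trace[record.id] = tuple(steps)
            continue
        steps.append(("cpr_rule_1", "pass"))

        flagged = _spans_by_sentence(anchor_spans) | _spans_by_sentence(positive_spans)
        if any(span.sentence_key in flagged for span in negation_spans):
            steps.append(("cpr_rule_3", "exclude"))
            trace[record.id] = tuple(steps)
            continue
        steps.append(("cpr_rule_3", "pass"))

        sentence_by_key = {
            (s.record_id, s.section_name, s.index): s for s in sentences
        }
        prefilled = False
        for span in anchor_spans:
            if span.token_start == 0:
                continue
            sentence = sentence_by_key[span.sentence_key]
            if sentence.tokens[span.token_start - 1].folded == "prefilled":
                prefilled = True
                break
        if exclusion_spans or prefilled:
            steps.append(("cpr_rule_4", "exclude"))
            trace[record.id] = tuple(steps)
            continue
        steps.append(("cpr_rule_4", "pass"))

        if proximity_match(anchor_spans, positive_spans, max_gap):
            steps.append(("cpr_rule_5", "include"))
            retrieved.add(record.id)
        else:
            steps.append(("cpr_rule_5", "exclude"))
        trace[record.id] = tuple(steps)

    return MethodResult("cpr", frozenset(retrieved), trace)


# ---------------------------------------------------------------------------
# I2E


def _rule_fires(
    rule: PatternRule, record: ICSRRecord, sentences: Sequence[Sentence]
) -> bool:
    """Whether the rule's pattern is present (meaning depends on kind)."""
    if rule.kind == "require_phrase_in_sentence" or rule.kind == "exclude_phrase":
        return bool(tag(sentences, rule.lexicons[0]))
    if rule.kind == "require_cooccurrence":
        spans_a = tag(sentences, rule.lexicons[0])
        spans_b = tag(sentences, rule.lexicons[1])
        if rule.max_gap is not None:
            return bool(proximity_match(spans_a, spans_b, rule.max_gap))
        keys_b = _spans_by_sentence(spans_b)
        return any(s.sentence_key in keys_b for s in spans_a)
    if rule.kind == "require_product_mention":
        if tag(sentences, rule.lexicons[0]):
            return True
        # structured product list: full product name, case-folded, must be
        # a phrase of the lexicon (after identical tokenization)
        phrases = rule.lexicons[0].phrase_set
        for product in record.products:
            toks = tuple(t.folded for t in tokenize_words(product))
            if toks in phrases:
                return True
        return False
    raise CorpusError(f"rule {rule.rule_id!r}: kind {rule.kind!r} not evaluable here")


def run_i2e(corpus: Sequence[ICSRRecord], ruleset: RuleSet) -> MethodResult:
    """Evaluate a rule cascade at sentence scope over each record.

    A record is retrieved iff every include rule passes on its retained
    text and no exclude rule fires. By default the cascade operates on the
    raw narrative (all sections); ``exclude_section`` rules restrict it.
    """
    excluded = ruleset.excluded_sections
    retrieved: set[str] = set()
    trace: dict[str, tuple[tuple[str, str], ...]] = {}
    for record in corpus:
        sentences = sentences_of_record(record, excluded)
        steps: list[tuple[str, str]] = []
        ok = True
        for rule in ruleset.rules:
            if rule.kind == "exclude_section":
                steps.append((rule.rule_id, "pass"))
                continue
            fired = _rule_fires(rule, record, sentences)
            if rule.kind == "exclude_phrase":
                if fired:
                    steps.append((rule.rule_id, "exclude"))
                    ok = False
                    break
                steps.append((rule.rule_id, "pass"))
            else:
                if not fired:
                    steps.append((rule.rule_id, "exclude"))
                    ok = False
                    break
                steps.append((rule.rule_id, "pass"))
        if ok:
            steps.append(("i2e_accept", "include"))
            retrieved.add(record.id)
        trace[record.id] = tuple(steps)
    return MethodResult("i2e", frozenset(retrieved), trace)


def default_i2e_ruleset(
    anchor: Lexicon,
    verbs: Lexicon,
    products: Lexicon,
    exclusion: Lexicon,
) -> RuleSet:
    """The shipped default rule cascade (a documented reconstruction).

    rule 1: anchor present; rule 2: product mention (text or structured
    product list); rule 3: no inhaled-insulin vocabulary; rule 4: an
    action verb in the same sentence as the anchor.
    """
    return RuleSet(
        rules=(
            PatternRule("i2e_rule_1", "require_phrase_in_sentence", (anchor,)),
            PatternRule("i2e_rule_2", "require_product_mention", (products,)),
            PatternRule("i2e_rule_3", "exclude_phrase", (exclusion,)),
            PatternRule("i2e_rule_4", "require_cooccurrence", (anchor, verbs)),
        )
    )
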