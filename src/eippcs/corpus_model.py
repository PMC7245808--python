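"""Domain types and file I/O for ICSR corpora, MedDRA mock hierarchies,
lexicons, gold annotations and detector results.

An ICSR (individual case safety report) is a single adverse-event report:
an opaque identifier, a free-text narrative split into named sections, a
set of MedDRA preferred-term (PT) codes, a product list and a source tag.
Corpora are stored as JSONL (one record per line); the mock PT->HLGT
hierarchy as TSV; lexicons as plain text (one phrase per line, ``#``
comments); annotations as a two-column CSV.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SOURCES",
    "LEXICON_ROLES",
    "ICSRRecord",
    "MedDRAHierarchy",
    "Lexicon",
    "AnnotationSet",
    "MethodResult",
    "CorpusError",
    "normalize_text",
    "fold",
    "read_corpus",
    "write_corpus",
    "read_hierarchy",
    "write_hierarchy",
    "read_lexicon",
    "write_lexicon",
    "read_annotations",
    "write_annotations",
    "write_method_result",
]

SOURCES = ("spontaneous", "solicited", "literature", "clinical_trial", "unknown")
LEXICON_ROLES = ("positive", "product", "anchor", "negation", "exclusion")

#: labels used by gold annotations
POSITIVE_LABEL = "EIPPCS"
NEGATIVE_LABEL = "non_EIPPCS"

_TRADEMARK_GLYPHS = str.maketrans("", "", "®™")  # (R) and TM


class CorpusError(ValueError):
    """Malformed or invariant-violating corpus/hierarchy/lexicon input."""


def normalize_text(text: str) -> str:
    """Canonicalise narrative text: Unicode NFKC, trademark glyphs stripped.

    Rules match plain words while real narratives carry glyphs such as
    "NovoLog(R) FlexPen(R)"; normalising on ingest keeps every downstream
    component glyph-free.
    """
    # glyphs first: NFKC would otherwise expand (TM) into the letters "TM"
    return unicodedata.normalize("NFKC", text.translate(_TRADEMARK_GLYPHS))


def fold(text: str) -> str:
    """Case-fold after normalisation; the single folding used everywhere."""
    return normalize_text(text).casefold()


@dataclass(frozen=True)
class ICSRRecord:
    """One individual case safety report."""

    id: str
    sections: tuple[tuple[str, str], ...]  # ordered (name, text)
    pt_codes: frozenset[str]
    products: frozenset[str]
    source: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusError("record id must be non-empty")
        if not self.sections:
            raise CorpusError(f"record {self.id!r}: at least one section required")
        names = [name for name, _ in self.sections]
        if len(set(names)) != len(names):
            raise CorpusError(f"record {self.id!r}: duplicate section names")
        if self.source not in SOURCES:
            raise CorpusError(f"record {self.id!r}: unknown source {self.source!r}")

    @property
    def full_text(self) -> str:
        """All section texts joined; used by raw-narrative keyword search."""
        return "\n".join(text for _, text in self.sections)

    def to_json_obj(self) -> dict:
        return {
            "id": self.id,
            "sections": [{"name": n, "text": t} for n, t in self.sections],
            "pt_codes": sorted(self.pt_codes),
            "products": sorted(self.products),
            "source": self.source,
        }

    @classmethod
    def from_json_obj(cls, obj: Mapping) -> "ICSRRecord":
        return cls(
            id=str(obj["id"]),
            sections=tuple((s["name"], s["text"]) for s in obj["sections"]),
            pt_codes=frozenset(str(c) for c in obj.get("pt_codes", ())),
            products=frozenset(str(p) for p in obj.get("products", ())),
            source=obj.get("source", "unknown"),
        )


@dataclass(frozen=True)
class MedDRAHierarchy:
    """Single-path mock of the PT -> HLGT level of the MedDRA hierarchy.

    Every PT code maps to exactly one (pt_name, hlgt_name) pair. Name
    lookups are case-insensitive; codes are matched verbatim.
    """

    entries: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        by_name = {}
        for code, (pt_name, hlgt_name) in self.entries.items():
            if not pt_name or not hlgt_name:
                raise CorpusError(f"PT {code}: empty pt_name or hlgt_name")
            by_name[fold(pt_name)] = (code, hlgt_name)
        object.__setattr__(self, "_by_folded_name", by_name)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pt_code: str) -> bool:
        return pt_code in self.entries

    def pt_name(self, pt_code: str) -> str:
        return self.entries[pt_code][0]

    def hlgt_of_code(self, pt_code: str) -> str:
        return self.entries[pt_code][1]

    def hlgt_of_name(self, pt_name: str) -> str:
        return self._by_folded_name[fold(pt_name)][1]


@dataclass(frozen=True)
class Lexicon:
    """A named list of lowercased phrases (1-6 tokens) with a role.

    Phrases are stored as token tuples, case-folded, deduplicated
    preserving first occurrence.
    """

    name: str
    phrases: tuple[tuple[str, ...], ...]
    role: str

    def __post_init__(self) -> None:
        if self.role not in LEXICON_ROLES:
            raise CorpusError(f"lexicon {self.name!r}: unknown role {self.role!r}")
        if not self.phrases:
            raise CorpusError(f"lexicon {self.name!r}: empty lexicon")
        seen = set()
        for phrase in self.phrases:
            if not phrase or not (1 <= len(phrase) <= 6):
                raise CorpusError(
                    f"lexicon {self.name!r}: phrase length must be 1..6 tokens: {phrase!r}"
                )
            if any(tok != tok.casefold() for tok in phrase):
                raise CorpusError(f"lexicon {self.name!r}: phrase not case-folded: {phrase!r}")
            if phrase in seen:
                raise CorpusError(f"lexicon {self.name!r}: duplicate phrase {phrase!r}")
            seen.add(phrase)

    def __len__(self) -> int:
        return len(self.phrases)

    @property
    def max_len(self) -> int:
        return max(len(p) for p in self.phrases)

    @property
    def phrase_set(self) -> frozenset[tuple[str, ...]]:
        return frozenset(self.phrases)


@dataclass(frozen=True)
class AnnotationSet:
    """Gold labels: record id -> {EIPPCS, non_EIPPCS}."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", dict(self.labels))
        for rid, label in self.labels.items():
            if label not in (POSITIVE_LABEL, NEGATIVE_LABEL):
                raise CorpusError(f"record {rid!r}: unknown label {label!r}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def positives(self) -> frozenset[str]:
        return frozenset(r for r, l in self.labels.items() if l == POSITIVE_LABEL)

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.labels)


@dataclass(frozen=True)
class MethodResult:
    """A detector's retrieved-id set plus a per-record decision trace.

    The trace maps each examined record id to the ordered list of
    ``(rule_id, decision)`` steps, decision in {include, exclude, pass};
    every retrieved id's trace ends in an include decision.
    """

    method_name: str
    retrieved_ids: frozenset[str]
    trace: Mapping[str, tuple[tuple[str, str], ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trace", dict(self.trace))
        for rid in self.retrieved_ids:
            steps = self.trace.get(rid)
            if not steps or steps[-1][1] != "include":
                raise CorpusError(
                    f"{self.method_name}: retrieved id {rid!r} lacks a trace "
                    "ending in an include decision"
                )
        for rid, steps in self.trace.items():
            for rule_id, decision in steps:
                if decision not in ("include", "exclude", "pass"):
                    raise CorpusError(
                        f"{self.method_name}: bad decision {decision!r} for {rid!r}"
                    )

    def last_step(self, rid: str) -> tuple[str, str]:
        return self.trace[rid][-1]


# ---------------------------------------------------------------------------
# File I/O


def read_corpus(path: str | Path) -> list[ICSRRecord]:
    """Read a JSONL corpus; rejects duplicate ids, names bad line numbers."""
    records: list[ICSRRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                record = ICSRRecord.from_json_obj(obj)
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise CorpusError(f"{path}: malformed record on line {lineno}: {exc}") from exc
            if record.id in seen:
                raise CorpusError(f"{path}: duplicate record id {record.id!r} on line {lineno}")
            seen.add(record.id)
            records.append(record)
    return records


def write_corpus(records: Iterable[ICSRRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for record in records:
            handle.write(json.dumps(record.to_json_obj(), ensure_ascii=False) + "\n")


def read_hierarchy(path: str | Path) -> MedDRAHierarchy:
    """Read the PT->HLGT mock hierarchy from TSV with a fixed header.

    Duplicate pt_code rows with conflicting targets are rejected;
    exact duplicate rows are tolerated.
    """
    entries: dict[str, tuple[str, str]] = {}
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"pt_code", "pt_name", "hlgt_name"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CorpusError(f"{path}: hierarchy needs columns {sorted(required)}")
        for row in reader:
            code = row["pt_code"].strip()
            target = (row["pt_name"].strip(), row["hlgt_name"].strip())
            if code in entries and entries[code] != target:
                raise CorpusError(f"{path}: conflicting rows for pt_code {code!r}")
            entries[code] = target
    return MedDRAHierarchy(entries)


def write_hierarchy(hierarchy: MedDRAHierarchy, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["pt_code", "pt_name", "hlgt_name"])
        for code in sorted(hierarchy.entries):
            pt_name, hlgt_name = hierarchy.entries[code]
            writer.writerow([code, pt_name, hlgt_name])


def read_lexicon(path: str | Path, name: str, role: str) -> Lexicon:
    """Read a plain-text lexicon (one phrase per line, ``#`` comments).

    Phrases are case-folded and tokenized with the same tokenizer used on
    narratives so dictionary entries and text always agree; duplicates are
    dropped preserving first occurrence. An effectively empty lexicon is a
    validation error — a detector with an empty positive dictionary is
    meaningless.
    """
    from .text_engine import tokenize_words  # deferred: avoids an import cycle

    phrases: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = tuple(tok.folded for tok in tokenize_words(line))
            if not tokens or tokens in seen:
                continue
            seen.add(tokens)
            phrases.append(tokens)
    if not phrases:
        raise CorpusError(f"{path}: lexicon {name!r} is empty after comments/dedup")
    return Lexicon(name=name, phrases=tuple(phrases), role=role)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"# lexicon: {lexicon.name} (role: {lexicon.role})\n")
        for phrase in lexicon.phrases:
            handle.write(" ".join(phrase) + "\n")


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read gold labels from CSV with header ``id,label``."""
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or not {"id", "label"}.issubset(reader.fieldnames):
            raise CorpusError(f"{path}: annotations need columns ['id', 'label']")
        for row in reader:
            rid = row["id"].strip()
            if rid in labels:
                raise CorpusError(f"{path}: id {rid!r} labelled more than once")
            labels[rid] = row["label"].strip()
    return AnnotationSet(labels)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["id", "label"])
        for rid in sorted(annotations.labels):
            writer.writerow([rid, annotations.labels[rid]])


def write_method_result(result: MethodResult, csv_path: str | Path,
                        trace_path: str | Path | None = None) -> None:
    """Serialize a MethodResult: summary CSV plus optional JSONL trace."""
    with open(csv_path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["id", "retrieved", "last_rule", "decision"])
        for rid in sorted(result.trace):
            rule_id, decision = result.last_step(rid)
            writer.writerow([rid, int(rid in result.retrieved_ids), rule_id, decision])
    if trace_path is not None:
        with open(trace_path, "w", encoding="utf-8") as handle:
            for rid in sorted(result.trace):
                obj = {
                    "id": rid,
                    "method": result.method_name,
                    "steps": [[r, d] for r, d in result.trace[rid]],
                }
                handle.write(json.dumps(obj) + "\n")
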