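"""MedDRA hierarchy collapsing and the two code-level filter cascades.

The annotation pipeline pre-filters a corpus to records coded under two
high level group terms (HLGTs) — *Device issues* and *Medication errors,
and other product use errors and issues* — then draws a 10% random sample
for manual annotation. The traditional surveillance (SSA) method uses a
curated set of 12 preferred terms (PTs) as its second filter.

Filters match on PT/HLGT *names*, case-insensitively with internal
whitespace collapsed; numeric codes are carried for bookkeeping only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .corpus_model import CorpusError, ICSRRecord, MedDRAHierarchy

__all__ = [
    "HLGTFilterSpec",
    "PTFilterSpec",
    "collapse_to_hlgt",
    "hlgt_filter",
    "pt_filter",
    "record_pt_names",
    "sample_fraction",
    "round_half_up",
]

logger = logging.getLogger(__name__)


def _canon(name: str) -> str:
    """Case-fold and collapse internal whitespace for name comparison."""
    return " ".join(name.casefold().split())


@dataclass(frozen=True)
class HLGTFilterSpec:
    """Set of HLGT names a record must intersect to pass the pre-filter."""

    hlgt_names: frozenset[str]

    def __post_init__(self) -> None:
        if not self.hlgt_names:
            raise CorpusError("HLGTFilterSpec requires at least one HLGT name")
        object.__setattr__(
            self, "_canon_names", frozenset(_canon(n) for n in self.hlgt_names)
        )

    def matches(self, hlgt_name: str) -> bool:
        return _canon(hlgt_name) in self._canon_names


@dataclass(frozen=True)
class PTFilterSpec:
    """Set of PT names (the SSA method's curated 12 by default)."""

    pt_names: frozenset[str]

    def __post_init__(self) -> None:
        if not self.pt_names:
            raise CorpusError("PTFilterSpec requires at least one PT name")
        object.__setattr__(
            self, "_canon_names", frozenset(_canon(n) for n in self.pt_names)
        )

    def matches(self, pt_name: str) -> bool:
        return _canon(pt_name) in self._canon_names


def collapse_to_hlgt(
    record: ICSRRecord, hierarchy: MedDRAHierarchy, strict: bool = False
) -> set[str]:
    """Collapse a record's PT codes to the set of distinct HLGT names.

    Unknown PT codes raise in strict mode; the lenient default skips and
    logs them (synthetic coding noise deliberately includes uncoded terms).
    """
    hlgts: set[str] = set()
    for code in record.pt_codes:
        if code in hierarchy:
            hlgts.add(hierarchy.hlgt_of_code(code))
        elif strict:
            raise CorpusError(f"record {record.id!r}: unknown PT code {code!r}")
        else:
            logger.debug("record %s: skipping unknown PT code %s", record.id, code)
    return hlgts


def hlgt_filter(
    corpus: Sequence[ICSRRecord],
    hierarchy: MedDRAHierarchy,
    spec: HLGTFilterSpec,
    strict: bool = False,
) -> list[ICSRRecord]:
    """Records whose collapsed HLGT set intersects the spec; order preserved."""
    return [
        record
        for record in corpus
        if any(spec.matches(h) for h in collapse_to_hlgt(record, hierarchy, strict))
    ]


def record_pt_names(
    record: ICSRRecord, hierarchy: MedDRAHierarchy, strict: bool = False
) -> set[str]:
    """PT names carried by a record, via hierarchy lookup of its codes."""
    names: set[str] = set()
    for code in record.pt_codes:
        if code in hierarchy:
            names.add(hierarchy.pt_name(code))
        elif strict:
            raise CorpusError(f"record {record.id!r}: unknown PT code {code!r}")
        else:
            logger.debug("record %s: skipping unknown PT code %s", record.id, code)
    return names


def pt_filter(
    corpus: Sequence[ICSRRecord],
    spec: PTFilterSpec,
    hierarchy: MedDRAHierarchy,
    strict: bool = False,
) -> list[ICSRRecord]:
    """Records carrying >= 1 PT whose name matches the spec (case-insensitive)."""
    return [
        record
        for record in corpus
        if any(spec.matches(n) for n in record_pt_names(record, hierarchy, strict))
    ]


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (0.5 -> 1).

    This is the convention under which a 10% sample of 25,328 records has
    size 2533, and 1.7% of 1000 synthetic records means 17 positives.
    """
    return int(math.floor(x + 0.5))


def sample_fraction(
    corpus: Sequence[ICSRRecord], fraction: float, seed: int
) -> list[ICSRRecord]:
    """Simple random sample without replacement of round(fraction * N) records.

    Deterministic for a given seed; uses an owned PCG64 stream so ambient
    global random state never leaks in. fraction must lie in (0, 1].
    """
    if not 0.0 < fraction <= 1.0:
        raise CorpusError(f"fraction must be in (0, 1], got {fraction}")
    n = len(corpus)
    k = round_half_up(fraction * n)
    rng = np.random.Generator(np.random.PCG64(seed))
    indices = rng.choice(n, size=k, replace=False) if n else np.array([], dtype=int)
    return [corpus[i] for i in indices]
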