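"""Packaged default vocabularies, filter specs and the mock hierarchy.

Every default ships as a plain-text fixture under ``eippcs/data`` and can
be overridden from the CLI by pointing at a replacement file of the same
format. The hierarchy here is an explicitly synthetic, single-path mock
of the PT -> HLGT level; the licensed MedDRA dictionary is out of scope.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .corpus_model import Lexicon, MedDRAHierarchy, read_hierarchy, read_lexicon
from .meddra import HLGTFilterSpec, PTFilterSpec

__all__ = [
    "data_path",
    "read_name_list",
    "default_hlgt_spec",
    "default_pt_spec",
    "default_hierarchy",
    "default_lexicon",
    "default_cpr_lexicons",
]

_DATA = resources.files("eippcs.data")

_LEXICON_ROLES = {
    "anchor": "anchor",
    "eippcs_dictionary": "positive",
    "products_cpr": "product",
    "products_i2e": "product",
    "action_verbs": "positive",
    "negation": "negation",
    "exclusion": "exclusion",
}


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    with resources.as_file(_DATA / name) as path:
        return Path(path)


def read_name_list(path: str | Path) -> list[str]:
    """Read verbatim names (HLGT/PT lists), one per line, '#' comments.

    Names are kept untokenized because HLGT names legitimately contain
    punctuation ("Medication errors, and other product use errors and
    issues"); spec matching canonicalises case and whitespace instead.
    """
    names: list[str] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return names


def default_hlgt_spec() -> HLGTFilterSpec:
    return HLGTFilterSpec(frozenset(read_name_list(data_path("hlgt_filter.txt"))))


def default_pt_spec() -> PTFilterSpec:
    return PTFilterSpec(frozenset(read_name_list(data_path("pt_filter.txt"))))


def default_hierarchy() -> MedDRAHierarchy:
    return read_hierarchy(data_path("mock_hierarchy.tsv"))


def default_lexicon(stem: str) -> Lexicon:
    """Load a packaged lexicon by file stem, e.g. ``default_lexicon("anchor")``."""
    role = _LEXICON_ROLES[stem]
    return read_lexicon(data_path(f"{stem}.txt"), name=stem, role=role)


def default_cpr_lexicons() -> dict[str, Lexicon]:
    """The five lexicons the CPR pipeline consumes, keyed by role-ish name."""
    return {
        "anchor": default_lexicon("anchor"),
        "positive": default_lexicon("eippcs_dictionary"),
        "product": default_lexicon("products_cpr"),
        "negation": default_lexicon("negation"),
        "exclusion": default_lexicon("exclusion"),
    }
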