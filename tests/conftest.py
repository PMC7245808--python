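"""Shared fixtures: default vocabularies, a tiny hand corpus, helpers."""

from __future__ import annotations

import pytest

from eippcs.corpus_model import ICSRRecord
from eippcs.defaults import (
    default_cpr_lexicons,
    default_hierarchy,
    default_hlgt_spec,
    default_lexicon,
    default_pt_spec,
)
from eippcs.detectors import default_i2e_ruleset


def make_record(
    rid: str,
    text: str | None = None,
    sections: tuple[tuple[str, str], ...] | None = None,
    pt_codes: set[str] = frozenset(),
    products: set[str] = frozenset(),
    source: str = "spontaneous",
) -> ICSRRecord:
    if sections is None:
        sections = (("narrative", text or ""),)
    return ICSRRecord(
        id=rid,
        sections=sections,
        pt_codes=frozenset(pt_codes),
        products=frozenset(products),
        source=source,
    )


@pytest.fixture(scope="session")
def hierarchy():
    return default_hierarchy()


@pytest.fixture(scope="session")
def pt_spec():
    return default_pt_spec()


@pytest.fixture(scope="session")
def hlgt_spec():
    return default_hlgt_spec()


@pytest.fixture(scope="session")
def cpr_lexicons():
    return default_cpr_lexicons()


@pytest.fixture(scope="session")
def i2e_ruleset():
    return default_i2e_ruleset(
        default_lexicon("anchor"),
        default_lexicon("action_verbs"),
        default_lexicon("products_i2e"),
        default_lexicon("exclusion"),
    )
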