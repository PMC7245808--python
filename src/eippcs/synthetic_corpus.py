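"""Deterministic generator of ICSR-like corpora with gold labels.

The real input to this kind of surveillance study — a manufacturer's
safety database — is proprietary, so the generator emulates the
structure the three detectors assume:

* ~1.7% prevalence of the sought error (extraction of insulin from a
  prefilled pen or cartridge by a syringe), the rate observed in
  annotated device/medication-error report samples;
* positive narratives phrased in the several root-cause styles seen in
  real case narratives (intentional mixing in one syringe, switching to
  a syringe after a pen fault, mistaken withdrawal from a pen), plus two
  *designed-miss* families: a cue-to-anchor word gap larger than the
  proximity window, and error wording confined to an "analysis results"
  section;
* false-positive drivers: prefilled-syringe product mentions, negated
  errors, inhaled-insulin trial reports, device-malfunction complaints
  mentioning a syringe in passing;
* PT coding correlated with the narrative's template family, perturbed
  by a configurable coding-noise rate that swaps in off-signal PTs
  (producing the "coded outside the curated PT list" miss mechanism).

Gold labels are assigned by template *semantics*, never by detector
behaviour, so detector imperfection stays measurable. Generation is
fully reproducible from the seed via an owned PCG64 stream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence
import warnings

import numpy as np

from .corpus_model import (
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    AnnotationSet,
    CorpusError,
    ICSRRecord,
)
from .meddra import round_half_up

__all__ = [
    "GeneratorConfig",
    "LabelledCorpus",
    "Template",
    "POSITIVE_TEMPLATES",
    "NEGATIVE_TEMPLATES",
    "designed_cpr_miss_fraction",
    "generate",
    "template_census",
]

#: Fictional pen/cartridge brands covered by both product dictionaries.
BRAND_POOL = ("GlarPen", "RapidFill", "MixoPen", "BasalFill")
#: FlexTouch-like brand: in the CPR product dictionary, deliberately
#: absent from the default I2E one.
UNCOVERED_BRAND = "DoseTouch"

# PT codes of the packaged mock hierarchy, by name, for template coding.
PT = {
    "Device failure": "10000001",
    "Device malfunction": "10000002",
    "Device use error": "10000003",
    "Device use issue": "10000004",
    "Device leakage": "10000006",
    "Drug administered in wrong device": "10000011",
    "Drug administration error": "10000012",
    "Intentional product misuse": "10000014",
    "Product use issue": "10000015",
    "Wrong technique in product usage process": "10000017",
    "Accidental overdose": "10000018",
    "Headache": "10000021",
    "Blood glucose increased": "10000022",
    "Hypoglycaemia": "10000023",
}

#: Off-signal PT sets used by coding noise: on passing the HLGT
#: pre-filter or not is template-independent, and none belong to the
#: curated 12-PT list, so a noised positive becomes an SSA miss.
_NOISE_PT_SETS = (
    frozenset({PT["Accidental overdose"]}),
    frozenset({PT["Headache"]}),
    frozenset({PT["Blood glucose increased"]}),
    frozenset({PT["Hypoglycaemia"]}),
)

_ANALYSIS_BOILERPLATE = (
    "The returned device was inspected and the product complaint could "
    "not be technically confirmed."
)


@dataclass(frozen=True)
class Template:
    """One narrative template: text builder plus coding/label semantics."""

    template_id: str
    family: str  # "positive" | "negative"
    weight: float
    build_sections: Callable[[np.random.Generator], tuple[tuple[str, str], ...]]
    pt_options: tuple[frozenset[str], ...]
    source: str = "spontaneous"
    cpr_designed_miss: bool = False
    i2e_designed_miss: bool = False
    products: Callable[[np.random.Generator], frozenset[str]] | None = None


def _brand(rng: np.random.Generator) -> str:
    return BRAND_POOL[int(rng.integers(len(BRAND_POOL)))]


def _two_brands(rng: np.random.Generator) -> tuple[str, str]:
    i, j = rng.choice(len(BRAND_POOL), size=2, replace=False)
    return BRAND_POOL[int(i)], BRAND_POOL[int(j)]


def _single(text_fn: Callable[[np.random.Generator], str]):
    def build(rng: np.random.Generator) -> tuple[tuple[str, str], ...]:
        return (("narrative", text_fn(rng)),)

    return build


# --- positive templates -----------------------------------------------------


def _pos_mix_text(rng: np.random.Generator) -> str:
    a, b = _two_brands(rng)
    return (
        f"It was reported that the patient had been using {a} and {b} for "
        f"the last 2 years. It was reported that {a} and {b} was "
        "intentionally mixed in the one syringe to minimise injections in "
        "paediatric patients."
    )


def _pos_pen_air_text(rng: np.random.Generator) -> str:
    return (
        "A patient experienced a pen with air inside and a bubble. She "
        "verified this problem as insulin was not coming out of the pen. "
        "For this reason the consumer is taking insulin with syringe."
    )


def _pos_withdrew_text(rng: np.random.Generator) -> str:
    p = _brand(rng)
    return (
        f"A man reported that he mistakenly withdrew insulin out of the {p} "
        f"with a regular syringe and then injected it back into the {p}."
    )


def _pos_gap_miss_text(rng: np.random.Generator) -> str:
    # the only cue ("mixed") sits far beyond the 8-word window from the anchor
    return (
        "The patient mixed the morning and evening insulin doses together "
        "after the pen failed to deliver a full dose and then used a spare "
        "syringe from the kit."
    )


def _pos_analysis_only(rng: np.random.Generator) -> tuple[tuple[str, str], ...]:
    return (
        (
            "narrative",
            "The patient reported dosing problems with the pen and the "
            "device was returned to the company.",
        ),
        (
            "analysis results",
            "Analysis of the returned product confirmed that the patient "
            "withdrew insulin from the cartridge with a syringe.",
        ),
    )


def _pos_dosetouch_text(rng: np.random.Generator) -> str:
    return (
        f"She extracted insulin from the {UNCOVERED_BRAND} using a syringe "
        "because the injector was damaged."
    )


def _pos_short_text(rng: np.random.Generator) -> str:
    p = _brand(rng)
    return (
        f"Patient drew up insulin from the {p} cartridge with an insulin "
        "syringe to continue treatment."
    )


POSITIVE_TEMPLATES: tuple[Template, ...] = (
    Template(
        "pos_mix", "positive", 0.20, _single(_pos_mix_text),
        (
            frozenset({PT["Intentional product misuse"]}),
            frozenset({PT["Wrong technique in product usage process"]}),
            frozenset({PT["Intentional product misuse"],
                       PT["Wrong technique in product usage process"]}),
        ),
    ),
    Template(
        "pos_pen_air", "positive", 0.15, _single(_pos_pen_air_text),
        (
            frozenset({PT["Wrong technique in product usage process"]}),
            frozenset({PT["Device malfunction"],
                       PT["Wrong technique in product usage process"]}),
        ),
    ),
    Template(
        "pos_withdrew", "positive", 0.20, _single(_pos_withdrew_text),
        (
            frozenset({PT["Drug administered in wrong device"]}),
            frozenset({PT["Drug administration error"]}),
        ),
    ),
    Template(
        "pos_gap_miss", "positive", 0.10, _single(_pos_gap_miss_text),
        (
            frozenset({PT["Wrong technique in product usage process"]}),
            frozenset({PT["Product use issue"]}),
        ),
        cpr_designed_miss=True,
    ),
    Template(
        "pos_analysis_only", "positive", 0.10, _pos_analysis_only,
        (
            frozenset({PT["Wrong technique in product usage process"]}),
            frozenset({PT["Drug administered in wrong device"]}),
        ),
        cpr_designed_miss=True,
    ),
    Template(
        "pos_dosetouch", "positive", 0.10, _single(_pos_dosetouch_text),
        (
            frozenset({PT["Drug administered in wrong device"]}),
            frozenset({PT["Drug administration error"]}),
        ),
        i2e_designed_miss=True,
        products=lambda rng: frozenset({UNCOVERED_BRAND}),
    ),
    Template(
        "pos_short", "positive", 0.15, _single(_pos_short_text),
        (
            frozenset({PT["Wrong technique in product usage process"]}),
            frozenset({PT["Device use error"]}),
        ),
    ),
)


# --- negative templates -----------------------------------------------------


def _neg_device_text(rng: np.random.Generator) -> str:
    p = _brand(rng)
    return (
        f"The patient reported that the {p} was leaking insulin and the "
        f"device failed to deliver the set dose. The {p} was returned to "
        "the manufacturer for investigation."
    )


def _neg_prefilled_text(rng: np.random.Generator) -> str:
    return (
        "The pharmacy dispensed prefilled syringes to the woman and she "
        "mixed the contents before use. She reported elevated blood "
        "glucose and changes while using the conventional insulin."
    )


def _neg_negated_text(rng: np.random.Generator) -> str:
    p = _brand(rng)
    return (
        f"The nurse asked whether insulin was drawn up from the {p} "
        "cartridge with a syringe but the patient denied this and never "
        "used a syringe at home."
    )


def _neg_inhaled_text(rng: np.random.Generator) -> str:
    return (
        "In the inhaled insulin clinical trial the subject used the "
        "inhaler before each meal. A syringe was provided by the site to "
        "collect blood samples."
    )


def _neg_elevated_text(rng: np.random.Generator) -> str:
    p = _brand(rng)
    return (
        f"A woman who was introduced to the {p} pen reported elevated "
        "blood glucose levels and changes in her daily activity. Her "
        "blood was monitored prior to the clinic visit."
    )


def _neg_vial_text(rng: np.random.Generator) -> str:
    # normal clinical practice, not a pen/cartridge extraction error: the
    # cue-near-anchor pattern makes this a designed text-mining FP driver
    return (
        "Insulin was drawn up from a vial with a syringe by the nurse "
        "during the hospital admission. The patient later resumed the "
        "usual pen treatment at home."
    )


def _neg_device_syringe_text(rng: np.random.Generator) -> str:
    p = _brand(rng)
    return (
        f"The {p} pen clicked but no dose was delivered and the patient "
        "reported a device malfunction. A conventional insulin syringe "
        "was mentioned by the pharmacist as an alternative while using "
        "the backup supply."
    )


NEGATIVE_TEMPLATES: tuple[Template, ...] = (
    Template(
        "neg_device_malfunction", "negative", 0.30, _single(_neg_device_text),
        (
            frozenset({PT["Device malfunction"]}),
            frozenset({PT["Device failure"]}),
            frozenset({PT["Device malfunction"], PT["Device failure"]}),
        ),
    ),
    Template(
        "neg_prefilled", "negative", 0.15, _single(_neg_prefilled_text),
        (
            frozenset({PT["Product use issue"]}),
            frozenset({PT["Blood glucose increased"]}),
            frozenset({PT["Product use issue"], PT["Blood glucose increased"]}),
        ),
        products=lambda rng: frozenset({_brand(rng)}),
    ),
    Template(
        "neg_negated", "negative", 0.10, _single(_neg_negated_text),
        (
            frozenset({PT["Device use error"]}),
            frozenset({PT["Drug administration error"]}),
        ),
    ),
    Template(
        "neg_inhaled", "negative", 0.10, _single(_neg_inhaled_text),
        (
            frozenset({PT["Blood glucose increased"]}),
            frozenset({PT["Hypoglycaemia"]}),
        ),
        source="clinical_trial",
        products=lambda rng: frozenset({_brand(rng)}),
    ),
    Template(
        "neg_vial", "negative", 0.08, _single(_neg_vial_text),
        (
            frozenset({PT["Drug administration error"]}),
            frozenset({PT["Product use issue"]}),
            frozenset({PT["Blood glucose increased"]}),
        ),
        source="solicited",
        products=lambda rng: frozenset({_brand(rng)}),
    ),
    Template(
        "neg_elevated", "negative", 0.17, _single(_neg_elevated_text),
        (
            frozenset({PT["Blood glucose increased"]}),
            frozenset({PT["Headache"]}),
            frozenset({PT["Hypoglycaemia"]}),
            frozenset({PT["Device leakage"]}),
        ),
    ),
    Template(
        "neg_device_syringe", "negative", 0.10, _single(_neg_device_syringe_text),
        (
            frozenset({PT["Device malfunction"]}),
            frozenset({PT["Device failure"]}),
        ),
    ),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one generated corpus.

    ``prevalence`` defaults to 0.017, the positive rate observed when a
    device/medication-error filtered sample of real reports was manually
    annotated. ``coding_noise`` is the chance a record's PT set is
    replaced by off-signal PTs; ``section_layout`` the chance of an extra
    "analysis results" boilerplate section.
    """

    n_records: int
    prevalence: float = 0.017
    seed: int = 0
    template_weights: Mapping[str, float] | None = None
    distractor_weights: Mapping[str, float] | None = None
    coding_noise: float = 0.05
    section_layout: float = 0.10

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise CorpusError("n_records must be positive")
        if not 0.0 <= self.prevalence <= 1.0:
            raise CorpusError("prevalence must be in [0, 1]")
        for name in ("coding_noise", "section_layout"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise CorpusError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class LabelledCorpus:
    """Generated records plus gold labels and per-record template provenance."""

    records: tuple[ICSRRecord, ...]
    annotations: AnnotationSet
    provenance: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "provenance", dict(self.provenance))
        for record in self.records:
            if record.id not in self.annotations.labels:
                raise CorpusError(f"record {record.id!r} lacks a gold label")


def _resolve_weights(
    templates: Sequence[Template], overrides: Mapping[str, float] | None
) -> list[float]:
    weights = []
    override = dict(overrides) if overrides else {}
    for template in templates:
        weights.append(float(override.pop(template.template_id, template.weight)))
    if override:
        raise CorpusError(f"unknown template ids in weights: {sorted(override)}")
    if any(w < 0 for w in weights):
        raise CorpusError("template weights must be non-negative")
    total = sum(weights)
    if total <= 0:
        raise CorpusError("template weights must not all be zero")
    return [w / total for w in weights]


def _allocate(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of ``total`` among ``weights``.

    Deterministic (ties broken by template order) so the per-template
    census — and hence the designed-miss fraction — is exact, not
    multinomial.
    """
    raw = [w * total for w in weights]
    counts = [int(x) for x in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def designed_cpr_miss_fraction(
    config: GeneratorConfig | None = None, n_positive: int | None = None
) -> float:
    """Exact fraction of positives drawn from designed CPR-miss templates.

    Computed from the deterministic allocation, so CPR recall on the
    generated corpus equals 1 minus this value in exact arithmetic.
    """
    config = config or GeneratorConfig(n_records=1000)
    if n_positive is None:
        n_positive = round_half_up(config.prevalence * config.n_records)
    weights = _resolve_weights(POSITIVE_TEMPLATES, config.template_weights)
    counts = _allocate(n_positive, weights)
    missed = sum(
        c for t, c in zip(POSITIVE_TEMPLATES, counts) if t.cpr_designed_miss
    )
    return missed / n_positive if n_positive else 0.0


def generate(config: GeneratorConfig) -> LabelledCorpus:
    """Generate a labelled corpus under ``config``; reproducible from seed."""
    rng = np.random.Generator(np.random.PCG64(config.seed))
    n_pos = round_half_up(config.prevalence * config.n_records)
    if config.prevalence > 0 and n_pos == 0:
        warnings.warn(
            "prevalence > 0 but positive count rounds to 0", stacklevel=2
        )
    n_neg = config.n_records - n_pos

    pos_weights = _resolve_weights(POSITIVE_TEMPLATES, config.template_weights)
    neg_weights = _resolve_weights(NEGATIVE_TEMPLATES, config.distractor_weights)

    plan: list[Template] = []
    for template, count in zip(POSITIVE_TEMPLATES, _allocate(n_pos, pos_weights)):
        plan.extend([template] * count)
    for template, count in zip(NEGATIVE_TEMPLATES, _allocate(n_neg, neg_weights)):
        plan.extend([template] * count)
    order = rng.permutation(len(plan))

    records: list[ICSRRecord] = []
    labels: dict[str, str] = {}
    provenance: dict[str, str] = {}
    for position, plan_index in enumerate(order, start=1):
        template = plan[int(plan_index)]
        rid = f"SYN-{position:06d}"
        sections = template.build_sections(rng)
        pt_codes = template.pt_options[int(rng.integers(len(template.pt_options)))]
        if rng.random() < config.coding_noise:
            pt_codes = _NOISE_PT_SETS[int(rng.integers(len(_NOISE_PT_SETS)))]
        has_analysis = any("analysis" in name.casefold() for name, _ in sections)
        if not has_analysis and rng.random() < config.section_layout:
            sections = sections + (("analysis results", _ANALYSIS_BOILERPLATE),)
        products = template.products(rng) if template.products else frozenset()
        records.append(
            ICSRRecord(
                id=rid,
                sections=sections,
                pt_codes=pt_codes,
                products=products,
                source=template.source,
            )
        )
        labels[rid] = POSITIVE_LABEL if template.family == "positive" else NEGATIVE_LABEL
        provenance[rid] = template.template_id

    return LabelledCorpus(tuple(records), AnnotationSet(labels), provenance)


def template_census(corpus: LabelledCorpus) -> dict[str, int]:
    """Counts of records per template id; sums to the corpus size."""
    return dict(Counter(corpus.provenance.values()))
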