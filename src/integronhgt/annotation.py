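"""Deterministic re-categorisation and filtering rules for cassette-protein
annotations.

Toxin–antitoxin (TA) components and transposases dominate cassette
annotation sets, so they are pulled out of the generic COG categories
into their own labels before any proportion testing.  The remaining
rules are plain filters: IS-family assignment by top alignment hit,
plant-growth-promoting-trait (PGPT) KO retention above model-specific
thresholds, effector calls by two-predictor consensus, and identity/
coverage cutoffs for homology filtering.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    AlignmentHit,
    AnnotationRecord,
    CATEGORY_FUNCTION_UNKNOWN,
    CATEGORY_TOXIN_ANTITOXIN,
    CATEGORY_TRANSPOSASES,
    CATEGORY_UNANNOTATED,
    COG_CATEGORY_NAMES,
    KoHit,
)

log = logging.getLogger(__name__)

#: Annotation-description terms that mark toxin–antitoxin system components.
#: Matched case-insensitively as plain substrings: fragments like "antitox"
#: are deliberate, and "toxin" itself covers e.g. "antitoxin" and "toxin
#: secretion" descriptions.
DEFAULT_TA_TERMS = (
    "toxin",
    "antitoxin",
    "addiction module",
    "plasmid maintenance system killer",
    "plasmid stabilization",
    "antidote",
    "TA system",
    "antitox",
    "post-segregation",
)

#: PGPT subclasses retained for plant-interaction screening.
DEFAULT_PGPT_SUBCLASSES = frozenset({
    "Bio-fertilization",
    "Stress_control|biocontrol",
    "Bio-remediation",
    "Phytohormone|plant_signal_production",
    "Plant_immune_response_stimulation",
    "Colonising_plant_system",
})


def recategorize_annotations(
    records: Iterable[AnnotationRecord],
    ta_terms: Sequence[str] = DEFAULT_TA_TERMS,
) -> list[AnnotationRecord]:
    """Assign each protein a single functional category.

    Precedence: transposase > toxin–antitoxin > first COG letter's
    standard name (COG S → "Function unknown") > "Unannotated".  A
    description matching both the transposase and a TA term keeps
    "Transposases" and logs a warning.  Idempotent.
    """
    terms = [t.lower() for t in ta_terms]
    out: list[AnnotationRecord] = []
    for rec in records:
        desc = rec.description.lower()
        is_ta = any(t in desc for t in terms)
        is_tnp = "transposase" in desc
        if is_tnp and is_ta:
            log.warning("protein %s matches both transposase and TA terms; "
                        "assigned Transposases", rec.protein_id)
        if is_tnp:
            cat = CATEGORY_TRANSPOSASES
        elif is_ta:
            cat = CATEGORY_TOXIN_ANTITOXIN
        elif rec.cog_categories:
            letter = rec.cog_categories[0]
            if len(rec.cog_categories) > 1:
                log.info("protein %s has COG letters %s; using first (%s)",
                         rec.protein_id, rec.cog_categories, letter)
            if letter == "S":
                cat = CATEGORY_FUNCTION_UNKNOWN
            else:
                cat = COG_CATEGORY_NAMES.get(letter, CATEGORY_FUNCTION_UNKNOWN)
        else:
            cat = CATEGORY_UNANNOTATED
        out.append(AnnotationRecord(rec.protein_id, rec.cog_categories,
                                    rec.description, cat))
    return out


def assign_is_family(
    hits: Iterable[AlignmentHit], queries: Iterable[str] | None = None
) -> dict[str, str]:
    """Per query, the insertion-sequence family of the maximum-bit-score
    hit; the subject id encodes the family (e.g. ``IS5_...``).

    Ties are broken by the lexicographically smallest subject id (logged).
    When ``queries`` lists the full query universe, queries without any
    hit are mapped to ``"unassigned"``.
    """
    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    result: dict[str, str] = {q: "unassigned" for q in (queries or ())}
    for query, qhits in by_query.items():
        best_score = max(h.bit_score for h in qhits)
        top = sorted(h.subject_id for h in qhits if h.bit_score == best_score)
        if len(top) > 1:
            log.warning("query %s: bit-score tie among %s; taking %s",
                        query, top, top[0])
        result[query] = _is_family_of(top[0])
    return result


def _is_family_of(subject_id: str) -> str:
    # Subject ids are either bare family names ("IS5") or family-prefixed
    # ("IS5_Psy123"); take the token before the first underscore.
    return subject_id.split("_", 1)[0]


def filter_pgpt_hits(
    hits: Iterable[KoHit],
    pgpt_kos: set[str],
    allowed_subclasses: frozenset[str] | set[str] = DEFAULT_PGPT_SUBCLASSES,
) -> list[KoHit]:
    """Retain KO assignments scoring strictly above the model-specific
    threshold, restricted to the PGPT KO list and allowed subclasses.

    Hits lacking a threshold are dropped with a log note.
    """
    retained = []
    for h in hits:
        if h.model_threshold is None:
            log.info("KO hit %s/%s has no model threshold; dropped",
                     h.protein_id, h.ko_id)
            continue
        if h.score > h.model_threshold and h.ko_id in pgpt_kos \
                and h.subclass in allowed_subclasses:
            retained.append(h)
    return retained


def effector_consensus(
    calls_a: Mapping[str, bool], calls_b: Mapping[str, bool]
) -> set[str]:
    """Proteins called effector by *both* predictors.

    A protein absent from either call table counts as a negative — only
    agreement in positive prediction makes an effector.
    """
    return {p for p, v in calls_a.items() if v and calls_b.get(p, False)}


def filter_alignment_hits(
    hits: Iterable[AlignmentHit], min_identity: float, min_cover: float
) -> list[AlignmentHit]:
    """Retain hits with identity and query cover at or above the cutoffs
    (e.g. 95/95 for integrase homology assignment)."""
    return [h for h in hits
            if h.percent_identity >= min_identity
            and h.percent_query_cover >= min_cover]


def summarize_categories(
    records: Sequence[AnnotationRecord],
    group_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Category counts and within-group proportions.

    ``group_labels`` maps protein_id → group (e.g. plant site).  Counts
    conserve the number of labelled records; proportions sum to 1 per
    non-empty group.
    """
    per_group: dict[str, Counter] = defaultdict(Counter)
    for rec in records:
        group = group_labels.get(rec.protein_id)
        if group is None:
            continue
        per_group[group][rec.assigned_category] += 1
    cats = sorted({c for ctr in per_group.values() for c in ctr})
    rows = []
    for group in sorted(set(group_labels.values())):
        ctr = per_group.get(group, Counter())
        total = sum(ctr.values())
        if total == 0:
            log.warning("group %r has no annotated records", group)
        for cat in cats:
            rows.append({
                "group": group,
                "category": cat,
                "count": ctr.get(cat, 0),
                "proportion": (ctr.get(cat, 0) / total) if total else 0.0,
            })
    return pd.DataFrame(rows, columns=["group", "category", "count", "proportion"])
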