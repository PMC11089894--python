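"""Cross-species horizontal gene-cassette transfer detection.

A transfer event is called when two cassettes from *different* species
share 100 % nucleotide identity over the full length of the shorter
sequence — i.e. the shorter sequence equals, or occurs as an exact
substring of, the longer one, on either strand.  Identical cassettes
within one species are excluded so that vertical transmission is never
mistaken for horizontal transfer.

Exact (sub)string matching is equivalent to an all-vs-all nucleotide
search filtered at 100 % identity and 100 % query cover, and is fully
deterministic.  The ambiguity code N never matches anything: a shorter
sequence containing N cannot achieve full-cover identity and is skipped.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .model import CassetteRecord, HGTEvent, reverse_complement

log = logging.getLogger(__name__)


def _match(shorter: str, longer: str) -> str | None:
    """Return the strand of ``longer`` on which ``shorter`` occurs exactly,
    or None.  Forward matches take precedence."""
    if "N" in shorter:
        return None  # N never matches: full-cover identity is impossible
    if shorter in longer:
        return "forward"
    if shorter in reverse_complement(longer):
        return "reverse_complement"
    return None


def find_identical_cassettes(records: Sequence[CassetteRecord]) -> list[HGTEvent]:
    """Call one HGT event per unordered cross-species cassette pair whose
    sequences match exactly (equal or substring, either strand).

    Output is sorted by the canonical ``(cassette_id_a, cassette_id_b)``
    pair, so it is invariant to input row order.
    """
    recs = sorted(records, key=lambda r: r.cassette_id)
    events: list[HGTEvent] = []
    n = len(recs)
    for ia in range(n):
        a = recs[ia]
        for ib in range(ia + 1, n):
            b = recs[ib]
            if a.species_label == b.species_label:
                continue
            shorter, longer = (a, b) if len(a.sequence) <= len(b.sequence) else (b, a)
            strand = _match(shorter.sequence, longer.sequence)
            if strand is None:
                continue
            kind = "equal" if len(a.sequence) == len(b.sequence) else "substring"
            events.append(
                HGTEvent(
                    cassette_id_a=a.cassette_id,
                    cassette_id_b=b.cassette_id,
                    species_a=a.species_label,
                    species_b=b.species_label,
                    site_a=a.plant_site,
                    site_b=b.plant_site,
                    match_kind=kind,
                    strand=strand,
                )
            )
    events.sort(key=lambda e: e.pair)
    return events


def summarize_events_by_site(
    events: Iterable[HGTEvent], *, drop_both_not_announced: bool = False
) -> pd.DataFrame:
    """Tally events into a symmetric plant-site × plant-site count matrix.

    The diagonal holds within-site counts.  With ``drop_both_not_announced``
    the pairs where both partners lack a recorded isolation site are
    omitted (they carry no habitat information).
    """
    events = list(events)
    if drop_both_not_announced:
        events = [e for e in events
                  if not (e.site_a == "not_announced" and e.site_b == "not_announced")]
    sites = sorted({e.site_a for e in events} | {e.site_b for e in events})
    mat = pd.DataFrame(0, index=sites, columns=sites, dtype=int)
    for e in events:
        mat.loc[e.site_a, e.site_b] += 1
        if e.site_a != e.site_b:
            mat.loc[e.site_b, e.site_a] += 1
    return mat


def events_to_frame(events: Iterable[HGTEvent]) -> pd.DataFrame:
    cols = ["cassette_id_a", "cassette_id_b", "species_a", "species_b",
            "site_a", "site_b", "match_kind", "strand"]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in events], columns=cols)
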