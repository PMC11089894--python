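"""Enrichment statistics for horizontal cassette transfer.

The null model for per-site transfer counts is proportional sampling:
under no site effect, both partners of an event are drawn independently
in proportion to per-site cassette abundance, so a site holding a
fraction *f* of all cassettes expects ``total_events * f**2`` within-site
events.  (With 620 events and a 33.6 % cassette share this gives
620 × 0.336² ≈ 70 expected within-site events — the squared-fraction
form, not ``total × f``, reproduces that arithmetic.)

Observed vs expected counts are compared with a two-sided Fisher exact
test computed from the hypergeometric distribution; category-proportion
comparisons between habitats use the same 2×2 test per category, with
star labels at the conventional 0.05 / 0.01 / 0.001 thresholds and
Benjamini–Hochberg adjusted p-values reported alongside the raw ones.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import CassetteRecord, HGTEvent, SiteHGTSummary

log = logging.getLogger(__name__)

#: Relative tolerance when comparing hypergeometric point probabilities
#: against the observed table's probability (two-sided tail inclusion).
_REL_TOL = 1e-7


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2×2 count table.

    The p-value sums hypergeometric point probabilities of every table
    with the observed margins whose probability does not exceed that of
    the observed table (within relative tolerance 1e-7).  An all-zero
    table returns 1 by convention.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError(f"2x2 table entries must be non-negative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    # a ~ Hypergeom(N=n, K=c1, n=r1)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())
    return min(1.0, max(p, float(p_obs)))


def expected_within_site_events(
    total_events: int, site_fractions: Mapping[str, float]
) -> dict[str, float]:
    """Expected within-site event counts under the proportional null.

    Both partners of an event are drawn independently by cassette
    abundance, so site *s* with cassette fraction *f_s* expects
    ``total_events * f_s**2`` within-site events.
    """
    if total_events < 0:
        raise ValueError("total_events must be non-negative")
    for site, f in site_fractions.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"fraction for {site!r} outside [0, 1]: {f}")
    if sum(site_fractions.values()) > 1 + 1e-9:
        raise ValueError("site fractions sum to more than 1")
    return {site: total_events * f * f for site, f in site_fractions.items()}


def cassette_site_fractions(records: Sequence[CassetteRecord]) -> dict[str, float]:
    """Per-site cassette fractions over *all* cassettes, including those
    with no announced isolation site."""
    counts = Counter(r.plant_site for r in records)
    total = sum(counts.values())
    if total == 0:
        return {}
    return {site: c / total for site, c in sorted(counts.items())}


def site_enrichment_tests(
    events: Sequence[HGTEvent],
    records: Sequence[CassetteRecord],
    *,
    alpha: float = 0.001,
) -> list[SiteHGTSummary]:
    """Observed vs expected within-site HGT events, per plant site.

    For each site the 2×2 table
    ``[[observed_within, observed_elsewhere],
    [round(expected_within), round(expected_elsewhere)]]``
    is tested with :func:`fisher_exact_2x2`; the constructed table is
    logged for audit.  ``significant`` flags p < ``alpha``.
    """
    fractions = cassette_site_fractions(records)
    counts = Counter(r.plant_site for r in records)
    total_events = len(events)
    expected = expected_within_site_events(total_events, fractions)
    within = Counter(e.site_a for e in events if e.site_a == e.site_b)

    summaries: list[SiteHGTSummary] = []
    for site in sorted(fractions):
        obs_w = within.get(site, 0)
        exp_w = expected[site]
        if counts[site] == 0:
            summaries.append(SiteHGTSummary(site, 0, 0.0, 0, 0.0, 1.0, False))
            continue
        obs_e = total_events - obs_w
        exp_e = total_events - exp_w
        tab = [[obs_w, obs_e], [round(exp_w), round(exp_e)]]
        p = fisher_exact_2x2(tab)
        log.info("site %s: table %s -> p=%.3g", site, tab, p)
        summaries.append(
            SiteHGTSummary(
                site=site,
                cassette_count=counts[site],
                cassette_fraction=fractions[site],
                observed_within=obs_w,
                expected_within=exp_w,
                p_value=p,
                significant=p < alpha,
            )
        )
    return summaries


def significance_stars(p: float) -> str:
    """Star label at the conventional printed thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def category_proportion_tests(
    counts_a: Mapping[str, int], counts_b: Mapping[str, int]
) -> pd.DataFrame:
    """Per-category two-sided Fisher tests between two habitats.

    For category *c* with group totals *A*, *B* the table is
    ``[[a_c, A - a_c], [b_c, B - b_c]]``.  Returns a frame with raw p,
    BH-adjusted p, and star labels (stars from raw p, matching how such
    panels are conventionally annotated).
    """
    cats = sorted(set(counts_a) | set(counts_b))
    total_a = sum(counts_a.values())
    total_b = sum(counts_b.values())
    rows = []
    for cat in cats:
        a_c = counts_a.get(cat, 0)
        b_c = counts_b.get(cat, 0)
        if a_c == 0 and b_c == 0:
            log.info("category %r absent from both groups; skipped", cat)
            continue
        p = fisher_exact_2x2([[a_c, total_a - a_c], [b_c, total_b - b_c]])
        rows.append({
            "category": cat,
            "count_a": a_c,
            "count_b": b_c,
            "prop_a": a_c / total_a if total_a else 0.0,
            "prop_b": b_c / total_b if total_b else 0.0,
            "p_value": p,
        })
    df = pd.DataFrame(rows, columns=["category", "count_a", "count_b",
                                     "prop_a", "prop_b", "p_value"])
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["stars"] = df["p_value"].map(significance_stars)
    else:
        df["p_adjusted"] = []
        df["stars"] = []
    return df


def summaries_to_frame(summaries: Iterable[SiteHGTSummary]) -> pd.DataFrame:
    cols = ["site", "cassette_count", "cassette_fraction", "observed_within",
            "expected_within", "p_value", "significant"]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in summaries], columns=cols)
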