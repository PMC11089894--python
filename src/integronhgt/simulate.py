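"""Synthetic communities, *attC* sites, and tree pairs with known truth.

Every downstream stage is testable without any genome download: the
community generator emulates the statistical structure of a
plant-associated isolate screen — multiple species across plant sites
with uneven per-site cassette abundances and a known set of planted
cross-species identical cassette pairs (the HGT ground truth); the
*attC* generator emits clade-specific hairpin-forming sequences from a
stem–loop template; and the tree-pair generator produces binary trees
sharing an exact, verified number of non-trivial bipartitions.

Default site fractions follow the abundance profile reported for
plant-associated integron cassettes (roughly a third rhizosphere, a
sixth phyllosphere, a small spermosphere share, and the remainder with
no announced site); all sizes are deliberately small enough for exact
brute-force verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io import parse_newick
from .model import CassetteRecord, HGTEvent, reverse_complement
from .treecmp import bipartitions

_BASES = np.array(list("ACGT"))

#: Per-site cassette-abundance fractions used by default; mirrors the
#: reported cassette shares (33.6 % rhizosphere, 15.4 % phyllosphere),
#: a small spermosphere share, and the rest unannounced.
DEFAULT_SITE_FRACTIONS = {
    "rhizosphere": 0.336,
    "phyllosphere": 0.154,
    "spermosphere": 0.05,
    "not_announced": 0.46,
}


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of one synthetic community draw."""

    n_species: int = 12
    genomes_per_species: int = 2
    cassettes_per_genome: int = 8
    site_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_FRACTIONS)
    )
    n_planted_hgt: int = 12
    cross_site_hgt_fraction: float = 0.5
    cassette_length_range: tuple[int, int] = (60, 200)
    species_per_clade: int = 3
    #: restrict within-site planted events to this site (None = any site);
    #: used to emulate site-specific transfer enrichment
    planted_within_site: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.genomes_per_species < 1:
            raise ValueError("need at least 1 genome per species")
        if self.cassettes_per_genome < 0 or self.n_planted_hgt < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 <= self.cross_site_hgt_fraction <= 1.0):
            raise ValueError("cross_site_hgt_fraction must be in [0, 1]")
        lo, hi = self.cassette_length_range
        if lo < 50 or hi < lo:
            raise ValueError("cassette lengths must be >= 50 with lo <= hi")
        total = sum(self.site_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"site fractions sum to {total}, expected 1")

    @property
    def total_cassettes(self) -> int:
        return self.n_species * self.genomes_per_species * self.cassettes_per_genome


@dataclass(frozen=True)
class AttcTemplate:
    """A clade's hairpin template: conserved stem, free loop, and a
    per-base mutation rate for within-clade variation."""

    clade_label: str
    stem_sequence: str
    loop_length: int = 5
    mutation_rate: float = 0.02

    def __post_init__(self) -> None:
        if not self.stem_sequence:
            raise ValueError("stem must be non-empty")
        if self.loop_length < 3:
            raise ValueError("loop must allow a hairpin (>= 3)")
        if not (0.0 <= self.mutation_rate < 0.5):
            raise ValueError("mutation_rate must be in [0, 0.5)")


#: Two well-separated clade templates: GC-only stems (so the poly-A spacer
#: stays unpaired under maximum-pairing folding) with distinct paired
#: fractions, which is what the scale-free mountain profile discriminates.
DEFAULT_ATTC_TEMPLATES = (
    AttcTemplate("Clade_A", "GCGGCGGCCGGCGGCCGCGC", loop_length=4, mutation_rate=0.01),
    AttcTemplate("Clade_B", "GCCGGCGC", loop_length=14, mutation_rate=0.01),
)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _fresh_seq(rng: np.random.Generator, length: int, taken: set[str]) -> str:
    # redraw on collision so the zero-HGT null is exact
    while True:
        s = _random_seq(rng, length)
        if s not in taken and reverse_complement(s) not in taken:
            return s


def _apportion(total: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` across sites."""
    items = sorted(fractions.items())
    raw = {s: total * f for s, f in items}
    counts = {s: int(np.floor(v)) for s, v in raw.items()}
    short = total - sum(counts.values())
    by_rem = sorted(items, key=lambda kv: (-(raw[kv[0]] - counts[kv[0]]), kv[0]))
    for s, _ in by_rem[:short]:
        counts[s] += 1
    return counts


def generate_community(
    config: CommunityConfig,
) -> tuple[list[CassetteRecord], list[HGTEvent]]:
    """Draw a community and its planted cross-species HGT truth.

    Background cassettes are pairwise-distinct uniform random sequences;
    exactly ``n_planted_hgt`` disjoint cross-species pairs share a
    verbatim sequence, ``round(cross_site_hgt_fraction * n_planted_hgt)``
    of them spanning two plant sites.  Per-site cassette counts match
    ``site_fractions`` to within rounding.  Fully reproducible from the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cassette_length_range
    total = config.total_cassettes

    site_counts = _apportion(total, config.site_fractions)
    site_pool = [s for s, c in sorted(site_counts.items()) for _ in range(c)]
    site_assignment = [site_pool[i] for i in rng.permutation(total)]

    meta: list[tuple[str, str, str, str, str]] = []
    idx = 0
    for sp in range(config.n_species):
        species = f"Species_{sp:03d}"
        clade = f"Clade_{sp // config.species_per_clade:02d}"
        for g in range(config.genomes_per_species):
            genome = f"{species}_g{g}"
            for _ in range(config.cassettes_per_genome):
                cid = f"cas_{idx:05d}"
                meta.append((cid, genome, species, clade, site_assignment[idx]))
                idx += 1

    n_cross = round(config.cross_site_hgt_fraction * config.n_planted_hgt)
    n_within = config.n_planted_hgt - n_cross
    order = list(rng.permutation(total))
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []

    def _take_pair(want_cross: bool) -> tuple[int, int] | None:
        for ii, i in enumerate(order):
            if i in used:
                continue
            for j in order[ii + 1:]:
                if j in used:
                    continue
                if meta[i][2] == meta[j][2]:
                    continue
                cross = meta[i][4] != meta[j][4]
                if cross != want_cross:
                    continue
                if (not cross and config.planted_within_site is not None
                        and meta[i][4] != config.planted_within_site):
                    continue
                used.update((i, j))
                return (i, j)
        return None

    for want_cross, count in ((True, n_cross), (False, n_within)):
        for _ in range(count):
            pair = _take_pair(want_cross)
            if pair is None:
                kind = "cross-site" if want_cross else "within-site"
                raise ValueError(
                    f"infeasible config: cannot plant {count} {kind} "
                    f"cross-species pairs in {total} cassettes"
                )
            pairs.append(pair)

    taken: set[str] = set()
    seqs: list[str | None] = [None] * total
    for i, j in pairs:
        s = _fresh_seq(rng, int(rng.integers(lo, hi + 1)), taken)
        taken.add(s)
        seqs[i] = seqs[j] = s
    for i in range(total):
        if seqs[i] is None:
            s = _fresh_seq(rng, int(rng.integers(lo, hi + 1)), taken)
            taken.add(s)
            seqs[i] = s

    records = [
        CassetteRecord(cid, genome, species, clade, site, seqs[i])
        for i, (cid, genome, species, clade, site) in enumerate(meta)
    ]
    by_idx = {i: records[i] for i in range(total)}
    truth = []
    for i, j in pairs:
        a, b = sorted((by_idx[i], by_idx[j]), key=lambda r: r.cassette_id)
        truth.append(
            HGTEvent(
                cassette_id_a=a.cassette_id,
                cassette_id_b=b.cassette_id,
                species_a=a.species_label,
                species_b=b.species_label,
                site_a=a.plant_site,
                site_b=b.plant_site,
                match_kind="equal",
                strand="forward",
            )
        )
    truth.sort(key=lambda e: e.pair)
    return records, truth


def generate_attc(template: AttcTemplate, n: int, seed: int | None = None) -> list[str]:
    """Draw ``n`` hairpin-forming *attC* sequences from a clade template.

    Each sequence is stem + loop spacer + reverse-complement(stem), then
    mutated per base at the template's mutation rate (mutations pick a
    different base uniformly).  The spacer is poly-A — an unpaired loop
    by construction, emulating the extrahelical spacer between the box
    domains of real *attC* hairpins — so with mutation rate 0 every draw
    is the identical template hairpin and (for stems without T) folds to
    exactly ``len(stem)`` pairs.  Loop variation comes from mutations.
    """
    rng = np.random.default_rng(seed)
    stem = template.stem_sequence.upper()
    loop = "A" * template.loop_length
    out = []
    for _ in range(n):
        seq = list(stem + loop + reverse_complement(stem))
        if template.mutation_rate > 0:
            hits = rng.random(len(seq)) < template.mutation_rate
            for pos in np.flatnonzero(hits):
                choices = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = choices[int(rng.integers(3))]
        out.append("".join(seq))
    return out


def random_binary_tree(
    labels: list[str], rng: np.random.Generator
) -> dendropy.Tree:
    """A random rooted binary tree over ``labels`` by uniform random
    sequential joins."""
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    subtrees = list(labels)
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a},{b})")
    return parse_newick(subtrees[0] + ";")


def make_tree_pair(
    n_leaves: int, n_shared: int, seed: int | None = None,
    max_tries: int = 20_000,
) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Two random binary trees on one leaf set sharing exactly
    ``n_shared`` non-trivial bipartitions.

    Constructed by rejection sampling over random topologies and
    verified by bipartition intersection before returning.  ``n_shared``
    must be at most ``n_leaves - 3`` (the split count of a binary tree);
    if the sampling budget is exhausted a hard error suggests a smaller
    ``n_shared``.
    """
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves")
    if not (0 <= n_shared <= n_leaves - 3):
        raise ValueError(f"n_shared must be in [0, {n_leaves - 3}]")
    rng = np.random.default_rng(seed)
    labels = [f"L{i:03d}" for i in range(n_leaves)]
    t1 = random_binary_tree(labels, rng)
    s1 = bipartitions(t1).splits
    if n_shared == n_leaves - 3:
        from .io import tree_to_newick

        newick = tree_to_newick(t1)
        return t1, parse_newick(newick if newick.endswith(";") else newick + ";")
    for _ in range(max_tries):
        t2 = random_binary_tree(labels, rng)
        if len(s1 & bipartitions(t2).splits) == n_shared:
            return t1, t2
    raise RuntimeError(
        f"could not sample a tree pair sharing exactly {n_shared} splits "
        f"on {n_leaves} leaves within {max_tries} tries; try a smaller n_shared"
    )
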