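"""Core domain types shared by all pipeline stages.

The central object is the :class:`CassetteRecord` — one integron gene
cassette (an ORF plus its *attC* recombination site) recovered from a
bacterial genome, carrying the taxonomy and plant-site metadata needed
downstream.  Horizontal transfer calls, annotation rows, and folded
*attC* structures each get a small frozen dataclass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_SITE_DEFAULT = "not_announced"

# Strict DNA alphabet.  U is accepted on input for attC sites (they act as
# folded single strands) and mapped to T; anything else is rejected at
# parse time so that downstream exact-identity matching cannot silently
# miscount.
DNA_ALPHABET = frozenset("ACGTN")

#: Standard one-letter COG functional category names.
COG_CATEGORY_NAMES = {
    "J": "Translation, ribosomal structure and biogenesis",
    "A": "RNA processing and modification",
    "K": "Transcription",
    "L": "Replication, recombination and repair",
    "B": "Chromatin structure and dynamics",
    "D": "Cell cycle control, cell division, chromosome partitioning",
    "Y": "Nuclear structure",
    "V": "Defense mechanisms",
    "T": "Signal transduction mechanisms",
    "M": "Cell wall/membrane/envelope biogenesis",
    "N": "Cell motility",
    "Z": "Cytoskeleton",
    "W": "Extracellular structures",
    "U": "Intracellular trafficking, secretion, and vesicular transport",
    "O": "Posttranslational modification, protein turnover, chaperones",
    "X": "Mobilome: prophages, transposons",
    "C": "Energy production and conversion",
    "G": "Carbohydrate transport and metabolism",
    "E": "Amino acid transport and metabolism",
    "F": "Nucleotide transport and metabolism",
    "H": "Coenzyme transport and metabolism",
    "I": "Lipid transport and metabolism",
    "P": "Inorganic ion transport and metabolism",
    "Q": "Secondary metabolites biosynthesis, transport and catabolism",
    "R": "General function prediction only",
    "S": "Function unknown",
}

CATEGORY_TOXIN_ANTITOXIN = "Toxin-antitoxin systems"
CATEGORY_TRANSPOSASES = "Transposases"
CATEGORY_FUNCTION_UNKNOWN = "Function unknown"
CATEGORY_UNANNOTATED = "Unannotated"


def canonical_site(site: str | None) -> str:
    """Canonicalise a plant-site label to lower-case snake-case.

    Empty or missing labels become ``"not_announced"``.  The vocabulary is
    open: real datasets record more habitats (spermosphere, carposphere,
    ...) than any fixed enumeration.
    """
    if site is None:
        return VALID_SITE_DEFAULT
    s = site.strip().lower().replace(" ", "_").replace("-", "_")
    return s if s else VALID_SITE_DEFAULT


def clean_dna(seq: str, *, allow_u: bool = False, context: str = "sequence") -> str:
    """Upper-case and validate a DNA string over {A,C,G,T,N}.

    With ``allow_u`` (attC sites), U/u is mapped to T.  Raises
    ``ValueError`` on any other character — fail fast rather than let an
    ambiguous base slip into exact-identity comparisons.
    """
    s = seq.strip().upper()
    if allow_u:
        s = s.replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"invalid character(s) {sorted(bad)} in {context}: only A,C,G,T,N allowed"
        )
    return s


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CassetteRecord:
    """One integron gene cassette with its genome and habitat metadata."""

    cassette_id: str
    genome_id: str
    species_label: str
    clade_label: str
    plant_site: str
    sequence: str
    attc_sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.cassette_id:
            raise ValueError("cassette_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"cassette {self.cassette_id}: empty sequence")
        object.__setattr__(self, "plant_site", canonical_site(self.plant_site))
        object.__setattr__(
            self, "sequence", clean_dna(self.sequence, context=f"cassette {self.cassette_id}")
        )
        if self.attc_sequence:
            object.__setattr__(
                self,
                "attc_sequence",
                clean_dna(self.attc_sequence, allow_u=True,
                          context=f"attC of cassette {self.cassette_id}"),
            )
        else:
            object.__setattr__(self, "attc_sequence", None)


@dataclass(frozen=True)
class HGTEvent:
    """An unordered cross-species cassette pair identical at 100 % identity
    over the full length of the shorter sequence.

    ``cassette_id_a < cassette_id_b`` lexicographically (canonical form);
    ``match_kind`` records whether the two sequences are equal or the
    shorter is a proper substring of the longer; ``strand`` records the
    strand of the longer sequence on which the match lies.
    """

    cassette_id_a: str
    cassette_id_b: str
    species_a: str
    species_b: str
    site_a: str
    site_b: str
    match_kind: str  # "equal" | "substring"
    strand: str  # "forward" | "reverse_complement"

    def __post_init__(self) -> None:
        if self.cassette_id_a >= self.cassette_id_b:
            raise ValueError("event ids must satisfy cassette_id_a < cassette_id_b")
        if self.species_a == self.species_b:
            raise ValueError("an HGT event must join two different species")
        if self.match_kind not in ("equal", "substring"):
            raise ValueError(f"bad match_kind {self.match_kind!r}")
        if self.strand not in ("forward", "reverse_complement"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.cassette_id_a, self.cassette_id_b)


@dataclass(frozen=True)
class AnnotationRecord:
    """A cassette-protein functional annotation (eggNOG-style).

    ``cog_categories`` preserves input order (the first letter drives
    passthrough categorisation); ``assigned_category`` is filled by the
    re-categorisation rules.
    """

    protein_id: str
    cog_categories: tuple[str, ...] = ()
    description: str = ""
    assigned_category: str = ""


@dataclass(frozen=True)
class KoHit:
    """A KEGG Ortholog assignment with its HMM score and the
    model-specific significance threshold."""

    protein_id: str
    ko_id: str
    score: float
    model_threshold: float | None
    subclass: str = ""


@dataclass(frozen=True)
class AlignmentHit:
    """A protein alignment hit with identity/coverage percentages."""

    query_id: str
    subject_id: str
    percent_identity: float
    percent_query_cover: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (0 <= self.percent_identity <= 100):
            raise ValueError(f"identity {self.percent_identity} outside [0, 100]")
        if not (0 <= self.percent_query_cover <= 100):
            raise ValueError(f"query cover {self.percent_query_cover} outside [0, 100]")


@dataclass(frozen=True)
class SiteHGTSummary:
    """Per-plant-site observed vs expected within-site HGT counts."""

    site: str
    cassette_count: int
    cassette_fraction: float
    observed_within: int
    expected_within: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested (pseudoknot-free) set of base pairs on one sequence.

    ``pairs`` are 0-based ``(i, j)`` with ``i < j``; each index occurs in
    at most one pair and no two pairs cross.
    """

    sequence: str
    pairs: frozenset[tuple[int, int]]
    dot_bracket: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise ValueError(f"pair ({i},{j}) outside sequence of length {n}")
            if i in seen or j in seen:
                raise ValueError(f"index reused in pair ({i},{j})")
            seen.update((i, j))
        for (i, j) in self.pairs:
            for (k, l) in self.pairs:
                if i < k < j < l:
                    raise ValueError(f"crossing pairs ({i},{j}) and ({k},{l})")
        if not self.dot_bracket:
            db = ["."] * n
            for i, j in self.pairs:
                db[i], db[j] = "(", ")"
            object.__setattr__(self, "dot_bracket", "".join(db))

    def __len__(self) -> int:
        return len(self.sequence)
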