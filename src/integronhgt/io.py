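"""Readers and writers for the formats the pipeline exchanges.

TSV tables (tab-separated, UTF-8, header row required, ``#``-prefixed
comment lines skipped), FASTA, and Newick.  Every reader/writer pair is a
lossless round trip on valid input.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import CassetteRecord

CASSETTE_COLUMNS = [
    "cassette_id",
    "genome_id",
    "species_label",
    "clade_label",
    "plant_site",
    "sequence",
    "attc_sequence",
]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_cassette_table(path: str | Path) -> list[CassetteRecord]:
    """Parse a cassette TSV into validated :class:`CassetteRecord` rows.

    Missing ``plant_site`` values default to ``"not_announced"``; the
    ``attc_sequence`` column is optional.  Duplicate cassette ids and
    empty sequences are hard errors.
    """
    df = _read_tsv(path)
    required = [c for c in CASSETTE_COLUMNS if c not in ("attc_sequence", "clade_label")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    dupes = df["cassette_id"][df["cassette_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate cassette_id(s): {', '.join(dupes)}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            CassetteRecord(
                cassette_id=d["cassette_id"],
                genome_id=d["genome_id"],
                species_label=d["species_label"],
                clade_label=d.get("clade_label", "") or "",
                plant_site=d.get("plant_site", ""),
                sequence=d["sequence"],
                attc_sequence=d.get("attc_sequence") or None,
            )
        )
    return records


def write_cassette_table(records: Iterable[CassetteRecord], path: str | Path) -> None:
    rows = [
        {
            "cassette_id": r.cassette_id,
            "genome_id": r.genome_id,
            "species_label": r.species_label,
            "clade_label": r.clade_label,
            "plant_site": r.plant_site,
            "sequence": r.sequence,
            "attc_sequence": r.attc_sequence or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CASSETTE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id → sequence mapping; duplicate ids are errors."""
    mapping: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in mapping:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        mapping[rec.id] = str(rec.seq).upper()
    return mapping


def write_fasta(mapping: Mapping[str, str], path: str | Path) -> None:
    """Write an id → sequence mapping as FASTA, wrapped at 80 columns."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in mapping.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def _check_unique_leaves(tree: dendropy.Tree, source: str) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    seen: set[str] = set()
    dupes = {l for l in labels if l in seen or seen.add(l)}  # type: ignore[func-returns-value]
    if dupes:
        raise ValueError(f"{source}: duplicate leaf label(s): {sorted(dupes)}")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; unbalanced parentheses and duplicate leaf
    labels are hard errors."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"{path}: malformed Newick ({exc})") from exc
    _check_unique_leaves(tree, str(path))
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick ({exc})") from exc
    _check_unique_leaves(tree, "<string>")
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")
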