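"""Readers and writers for every sequence and table format the pipeline touches.

Sequences travel as FASTA (Biopython-parsed), tables as tab-separated text
with ``#``-prefixed comment lines and a deterministic column order so that
outputs diff bit-exactly between runs.  All interval columns are 0-based
half-open.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger("virocat")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class ParseError(ValueError):
    """Malformed sequence or table input."""


class SchemaError(ValueError):
    """A table is missing required columns."""


class ValidationError(ValueError):
    """Inputs are well-formed but violate a contract (e.g. duplicate ids)."""


ASSEMBLY_SOURCES = ("short", "long", "hybrid")


@dataclass
class Contig:
    """A candidate genome sequence with sample and assembly provenance."""

    id: str
    sequence: str
    sample_id: str = ""
    assembly_source: str = "short"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"contig {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> List[Contig]:
    """Parse a FASTA file into :class:`Contig` records.

    The header token before the first whitespace becomes the id; sequences
    are upper-cased.  Duplicate ids raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: List[Contig] = []
    seen: set = set()
    with _open_maybe_gzip(path) as handle:
        first = handle.read(1)
        if first == "":
            log.warning("empty FASTA file: %s", path)
            return []
        if first != ">":
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            contigs.append(Contig(id=rec.id, sequence=str(rec.seq)))
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 80) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as out:
        for c in contigs:
            out.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), width):
                out.write(c.sequence[i:i + width] + "\n")


def read_fasta_labelled(path: str | Path, label_key: str = "host") -> List[tuple]:
    """Parse FASTA whose headers carry ``>seqid|host=species_id`` labels.

    Returns ``(seq_id, label, sequence)`` tuples; label is '' when absent.
    """
    out = []
    for c in read_fasta(path):
        seq_id, label = c.id, ""
        if "|" in c.id:
            seq_id, _, rest = c.id.partition("|")
            for part in rest.split("|"):
                k, _, v = part.partition("=")
                if k == label_key:
                    label = v
        out.append((seq_id, label, c.sequence))
    return out


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

#: Required columns per named table schema.  Extra columns are preserved.
TABLE_SCHEMAS: Dict[str, List[str]] = {
    "contig_meta": ["contig_id", "sample_id", "assembly_source"],
    "evidence": ["contig_id", "virsorter_score", "virfinder_score",
                 "pprmeta_score", "refseq_hit_identity", "refseq_hit_coverage",
                 "pog_hit_orfs", "checkv_completeness"],
    "coverage": ["sample_id", "contig_id", "breadth", "mean_depth",
                 "mapped_reads"],
    "placements": ["sample_id", "read_id", "contig_id", "start", "end",
                   "strand"],
    "lifestyle": ["contig_id", "score"],
    "cog": ["protein_id", "contig_id", "category"],
    "spacer-map": ["spacer_id", "host_species_id"],
    "prophage-intervals": ["genome_id", "start", "end"],
    "hsp": ["query_id", "subject_id", "q_start", "q_end", "s_start", "s_end",
            "identity", "aligned_len", "strand", "score"],
    "taxonomy": ["node_id", "parent_id", "rank", "name"],
    "crass-protein-hits": ["contig_id", "target", "significant"],
}

_STRING_COLS = {"contig_id", "sample_id", "assembly_source", "read_id",
                "strand", "query_id", "subject_id", "protein_id", "category",
                "spacer_id", "host_species_id", "genome_id", "node_id",
                "parent_id", "rank", "name", "target", "checkv_quality",
                "vc_id", "member_id", "virus_id", "reference_id", "class",
                "method", "group", "confidence", "clade", "layer"}


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    """Read a TSV table, validating against a named schema.

    ``NA`` / empty fields become missing values (never zero).  ``#`` comment
    lines are skipped.  Unknown columns are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema is not None and schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table schema {schema!r}; "
                          f"known: {sorted(TABLE_SCHEMAS)}")
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA", ""],
                     keep_default_na=True, dtype="object")
    if schema is not None:
        missing = [c for c in TABLE_SCHEMAS[schema] if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s) {missing} for schema "
                f"{schema!r}; expected header includes {TABLE_SCHEMAS[schema]}")
    # Columns not known to be strings are coerced to bool/numeric when possible.
    for col in df.columns:
        if col in _STRING_COLS:
            continue
        values = df[col].dropna()
        if len(values) and values.isin(["True", "False"]).all():
            df[col] = df[col].map({"True": True, "False": False})
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        # keep original text if coercion destroys non-missing values
        if coerced.notna().sum() >= df[col].notna().sum():
            df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path,
                comment: str | None = None) -> None:
    """Write a TSV with optional ``#`` header comment, missing values as NA.

    Floats are rendered with :func:`repr`-faithful precision so a write→read
    round trip reproduces the frame exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as out:
        out.write("# interval columns are 0-based half-open\n")
        if comment:
            for line in comment.splitlines():
                out.write(f"# {line}\n")
        df.to_csv(out, sep="\t", index=False, na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# Catalogue output
# ---------------------------------------------------------------------------

def write_catalogue(votus: Sequence[Contig],
                    annotations: Mapping[str, pd.DataFrame],
                    outdir: str | Path) -> List[Path]:
    """Emit the final catalogue: one FASTA plus one TSV per annotation layer.

    Every annotation layer must key on ``contig_id`` and reference only
    catalogue members.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = {c.id for c in votus}
    written: List[Path] = []
    fasta = outdir / "votus.fasta"
    write_fasta(votus, fasta)
    written.append(fasta)
    for layer, df in sorted(annotations.items()):
        if "contig_id" not in df.columns:
            raise ValidationError(f"annotation layer {layer!r} lacks contig_id")
        stray = set(df["contig_id"]) - ids
        if stray:
            raise ValidationError(
                f"annotation layer {layer!r} references non-catalogue ids: "
                f"{sorted(stray)[:5]}")
        p = outdir / f"{layer}.tsv"
        write_table(df, p, comment=f"catalogue annotation layer: {layer}")
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

RANK_ORDER = ["species", "genus", "family", "order", "class", "phylum",
              "domain"]


@dataclass
class Taxonomy:
    """A rank-labelled tree read from a 4-column TSV.

    node_id → (parent_id, rank, name); the root is its own parent or has
    parent ``''``/NA.
    """

    parent: Dict[str, str]
    rank: Dict[str, str]
    name: Dict[str, str]
    root: str = field(init=False)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p in ("", n) or p is None]
        if len(roots) != 1:
            raise ValidationError(f"taxonomy must have exactly one root, got {roots}")
        self.root = roots[0]
        for n, p in self.parent.items():
            if n != self.root and p not in self.parent:
                raise ValidationError(f"taxonomy parent {p!r} of {n!r} unresolvable")

    def ancestors(self, node: str) -> List[str]:
        """Path from node to root, inclusive."""
        if node not in self.parent:
            raise ValidationError(f"unknown taxonomy node {node!r}")
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def ancestor_at_rank(self, node: str, rank: str) -> str | None:
        for anc in self.ancestors(node):
            if self.rank[anc] == rank:
                return anc
        return None

    def lca(self, nodes: Sequence[str]) -> str:
        if not nodes:
            raise ValidationError("LCA of an empty host set is undefined")
        paths = [self.ancestors(n)[::-1] for n in set(nodes)]
        lca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            level = {p[depth] for p in paths}
            if len(level) == 1:
                lca = level.pop()
            else:
                break
        return lca


def read_taxonomy(path: str | Path) -> Taxonomy:
    df = read_table(path, schema="taxonomy")
    parent = {}
    rank = {}
    name = {}
    for row in df.itertuples(index=False):
        pid = "" if pd.isna(row.parent_id) else str(row.parent_id)
        parent[str(row.node_id)] = pid
        rank[str(row.node_id)] = str(row.rank)
        name[str(row.node_id)] = str(row.name)
    return Taxonomy(parent=parent, rank=rank, name=name)
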