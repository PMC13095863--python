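"""Core domain types and file I/O.

The pipeline works with four kinds of external data: per-gene multiple
sequence alignments (FASTA), a species phylogeny (Newick), a
foreground/background taxon partition (TSV) and optional protein-domain
intervals (TSV).  All coordinates are 1-based and intervals are inclusive
on both ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

_NT_ALPHABET = frozenset("ACGTN-")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX-*")


class FormatError(ValueError):
    """Malformed input file."""


class AlignmentShapeError(FormatError):
    """Rows of an alignment differ in length."""


class DuplicateTaxonError(FormatError):
    """A taxon name occurs more than once."""


class TreeParseError(FormatError):
    """Newick string could not be parsed."""


@dataclass
class GeneAlignment:
    """One gene's multiple sequence alignment.

    Rows are uppercase strings over {A,C,G,T,N,-} in nucleotide mode or the
    20 standard amino acids plus {X,-,*} in protein mode.  The gap character
    is "-"; "." in input files is normalized on read.
    """

    gene_id: str
    taxa: list[str]
    rows: list[str]
    seq_type: str
    codon_aligned: bool = False

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentShapeError(
                f"{self.gene_id}: {len(self.taxa)} taxa but {len(self.rows)} rows")
        if not self.rows:
            raise FormatError(f"{self.gene_id}: empty alignment")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise DuplicateTaxonError(f"{self.gene_id}: duplicate taxa {dup}")
        length = len(self.rows[0])
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != length:
                raise AlignmentShapeError(
                    f"{self.gene_id}: row {taxon!r} has length {len(row)}, expected {length}")
        if self.seq_type not in (NUCLEOTIDE, PROTEIN):
            raise ValueError(f"unknown seq_type {self.seq_type!r}")
        alphabet = _NT_ALPHABET if self.seq_type == NUCLEOTIDE else _AA_ALPHABET
        for taxon, row in zip(self.taxa, self.rows):
            bad = set(row) - alphabet
            if bad:
                raise FormatError(
                    f"{self.gene_id}: row {taxon!r} contains illegal characters {sorted(bad)}")
        if self.codon_aligned:
            if self.seq_type != NUCLEOTIDE:
                raise ValueError(f"{self.gene_id}: codon_aligned requires nucleotide mode")
            if length % 3 != 0:
                raise AlignmentShapeError(
                    f"{self.gene_id}: codon-aligned length {length} not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment {self.gene_id}")

    def column(self, col: int) -> dict[str, str]:
        """Characters of 1-based column ``col`` keyed by taxon."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} out of range 1..{self.length}")
        return {t: r[col - 1] for t, r in zip(self.taxa, self.rows)}


@dataclass
class Phylogeny:
    """A rooted species tree with branch lengths in substitutions per site.

    Nodes are stored in preorder (root first); ``parent[i]`` is the preorder
    index of node i's parent (-1 for the root) and ``lengths[i]`` the length
    of the branch above node i.
    """

    labels: list[str]
    parent: list[int]
    lengths: list[float]
    is_tip: list[bool]
    newick: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        tips = self.tip_names
        if len(set(tips)) != len(tips):
            raise DuplicateTaxonError("duplicate tip names in tree")
        for i, t in enumerate(self.lengths):
            if not (t >= 0.0 and t == t and t != float("inf")):
                raise ValueError(f"branch length of node {self.labels[i]!r} is {t}")

    @property
    def tip_names(self) -> list[str]:
        return [lab for lab, tip in zip(self.labels, self.is_tip) if tip]

    @property
    def n_branches(self) -> int:
        # every non-root node subtends one branch
        return len(self.labels) - 1

    def children(self, i: int) -> list[int]:
        return [j for j, p in enumerate(self.parent) if p == i]


@dataclass
class TaxonPartition:
    """Foreground/background bipartition of the analysis taxa.

    Foreground taxa are the lineages of interest (here: diving species whose
    terminal branches form the foreground branch class); background taxa are
    everything else.
    """

    foreground: frozenset[str]
    background: frozenset[str]

    def __post_init__(self) -> None:
        self.foreground = frozenset(self.foreground)
        self.background = frozenset(self.background)
        if not self.foreground:
            raise ValueError("empty foreground set")
        if not self.background:
            raise ValueError("empty background set")
        overlap = self.foreground & self.background
        if overlap:
            raise DuplicateTaxonError(f"taxa in both classes: {sorted(overlap)}")

    @property
    def taxa(self) -> frozenset[str]:
        return self.foreground | self.background

    def swapped(self) -> "TaxonPartition":
        return TaxonPartition(self.background, self.foreground)


@dataclass(frozen=True)
class DomainInterval:
    """A named protein domain of a gene, 1-based inclusive coordinates."""

    gene_id: str
    domain_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"{self.gene_id}/{self.domain_name}: invalid interval [{self.start}, {self.end}]")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


# ---------------------------------------------------------------------------
# readers / writers


def _infer_seq_type(rows: list[str]) -> str:
    chars = set("".join(rows))
    return NUCLEOTIDE if chars <= _NT_ALPHABET else PROTEIN


def read_alignment_fasta(path: str | Path, gene_id: str | None = None,
                         seq_type: str | None = None) -> GeneAlignment:
    """Read one gene alignment from a FASTA file.

    ``seq_type`` is inferred from the residue alphabet when not given
    (sequences over {A,C,G,T,N,-} are taken as nucleotide).  Lowercase is
    folded to uppercase and "." gaps are normalized to "-".
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    taxa = [r.id for r in records]
    rows = [str(r.seq).upper().replace(".", "-") for r in records]
    if len(set(taxa)) != len(taxa):
        dup = sorted({t for t in taxa if taxa.count(t) > 1})
        raise DuplicateTaxonError(f"{path}: duplicate headers {dup}")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise AlignmentShapeError(f"{path}: ragged alignment, row lengths {sorted(lengths)}")
    if gene_id is None:
        gene_id = path.stem
    if seq_type is None:
        seq_type = _infer_seq_type(rows)
    codon_aligned = seq_type == NUCLEOTIDE and len(rows[0]) % 3 == 0
    return GeneAlignment(gene_id, taxa, rows, seq_type, codon_aligned=codon_aligned)


def write_alignment_fasta(aln: GeneAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(row), id=taxon, description="")
               for taxon, row in zip(aln.taxa, aln.rows)]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def read_tree_newick(path_or_string: str | Path) -> Phylogeny:
    """Read a single rooted Newick tree.

    Accepts a path or a raw Newick string.  Branch lengths absent from the
    file default to 0.0 with a warning.
    """
    text = None
    p = Path(str(path_or_string))
    if "(" not in str(path_or_string) and p.exists():
        text = p.read_text()
    elif "(" in str(path_or_string):
        text = str(path_or_string)
    else:
        raise FileNotFoundError(f"tree file not found: {path_or_string}")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"could not parse Newick tree: {exc}") from exc

    labels: list[str] = []
    parent: list[int] = []
    lengths: list[float] = []
    is_tip: list[bool] = []
    index: dict[int, int] = {}
    missing_lengths = 0
    for node in tree.preorder_node_iter():
        i = len(labels)
        index[id(node)] = i
        if node.is_leaf():
            labels.append(node.taxon.label if node.taxon else f"tip{i}")
        else:
            labels.append(node.label or f"node{i}")
        parent.append(index[id(node.parent_node)] if node.parent_node else -1)
        if node.parent_node is None:
            lengths.append(0.0)
        elif node.edge.length is None:
            missing_lengths += 1
            lengths.append(0.0)
        else:
            lengths.append(float(node.edge.length))
        is_tip.append(node.is_leaf())
    if missing_lengths:
        warnings.warn(
            f"{missing_lengths} branch length(s) absent from Newick input; defaulting to 0.0",
            stacklevel=2)
    return Phylogeny(labels, parent, lengths, is_tip,
                     newick=tree.as_string(schema="newick").strip())


def read_partition(path: str | Path) -> TaxonPartition:
    """Read the taxon partition TSV (header line, columns: taxon, class)."""
    path = Path(path)
    fg: set[str] = set()
    bg: set[str] = set()
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty partition file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            taxon, cls = parts[0].strip(), parts[1].strip().lower()
            if taxon in seen:
                raise DuplicateTaxonError(f"{path}:{lineno}: taxon {taxon!r} listed twice")
            seen.add(taxon)
            if cls == "foreground":
                fg.add(taxon)
            elif cls == "background":
                bg.add(taxon)
            else:
                raise FormatError(
                    f"{path}:{lineno}: unknown class {parts[1]!r} "
                    "(expected 'foreground' or 'background')")
    if not fg:
        raise ValueError(f"{path}: no foreground taxa")
    if not bg:
        raise ValueError(f"{path}: no background taxa")
    return TaxonPartition(frozenset(fg), frozenset(bg))


def write_partition(partition: TaxonPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tclass\n")
        for taxon in sorted(partition.foreground):
            fh.write(f"{taxon}\tforeground\n")
        for taxon in sorted(partition.background):
            fh.write(f"{taxon}\tbackground\n")


def read_domains(path: str | Path) -> list[DomainInterval]:
    """Read domain intervals TSV (header; gene_id, domain_name, start, end)."""
    path = Path(path)
    out: list[DomainInterval] = []
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
            out.append(DomainInterval(parts[0], parts[1], int(parts[2]), int(parts[3])))
    return out


def map_column_to_reference(aln: GeneAlignment, column: int, ref_taxon: str) -> int | None:
    """Map a 1-based alignment column to the 1-based ungapped position in a
    reference taxon's sequence.

    Returns None when the reference carries a gap at that column.  The
    mapping is the count of non-gap reference characters in columns
    1..column, which makes it non-decreasing in the column index.
    """
    ref = aln.row(ref_taxon)
    if not 1 <= column <= aln.length:
        raise IndexError(f"column {column} out of range 1..{aln.length}")
    if ref[column - 1] == "-":
        return None
    return column - ref[:column].count("-")
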