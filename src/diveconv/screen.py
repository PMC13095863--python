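"""Screen for shared (convergent) amino-acid substitutions.

A column of a protein alignment is called convergent when every background
taxon carries one standard residue, every foreground taxon carries a single
different standard residue, and the policy's conditions on gaps, ambiguous
residues and missing taxa hold.  Under the default strict policy any gap,
"X", "*" or absent taxon anywhere in the column vetoes the call — the
reading used for single-copy ortholog sets where every species is expected
to be present.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._codon import AMINO_ACIDS
from .io_model import (
    PROTEIN,
    GeneAlignment,
    TaxonPartition,
    map_column_to_reference,
)

_STANDARD = frozenset(AMINO_ACIDS)


class UnknownTaxonError(KeyError):
    """Column references a taxon outside the partition."""


@dataclass(frozen=True)
class ScreenPolicy:
    """Gap/ambiguity handling of the screen.

    ``strict`` (default): every partition taxon must be present with a
    standard residue.  ``tolerate_k``: up to ``max_missing`` taxa per column
    may be absent or carry a gap/ambiguous character; the remaining taxa
    must still be class-uniform and both classes non-empty.
    """

    missing_policy: str = "strict"
    max_missing: int = 0
    treat_x_as_missing: bool = True
    require_all_taxa_present: bool = True

    def __post_init__(self) -> None:
        if self.missing_policy not in ("strict", "tolerate_k"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        if self.max_missing < 0:
            raise ValueError("max_missing must be >= 0")

    @classmethod
    def from_string(cls, text: str) -> "ScreenPolicy":
        """Parse "strict" or "tolerate:K"."""
        if text == "strict":
            return cls()
        if text.startswith("tolerate:"):
            return cls(missing_policy="tolerate_k", max_missing=int(text.split(":", 1)[1]),
                       require_all_taxa_present=False)
        raise ValueError(f"unknown policy {text!r} (expected 'strict' or 'tolerate:K')")


@dataclass(frozen=True)
class ConvergentSite:
    """One qualifying column: background residue shared by all background
    taxa, a different foreground residue shared by all foreground taxa."""

    gene_id: str
    column: int
    ref_position: int | None
    bg_residue: str
    fg_residue: str

    def __post_init__(self) -> None:
        if self.bg_residue not in _STANDARD or self.fg_residue not in _STANDARD:
            raise ValueError(f"{self.gene_id}:{self.column}: non-standard residue call")
        if self.bg_residue == self.fg_residue:
            raise ValueError(f"{self.gene_id}:{self.column}: bg and fg residues equal")


def classify_column(column: dict[str, str], partition: TaxonPartition,
                    policy: ScreenPolicy = ScreenPolicy()) -> tuple[str, str] | None:
    """Classify one alignment column; returns (bg_residue, fg_residue) for a
    convergent call, else None."""
    unknown = set(column) - partition.taxa
    if unknown:
        raise UnknownTaxonError(f"column contains taxa outside the partition: {sorted(unknown)}")

    missing_chars = {"-", "*"}
    if policy.treat_x_as_missing:
        missing_chars.add("X")

    n_missing = 0
    bg_residues: set[str] = set()
    fg_residues: set[str] = set()
    for taxon in partition.taxa:
        char = column.get(taxon)
        if char is None or char in missing_chars or char not in _STANDARD:
            n_missing += 1
            continue
        if taxon in partition.foreground:
            fg_residues.add(char)
        else:
            bg_residues.add(char)

    if policy.missing_policy == "strict":
        if n_missing > 0:
            return None
    else:
        if n_missing > policy.max_missing:
            return None
    if len(bg_residues) != 1 or len(fg_residues) != 1:
        return None
    (bg,) = bg_residues
    (fg,) = fg_residues
    if bg == fg:
        return None
    return bg, fg


def scan_alignment(aln: GeneAlignment, partition: TaxonPartition,
                   policy: ScreenPolicy = ScreenPolicy(),
                   ref_taxon: str | None = None) -> list[ConvergentSite]:
    """Scan every column of a protein alignment; returns qualifying sites in
    ascending column order, with positions mapped onto ``ref_taxon``'s
    ungapped coordinates when a reference is given."""
    if aln.seq_type != PROTEIN:
        raise TypeError(f"{aln.gene_id}: screen requires a protein alignment")
    present = set(aln.taxa)
    absent = partition.taxa - present
    if absent and policy.require_all_taxa_present:
        raise ValueError(f"{aln.gene_id}: partition taxa missing from alignment: {sorted(absent)}")
    if ref_taxon is not None and ref_taxon not in present:
        raise KeyError(f"{aln.gene_id}: reference taxon {ref_taxon!r} not in alignment")

    rows = {t: r for t, r in zip(aln.taxa, aln.rows) if t in partition.taxa}
    sites: list[ConvergentSite] = []
    for col in range(1, aln.length + 1):
        column = {t: r[col - 1] for t, r in rows.items()}
        call = classify_column(column, partition, policy)
        if call is None:
            continue
        ref_pos = (map_column_to_reference(aln, col, ref_taxon)
                   if ref_taxon is not None else None)
        sites.append(ConvergentSite(aln.gene_id, col, ref_pos, call[0], call[1]))
    return sites


def screen_genes(alignments: list[GeneAlignment], partition: TaxonPartition,
                 policy: ScreenPolicy = ScreenPolicy(),
                 ref_taxon: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the screen over a gene set.

    Returns ``(sites, genes)``: one row per convergent site ordered by
    (gene_id, column), and one row per gene with at least one site.
    """
    ids = [a.gene_id for a in alignments]
    if len(set(ids)) != len(ids):
        dup = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene ids in input: {dup}")
    records = []
    for aln in sorted(alignments, key=lambda a: a.gene_id):
        for site in scan_alignment(aln, partition, policy, ref_taxon):
            records.append({
                "gene_id": site.gene_id,
                "column": site.column,
                "ref_position": site.ref_position,
                "bg_residue": site.bg_residue,
                "fg_residue": site.fg_residue,
            })
    sites = pd.DataFrame(records,
                         columns=["gene_id", "column", "ref_position",
                                  "bg_residue", "fg_residue"])
    if sites.empty:
        genes = pd.DataFrame(columns=["gene_id", "n_sites"])
    else:
        genes = (sites.groupby("gene_id", as_index=False).size()
                 .rename(columns={"size": "n_sites"})
                 .sort_values("gene_id", ignore_index=True))
    return sites, genes
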