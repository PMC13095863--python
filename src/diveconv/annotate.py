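"""Domain overlap of convergent sites and term over-representation.

Domain intervals (e.g. exported from SMART/InterPro) are user-supplied
protein coordinates of the same reference taxon used for site positions.
Term enrichment is a one-sided (over-representation) hypergeometric test
over user-supplied gene -> term assignments with Benjamini–Hochberg
correction; the term database itself is an input, never downloaded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .io_model import DomainInterval
from .screen import ConvergentSite
from .selection import bh_fdr


@dataclass(frozen=True)
class TermAssignment:
    gene_id: str
    term_id: str
    term_name: str = ""


def read_terms(path) -> list[TermAssignment]:
    """Read gene->term TSV (header; gene_id, term_id[, term_name])."""
    out = []
    seen = set()
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
            key = (parts[0], parts[1])
            if key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate assignment {key}")
            seen.add(key)
            out.append(TermAssignment(parts[0], parts[1],
                                      parts[2] if len(parts) > 2 else ""))
    return out


def overlap_sites_domains(sites: list[ConvergentSite],
                          domains: list[DomainInterval]) -> pd.DataFrame:
    """Label each convergent site with every same-gene domain containing its
    reference position (inclusive bounds).

    Sites lacking a reference position are skipped with a warning.  Output
    has one row per site (``domain`` empty when none covers it) plus a
    ``within_domain`` flag, sorted by (gene_id, ref_position, domain).
    """
    by_gene: dict[str, list[DomainInterval]] = {}
    for d in domains:
        by_gene.setdefault(d.gene_id, []).append(d)
    rows = []
    for site in sites:
        if site.ref_position is None:
            warnings.warn(f"{site.gene_id}: site at column {site.column} has no "
                          "reference position; skipped", stacklevel=2)
            continue
        covering = sorted(d.domain_name for d in by_gene.get(site.gene_id, [])
                          if d.contains(site.ref_position))
        base = {
            "gene_id": site.gene_id,
            "ref_position": site.ref_position,
            "bg_residue": site.bg_residue,
            "fg_residue": site.fg_residue,
            "within_domain": bool(covering),
        }
        if covering:
            for name in covering:
                rows.append({**base, "domain": name})
        else:
            rows.append({**base, "domain": ""})
    df = pd.DataFrame(rows, columns=["gene_id", "ref_position", "bg_residue",
                                     "fg_residue", "within_domain", "domain"])
    return df.sort_values(["gene_id", "ref_position", "domain"], ignore_index=True)


def hypergeom_pvalue(k: int, big_k: int, n: int, big_m: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k] for X ~ HG(M, K, n):
    drawing n genes from a universe of M containing K term members."""
    if not (0 <= k <= min(big_k, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={big_k}, n={n}")
    if big_k > big_m or n > big_m:
        raise ValueError(f"require K <= M and n <= M; got K={big_k}, n={n}, M={big_m}")
    return float(hypergeom.sf(k - 1, big_m, big_k, n))


def enrich_terms(flagged: set[str], assignments: list[TermAssignment],
                 universe: set[str]) -> pd.DataFrame:
    """Over-representation test of each term among the flagged genes.

    One row per term with at least one flagged gene, with hypergeometric p
    and BH q across the tested terms, sorted by (p, term_id).  Assignments
    to genes outside the universe are ignored.
    """
    flagged = set(flagged)
    universe = set(universe)
    stray = flagged - universe
    if stray:
        raise ValueError(f"flagged genes absent from universe: {sorted(stray)}")
    by_term: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for a in assignments:
        if a.gene_id not in universe:
            continue
        by_term.setdefault(a.term_id, set()).add(a.gene_id)
        if a.term_name:
            names.setdefault(a.term_id, a.term_name)
    big_m, n = len(universe), len(flagged)
    rows = []
    for term_id in sorted(by_term):
        members = by_term[term_id]
        k = len(members & flagged)
        if k == 0:
            continue
        rows.append({
            "term_id": term_id,
            "term_name": names.get(term_id, ""),
            "k": k, "K": len(members), "n": n, "M": big_m,
            "p_value": hypergeom_pvalue(k, len(members), n, big_m),
        })
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "M", "p_value"])
    if not df.empty:
        df["q_value"] = bh_fdr(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "term_id"], ignore_index=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df
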