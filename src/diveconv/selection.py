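"""Counting-based foreground/background selection scan plus LRT/FDR machinery.

This is an explicitly labeled desk-scale stand-in for a maximum-likelihood
branch-site analysis: ancestral codons are assigned by Fitch parsimony
(each codon treated as a single 61-state character), per-branch synonymous
and nonsynonymous changes are counted over minimal stop-free mutational
pathways, expected site counts follow Nei–Gojobori-style neighbor
enumeration, and significance of the foreground/background contrast
Delta = log(omega_fg / omega_bg) comes from a tip-relabeling permutation
null.  For externally computed likelihood pairs (e.g. codeml branch-site
fits), `lrt_pvalue` and `bh_fdr` apply the chi-square likelihood-ratio test
and Benjamini–Hochberg correction, with FDR-corrected p < 0.05 as the
positive-selection call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from ._codon import NONSYN_SITES, SYN_SITES, codon_indices, path_change_counts
from .io_model import NUCLEOTIDE, GeneAlignment, Phylogeny, TaxonPartition

FDR_THRESHOLD = 0.05


@dataclass
class BranchClassSummary:
    """Substitution and site counts aggregated over one branch class."""

    branch_class: str  # "foreground" | "background"
    nd: float  # nonsynonymous substitutions
    sd: float  # synonymous substitutions
    n_sites: float  # expected nonsynonymous sites (mean over branches)
    s_sites: float  # expected synonymous sites (mean over branches)
    total_branch_length: float

    @property
    def omega(self) -> float | None:
        """(Nd/N)/(Sd/S); None when no synonymous substitutions observed."""
        if self.sd == 0 or self.s_sites == 0 or self.n_sites == 0:
            return None
        return (self.nd / self.n_sites) / (self.sd / self.s_sites)


@dataclass
class SelectionResult:
    gene_id: str
    omega_fg: float | None
    omega_bg: float | None
    delta: float | None  # log(omega_fg / omega_bg)
    p_value: float
    q_value: float | None = None
    flagged: bool = False
    undefined: bool = False


@dataclass
class LRTRecord:
    gene_id: str
    lnl0: float
    lnl1: float
    statistic: float
    df: int
    p_value: float
    q_value: float | None = None


# ---------------------------------------------------------------------------
# Fitch parsimony over 61-state codon characters


def _fitch_column(tree: Phylogeny, postorder: list[int],
                  children: list[list[int]], tip_state: dict[int, int]) -> np.ndarray:
    """Fitch small parsimony for one codon column.

    State sets are bitmasks over the 61 sense codons; lexicographic
    tie-breaks fall out of picking the lowest set bit, since codons are
    indexed in lexicographic order.  Top-down resolution prefers the
    parent's state when it is in the node's set.
    """
    n = len(tree.labels)
    masks = [0] * n
    for i in postorder:
        if tree.is_tip[i]:
            masks[i] = 1 << int(tip_state[i])
        else:
            inter = ~0
            union = 0
            for c in children[i]:
                inter &= masks[c]
                union |= masks[c]
            masks[i] = inter if inter else union
    states = np.empty(n, dtype=np.int16)
    for i in range(n):  # preorder: parents precede children
        if tree.is_tip[i]:
            states[i] = tip_state[i]
            continue
        p = tree.parent[i]
        if p >= 0 and (masks[i] >> int(states[p])) & 1:
            states[i] = states[p]
        else:
            states[i] = (masks[i] & -masks[i]).bit_length() - 1
    return states


def _tree_arrays(tree: Phylogeny):
    n = len(tree.labels)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(1, n):
        children[tree.parent[i]].append(i)
    postorder = list(range(n - 1, -1, -1))  # reverse preorder
    return postorder, children


def fitch_ancestral_codons(aln: GeneAlignment, tree: Phylogeny) -> dict[str, str]:
    """Assign ancestral codon sequences to every node by Fitch parsimony.

    Requires a gapless codon alignment whose taxa match the tree tips.
    Returns node label -> codon sequence (tips echo their observed rows).
    """
    if aln.seq_type != NUCLEOTIDE or aln.length % 3 != 0:
        raise TypeError(f"{aln.gene_id}: need a codon-aligned nucleotide alignment")
    if any("-" in row or "N" in row for row in aln.rows):
        raise ValueError(f"{aln.gene_id}: gapped/ambiguous alignment; run QC first")
    if set(aln.taxa) != set(tree.tip_names):
        raise ValueError(f"{aln.gene_id}: alignment taxa do not match tree tips")
    states = _ancestral_states(aln, tree)
    from ._codon import indices_to_seq
    return {tree.labels[i]: indices_to_seq(states[i]) for i in range(len(tree.labels))}


def _ancestral_states(aln: GeneAlignment, tree: Phylogeny) -> np.ndarray:
    """(n_nodes, n_codons) array of codon indices from Fitch parsimony."""
    n = len(tree.labels)
    tip_of = {lab: i for i, lab in enumerate(tree.labels) if tree.is_tip[i]}
    n_codons = aln.length // 3
    tip_states = np.empty((n, n_codons), dtype=np.int16)
    for taxon, row in zip(aln.taxa, aln.rows):
        tip_states[tip_of[taxon]] = codon_indices(row)
    postorder, children = _tree_arrays(tree)
    tip_rows = [i for i in range(n) if tree.is_tip[i]]

    states = np.empty((n, n_codons), dtype=np.int16)
    # invariant columns (the common case on short branches) short-circuit
    col_min = tip_states[tip_rows].min(axis=0)
    col_max = tip_states[tip_rows].max(axis=0)
    invariant = col_min == col_max
    states[:, invariant] = tip_states[tip_rows[0], invariant]
    for k in np.nonzero(~invariant)[0]:
        tip_state = {i: int(tip_states[i, k]) for i in tip_rows}
        states[:, k] = _fitch_column(tree, postorder, children, tip_state)
    return states


# ---------------------------------------------------------------------------
# counting


def ng_site_counts(sequence: str | np.ndarray) -> tuple[float, float]:
    """Expected (nonsynonymous, synonymous) site counts of a gapless codon
    sequence, by single-nucleotide neighbor enumeration; changes to stop
    codons count toward neither class."""
    idx = codon_indices(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    return float(NONSYN_SITES[idx].sum()), float(SYN_SITES[idx].sum())


def count_branch_changes(parent_codon: str, child_codon: str) -> tuple[float, float]:
    """Fractional (nonsynonymous, synonymous) substitution counts between
    two sense codons, averaged over minimal stop-free pathways."""
    from ._codon import CODON_INDEX
    return path_change_counts(CODON_INDEX[parent_codon], CODON_INDEX[child_codon])


@dataclass
class _BranchStats:
    """Per-branch substitution/site statistics of one gene, reusable across
    foreground relabelings (the Fitch assignment is partition-free)."""

    branch_node: np.ndarray  # preorder node index of each branch's child node
    nd: np.ndarray
    sd: np.ndarray
    n_sites: np.ndarray  # mean of endpoint sequences
    s_sites: np.ndarray
    lengths: np.ndarray
    tip_branch: dict[str, int]  # tip name -> row in the arrays

    def class_summary(self, fg_tips: frozenset[str]) -> tuple[BranchClassSummary, BranchClassSummary]:
        fg_rows = np.array([self.tip_branch[t] for t in sorted(fg_tips)], dtype=int)
        mask = np.zeros(len(self.nd), dtype=bool)
        mask[fg_rows] = True
        out = []
        for cls, m in (("foreground", mask), ("background", ~mask)):
            out.append(BranchClassSummary(
                branch_class=cls,
                nd=float(self.nd[m].sum()),
                sd=float(self.sd[m].sum()),
                n_sites=float(self.n_sites[m].mean()) if m.any() else 0.0,
                s_sites=float(self.s_sites[m].mean()) if m.any() else 0.0,
                total_branch_length=float(self.lengths[m].sum()),
            ))
        return out[0], out[1]


def _branch_stats(aln: GeneAlignment, tree: Phylogeny) -> _BranchStats:
    states = _ancestral_states(aln, tree)
    n = len(tree.labels)
    nodes = list(range(1, n))  # every non-root node subtends a branch
    nd = np.zeros(len(nodes))
    sd = np.zeros(len(nodes))
    n_sites = np.zeros(len(nodes))
    s_sites = np.zeros(len(nodes))
    lengths = np.zeros(len(nodes))
    tip_branch: dict[str, int] = {}
    for row, i in enumerate(nodes):
        p = tree.parent[i]
        diff = np.nonzero(states[p] != states[i])[0]
        for k in diff:
            d_nd, d_sd = path_change_counts(int(states[p, k]), int(states[i, k]))
            nd[row] += d_nd
            sd[row] += d_sd
        n_p, s_p = ng_site_counts(states[p])
        n_c, s_c = ng_site_counts(states[i])
        n_sites[row] = 0.5 * (n_p + n_c)
        s_sites[row] = 0.5 * (s_p + s_c)
        lengths[row] = tree.lengths[i]
        if tree.is_tip[i]:
            tip_branch[tree.labels[i]] = row
    return _BranchStats(np.array(nodes), nd, sd, n_sites, s_sites, lengths, tip_branch)


def omega_by_class(aln: GeneAlignment, tree: Phylogeny,
                   partition: TaxonPartition) -> tuple[BranchClassSummary, BranchClassSummary]:
    """Counting-based omega per branch class.

    Foreground = terminal branches of the foreground tips; background = all
    other branches (internal branches included).
    """
    missing = partition.taxa - set(tree.tip_names)
    if missing:
        raise ValueError(f"partition taxa not in tree: {sorted(missing)}")
    stats = _branch_stats(aln, tree)
    return stats.class_summary(partition.foreground)


def _delta(fg: BranchClassSummary, bg: BranchClassSummary) -> float | None:
    """log(omega_fg/omega_bg); None when either omega is undefined (Sd=0),
    -inf/+inf when a numerator Nd is zero."""
    if fg.omega is None or bg.omega is None:
        return None
    if fg.omega == 0.0 and bg.omega == 0.0:
        return None
    if fg.omega == 0.0:
        return -math.inf
    if bg.omega == 0.0:
        return math.inf
    return math.log(fg.omega / bg.omega)


def permutation_test(aln: GeneAlignment, tree: Phylogeny, partition: TaxonPartition,
                     n_perm: int = 999, seed: int = 0,
                     _stats: _BranchStats | None = None) -> SelectionResult:
    """Tip-relabeling permutation test of elevated foreground omega.

    The null redraws a uniformly random foreground tip set of the original
    size and recomputes Delta; p = (1 + #{Delta_perm >= Delta_obs}) /
    (1 + n_perm).  Genes where Delta is undefined (no synonymous changes in
    a class) report p = 1 with the ``undefined`` flag.  Permutation Deltas
    that are themselves undefined are treated as +inf (conservative).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    tips = sorted(set(tree.tip_names))
    k = len(partition.foreground)
    if k >= len(tips):
        raise ValueError("foreground size equals tip count; no permutation space")
    stats = _stats if _stats is not None else _branch_stats(aln, tree)
    fg, bg = stats.class_summary(partition.foreground)
    delta_obs = _delta(fg, bg)
    if delta_obs is None:
        return SelectionResult(aln.gene_id, fg.omega, bg.omega, None,
                               p_value=1.0, undefined=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        subset = frozenset(rng.choice(tips, size=k, replace=False))
        pfg, pbg = stats.class_summary(subset)
        d = _delta(pfg, pbg)
        if d is None or d >= delta_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return SelectionResult(aln.gene_id, fg.omega, bg.omega, delta_obs, p_value=p)


def selection_scan(alignments: list[GeneAlignment], tree: Phylogeny,
                   partition: TaxonPartition, n_perm: int = 999, seed: int = 0,
                   fdr: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Permutation selection scan over a gene set with BH correction.

    Genes with FDR-corrected p below ``fdr`` are flagged as candidate
    positively selected genes.  Per-gene permutation seeds derive from the
    master seed.
    """
    results: list[SelectionResult] = []
    gene_seeds = np.random.SeedSequence(seed).generate_state(max(len(alignments), 1)) % (2 ** 31)
    for g_seed, aln in zip(gene_seeds, sorted(alignments, key=lambda a: a.gene_id)):
        results.append(permutation_test(aln, tree, partition, n_perm=n_perm, seed=int(g_seed)))
    if results:
        q = bh_fdr([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            r.flagged = bool(qv < fdr and not r.undefined)
    return pd.DataFrame([{
        "gene_id": r.gene_id,
        "omega_fg": r.omega_fg,
        "omega_bg": r.omega_bg,
        "delta": r.delta,
        "p_value": r.p_value,
        "q_value": r.q_value,
        "flagged": r.flagged,
        "undefined": r.undefined,
    } for r in results])


# ---------------------------------------------------------------------------
# LRT / FDR machinery


def lrt_pvalue(lnl0: float, lnl1: float, df: int = 1, mixture: bool = False) -> float:
    """Likelihood-ratio test p-value for nested codon models.

    The statistic 2(lnL1 - lnL0) is clamped at zero (boundary fits can make
    the alternative apparently worse) and referred to a chi-square with
    ``df`` degrees of freedom, or to the 50:50 point-mass/chi2_1 mixture
    when ``mixture`` is set.
    """
    if not (math.isfinite(lnl0) and math.isfinite(lnl1)):
        raise ValueError("log-likelihoods must be finite")
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = max(0.0, 2.0 * (lnl1 - lnl0))
    if mixture:
        return 1.0 if stat == 0.0 else 0.5 * float(chi2.sf(stat, 1))
    return float(chi2.sf(stat, df))


def lrt_table(records: list[tuple[str, float, float]], df: int = 1,
              mixture: bool = False, fdr: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Apply the LRT + BH decision rule to (gene_id, lnL0, lnL1) triples."""
    rows = []
    for gene_id, lnl0, lnl1 in records:
        stat = max(0.0, 2.0 * (lnl1 - lnl0))
        rows.append(LRTRecord(gene_id, lnl0, lnl1, stat, df,
                              lrt_pvalue(lnl0, lnl1, df=df, mixture=mixture)))
    q = bh_fdr([r.p_value for r in rows]) if rows else []
    for r, qv in zip(rows, q):
        r.q_value = float(qv)
    return pd.DataFrame([{
        "gene_id": r.gene_id, "lnl0": r.lnl0, "lnl1": r.lnl1,
        "statistic": r.statistic, "df": r.df, "p_value": r.p_value,
        "q_value": r.q_value, "significant": r.q_value < fdr,
    } for r in rows])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
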