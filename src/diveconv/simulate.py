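"""Phylogenetic sequence simulation with ground truth.

Two modes:

* **protein** — 20-state reversible model, by default uniform stationary
  frequencies and uniform exchangeabilities (a Poisson/JC-style model whose
  analytic expectations are easy to verify).  Used to exercise the
  convergence screen.
* **codon** — GY94-style model over the 61 sense codons with a
  transition/transversion ratio kappa and a nonsynonymous/synonymous rate
  ratio omega that may differ between background branches and the terminal
  branches of a designated foreground tip set.  Used to exercise the
  selection scan.

Sites evolve independently down the tree via the exact transition kernel
``expm(Q t)`` per branch, so output is exact (no Gillespie discretization)
and fully determined by the seed.  Convergent columns can be planted on top
of a simulated protein alignment, with the planted truth recorded for
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.linalg import expm

from . import _codon
from ._codon import AMINO_ACIDS, CODON_AA, N_CODONS, SENSE_CODONS, is_transition
from .io_model import (
    NUCLEOTIDE,
    PROTEIN,
    GeneAlignment,
    Phylogeny,
    TaxonPartition,
)


@dataclass
class ModelConfig:
    """Parameters of the simulated substitution process.

    In codon mode, ``omega_fg`` applies to the terminal branches of
    ``foreground_tips`` and ``omega_bg`` everywhere else; both default to a
    typical purifying value.  ``kappa`` defaults to 1 so that the default
    model has uniform exchangeabilities in both modes (a deliberately plain
    stated world whose stationary behavior is analytically checkable);
    realistic transition/transversion bias is a configuration choice.
    ``length`` counts sites in protein mode and codons in codon mode.
    """

    mode: str = PROTEIN
    length: int = 300
    pi: np.ndarray | None = None
    kappa: float = 1.0
    omega_bg: float = 0.2
    omega_fg: float | None = None
    foreground_tips: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (PROTEIN, "codon"):
            raise ValueError(f"unknown mode {self.mode!r}")
        n_states = 20 if self.mode == PROTEIN else N_CODONS
        if self.pi is None:
            self.pi = np.full(n_states, 1.0 / n_states)
        else:
            self.pi = np.asarray(self.pi, dtype=float)
            if self.pi.shape != (n_states,):
                raise ValueError(f"pi must have length {n_states}")
            if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-9:
                raise ValueError("pi must be non-negative and sum to 1 within 1e-9")
        for name in ("kappa", "omega_bg"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if self.omega_fg is None:
            self.omega_fg = self.omega_bg
        if not (np.isfinite(self.omega_fg) and self.omega_fg > 0):
            raise ValueError(f"omega_fg must be finite and positive, got {self.omega_fg}")
        self.foreground_tips = frozenset(self.foreground_tips)
        if self.length < 1:
            raise ValueError("length must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth of one simulated gene: planted convergent columns
    (1-based, with background/foreground residues) and the omega values
    actually used per branch class."""

    gene_id: str
    planted_columns: list[tuple[int, str, str]] = field(default_factory=list)
    omega_fg: float | None = None
    omega_bg: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for col, bg, fg in self.planted_columns:
            if bg == fg:
                raise ValueError(f"{self.gene_id}: planted column {col} has bg == fg")


def build_rate_matrix(config: ModelConfig, omega: float | None = None) -> np.ndarray:
    """Instantaneous rate matrix Q of the configured process.

    Codon mode: q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous] for
    codon pairs differing at exactly one nucleotide, 0 otherwise.  Protein
    mode: uniform exchangeabilities, q_ij = pi_j.  Rows sum to zero and Q is
    scaled so the expected substitution rate at stationarity is 1 per site.
    """
    pi = config.pi
    if config.mode == PROTEIN:
        q = np.tile(pi, (20, 1)).astype(float)
        np.fill_diagonal(q, 0.0)
    else:
        if omega is None:
            omega = config.omega_bg
        q = np.zeros((N_CODONS, N_CODONS))
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                if i == j:
                    continue
                diff = [p for p in range(3) if ci[p] != cj[p]]
                if len(diff) != 1:
                    continue
                rate = pi[j]
                p = diff[0]
                if is_transition(ci[p], cj[p]):
                    rate *= config.kappa
                if CODON_AA[i] != CODON_AA[j]:
                    rate *= omega
                q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total rate)")
    return q / scale


class _KernelCache:
    """Cumulative transition-probability rows per (rate matrix, branch length).

    expm is the dominant cost when many genes share one tree, so kernels are
    memoized across genes.
    """

    def __init__(self) -> None:
        self._cache: dict[tuple[int, float], np.ndarray] = {}

    def cumulative(self, q: np.ndarray, t: float) -> np.ndarray:
        # keyed by matrix content: id() is unsafe because freed arrays'
        # addresses are reused across genes
        key = (hash(q.tobytes()), float(t))
        if key not in self._cache:
            p = expm(q * t)
            np.clip(p, 0.0, None, out=p)
            p /= p.sum(axis=1, keepdims=True)
            self._cache[key] = np.cumsum(p, axis=1)
        return self._cache[key]


def _sample_states(cum_rows: np.ndarray, parents: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(parents.shape[0])
    rows = cum_rows[parents]
    return (rows < u[:, None]).sum(axis=1).astype(parents.dtype)


def _states_to_rows(states: np.ndarray, mode: str) -> str:
    if mode == PROTEIN:
        lut = np.array(list(AMINO_ACIDS))
        return "".join(lut[states])
    return "".join(SENSE_CODONS[s] for s in states)


def simulate_gene(tree: Phylogeny, config: ModelConfig, gene_id: str = "g0001",
                  _kernels: _KernelCache | None = None) -> tuple[GeneAlignment, TruthRecord]:
    """Evolve one gene along the tree; returns the tip alignment and truth.

    The root sequence is drawn from the stationary distribution; each branch
    then evolves every site independently through the exact transition
    kernel.  Randomness derives from per-node streams spawned from
    ``config.seed`` so output is reproducible node by node.
    """
    unknown = config.foreground_tips - set(tree.tip_names)
    if unknown:
        raise ValueError(f"foreground tips not in tree: {sorted(unknown)}")
    kernels = _kernels or _KernelCache()
    q_bg = build_rate_matrix(config, omega=config.omega_bg if config.mode == "codon" else None)
    q_fg = q_bg
    if config.mode == "codon" and config.omega_fg != config.omega_bg:
        q_fg = build_rate_matrix(config, omega=config.omega_fg)

    n_nodes = len(tree.labels)
    gene_entropy = int.from_bytes(gene_id.encode(), "big") % (2 ** 31)
    states = np.empty((n_nodes, config.length), dtype=np.int16)
    root_rng = np.random.default_rng(np.random.SeedSequence([config.seed, gene_entropy, 0]))
    cum_pi = np.cumsum(config.pi)
    states[0] = (cum_pi < root_rng.random(config.length)[:, None]).sum(axis=1)

    for i in range(1, n_nodes):
        is_fg_branch = tree.is_tip[i] and tree.labels[i] in config.foreground_tips
        q = q_fg if is_fg_branch else q_bg
        t = tree.lengths[i]
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, gene_entropy, i]))
        if t == 0.0:
            states[i] = states[tree.parent[i]]
        else:
            cum = kernels.cumulative(q, t)
            states[i] = _sample_states(cum, states[tree.parent[i]], rng)

    taxa = [lab for lab, tip in zip(tree.labels, tree.is_tip) if tip]
    tip_idx = [i for i, tip in enumerate(tree.is_tip) if tip]
    rows = [_states_to_rows(states[i], config.mode) for i in tip_idx]
    seq_type = PROTEIN if config.mode == PROTEIN else NUCLEOTIDE
    aln = GeneAlignment(gene_id, taxa, rows, seq_type,
                        codon_aligned=(seq_type == NUCLEOTIDE))
    truth = TruthRecord(gene_id, [], omega_fg=config.omega_fg,
                        omega_bg=config.omega_bg, seed=config.seed)
    return aln, truth


def plant_convergent_sites(aln: GeneAlignment, partition: TaxonPartition,
                           n_sites: int, seed: int) -> tuple[GeneAlignment, TruthRecord]:
    """Overwrite ``n_sites`` distinct columns of a protein alignment with a
    perfect convergent pattern: one residue in every background row, a
    different residue in every foreground row.  Returns the modified
    alignment plus the planted truth."""
    if aln.seq_type != PROTEIN:
        raise ValueError("plant_convergent_sites requires a protein alignment")
    if n_sites > aln.length:
        raise ValueError(f"cannot plant {n_sites} sites in alignment of length {aln.length}")
    rng = np.random.default_rng(seed)
    planted: list[tuple[int, str, str]] = []
    rows = {t: list(r) for t, r in zip(aln.taxa, aln.rows)}
    if n_sites > 0:
        cols = sorted(rng.choice(aln.length, size=n_sites, replace=False) + 1)
        for col in cols:
            bg_res, fg_res = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
            for taxon in aln.taxa:
                if taxon in partition.foreground:
                    rows[taxon][col - 1] = fg_res
                elif taxon in partition.background:
                    rows[taxon][col - 1] = bg_res
            planted.append((int(col), str(bg_res), str(fg_res)))
    new = GeneAlignment(aln.gene_id, list(aln.taxa),
                        ["".join(rows[t]) for t in aln.taxa], PROTEIN)
    return new, TruthRecord(aln.gene_id, planted, seed=seed)


def plant_convergent_codon_columns(aln: GeneAlignment, partition: TaxonPartition,
                                   n_sites: int, seed: int) -> tuple[GeneAlignment, TruthRecord]:
    """Codon-level analogue of :func:`plant_convergent_sites`: overwrite
    whole codon columns so that, after translation, the protein alignment
    carries a perfect convergent pattern at those amino-acid positions.

    Planted columns in the truth are protein (codon-column) positions.
    The lexicographically smallest codon of each residue is used, keeping
    planted rows deterministic and in-frame.
    """
    if aln.seq_type != NUCLEOTIDE or not aln.codon_aligned:
        raise ValueError("codon planting requires a codon-aligned nucleotide alignment")
    n_codons = aln.length // 3
    if n_sites > n_codons:
        raise ValueError(f"cannot plant {n_sites} sites in {n_codons} codons")
    first_codon = {}
    for codon, aa in zip(SENSE_CODONS, CODON_AA):
        first_codon.setdefault(aa, codon)
    rng = np.random.default_rng(seed)
    planted: list[tuple[int, str, str]] = []
    rows = {t: list(r) for t, r in zip(aln.taxa, aln.rows)}
    if n_sites > 0:
        cols = sorted(rng.choice(n_codons, size=n_sites, replace=False) + 1)
        for col in cols:
            bg_res, fg_res = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
            for taxon in aln.taxa:
                res = fg_res if taxon in partition.foreground else bg_res
                rows[taxon][(col - 1) * 3:(col - 1) * 3 + 3] = list(first_codon[str(res)])
            planted.append((int(col), str(bg_res), str(fg_res)))
    new = GeneAlignment(aln.gene_id, list(aln.taxa),
                        ["".join(rows[t]) for t in aln.taxa], NUCLEOTIDE,
                        codon_aligned=True)
    return new, TruthRecord(aln.gene_id, planted, seed=seed)


def simulate_dataset(tree: Phylogeny, configs: ModelConfig | list[ModelConfig],
                     n_genes: int, seed: int) -> list[tuple[GeneAlignment, TruthRecord]]:
    """Simulate ``n_genes`` genes with ids g0001..gNNNN.

    ``configs`` is a single ModelConfig applied to every gene or a list of
    length ``n_genes``.  Per-gene seeds are derived deterministically from
    the master seed; each gene's config seed is overridden.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if isinstance(configs, ModelConfig):
        configs = [configs] * n_genes
    if len(configs) != n_genes:
        raise ValueError(f"expected {n_genes} configs, got {len(configs)}")
    kernels = _KernelCache()
    out = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n_genes) % (2 ** 31)
    for k in range(n_genes):
        gene_id = f"g{k + 1:04d}"
        cfg = replace(configs[k], seed=int(child_seeds[k]))
        out.append(simulate_gene(tree, cfg, gene_id=gene_id, _kernels=kernels))
    return out


def write_truth_tsv(truths: list[TruthRecord], path: str | Path) -> None:
    """Truth table: one row per planted column; genes without planted
    columns get a single row with empty column fields."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcolumn\tbg_residue\tfg_residue\tomega_fg\tomega_bg\tseed\n")
        for tr in truths:
            om_fg = "" if tr.omega_fg is None else f"{tr.omega_fg:g}"
            om_bg = "" if tr.omega_bg is None else f"{tr.omega_bg:g}"
            if tr.planted_columns:
                for col, bg, fg in tr.planted_columns:
                    fh.write(f"{tr.gene_id}\t{col}\t{bg}\t{fg}\t{om_fg}\t{om_bg}\t{tr.seed}\n")
            else:
                fh.write(f"{tr.gene_id}\t\t\t\t{om_fg}\t{om_bg}\t{tr.seed}\n")
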