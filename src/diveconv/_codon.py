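"""Genetic-code tables and codon-level counting primitives.

Everything here is derived from the standard (universal) genetic code as
shipped with Biopython.  The 61 sense codons form the state space used by
both the codon simulator and the counting-based selection scan; the three
stop codons (TAA, TAG, TGA) are excluded, so mutational pathways through a
stop are impossible by construction.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]

#: the 61 sense codons of the standard code, in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
           if c not in _table.stop_codons)
)
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

#: amino acid (one-letter) encoded by each sense codon, aligned with SENSE_CODONS
CODON_AA: tuple[str, ...] = tuple(_table.forward_table[c] for c in SENSE_CODONS)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True when the nucleotide change a<->b is a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def translate_codon(codon: str) -> str:
    """One sense codon -> amino acid; stop codons raise KeyError."""
    return CODON_AA[CODON_INDEX[codon]]


def _neighbors(codon: str):
    """Yield (position, alt_codon) for the 9 single-nucleotide neighbors."""
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                yield pos, codon[:pos] + nt + codon[pos + 1:]


def _site_counts() -> tuple[np.ndarray, np.ndarray]:
    """Per-codon expected nonsynonymous (N) and synonymous (S) site counts.

    Each of the three codon positions contributes count/3 per neighbor class;
    changes into stop codons count toward neither class, so N + S for a codon
    equals 3 minus the stop-neighbor fraction.
    """
    n_sites = np.zeros(N_CODONS)
    s_sites = np.zeros(N_CODONS)
    for i, codon in enumerate(SENSE_CODONS):
        aa = CODON_AA[i]
        for _pos, alt in _neighbors(codon):
            if alt in STOP_CODONS:
                continue
            if translate_codon(alt) == aa:
                s_sites[i] += 1.0 / 3.0
            else:
                n_sites[i] += 1.0 / 3.0
    return n_sites, s_sites


#: expected nonsynonymous / synonymous site counts per sense codon
NONSYN_SITES, SYN_SITES = _site_counts()


@lru_cache(maxsize=None)
def path_change_counts(ci: int, cj: int) -> tuple[float, float]:
    """Fractional (nonsynonymous, synonymous) substitution counts between two
    sense codons, averaged over minimal single-step mutational pathways.

    Pathways whose intermediate codons are stops are excluded from the
    average.  In the rare case where every ordering of the differing
    positions passes through a stop, all pathways are used and any step into
    or out of a stop codon is counted as nonsynonymous (the amino acid
    necessarily changes).
    """
    a, b = SENSE_CODONS[ci], SENSE_CODONS[cj]
    diff = [p for p in range(3) if a[p] != b[p]]
    if not diff:
        return 0.0, 0.0

    def walk(order):
        nd = sd = 0.0
        cur = a
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            cur_aa = CODON_AA[CODON_INDEX[cur]] if cur not in STOP_CODONS else "*"
            nxt_aa = CODON_AA[CODON_INDEX[nxt]] if nxt not in STOP_CODONS else "*"
            if nxt in STOP_CODONS:
                ok = False
            if cur_aa == nxt_aa:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return nd, sd, ok

    results = [walk(order) for order in itertools.permutations(diff)]
    valid = [(nd, sd) for nd, sd, ok in results if ok]
    if not valid:
        valid = [(nd, sd) for nd, sd, _ok in results]
    nd = sum(v[0] for v in valid) / len(valid)
    sd = sum(v[1] for v in valid) / len(valid)
    return nd, sd


def codon_indices(seq: str) -> np.ndarray:
    """Encode a gapless in-frame nucleotide sequence as sense-codon indices."""
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    idx = np.empty(len(seq) // 3, dtype=np.int16)
    for k in range(0, len(seq), 3):
        codon = seq[k:k + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at nucleotide position {k + 1}")
        try:
            idx[k // 3] = CODON_INDEX[codon]
        except KeyError:
            raise ValueError(f"unrecognized codon {codon!r} at nucleotide position {k + 1}")
    return idx


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)
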