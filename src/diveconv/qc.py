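"""Alignment quality control and CDS translation.

Two exclusion rules are applied to codon alignments before any screening:
aligned length below 150 nt, and presence of alignment gaps.  By default
the rules act independently (either one excludes a gene); a combined mode
requiring both is available since the choice is a convention, and the
report always records every violated rule so either reading can be
recovered downstream.

A pairwise identity/coverage filter (identity >= 0.70 and coverage >= 0.50
of the reference CDS) is provided for CDS extracted from whole-genome
alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._codon import STOP_CODONS, translate_codon
from .io_model import NUCLEOTIDE, PROTEIN, GeneAlignment

MIN_LENGTH_NT = 150
MIN_IDENTITY = 0.70
MIN_COVERAGE = 0.50


class FrameError(ValueError):
    """CDS length not divisible by 3."""


class InternalStopError(ValueError):
    """Stop codon before the final codon of a CDS."""


class ModeError(TypeError):
    """Operation applied to the wrong sequence type."""


@dataclass
class QCReport:
    gene_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)
    length_nt: int = 0
    gap_count: int = 0
    identity: float | None = None
    coverage: float | None = None

    def __post_init__(self) -> None:
        if self.passed != (not self.reasons):
            raise ValueError("passed must be true iff reasons is empty")


def translate_cds(seq: str) -> str:
    """Translate an in-frame CDS with the standard genetic code.

    Codons containing N or a gap translate to "X".  A terminal stop codon is
    dropped; a stop anywhere else raises :class:`InternalStopError`.
    """
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise FrameError(f"CDS length {len(seq)} is not a multiple of 3")
    n_codons = len(seq) // 3
    out = []
    for k in range(n_codons):
        codon = seq[3 * k:3 * k + 3]
        if "N" in codon or "-" in codon:
            out.append("X")
        elif codon in STOP_CODONS:
            if k == n_codons - 1:
                break
            raise InternalStopError(
                f"internal stop codon {codon} at codon {k + 1} of {n_codons}")
        else:
            out.append(translate_codon(codon))
    return "".join(out)


def translate_alignment(aln: GeneAlignment) -> GeneAlignment:
    """Row-wise translation of a codon alignment to a protein alignment."""
    if aln.seq_type != NUCLEOTIDE:
        raise ModeError(f"{aln.gene_id}: translation requires a nucleotide alignment")
    if aln.length % 3 != 0:
        raise FrameError(f"{aln.gene_id}: aligned length {aln.length} not a multiple of 3")
    rows = []
    for taxon, row in zip(aln.taxa, aln.rows):
        try:
            rows.append(translate_cds(row))
        except InternalStopError as exc:
            raise InternalStopError(f"{aln.gene_id}/{taxon}: {exc}") from exc
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        # terminal-stop dropping desynchronized the rows; pad back
        target = max(lengths)
        rows = [r + "X" * (target - len(r)) for r in rows]
    return GeneAlignment(aln.gene_id, list(aln.taxa), rows, PROTEIN)


def qc_gene_alignment(aln: GeneAlignment, min_length_nt: int = MIN_LENGTH_NT,
                      rule: str = "or") -> QCReport:
    """Apply the length and gap exclusion rules to one codon alignment.

    ``rule="or"`` (default) excludes a gene violating either rule;
    ``rule="and"`` excludes only genes violating both.  All violated rules
    are always recorded in ``reasons``.
    """
    if aln.seq_type != NUCLEOTIDE:
        raise ModeError(f"{aln.gene_id}: QC requires a nucleotide codon alignment")
    if rule not in ("or", "and"):
        raise ValueError(f"unknown QC rule {rule!r}")
    reasons = []
    gap_count = sum(row.count("-") for row in aln.rows)
    if aln.length < min_length_nt:
        reasons.append("too_short")
    if gap_count > 0:
        reasons.append("contains_gaps")
    if aln.length % 3 != 0:
        reasons.append("not_codon_multiple")
    if rule == "and" and reasons in (["too_short"], ["contains_gaps"]):
        # combined mode: one violated rule alone does not exclude
        reasons = []
    return QCReport(aln.gene_id, passed=not reasons, reasons=reasons,
                    length_nt=aln.length, gap_count=gap_count)


def identity_coverage_filter(query_aligned: str, ref_aligned: str, ref_full_length: int,
                             min_identity: float = MIN_IDENTITY,
                             min_coverage: float = MIN_COVERAGE) -> tuple[float, float, bool]:
    """Pairwise identity/coverage filter for an aligned query/reference pair.

    Identity is matches over columns where both rows are non-gap; coverage
    is the non-gap reference length within the aligned region over the full
    ungapped reference length.  Passing requires identity >= 0.70 and
    coverage >= 0.50 (inclusive thresholds).
    """
    if len(query_aligned) != len(ref_aligned):
        raise ValueError("aligned rows differ in length")
    if ref_full_length < 1:
        raise ValueError("ref_full_length must be >= 1")
    comparable = matches = ref_cols = 0
    for q, r in zip(query_aligned.upper(), ref_aligned.upper()):
        if r != "-":
            ref_cols += 1
        if q != "-" and r != "-":
            comparable += 1
            if q == r:
                matches += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) columns; identity undefined")
    identity = matches / comparable
    coverage = ref_cols / ref_full_length
    return identity, coverage, identity >= min_identity and coverage >= min_coverage
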