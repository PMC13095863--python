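# Methods

This note documents the models and conventions behind `diveconv`: what each
stage computes, the defaults and why, what the synthetic data does and does
not emulate, and the known limitations.

## Study design

The analysis contrasts a **foreground** lineage set — here the terminal
branches of 8 diving waterfowl, which fall in two separate clades of the
25-taxon Anseriformes phylogeny, so diving evolved independently more than
once — against a **background** of the 17 non-diving species plus all
internal branches. Two complementary signals are screened: columns where
the foreground fixed a residue absent from a uniform background
(convergent substitutions), and genes whose foreground branches
accumulated nonsynonymous change faster than synonymous change relative to
the background (positive-selection candidates).

## Alignment QC

Codon alignments are excluded when the aligned length is below **150 nt**
or when any row contains a gap. These are applied as two independent rules
by default (`qc_rule="or"`): gapped alignments are conventionally unusable
for codon-model input, so either violation excludes. The source analysis's
phrasing is compatible with requiring both; `qc_rule="and"` recovers that
reading, and the report always records every violated rule so either
interpretation can be reconstructed from `qc_report.tsv`. A pairwise CDS
filter (identity ≥ 0.70 over columns where both rows are ungapped;
coverage ≥ 0.50 of the full ungapped reference CDS; both thresholds
inclusive) is provided for orthologs extracted from whole-genome
alignments. The identity denominator excludes gap-containing columns and
the coverage denominator is the full reference CDS length — the paper-style
thresholds come without definitions, and these are the most common
conventions.

Translation uses the standard genetic code; codons containing `N` or `-`
translate to `X`, a terminal stop is silently dropped, and an internal stop
excludes the gene with an explicit `internal_stop` reason rather than a
silent drop.

## Convergence screen

`classify_column` calls a column iff (i) all background taxa share one
standard residue X, (ii) all foreground taxa share one standard residue Y,
(iii) X ≠ Y, and (iv) the missing-data policy holds. The foreground must be
*uniform*: a single deviating diving species vetoes the call. Under the
default **strict** policy any gap, `X`, `*`, or absent taxon anywhere in
the column vetoes; this is the natural reading for single-copy ortholog
sets where every species is expected present. `tolerate:K` relaxes this to
at most K missing taxa per column, with the remaining taxa still required
to be class-uniform — any use of it is an explicit, logged deviation.
Coordinates are reported 1-based in the ungapped frame of a user-chosen
reference taxon (the well-annotated mallard by default); a site whose
reference row is gapped gets no reference position and is skipped by the
domain-overlap stage with a warning.

Ordering is lexicographic by (gene, column) throughout so outputs diff
cleanly across runs.

## Selection scan (counting stand-in)

The scan deliberately replaces maximum-likelihood branch-site machinery
with transparent counting; it is labeled as such and is *not* a codeml
reimplementation:

1. **Ancestral codons** by Fitch small parsimony, each codon one 61-state
   character (bitmask set operations; bottom-up intersection/union,
   top-down preferring the parent's state, ties broken lexicographically by
   codon). Parsimony ignores branch lengths; at the small divergences the
   simulator targets (≲ 0.03 subs/site per branch) inferred counts track
   the true history closely (verified against the simulator's truth).
2. **Per-branch counts**: for a parent/child codon pair differing at k
   positions, (nd, sd) is averaged over the k! single-step pathways that
   avoid stop codons; nd + sd = k always. If every ordering passes through
   a stop (rare), all orderings are used with stop-crossing steps counted
   as nonsynonymous.
3. **Expected sites** per sequence by neighbor enumeration: each codon
   position contributes count/3 per class over its single-nucleotide
   changes, with changes into stops counting toward neither class, so
   N + S = 3·(codons) − (stop-neighbor fraction). A branch's N, S are the
   means of its two endpoint sequences; a class's N, S are means over its
   branches (so they stay on the per-gene scale).
4. **ω per class** = (Nd/N)/(Sd/S), foreground = terminal branches of the
   foreground tips, background = everything else. With Sd = 0 the ratio is
   reported as undefined (never ∞) and such genes are never flagged.
5. **Permutation null** for Δ = log(ω̂_fg/ω̂_bg): foreground tip sets of
   the original size are redrawn uniformly at random,
   p = (1 + #{Δ_perm ≥ Δ_obs})/(1 + n_perm). Per-branch counts are computed
   once per gene and only re-aggregated per permutation, so n_perm = 999
   (the default) costs milliseconds. Permutation Δ that is itself undefined
   counts as ≥ Δ_obs (conservative). Type-I error at α = 0.05 is inside the
   binomial band under ω-homogeneous simulation (see the acceptance suite).
6. **Decision rule**: Benjamini–Hochberg across the gene set, flag at
   q < 0.05 — the same rule applied to externally supplied lnL pairs by the
   LRT path, where the statistic is max(0, 2(lnL1 − lnL0)) referred to
   χ²(df). df defaults to 1; the 50:50 point-mass/χ²₁ boundary mixture is
   available via `mixture=True` since the appropriate null for boundary
   hypotheses is a judgment call.

No multiple-hit correction is applied to the counts: the intended regime is
desk-scale divergence where saturation is negligible. Expect downwardly
biased ω at deep divergences.

## Sequence simulator

Sites evolve independently down the tree through the exact transition
kernel `expm(Q t)` per branch — no Gillespie discretization error — with
the root drawn from the stationary distribution. Protein mode uses a
20-state model with uniform π and uniform exchangeabilities by default;
codon mode is a GY94-style model over the 61 sense codons (stop codons are
excluded from the state space, so pathways through stops cannot arise),
with transition/transversion ratio κ and nonsynonymous/synonymous ratio ω,
where ω may differ between the foreground terminal branches (ω_fg) and
everything else (ω_bg). Q is scaled to one expected substitution per site
per unit branch length at stationarity, separately per branch class, so
elevated ω_fg changes the *composition*, not the amount, of foreground
change.

Defaults, chosen once: uniform π; **κ = 1** (uniform exchangeabilities in
both modes — the plainest analytically checkable world; realistic
transition bias, e.g. κ ≈ 2–4 for avian nuclear genes, is a configuration
choice, and note that the unweighted site counting above is biased when the
generating κ ≠ 1); ω_bg = 0.2, a typical purifying value; gene lengths of
300 amino acids / 200–2000 codons depending on use. The bundled 25-taxon
tree follows waterfowl taxonomy (divers in two clades) but its branch
lengths are **invented** at magnitudes typical of waterfowl nuclear
divergence (0.003–0.03 subs/site); it is a synthetic stand-in, not an
estimate. Randomness flows from a single master seed through per-gene and
per-node `SeedSequence` streams, so datasets are byte-reproducible and
per-gene results do not depend on execution order.

Convergent columns are **planted** by overwriting whole columns (protein
mode) or whole codon columns (demo) with one background and one different
foreground residue; planting therefore guarantees the strict screening
criterion by construction, which is what makes sensitivity-1.0 recovery a
meaningful implementation check rather than a statistical claim.

What the simulator does *not* emulate: indels and alignment error, rate
heterogeneity across sites (no Γ), site-class mixtures of a true
branch-site process, codon-usage or GC bias, orthology-inference error. A
green recovery test therefore establishes that the screen implements its
criterion exactly, not that the criterion is robust to real-data
messiness; the strict policy's behavior under missing data must be judged
separately (it vetoes, trading sensitivity for zero false convergence
calls from gaps).

## Enrichment and annotation

Domain intervals are 1-based inclusive protein coordinates in the same
reference frame as the reported site positions; coordinate consistency
between the two inputs is the user's responsibility. Term enrichment is a
one-sided (over-representation) hypergeometric test with BH correction —
the enrichment statistic of the original analysis is unstated, so this is
a reconstruction, and the background universe must be supplied explicitly
(it defaults in the pipeline to all genes passing QC).

## Numerical and edge-case choices

- Transition kernels are clipped at 0 and row-renormalized to absorb
  `expm` round-off; kernels are cached by matrix content and branch length.
- Branch lengths absent from a Newick file default to 0.0 with a warning; a
  zero-length branch copies the parent state exactly.
- `.` gaps normalize to `-` on read; taxon matching is exact and
  case-sensitive.
- Duplicate gene ids, duplicate taxa, ragged alignments, taxa outside the
  partition, and partition/tree mismatches are hard errors, not warnings.
- Empty screen input yields an empty table (with a warning in the CLI),
  not an error.

## Limitations

- The counting scan is a screen, not an estimator of selection intensity:
  parsimony misattribution grows with divergence, and the permutation null
  assumes tip-set exchangeability of Δ under homogeneity (branch-length
  asymmetries enter only through the estimator, not the null).
- The convergence screen is a deterministic pattern match; it does not
  model the expected rate of convergent substitution under neutrality, so
  flagged sites are candidates, not significance calls.
- BH control is across genes within one run; combining runs requires
  re-correction by the user.
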