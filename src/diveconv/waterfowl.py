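"""Reference configuration for the diving-waterfowl analysis.

The study system: 25 Anseriformes species, of which 8 are diving foragers
(sea ducks, stifftails and allies) forming the foreground lineage set and
17 are non-diving (dabbling ducks, geese, swans) forming the background.
This module carries the species list, a synthetic stand-in species tree,
and the published set of convergent amino-acid replacements used as the
worked example, plus a builder that encodes each replacement as a toy
protein alignment for end-to-end checks of the screen.
"""

from __future__ import annotations

import numpy as np

from .io_model import PROTEIN, GeneAlignment, TaxonPartition, read_tree_newick

#: diving foragers — the foreground lineage set (terminal branches)
DIVING_TAXA: tuple[str, ...] = (
    "Bucephala_clangula",
    "Clangula_hyemalis",
    "Heteronetta_atricapilla",
    "Melanitta_perspicillata",
    "Mergus_serrator",
    "Nettapus_auritus",
    "Oxyura_jamaicensis",
    "Somateria_mollissima",
)

#: non-diving species (dabbling, grazing) — the background set
NON_DIVING_TAXA: tuple[str, ...] = (
    "Aix_galericulata",
    "Alopochen_aegyptiaca",
    "Anas_bernieri",
    "Anas_platyrhynchos",
    "Anser_anser",
    "Anser_cygnoides",
    "Anser_indicus",
    "Asarcornis_scutulata",
    "Branta_ruficollis",
    "Cygnus_olor",
    "Lophonetta_specularioides",
    "Mareca_falcata",
    "Mareca_strepera",
    "Sibirionetta_formosa",
    "Spatula_versicolor",
    "Speculanas_specularis",
    "Tadorna_tadorna",
)

ALL_TAXA: tuple[str, ...] = tuple(sorted(DIVING_TAXA + NON_DIVING_TAXA))

#: the well-annotated mallard genome serves as the coordinate reference
REFERENCE_TAXON = "Anas_platyrhynchos"

#: Convergent amino-acid replacements reported in diving Anseriformes:
#: (gene, protein position in the reference, background residue shared by
#: the 17 non-diving species, foreground residue shared by the 8 divers).
KNOWN_CONVERGENT_SUBSTITUTIONS: tuple[tuple[str, int, str, str], ...] = (
    ("ARNT2", 176, "V", "I"),
    ("CHST9", 246, "G", "S"),
    ("CRACDL", 492, "P", "S"),
    ("GPR34", 152, "V", "I"),
    ("KIF11", 975, "V", "M"),
    ("PKD1", 194, "T", "A"),
    ("PLB1", 209, "L", "M"),
    ("PLEKHG1", 1144, "A", "V"),
    ("SH3TC1", 1286, "T", "I"),
    ("SLIT3", 1067, "H", "R"),
    ("THADA", 144, "S", "P"),
)

#: Synthetic stand-in species tree.  The topology follows waterfowl
#: taxonomy — a goose/swan grade, a stifftail clade (Oxyura, Heteronetta)
#: plus Nettapus near the base of the ducks, a sea-duck clade (Mergini),
#: and the dabbling ducks — so the 8 divers fall in two separate clades, as
#: in the real phylogeny.  Branch lengths (substitutions/site) are invented
#: at magnitudes typical for waterfowl nuclear divergence, not estimated
#: from data.
DEFAULT_TREE_NEWICK = (
    "((((Anser_anser:0.008,Anser_cygnoides:0.008):0.004,Anser_indicus:0.010):0.006,"
    "Branta_ruficollis:0.015):0.012,"
    "((Oxyura_jamaicensis:0.022,Heteronetta_atricapilla:0.024):0.010,"
    "(Nettapus_auritus:0.030,"
    "((Cygnus_olor:0.025,(Alopochen_aegyptiaca:0.020,Tadorna_tadorna:0.018):0.006):0.005,"
    "(((Somateria_mollissima:0.012,(Melanitta_perspicillata:0.010,"
    "(Clangula_hyemalis:0.011,(Bucephala_clangula:0.009,Mergus_serrator:0.009):0.004):0.003):0.003):0.014,"
    "(Aix_galericulata:0.020,Asarcornis_scutulata:0.019):0.006):0.006,"
    "((Lophonetta_specularioides:0.014,Speculanas_specularis:0.013):0.005,"
    "((Mareca_falcata:0.007,Mareca_strepera:0.007):0.005,"
    "((Anas_platyrhynchos:0.006,Anas_bernieri:0.008):0.004,"
    "(Sibirionetta_formosa:0.010,Spatula_versicolor:0.011):0.003):0.003):0.004):0.008):0.007):0.004):0.008):0.010);"
)


def default_partition() -> TaxonPartition:
    """The 8 diving / 17 non-diving foreground-background bipartition."""
    return TaxonPartition(frozenset(DIVING_TAXA), frozenset(NON_DIVING_TAXA))


def default_tree():
    """The synthetic 25-taxon stand-in species tree."""
    return read_tree_newick(DEFAULT_TREE_NEWICK)


def _toy_alignment(gene_id: str, position: int, bg_res: str, fg_res: str,
                   rng: np.random.Generator) -> GeneAlignment:
    """Encode one reported replacement as a 25-taxon protein alignment:
    background rows carry ``bg_res`` and foreground rows ``fg_res`` at the
    stated position; every other column is invariant."""
    length = position + 20
    backbone = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length)
    rows = []
    for taxon in ALL_TAXA:
        row = backbone.copy()
        row[position - 1] = fg_res if taxon in DIVING_TAXA else bg_res
        rows.append("".join(row))
    return GeneAlignment(gene_id, list(ALL_TAXA), rows, PROTEIN)


def build_worked_example(n_decoys: int = 4, seed: int = 0) -> list[GeneAlignment]:
    """Toy gene set for the worked example: one alignment per reported
    convergent replacement plus ``n_decoys`` decoy genes whose columns are
    all invariant (no qualifying column)."""
    rng = np.random.default_rng(seed)
    alignments = [_toy_alignment(gene, pos, bg, fg, rng)
                  for gene, pos, bg, fg in KNOWN_CONVERGENT_SUBSTITUTIONS]
    for d in range(n_decoys):
        backbone = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        alignments.append(GeneAlignment(f"decoy{d + 1}", list(ALL_TAXA),
                                        [backbone] * len(ALL_TAXA), PROTEIN))
    return alignments
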