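"""The murine hematopoietic study system: cell panel, differentiation
hierarchy, lineage paths, and the fixed topology used for ancestral
reconstruction.

The panel is the classical hierarchy: LSK stem cells give rise to a myeloid
branch (CMP, which splits into GMP -> neutrophils/monocytes and MEP ->
erythroblasts/immature megakaryocytes) and a lymphoid branch (B, CD4+ T,
CD8+ T and NK cells).  Accessibility profiles exist for the stem cell, the
three myeloid progenitors and the eight differentiated cell types; the
lymphoid progenitor is not observed, so lymphoid lineage paths are a single
step from LSK to the terminal cell.
"""

from __future__ import annotations

import dendropy

from ._tree import parse_newick
from .data import CellType

__all__ = [
    "STEM", "PROGENITORS", "TERMINALS", "OBSERVED_CELLS", "ANALYSIS_CELLS",
    "CELL_ROLES", "cell_panel", "differentiation_tree",
    "resolved_differentiation_tree", "RESOLVED_DIFFERENTIATION_NEWICK",
    "UNOBSERVED_RESOLVED", "LINEAGE_PATHS",
    "lineage_paths", "CONSTRAINT_NEWICK", "constraint_tree",
    "PROGENITOR_NODES", "LYMPHOID_DELTA_TAXA", "MYELOID_DELTA_TAXA",
]

STEM = "LSK"
PROGENITORS = ("CMP", "GMP", "MEP")
TERMINALS = ("Neu", "Mon", "Ery", "iMK", "B", "TCD4", "TCD8", "NK")

#: Columns observable in the study design (lymphoid progenitor is not).
OBSERVED_CELLS = (STEM,) + PROGENITORS + TERMINALS

#: Leaves used for tree inference: differentiated cells plus the LSK
#: outgroup; progenitor columns are held out for validating reconstructions.
ANALYSIS_CELLS = (STEM,) + TERMINALS

CELL_ROLES = {STEM: "stem", **{p: "progenitor" for p in PROGENITORS},
              **{t: "terminal" for t in TERMINALS}}


def cell_panel() -> list[CellType]:
    return [CellType(n, CELL_ROLES[n]) for n in OBSERVED_CELLS]


#: Known differentiation hierarchy.  "Lym" is the unobserved lymphoid
#: progenitor; it appears in the generating tree but never as a data column.
DIFFERENTIATION_NEWICK = "(((Neu,Mon)GMP,(Ery,iMK)MEP)CMP,(B,TCD4,TCD8,NK)Lym)LSK;"


def differentiation_tree() -> dendropy.Tree:
    """The known hierarchy as a rooted tree; the root is the LSK stem cell
    and internal labels name progenitors."""
    return parse_newick(DIFFERENTIATION_NEWICK, rooted=True)


#: Fully binary variant of the hierarchy with the lymphoid polytomy resolved
#: as (B, ((TCD4, TCD8), NK)) -- the consistently inferred lymphoid
#: topology.  Used as the generating tree whenever exact topology recovery
#: is the question, since a polytomy leaves some splits without any signal.
RESOLVED_DIFFERENTIATION_NEWICK = (
    "(((Neu,Mon)GMP,(Ery,iMK)MEP)CMP,(B,((TCD4,TCD8)T48,NK)TNK)Lym)LSK;")

#: Internal lymphoid nodes that never appear as data columns.
UNOBSERVED_RESOLVED = ("Lym", "T48", "TNK")


def resolved_differentiation_tree() -> dendropy.Tree:
    return parse_newick(RESOLVED_DIFFERENTIATION_NEWICK, rooted=True)


#: The eight lineage paths (stem -> terminal) along which site time courses
#: are classified.  Myeloid paths include the observed progenitors; lymphoid
#: paths are one step because lymphoid progenitor data are unavailable.
LINEAGE_PATHS: dict[str, tuple[str, ...]] = {
    "Neu": (STEM, "CMP", "GMP", "Neu"),
    "Mon": (STEM, "CMP", "GMP", "Mon"),
    "Ery": (STEM, "CMP", "MEP", "Ery"),
    "iMK": (STEM, "CMP", "MEP", "iMK"),
    "B": (STEM, "B"),
    "TCD4": (STEM, "TCD4"),
    "TCD8": (STEM, "TCD8"),
    "NK": (STEM, "NK"),
}


def lineage_paths() -> dict[str, tuple[str, ...]]:
    return dict(LINEAGE_PATHS)


#: Fixed topology for ancestral reconstruction: the known myeloid hierarchy
#: joined with the consistently inferred lymphoid topology
#: (B, ((TCD4, TCD8), NK)), rooted on the LSK outgroup.  Internal labels tie
#: nodes to the progenitors they represent.
CONSTRAINT_NEWICK = ("(LSK,((B,((TCD4,TCD8),NK))Lym,"
                     "((Neu,Mon)GMP,(Ery,iMK)MEP)CMP)Ingroup);")


def constraint_tree() -> dendropy.Tree:
    return parse_newick(CONSTRAINT_NEWICK, rooted=True)


#: Internal node label -> progenitor cell whose observed profile validates it.
PROGENITOR_NODES = {"CMP": "CMP", "GMP": "GMP", "MEP": "MEP"}

#: Taxon sets for the treelikeness (delta-plot) comparison.
LYMPHOID_DELTA_TAXA = (STEM, "B", "TCD4", "TCD8", "NK")
MYELOID_DELTA_TAXA = (STEM, "Neu", "Mon", "Ery", "iMK")
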