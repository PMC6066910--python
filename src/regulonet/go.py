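"""GO cellular-component category enrichment and the category graph.

Given a gene→GO-CC annotation table and a classified DE contrast, each
category is scored by the same hypergeometric machinery as regulon scoring
(the smaller of the enrichment and depletion tails is reported with a sign:
positive for enrichment, negative for depletion), BH-corrected across
categories, and assembled into an undirected graph whose edges connect
categories sharing annotated genes in the universe, weighted by the number
of shared genes. Categories are tagged with a supercategory (cell surface,
cytoskeleton, or other) via an explicit, user-editable term map; GO graph
topology (is_a propagation) is deliberately not traversed — annotations are
taken as given.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .diffexpr import DEResult, bh_fdr
from .regulon import overlap_odds_ratio, overlap_pvalues

logger = logging.getLogger(__name__)

DEFAULT_MIN_CATEGORY_SIZE = 3
DEFAULT_DISPLAY_Q = 0.05

#: default term→supercategory map covering the plasma-membrane/extracellular
#: terms (cell_surface) and cytoskeletal terms (cytoskeleton); anything
#: unmapped is "other". Users pass their own map to override.
DEFAULT_SUPERCATEGORY_MAP: dict[str, str] = {
    "GO:0009986": "cell_surface",  # cell surface
    "GO:0005886": "cell_surface",  # plasma membrane
    "GO:0005887": "cell_surface",  # integral component of plasma membrane
    "GO:0031226": "cell_surface",  # intrinsic component of plasma membrane
    "GO:0098552": "cell_surface",  # side of membrane
    "GO:0009897": "cell_surface",  # external side of plasma membrane
    "GO:0005576": "cell_surface",  # extracellular region
    "GO:0005615": "cell_surface",  # extracellular space
    "GO:0031012": "cell_surface",  # extracellular matrix
    "GO:0062023": "cell_surface",  # collagen-containing extracellular matrix
    "GO:0005856": "cytoskeleton",  # cytoskeleton
    "GO:0015629": "cytoskeleton",  # actin cytoskeleton
    "GO:0015630": "cytoskeleton",  # microtubule cytoskeleton
    "GO:0005884": "cytoskeleton",  # actin filament
    "GO:0005874": "cytoskeleton",  # microtubule
    "GO:0005882": "cytoskeleton",  # intermediate filament
    "GO:0099513": "cytoskeleton",  # polymeric cytoskeletal fiber
    "GO:0032432": "cytoskeleton",  # actin filament bundle
}


class AnnotationParseError(ValueError):
    """Malformed annotation file line (message carries the line number)."""


class UnknownCategoryError(KeyError):
    """Category ID absent from the annotation table."""


@dataclass
class AnnotationTable:
    """gene → set of category IDs, plus optional human-readable names."""

    gene_to_categories: dict[str, set[str]] = field(default_factory=dict)
    category_names: dict[str, str] = field(default_factory=dict)

    @property
    def categories(self) -> set[str]:
        cats: set[str] = set()
        for cs in self.gene_to_categories.values():
            cats |= cs
        return cats

    def annotated_genes(self, category: str) -> set[str]:
        return {g for g, cs in self.gene_to_categories.items() if category in cs}

    def members_by_category(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, cats in self.gene_to_categories.items():
            for cat in cats:
                out.setdefault(cat, set()).add(gene)
        return out


@dataclass
class CategoryScore:
    """Signed enrichment/depletion statistics for one GO category."""

    category_id: str
    contrast_id: str
    name: str
    n_universe: int
    n_category: int
    k: int
    p_enrichment: float
    p_depletion: float
    p: float
    direction: str  # enriched | depleted | none
    q_value: float = math.nan
    signed_score: float = 0.0
    odds_ratio: float = math.nan
    supercategory: str = "other"


def load_annotations(
    path: str | Path,
    format: str = "two_column_tsv",
    names_path: str | Path | None = None,
) -> AnnotationTable:
    """Load gene→category annotations from a two-column TSV or a GAF subset.

    GAF rows are restricted to the cellular-component aspect (column 9 = "C").
    Gene symbols are upper-cased; duplicate (gene, category) pairs collapse.
    """
    path = Path(path)
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            if format == "two_column_tsv":
                if lineno == 1 and line.lower().startswith("gene\t"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                    raise AnnotationParseError(
                        f"{path.name}:{lineno}: expected gene<TAB>category, got {line!r}"
                    )
                gene, category = parts[0], parts[1]
            elif format == "gaf_subset":
                parts = line.split("\t")
                if len(parts) < 9:
                    raise AnnotationParseError(
                        f"{path.name}:{lineno}: GAF row needs >=9 columns"
                    )
                if parts[8].strip() != "C":
                    continue
                gene, category = parts[2], parts[4]
            else:
                raise ValueError(f"unknown annotation format: {format!r}")
            gene = gene.strip().upper()
            table.gene_to_categories.setdefault(gene, set()).add(category.strip())
    if not table.gene_to_categories:
        logger.warning("%s: empty annotation table", path.name)
    if names_path is not None:
        names = pd.read_csv(names_path, sep="\t", header=None, names=["id", "name"])
        table.category_names = dict(zip(names["id"], names["name"]))
    return table


def go_universe(de: DEResult, annotations: AnnotationTable) -> set[str]:
    """Background for GO scoring: tested genes carrying >=1 CC annotation."""
    return de.universe & set(annotations.gene_to_categories)


def score_category(
    category: str,
    de_set: set[str],
    annotations: AnnotationTable,
    universe: set[str],
    contrast_id: str = "contrast",
    min_category_size: int = DEFAULT_MIN_CATEGORY_SIZE,
) -> CategoryScore | None:
    """Hypergeometric enrichment/depletion of *de_set* in one category.

    Shares :func:`regulonet.regulon.overlap_pvalues` with regulon scoring so
    both analyses use the identical statistical core. The smaller tail is
    reported as ``p`` with matching sign semantics; q is filled later by
    :func:`score_categories`. Returns None (logged) when the category has
    fewer than ``min_category_size`` members in the universe.
    """
    if category not in annotations.categories:
        raise UnknownCategoryError(category)
    members = annotations.annotated_genes(category) & universe
    m = len(members)
    if m < min_category_size:
        logger.info("category %s skipped: %d member(s) < %d", category, m, min_category_size)
        return None
    de_set = de_set & universe
    n, n_de = len(universe), len(de_set)
    k = len(members & de_set)
    p_enr, p_depl = overlap_pvalues(n, n_de, m, k)
    if n_de == 0:
        direction, p = "none", 1.0
    elif p_enr <= p_depl:
        direction, p = "enriched", p_enr
    else:
        direction, p = "depleted", p_depl
    return CategoryScore(
        category_id=category,
        contrast_id=contrast_id,
        name=annotations.category_names.get(category, category),
        n_universe=n,
        n_category=m,
        k=k,
        p_enrichment=p_enr,
        p_depletion=p_depl,
        p=p,
        direction=direction,
        odds_ratio=overlap_odds_ratio(n, n_de, m, k),
    )


def score_categories(
    de: DEResult,
    annotations: AnnotationTable,
    de_set: set[str] | None = None,
    supercategory_map: Mapping[str, str] | None = None,
    min_category_size: int = DEFAULT_MIN_CATEGORY_SIZE,
) -> list[CategoryScore]:
    """Score all categories against the combined (or given) DE set.

    BH-FDR across categories; signed_score = -log10(q) for enrichment,
    +log10(q) (negative) for depletion, 0 when the DE set is empty. Output
    sorted by q then category ID (stable node numbering).
    """
    if supercategory_map is None:
        supercategory_map = DEFAULT_SUPERCATEGORY_MAP
    universe = go_universe(de, annotations)
    if de_set is None:
        de_set = de.up_set | de.down_set
    scores: list[CategoryScore] = []
    for category in sorted(annotations.categories):
        s = score_category(
            category, de_set, annotations, universe,
            contrast_id=de.contrast_id, min_category_size=min_category_size,
        )
        if s is not None:
            s.supercategory = supercategory_map.get(category, "other")
            scores.append(s)
    if not scores:
        return []
    qvals = bh_fdr([s.p for s in scores])
    for s, q in zip(scores, qvals):
        s.q_value = float(q)
        if s.direction == "enriched":
            s.signed_score = -math.log10(max(q, 1e-300))
        elif s.direction == "depleted":
            s.signed_score = math.log10(max(q, 1e-300))
        else:
            s.signed_score = 0.0
    scores.sort(key=lambda s: (s.q_value, s.category_id))
    return scores


def build_category_graph(
    scores: Sequence[CategoryScore],
    annotations: AnnotationTable,
    universe: set[str],
    supercategory_map: Mapping[str, str] | None = None,
    display_q: float = DEFAULT_DISPLAY_Q,
) -> nx.Graph:
    """Category graph: nodes passing the display filter, shared-gene edges.

    Edge weight = |annotated(c1) ∩ annotated(c2) ∩ universe|; pairs sharing
    no universe gene get no edge. Nodes carry signed_score, supercategory
    (shape class), q and member count.
    """
    if supercategory_map is None:
        supercategory_map = DEFAULT_SUPERCATEGORY_MAP
    shown = [s for s in scores if math.isfinite(s.q_value) and s.q_value <= display_q]
    members = {
        s.category_id: annotations.annotated_genes(s.category_id) & universe
        for s in shown
    }
    graph = nx.Graph()
    for s in shown:
        graph.add_node(
            s.category_id,
            name=s.name,
            signed_score=s.signed_score,
            q_value=s.q_value,
            supercategory=supercategory_map.get(s.category_id, s.supercategory),
            n_members=len(members[s.category_id]),
        )
    ids = [s.category_id for s in shown]
    for i, c1 in enumerate(ids):
        for c2 in ids[i + 1 :]:
            shared = len(members[c1] & members[c2])
            if shared >= 1:
                graph.add_edge(c1, c2, weight=shared)
    return graph


def category_scores_to_frame(scores: Sequence[CategoryScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": s.category_id,
                "name": s.name,
                "contrast": s.contrast_id,
                "n_category": s.n_category,
                "k": s.k,
                "p_enrichment": s.p_enrichment,
                "p_depletion": s.p_depletion,
                "p": s.p,
                "q": s.q_value,
                "direction": s.direction,
                "signed_score": s.signed_score,
                "supercategory": s.supercategory,
            }
            for s in scores
        ]
    )


def write_annotations(
    annotations: AnnotationTable, path: str | Path, names_path: str | Path | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcategory\n")
        for gene in sorted(annotations.gene_to_categories):
            for cat in sorted(annotations.gene_to_categories[gene]):
                fh.write(f"{gene}\t{cat}\n")
    if names_path is not None and annotations.category_names:
        with open(names_path, "w") as fh:
            for cat in sorted(annotations.category_names):
                fh.write(f"{cat}\t{annotations.category_names[cat]}\n")
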