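"""Regulon extraction, signed enrichment scoring, and network assembly.

A *regulon* is the set of known targets of one transcription factor (TF) in
an interaction database. For a given differential-expression contrast, each
regulon is tested by hypergeometric over-representation against the up- and
down-regulated gene sets (and by a lower-tail depletion test against the
combined DE set); the dominant tail gives a signed score,

    signed_score = -log10(FDR)   if the regulon is enriched among UP genes,
    signed_score = +log10(FDR)   (a negative number) if enriched among DOWN
                                 genes or depleted overall,

so positive scores mean the TF's targets are predominantly upregulated.
Regulons passing an FDR, minimum-overlap and odds-ratio gate are flagged
``selected`` and assembled, together with anchor genes (GATA2 by default),
into a directed TF→target network whose nodes carry the TF's own fold
change (size category U/NC/D) and signed score.

The data-driven selection rule used here (FDR ≤ α, dominant overlap ≥ k_min,
odds ratio ≥ OR_min) is this package's own definition of "functionally
relevant"; it is a pragmatic replacement for procedures whose details vary
between studies, not a reproduction of any particular one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import DEResult, bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_MIN_REGULON_SIZE = 3
DEFAULT_SELECT_ALPHA = 0.05
DEFAULT_MIN_OVERLAP = 3
DEFAULT_MIN_ODDS_RATIO = 2.0
#: |log2fc| at or above which a TF node is called U or D (1.5-fold)
DEFAULT_SIZE_CATEGORY_LFC = 0.585

DEFAULT_ANCHORS = frozenset({"GATA2"})


class UnknownRegulatorError(KeyError):
    """Requested TF is not a regulator in the interaction database."""


class InteractionParseError(ValueError):
    """Malformed interaction file line (message carries the line number)."""


@dataclass(frozen=True)
class InteractionDatabase:
    """A directed TF→target edge set defining regulons.

    ``edges`` holds ordered (regulator, target) pairs; duplicates and
    self-edges are disallowed by construction in the loaders/generators.
    """

    edges: frozenset[tuple[str, str]]
    source_labels: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for reg, tgt in self.edges:
            if reg == tgt:
                raise ValueError(f"self-edge not allowed: {reg}")

    @property
    def regulators(self) -> set[str]:
        return {r for r, _ in self.edges}

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.edges}

    @property
    def genes(self) -> set[str]:
        return self.regulators | self.targets

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class Regulon:
    tf_id: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if self.tf_id in self.targets:
            raise ValueError(f"regulon of {self.tf_id} contains itself")
        if not self.targets:
            raise ValueError(f"regulon of {self.tf_id} is empty")


@dataclass
class RegulonScore:
    """Signed enrichment/depletion statistics for one regulon in one contrast."""

    tf_id: str
    contrast_id: str
    n_universe: int
    n_regulon_in_universe: int
    k_up: int
    k_down: int
    p_up: float
    p_down: float
    p_depletion: float
    dominant_direction: str = "none"  # up | down | depleted | none
    q_value: float = math.nan
    signed_score: float = 0.0
    odds_ratio: float = math.nan
    tf_log2fc: float = math.nan
    tf_size_category: str = "NC"  # U | NC | D
    selected: bool = False

    @property
    def dominant_p(self) -> float:
        return {
            "up": self.p_up,
            "down": self.p_down,
            "depleted": self.p_depletion,
        }.get(self.dominant_direction, 1.0)

    @property
    def dominant_overlap(self) -> int:
        return {
            "up": self.k_up,
            "down": self.k_down,
            "depleted": self.k_up + self.k_down,
        }.get(self.dominant_direction, 0)


# ---------------------------------------------------------------------------
# loading and set algebra


def _upper(symbol: str) -> str:
    return symbol.strip().upper()


def load_interactions(path: str | Path, format: str = "tsv") -> InteractionDatabase:
    """Load a TF→target table from TSV (``regulator<TAB>target[<TAB>source]``)
    or SIF (``source relation target [target ...]``).

    Edges are deduplicated, symbols upper-cased, and self-edges dropped with
    a warning. An empty file yields a valid empty database (with a warning).
    """
    path = Path(path)
    edges: dict[tuple[str, str], str] = {}
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if format == "tsv":
                if lineno == 1 and line.lower().startswith("regulator\t"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                    raise InteractionParseError(
                        f"{path.name}:{lineno}: expected regulator<TAB>target, got {line!r}"
                    )
                source = parts[2] if len(parts) > 2 else ""
                pairs = [(parts[0], parts[1], source)]
            elif format == "sif":
                parts = line.split()
                if len(parts) < 3:
                    raise InteractionParseError(
                        f"{path.name}:{lineno}: SIF line needs source relation target(s), "
                        f"got {line!r}"
                    )
                relation = parts[1]
                pairs = [(parts[0], tgt, relation) for tgt in parts[2:]]
            else:
                raise ValueError(f"unknown interaction format: {format!r}")
            for reg, tgt, src in pairs:
                reg, tgt = _upper(reg), _upper(tgt)
                if reg == tgt:
                    n_self += 1
                    continue
                edges.setdefault((reg, tgt), src)
    if n_self:
        logger.warning("%s: dropped %d self-edge(s)", path.name, n_self)
    if not edges:
        logger.warning("%s: empty interaction database", path.name)
    return InteractionDatabase(edges=frozenset(edges), source_labels=edges)


def write_interactions(db: InteractionDatabase, path: str | Path) -> None:
    """Write the TSV dialect (sorted for determinism)."""
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tsource\n")
        for reg, tgt in sorted(db.edges):
            fh.write(f"{reg}\t{tgt}\t{db.source_labels.get((reg, tgt), '')}\n")


def regulon_of(db: InteractionDatabase, tf: str) -> set[str]:
    """All targets of *tf*; raises :class:`UnknownRegulatorError` if absent."""
    tf = _upper(tf)
    targets = {t for r, t in db.edges if r == tf}
    if not targets:
        raise UnknownRegulatorError(tf)
    return targets


def regulons(db: InteractionDatabase) -> dict[str, set[str]]:
    """All regulons keyed by TF (single pass over the edge set)."""
    out: dict[str, set[str]] = {}
    for reg, tgt in db.edges:
        out.setdefault(reg, set()).add(tgt)
    return out


def regulators_of(db: InteractionDatabase, gene: str) -> set[str]:
    """Upstream regulators of *gene*; empty set if none (never an error)."""
    gene = _upper(gene)
    return {r for r, t in db.edges if t == gene}


def common_regulators(db: InteractionDatabase, genes: Iterable[str]) -> set[str]:
    """Intersection of ``regulators_of`` over a nonempty gene collection."""
    genes = [_upper(g) for g in genes]
    if not genes:
        raise ValueError("common_regulators requires a nonempty gene set")
    common = regulators_of(db, genes[0])
    for gene in genes[1:]:
        common &= regulators_of(db, gene)
    return common


def regulators_per_gene(db: InteractionDatabase) -> pd.Series:
    """Number of upstream regulators per target gene (summary statistic)."""
    counts: dict[str, int] = {}
    for _, tgt in db.edges:
        counts[tgt] = counts.get(tgt, 0) + 1
    return pd.Series(counts, name="n_regulators").sort_index()


# ---------------------------------------------------------------------------
# shared hypergeometric core (also used by GO category scoring)


def overlap_pvalues(
    n_universe: int, n_successes: int, n_drawn: int, k: int
) -> tuple[float, float]:
    """Hypergeometric tail probabilities for a set-overlap of size *k*.

    Drawing ``n_drawn`` genes from a universe of ``n_universe`` containing
    ``n_successes`` marked genes, returns ``(P(X >= k), P(X <= k))`` —
    the enrichment (upper) and depletion (lower) tails.
    """
    if not 0 <= k <= min(n_drawn, n_successes):
        raise ValueError(
            f"impossible overlap k={k} for draw {n_drawn} / successes {n_successes}"
        )
    upper = float(hypergeom.sf(k - 1, n_universe, n_successes, n_drawn))
    lower = float(hypergeom.cdf(k, n_universe, n_successes, n_drawn))
    return min(upper, 1.0), min(lower, 1.0)


def overlap_odds_ratio(n_universe: int, n_successes: int, n_drawn: int, k: int) -> float:
    """Sample odds ratio of the 2x2 overlap table; inf when a null cell is 0."""
    a = k
    b = n_drawn - k
    c = n_successes - k
    d = n_universe - n_drawn - n_successes + k
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# scoring


def score_regulon(
    regulon: Regulon,
    de: DEResult,
    universe: set[str] | None = None,
    min_regulon_size: int = DEFAULT_MIN_REGULON_SIZE,
) -> RegulonScore | None:
    """Score one regulon against a classified DE result (q left NaN).

    The regulon is intersected with the tested-gene universe first; if fewer
    than ``min_regulon_size`` members remain the regulon is skipped (None,
    with a logged reason). Three tails are computed — up-enrichment,
    down-enrichment, and depletion of the combined DE set — and the smallest
    defines ``dominant_direction``. Ties break toward the larger overlap
    count, then toward ``up``.
    """
    universe = de.universe if universe is None else set(universe)
    members = set(regulon.targets) & universe
    m = len(members)
    if m < min_regulon_size:
        logger.info(
            "regulon %s skipped: %d member(s) in universe < %d",
            regulon.tf_id, m, min_regulon_size,
        )
        return None
    up = de.up_set & universe
    down = de.down_set & universe
    n = len(universe)
    k_up = len(members & up)
    k_down = len(members & down)
    p_up, _ = overlap_pvalues(n, len(up), m, k_up)
    p_down, _ = overlap_pvalues(n, len(down), m, k_down)
    n_de = len(up | down)
    _, p_depl = overlap_pvalues(n, n_de, m, k_up + k_down)

    if n_de == 0:
        dominant = "none"
    else:
        candidates = [
            ("up", p_up, k_up),
            ("down", p_down, k_down),
            ("depleted", p_depl, k_up + k_down),
        ]
        best_p = min(p for _, p, _ in candidates)
        tied = [c for c in candidates if c[1] == best_p]
        # ties: larger overlap wins, then the listed order (up first)
        tied.sort(key=lambda c: -c[2])
        dominant = tied[0][0]

    if dominant == "up":
        odds = overlap_odds_ratio(n, len(up), m, k_up)
    elif dominant == "down":
        odds = overlap_odds_ratio(n, len(down), m, k_down)
    elif dominant == "depleted":
        odds = overlap_odds_ratio(n, n_de, m, k_up + k_down)
    else:
        odds = math.nan

    tf = regulon.tf_id
    tf_lfc = float(de.table.at[tf, "log2fc"]) if tf in de.table.index else math.nan
    return RegulonScore(
        tf_id=tf,
        contrast_id=de.contrast_id,
        n_universe=n,
        n_regulon_in_universe=m,
        k_up=k_up,
        k_down=k_down,
        p_up=p_up,
        p_down=p_down,
        p_depletion=p_depl,
        dominant_direction=dominant,
        odds_ratio=odds,
        tf_log2fc=tf_lfc,
        tf_size_category=size_category(tf_lfc),
    )


def size_category(log2fc: float, threshold: float = DEFAULT_SIZE_CATEGORY_LFC) -> str:
    """U / NC / D call for a TF node from its own mRNA fold change."""
    if not np.isfinite(log2fc) or abs(log2fc) < threshold:
        return "NC"
    return "U" if log2fc > 0 else "D"


def score_contrast(
    db: InteractionDatabase,
    de: DEResult,
    min_regulon_size: int = DEFAULT_MIN_REGULON_SIZE,
    select_alpha: float = DEFAULT_SELECT_ALPHA,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_odds_ratio: float = DEFAULT_MIN_ODDS_RATIO,
) -> list[RegulonScore]:
    """Score every admissible regulon, BH-correct, sign, and select.

    BH-FDR is applied across regulons within this contrast using each
    regulon's dominant-direction p. ``signed_score`` is -log10(q) for
    up-dominant regulons (positive) and +log10(q) for down-dominant or
    depleted ones (negative). A regulon is ``selected`` when q <= alpha,
    its dominant overlap >= min_overlap, its odds ratio >= min_odds_ratio,
    and its dominant tail is an enrichment (up or down). Output is ordered
    by q then tf_id.
    """
    scores: list[RegulonScore] = []
    for tf, targets in sorted(regulons(db).items()):
        reg = Regulon(tf_id=tf, targets=frozenset(targets) - {tf})
        score = score_regulon(reg, de, min_regulon_size=min_regulon_size)
        if score is not None:
            scores.append(score)
    if not scores:
        logger.warning("contrast %s: no admissible regulons", de.contrast_id)
        return []

    qvals = bh_fdr([s.dominant_p for s in scores])
    for score, q in zip(scores, qvals):
        score.q_value = float(q)
        if score.dominant_direction == "none":
            score.signed_score = 0.0
        elif score.dominant_direction == "up":
            score.signed_score = -math.log10(max(q, 1e-300))
        else:
            score.signed_score = math.log10(max(q, 1e-300))
        score.selected = bool(
            score.dominant_direction in ("up", "down")
            and score.q_value <= select_alpha
            and score.dominant_overlap >= min_overlap
            and score.odds_ratio >= min_odds_ratio
        )
    scores.sort(key=lambda s: (s.q_value, s.tf_id))
    return scores


def scores_to_frame(scores: Sequence[RegulonScore]) -> pd.DataFrame:
    """Tabular form matching the regulon_scores.tsv interface."""
    return pd.DataFrame(
        [
            {
                "tf": s.tf_id,
                "contrast": s.contrast_id,
                "n_regulon": s.n_regulon_in_universe,
                "k_up": s.k_up,
                "k_down": s.k_down,
                "p_up": s.p_up,
                "p_down": s.p_down,
                "p_depletion": s.p_depletion,
                "q": s.q_value,
                "direction": s.dominant_direction,
                "signed_score": s.signed_score,
                "odds_ratio": s.odds_ratio,
                "tf_log2fc": s.tf_log2fc,
                "size_category": s.tf_size_category,
                "selected": s.selected,
            }
            for s in scores
        ]
    )


# ---------------------------------------------------------------------------
# network assembly


def build_network(
    db: InteractionDatabase,
    scores: Sequence[RegulonScore],
    de: DEResult,
    anchors: Iterable[str] = DEFAULT_ANCHORS,
    size_category_lfc: float = DEFAULT_SIZE_CATEGORY_LFC,
) -> nx.DiGraph:
    """Assemble the TF regulatory network for one contrast.

    Nodes are the selected TFs plus the anchor genes (GATA2 by default);
    edges are all database edges with both endpoints in that node set.
    Each node carries ``log2fc``, ``size_category`` and, when the gene was
    scored as a regulon, ``signed_score`` and ``selected``.
    """
    by_tf = {s.tf_id: s for s in scores}
    selected = {s.tf_id for s in scores if s.selected}
    anchors = {_upper(a) for a in anchors}
    node_set = selected | anchors

    graph = nx.DiGraph(contrast=de.contrast_id)
    for gene in sorted(node_set):
        lfc = float(de.table.at[gene, "log2fc"]) if gene in de.table.index else math.nan
        attrs = {
            "log2fc": lfc,
            "size_category": size_category(lfc, size_category_lfc),
            "anchor": gene in anchors,
        }
        score = by_tf.get(gene)
        if score is not None:
            attrs["signed_score"] = score.signed_score
            attrs["selected"] = score.selected
        elif gene in anchors and gene not in db.genes and gene not in de.table.index:
            logger.warning("anchor %s absent from database and DE result", gene)
        graph.add_node(gene, **attrs)
    for reg, tgt in sorted(db.edges):
        if reg in node_set and tgt in node_set:
            graph.add_edge(reg, tgt)
    return graph
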