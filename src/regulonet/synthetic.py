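"""Ground-truth synthetic data: interaction databases and NB count matrices.

This module emulates the kind of data the downstream analyses consume — a
public TF→target interaction resource and a bulk RNA-seq count matrix over
hematopoietic cell subsets (HE, non-HE, CD43+) in two genotypes (WT, KO) —
with every perturbation recorded as ground truth, so that calibration and
recovery of the whole pipeline can be tested without external data.

Counts are negative binomial with variance mu + alpha*mu^2 (dispersion
``alpha``), per-gene log-normal baselines, and log-uniform per-sample
library-size factors. Differential signal is *regulon structured*: an active
regulon applies a log2 fold change to a chosen fraction of its targets
between the two groups of a named contrast, which is how a master regulator
manifests in expression data.

The interaction generator draws regulon sizes from a truncated negative
binomial (minimum 3, mirroring the heavy tail of curated regulon databases),
shares targets through a common pool sampled per slot with probability
``regulon_overlap``, and guarantees that every target of the database is
covered by at least one regulator. ``regulon_overlap=1.0`` is the documented
degenerate case in which all regulons share one identical target set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix
from .regulon import InteractionDatabase, UnknownRegulatorError, regulons, write_interactions

logger = logging.getLogger(__name__)

MIN_REGULON_SIZE = 3
#: NB shape parameter for the regulon-size distribution (heavy-tailed)
REGULON_SIZE_SHAPE = 5.0


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    """One experimental condition: cell subset x genotype x dox, n replicates."""

    subset: str  # HE | nonHE | CD43pos (free-form)
    genotype: str  # WT | KO
    dox: str = "no"
    n_replicates: int = 3

    @property
    def label(self) -> str:
        dox = "_dox" if self.dox == "yes" else ""
        return f"{self.subset}_{self.genotype}{dox}"

    def sample_ids(self) -> list[str]:
        return [f"{self.label}_{r}" for r in range(1, self.n_replicates + 1)]


@dataclass(frozen=True)
class ContrastSpec:
    """Named contrast: B over A selectors on sample metadata."""

    contrast_id: str
    group_a: Mapping[str, str]
    group_b: Mapping[str, str]


@dataclass(frozen=True)
class ActiveRegulon:
    """A regulon perturbed in one contrast.

    ``lfc`` (log2 units) is applied to ``fraction_responsive`` of the
    regulon's targets in the contrast's group-B samples.
    """

    tf_id: str
    contrast_id: str
    lfc: float
    fraction_responsive: float = 1.0


@dataclass
class SimulationConfig:
    """Everything that defines one simulated study (fully seeded)."""

    n_genes: int = 2000
    groups: Sequence[GroupSpec] = field(
        default_factory=lambda: (
            GroupSpec("HE", "WT", n_replicates=3),
            GroupSpec("HE", "KO", n_replicates=3),
        )
    )
    contrasts: Sequence[ContrastSpec] = field(
        default_factory=lambda: (
            ContrastSpec(
                "HE_WT_vs_KO",
                group_a={"subset": "HE", "genotype": "KO"},
                group_b={"subset": "HE", "genotype": "WT"},
            ),
        )
    )
    active_regulons: Sequence[ActiveRegulon] = ()
    baseline_mean: float = 100.0  # median of the log-normal baseline (counts)
    baseline_sigma: float = 1.0  # log-normal spread of baselines
    dispersion: float = 0.1  # NB alpha: variance = mu + alpha*mu^2
    library_size_range: tuple[float, float] = (0.7, 1.4)
    perturb_tf_mrna: bool = True  # active TF's own mRNA shifts with its regulon
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise InvalidConfigError("dispersion must be > 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise InvalidConfigError("library_size_range must be 0 < lo <= hi")
        for ar in self.active_regulons:
            if not 0 < ar.fraction_responsive <= 1:
                raise InvalidConfigError("fraction_responsive must be in (0, 1]")


@dataclass
class GroundTruth:
    """Which genes and regulons were actually perturbed, per contrast."""

    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    active_regulons: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def truly_de(self, contrast_id: str) -> set[str]:
        return set(self.de_genes.get(contrast_id, {}))

    def truly_active(self, contrast_id: str) -> set[str]:
        return {tf for tf, _ in self.active_regulons.get(contrast_id, set())}


# ---------------------------------------------------------------------------
# interaction database generation


def _nb_sizes(rng: np.random.Generator, mean: float, n: int, lo: int, hi: int) -> np.ndarray:
    """Truncated-NB regulon sizes around *mean*, clipped to [lo, hi]."""
    r = REGULON_SIZE_SHAPE
    mu = max(mean, 1e-9)
    draws = rng.negative_binomial(r, r / (r + mu), size=n)
    return np.clip(draws, lo, hi).astype(int)


def generate_interaction_db(
    n_tfs: int,
    n_targets: int,
    mean_regulon_size: int,
    regulon_overlap: float,
    seed: int,
) -> InteractionDatabase:
    """Generate a deterministic TF→target database.

    ``n_targets`` is the size of the database's covered target universe:
    every target ends up in at least one regulon (uncovered targets are
    assigned to a random TF after the main draw). Target sharing between
    regulons is driven by a common pool of ``mean_regulon_size`` targets
    sampled per slot with probability ``regulon_overlap``.
    """
    if n_tfs < 1:
        raise InvalidConfigError("n_tfs must be >= 1")
    if mean_regulon_size > n_targets:
        raise InvalidConfigError(
            f"mean_regulon_size {mean_regulon_size} exceeds n_targets {n_targets}"
        )
    if not 0 <= regulon_overlap <= 1:
        raise InvalidConfigError("regulon_overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i:03d}" for i in range(1, n_tfs + 1)]
    targets = np.array([f"G{i:05d}" for i in range(1, n_targets + 1)])
    lo = min(MIN_REGULON_SIZE, n_targets)

    edges: set[tuple[str, str]] = set()
    if regulon_overlap >= 1.0:
        # degenerate full overlap: one shared target set for every TF
        size = int(_nb_sizes(rng, mean_regulon_size, 1, lo, n_targets)[0])
        shared = rng.choice(targets, size=size, replace=False)
        for tf in tfs:
            edges.update((tf, str(t)) for t in shared)
        return InteractionDatabase(edges=frozenset(edges))

    sizes = _nb_sizes(rng, mean_regulon_size, n_tfs, lo, n_targets)
    pool = rng.choice(targets, size=min(max(lo, mean_regulon_size), n_targets), replace=False)
    pool_set = set(pool)
    outside = np.array(sorted(set(targets) - pool_set))
    for tf, size in zip(tfs, sizes):
        n_shared = min(int(rng.binomial(size, regulon_overlap)), len(pool))
        n_private = min(size - n_shared, len(outside))
        chosen: list[str] = []
        if n_shared:
            chosen.extend(rng.choice(pool, size=n_shared, replace=False))
        if n_private:
            chosen.extend(rng.choice(outside, size=n_private, replace=False))
        edges.update((tf, str(t)) for t in chosen)

    covered = {t for _, t in edges}
    uncovered = [t for t in targets if t not in covered]
    for t in uncovered:
        edges.add((tfs[int(rng.integers(n_tfs))], str(t)))
    return InteractionDatabase(edges=frozenset(edges))


# ---------------------------------------------------------------------------
# count simulation


def _build_metadata(groups: Sequence[GroupSpec]) -> pd.DataFrame:
    rows = []
    for g in groups:
        for r, sample in enumerate(g.sample_ids(), start=1):
            rows.append(
                {"sample": sample, "subset": g.subset, "genotype": g.genotype,
                 "dox": g.dox, "replicate": r}
            )
    return pd.DataFrame(rows).set_index("sample")


def _match(metadata: pd.DataFrame, selector: Mapping[str, str]) -> list[str]:
    mask = pd.Series(True, index=metadata.index)
    for key, value in selector.items():
        mask &= metadata[key].astype(str) == str(value)
    return list(metadata.index[mask])


def simulate_counts(
    db: InteractionDatabase, config: SimulationConfig
) -> tuple[CountMatrix, GroundTruth]:
    """Draw a regulon-structured NB count matrix plus its ground truth.

    The gene universe is the database's regulators and targets padded with
    background genes (``BG#####``) up to ``config.n_genes``. For each active
    regulon the configured log2 fold change is applied multiplicatively to
    the mean of the responsive targets (and, by default, the TF's own mRNA)
    in the group-B samples of the named contrast. Identical config and seed
    give bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    regs = regulons(db)
    db_genes = sorted(db.genes)
    if config.n_genes < len(db_genes):
        raise InvalidConfigError(
            f"n_genes {config.n_genes} < genes in database {len(db_genes)}"
        )
    background = [f"BG{i:05d}" for i in range(1, config.n_genes - len(db_genes) + 1)]
    genes = db_genes + background
    metadata = _build_metadata(config.groups)
    samples = list(metadata.index)
    contrasts = {c.contrast_id: c for c in config.contrasts}

    baselines = config.baseline_mean * rng.lognormal(
        mean=0.0, sigma=config.baseline_sigma, size=len(genes)
    )
    lo, hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))

    gene_idx = {g: i for i, g in enumerate(genes)}
    sample_idx = {s: j for j, s in enumerate(samples)}
    log2_effect = np.zeros((len(genes), len(samples)))
    truth = GroundTruth()

    for ar in config.active_regulons:
        if ar.tf_id not in regs:
            raise UnknownRegulatorError(ar.tf_id)
        if ar.contrast_id not in contrasts:
            raise InvalidConfigError(f"unknown contrast: {ar.contrast_id!r}")
        contrast = contrasts[ar.contrast_id]
        b_samples = _match(metadata, contrast.group_b)
        members = sorted(regs[ar.tf_id])
        n_resp = max(1, int(round(ar.fraction_responsive * len(members))))
        responsive = list(rng.choice(members, size=n_resp, replace=False))
        perturbed = list(responsive)
        if config.perturb_tf_mrna:
            perturbed.append(ar.tf_id)
        cols = [sample_idx[s] for s in b_samples]
        for g in perturbed:
            log2_effect[gene_idx[g], cols] += ar.lfc
        de = truth.de_genes.setdefault(ar.contrast_id, {})
        for g in perturbed:
            de[g] = de.get(g, 0.0) + ar.lfc
        truth.active_regulons.setdefault(ar.contrast_id, set()).add(
            (ar.tf_id, "up" if ar.lfc > 0 else "down")
        )

    mu = baselines[:, None] * lib[None, :] * np.exp2(log2_effect)
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    return CountMatrix(counts=counts_df, metadata=metadata), truth


# ---------------------------------------------------------------------------
# canned study designs


def wt_ko_groups(subsets: Sequence[str] = ("HE", "nonHE", "CD43pos"), n_replicates: int = 3
                 ) -> tuple[GroupSpec, ...]:
    return tuple(
        GroupSpec(subset, genotype, n_replicates=n_replicates)
        for subset in subsets
        for genotype in ("WT", "KO")
    )


def wt_ko_contrasts(subsets: Sequence[str] = ("HE", "nonHE", "CD43pos")) -> tuple[ContrastSpec, ...]:
    """WT-over-KO contrast per cell subset (positive lfc = higher in WT)."""
    return tuple(
        ContrastSpec(
            f"{subset}_WT_vs_KO",
            group_a={"subset": subset, "genotype": "KO"},
            group_b={"subset": subset, "genotype": "WT"},
        )
        for subset in subsets
    )


def null_study(seed: int) -> tuple[InteractionDatabase, SimulationConfig]:
    """Global-null calibration study: no active regulons.

    2,000 genes, 100 TFs (regulons ~20 targets), one WT-vs-KO contrast at
    n=3/group — sized for type-I-error / FDR calibration runs.
    """
    db = generate_interaction_db(
        n_tfs=100, n_targets=1500, mean_regulon_size=20, regulon_overlap=0.1, seed=seed
    )
    config = SimulationConfig(
        n_genes=2000,
        groups=wt_ko_groups(subsets=("HE",), n_replicates=3),
        contrasts=wt_ko_contrasts(subsets=("HE",)),
        active_regulons=(),
        seed=seed,
    )
    return db, config


def recovery_study(
    seed: int, n_active: int = 5, lfc: float = 2.0, n_replicates: int = 4
) -> tuple[InteractionDatabase, SimulationConfig]:
    """Signal-recovery study: *n_active* fully responsive regulons at *lfc*.

    100 TFs with regulons around 50 targets; the first *n_active* TFs are
    activated in a single WT-vs-KO contrast (every target responsive), the
    rest stay null — sized for selection sensitivity / false-selection runs.
    """
    db = generate_interaction_db(
        n_tfs=100, n_targets=1800, mean_regulon_size=50, regulon_overlap=0.1, seed=seed
    )
    tfs = sorted(regulons(db))
    config = SimulationConfig(
        n_genes=2000,
        groups=wt_ko_groups(subsets=("HE",), n_replicates=n_replicates),
        contrasts=wt_ko_contrasts(subsets=("HE",)),
        active_regulons=tuple(
            ActiveRegulon(tf, "HE_WT_vs_KO", lfc=lfc, fraction_responsive=1.0)
            for tf in tfs[:n_active]
        ),
        seed=seed,
    )
    return db, config


def default_study(seed: int) -> tuple[InteractionDatabase, SimulationConfig]:
    """Full-scale emulation of a three-subset WT-vs-KO RNA-seq study.

    16,000 genes of which the interaction database covers 12,000 targets
    (150 TFs, regulons around 80 targets — dense, like comprehensive public
    resources), three cell subsets (HE, non-HE, CD43+) at n=3/group.
    Active-regulon counts and effect sizes are calibrated so the three
    detected DE sets land in the ~700–1,700-gene range such knockout
    studies report, smallest in the endothelial subsets and largest in
    CD43+ blood, with both up- and downregulated regulons per contrast.
    """
    db = generate_interaction_db(
        n_tfs=150, n_targets=12000, mean_regulon_size=80, regulon_overlap=0.05, seed=seed
    )
    tfs = sorted(regulons(db))
    n_active = {"HE_WT_vs_KO": 15, "nonHE_WT_vs_KO": 16, "CD43pos_WT_vs_KO": 26}
    active: list[ActiveRegulon] = []
    cursor = 0
    for contrast_id, n in n_active.items():
        for i in range(n):
            tf = tfs[(cursor + i) % len(tfs)]
            active.append(
                ActiveRegulon(
                    tf, contrast_id,
                    lfc=3.0 if i % 2 == 0 else -3.0,
                    fraction_responsive=0.8,
                )
            )
        cursor += n
    config = SimulationConfig(
        n_genes=16000,
        groups=wt_ko_groups(n_replicates=3),
        contrasts=wt_ko_contrasts(),
        active_regulons=tuple(active),
        baseline_mean=200.0,
        dispersion=0.05,
        seed=seed,
    )
    return db, config


def generate_annotation_table(
    genes: Sequence[str],
    n_categories: int = 40,
    mean_category_size: int = 30,
    seed: int = 0,
):
    """Synthetic GO-CC-style annotation table over *genes*.

    Category IDs reuse the real GO-CC identifiers from the default
    supercategory map first (so cell-surface / cytoskeleton supercategories
    appear in downstream graphs), then pad with synthetic ``GO:09xxxxx`` IDs.
    Sizes are Poisson around ``mean_category_size`` (minimum 3).
    """
    from .go import DEFAULT_SUPERCATEGORY_MAP, AnnotationTable

    rng = np.random.default_rng(seed)
    known = list(DEFAULT_SUPERCATEGORY_MAP)
    ids = known[:n_categories]
    ids += [f"GO:09{i:05d}" for i in range(1, n_categories - len(ids) + 1)]
    genes = np.asarray(sorted(genes))
    table = AnnotationTable()
    for cat in ids:
        size = min(max(3, int(rng.poisson(mean_category_size))), len(genes))
        for g in rng.choice(genes, size=size, replace=False):
            table.gene_to_categories.setdefault(str(g), set()).add(cat)
        table.category_names[cat] = cat
    return table


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixtures(
    db: InteractionDatabase,
    counts: CountMatrix,
    truth: GroundTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Emit interactions.tsv, counts.tsv, metadata.tsv, truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": directory / "interactions.tsv",
        "counts": directory / "counts.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.json",
    }
    write_interactions(db, paths["interactions"])
    counts.counts.rename_axis("gene").to_csv(paths["counts"], sep="\t")
    counts.metadata.rename_axis("sample").to_csv(paths["metadata"], sep="\t")
    payload = {
        contrast: {
            "de_genes": dict(sorted(truth.de_genes.get(contrast, {}).items())),
            "active_regulons": sorted(truth.active_regulons.get(contrast, set())),
        }
        for contrast in sorted(set(truth.de_genes) | set(truth.active_regulons))
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True))
    return paths


def load_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    truth = GroundTruth()
    for contrast, entry in payload.items():
        truth.de_genes[contrast] = {g: float(l) for g, l in entry["de_genes"].items()}
        truth.active_regulons[contrast] = {(tf, d) for tf, d in entry["active_regulons"]}
    return truth
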