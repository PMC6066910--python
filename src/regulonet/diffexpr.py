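"""Count normalization and differential expression for named contrasts.

The DE engine is deliberately simple and transparent: median-of-ratios size
factors, a log2 transform with a pseudocount, and a per-gene Welch two-sample
t-test with Benjamini–Hochberg FDR control. Genes are then partitioned into
``up`` / ``down`` / ``nc`` by joint FDR and fold-change thresholds; those sets
drive the regulon and GO category scoring downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: metadata columns every sample must carry
METADATA_COLUMNS = ("subset", "genotype", "dox", "replicate")

#: floor on the Welch standard-error denominator (log2 scale, squared units)
VARIANCE_FLOOR = 1e-8

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_LFC_THRESHOLD = 1.0


class NormalizationError(ValueError):
    """No gene is expressed in every sample; size factors are undefined."""


class ContrastError(ValueError):
    """Invalid contrast definition (overlapping groups, unknown samples...)."""


class InsufficientReplicationError(ContrastError):
    """Fewer than two replicates in one of the contrast groups."""


@dataclass
class CountMatrix:
    """Genes x samples raw integer counts plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene symbol with one column per sample ID;
        non-negative integers.
    metadata
        DataFrame indexed by sample ID with at least the columns
        ``subset``, ``genotype``, ``dox``, ``replicate``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts.index = self.counts.index.astype(str).str.upper()
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dupes)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        absent = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if absent:
            raise ValueError(f"metadata missing columns: {absent}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def select_samples(self, selector: Mapping[str, object]) -> list[str]:
        """Sample IDs whose metadata match every key/value in *selector*.

        Unknown selector keys raise :class:`ContrastError` so that config
        typos fail loudly instead of silently selecting nothing.
        """
        mask = pd.Series(True, index=self.metadata.index)
        for key, value in selector.items():
            if key not in self.metadata.columns:
                raise ContrastError(f"unknown sample selector key: {key!r}")
            mask &= self.metadata[key].astype(str) == str(value)
        return [s for s in self.samples if mask.get(s, False)]


@dataclass
class DEResult:
    """Per-gene differential expression statistics for one contrast.

    ``table`` is indexed by gene with columns ``log2fc``, ``p_value``,
    ``q_value`` and ``direction`` (one of ``up``/``down``/``nc``).
    ``untested`` lists genes dropped before testing (all-zero in both groups).
    Fold changes follow the group-B-over-group-A convention on the log2 scale.
    """

    table: pd.DataFrame
    contrast_id: str
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)
    untested: list[str] = field(default_factory=list)
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD

    @property
    def universe(self) -> set[str]:
        """All tested genes — the background for enrichment scoring."""
        return set(self.table.index)

    def gene_set(self, direction: str) -> set[str]:
        return set(self.table.index[self.table["direction"] == direction])

    @property
    def up_set(self) -> set[str]:
        return self.gene_set("up")

    @property
    def down_set(self) -> set[str]:
        return self.gene_set("down")

    def to_frame(self) -> pd.DataFrame:
        out = self.table.reset_index().rename(columns={"index": "gene"})
        out["contrast"] = self.contrast_id
        return out


# ---------------------------------------------------------------------------
# normalization


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Reference genes are those with a nonzero count in every sample; each
    sample's factor is the median over reference genes of
    count / geometric-mean-across-samples.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    reference = (arr > 0).all(axis=1)
    if not reference.any():
        raise NormalizationError("no gene has nonzero counts in all samples")
    ref = arr[reference]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geomean)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def normalize_counts(counts: CountMatrix) -> pd.DataFrame:
    """Counts divided by per-sample size factors (float matrix)."""
    factors = estimate_size_factors(counts)
    return counts.counts / factors


# ---------------------------------------------------------------------------
# testing


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t-test on rows of *a* vs *b* (two-sided p).

    A floor on the squared standard error guards zero-variance rows; rows
    with equal means and zero variance in both groups get t=0, p=1.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    se2 = np.maximum(sa + sb, VARIANCE_FLOOR)
    t = (mb - ma) / np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    df = np.where(np.isfinite(df), df, na + nb - 2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var_equal = (se2 <= VARIANCE_FLOOR) & np.isclose(ma, mb)
    t = np.where(zero_var_equal, 0.0, t)
    p = np.where(zero_var_equal, 1.0, p)
    return t, np.clip(p, 0.0, 1.0)


def de_test(
    counts: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    contrast_id: str = "contrast",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DEResult:
    """Welch t-test on log2(normalized count + pseudocount), B over A.

    Genes with zero counts in every sample of both groups are dropped and
    reported in ``DEResult.untested``. ``q_value`` is left NaN; apply
    :func:`bh_fdr` via :func:`classify_de` or fill it explicitly.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ContrastError("groups A and B overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise InsufficientReplicationError(
            f"need >=2 replicates per group, got {len(group_a)} vs {len(group_b)}"
        )
    unknown = (set(group_a) | set(group_b)) - set(counts.samples)
    if unknown:
        raise ContrastError(f"samples not in count matrix: {sorted(unknown)}")

    norm = normalize_counts(counts)
    sub = norm[group_a + group_b]
    raw = counts.counts[group_a + group_b]
    tested = raw.sum(axis=1) > 0
    untested = list(raw.index[~tested])
    sub = sub.loc[tested]

    logged = np.log2(sub.to_numpy() + pseudocount)
    a = logged[:, : len(group_a)]
    b = logged[:, len(group_a) :]
    t, p = _welch(a, b)
    table = pd.DataFrame(
        {
            "log2fc": b.mean(axis=1) - a.mean(axis=1),
            "p_value": p,
            "q_value": np.nan,
            "direction": "nc",
        },
        index=sub.index,
    )
    return DEResult(
        table=table,
        contrast_id=contrast_id,
        group_a=group_a,
        group_b=group_b,
        untested=untested,
    )


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_de(
    result: DEResult,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> DEResult:
    """Fill q-values (BH) and assign up/down/nc directions in place.

    ``up``: q <= fdr_threshold and log2fc >= +lfc_threshold;
    ``down``: q <= fdr_threshold and log2fc <= -lfc_threshold;
    everything else ``nc``.
    """
    if fdr_threshold < 0 or lfc_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    table = result.table
    if table["q_value"].isna().any():
        table["q_value"] = bh_fdr(table["p_value"])
    sig = table["q_value"] <= fdr_threshold
    table["direction"] = np.select(
        [sig & (table["log2fc"] >= lfc_threshold), sig & (table["log2fc"] <= -lfc_threshold)],
        ["up", "down"],
        default="nc",
    )
    result.fdr_threshold = fdr_threshold
    result.lfc_threshold = lfc_threshold
    return result


def run_contrast(
    counts: CountMatrix,
    group_a_selector: Mapping[str, object],
    group_b_selector: Mapping[str, object],
    contrast_id: str = "contrast",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> DEResult:
    """Select samples by metadata, test, and classify — one-call contrast."""
    group_a = counts.select_samples(group_a_selector)
    group_b = counts.select_samples(group_b_selector)
    if not group_a or not group_b:
        raise ContrastError(
            f"contrast {contrast_id!r}: selectors matched {len(group_a)} vs "
            f"{len(group_b)} samples"
        )
    result = de_test(counts, group_a, group_b, contrast_id, pseudocount)
    return classify_de(result, fdr_threshold, lfc_threshold)


# ---------------------------------------------------------------------------
# I/O


def load_counts(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read the TSV count-matrix dialect (first column ``gene``) + metadata."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, metadata=metadata)


def write_de_results(results: Iterable[DEResult], path: str | Path) -> None:
    frames = [r.to_frame() for r in results]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
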