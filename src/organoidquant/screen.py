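"""Single-cell expression screen: QC filtering, fixed-size downsampling,
cluster-aggregate log2 sample ratios, DE selection, NES-based cell-type
assignment, and a binomial overrepresentation test.

This module implements the *numeric rules* of the screen over a gene × cell
count matrix; clustering, integration, doublet calling and GSEA scoring are
inputs produced upstream (cluster labels and NES tables are consumed, not
computed).  The rules, with their defaults:

* QC removal: ``nFeature > 8000``, ``nFeature < 200``, ``nCount > 50000`` or
  ``pct_mito > 20`` (all strict, so boundary cells survive);
* downsampling: a uniform, seeded sample of exactly 6,400 cells without
  replacement;
* cluster aggregates: per (gene, cluster) mean of library-size-normalized
  counts (counts / cell total × 10,000), compared between samples as
  ``log2((mean_A + ε) / (mean_B + ε))`` with ε = 0.01;
* DE selection: ``log2 ratio > 1`` or ``< −1`` (strict);
* enrichment filter: NES >= 7.5 keeps a (cluster, gene set) row; the
  assignment is the arg-max NES among kept rows;
* overrepresentation: one-sided binomial tail P(X >= k) with
  p0 = |set ∩ background| / |background|, Bonferroni-corrected over the sets
  tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "compute_cell_qc",
    "qc_filter",
    "downsample_cells",
    "cluster_aggregate_log2ratio",
    "select_de_genes",
    "filter_enrichment",
    "overrepresentation_test",
]

NORMALIZATION_SCALE = 10_000.0
DOUBLETFINDER_MULTIPLET_RATE = 0.008  # upstream doublet-calling rate, provenance metadata only


@dataclass
class CountMatrix:
    """Genes × cells integer count matrix with identifiers and labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    sample: str = "sample"
    clusters: np.ndarray | None = None  # per-cell cluster label
    mito_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2D (genes × cells)")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.isfinite(c)) or np.any(c != np.round(c)):
                raise ValueError("counts must be finite integers")
            c = c.astype(np.int64)
        if c.size and c.min() < 0:
            raise ValueError("counts must be non-negative")
        if c.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if self.clusters is not None:
            cl = np.asarray(self.clusters)
            if cl.shape != (len(self.cell_ids),):
                raise ValueError("one cluster label per cell required")
            self.clusters = cl
        self.counts = c
        self.mito_genes = frozenset(self.mito_genes)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class QCThresholds:
    """Strict removal cutoffs for per-cell QC."""

    max_nFeature: int = 8000
    min_nFeature: int = 200
    max_nCount: int = 50_000
    max_pct_mito: float = 20.0

    def __post_init__(self) -> None:
        if min(self.max_nFeature, self.min_nFeature, self.max_nCount, self.max_pct_mito) <= 0:
            raise ValueError("QC thresholds must be positive")


def compute_cell_qc(m: CountMatrix) -> pd.DataFrame:
    """Per-cell QC metrics: nFeature (genes with count > 0), nCount (total
    counts) and pct_mito (percent of counts from mitochondrial genes)."""
    unknown = m.mito_genes - set(m.gene_ids)
    if unknown:
        raise KeyError(f"mitochondrial gene ids not in matrix: {sorted(unknown)}")
    n_feature = (m.counts > 0).sum(axis=0)
    n_count = m.counts.sum(axis=0)
    mito_idx = [i for i, g in enumerate(m.gene_ids) if g in m.mito_genes]
    mito_counts = m.counts[mito_idx].sum(axis=0) if mito_idx else np.zeros(m.n_cells, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        pct = np.where(n_count > 0, 100.0 * mito_counts / np.maximum(n_count, 1), 0.0)
    return pd.DataFrame(
        {"nFeature": n_feature.astype(int), "nCount": n_count.astype(int), "pct_mito": pct},
        index=pd.Index(m.cell_ids, name="cell_id"),
    )


def qc_filter(qc: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> list[str]:
    """Surviving cell ids, input order preserved.

    A cell is removed iff ``nFeature > max`` OR ``nFeature < min`` OR
    ``nCount > max`` OR ``pct_mito > max`` — every inequality strict, so a
    cell sitting exactly on a cutoff is kept.
    """
    t = thresholds
    removed = (
        (qc["nFeature"] > t.max_nFeature)
        | (qc["nFeature"] < t.min_nFeature)
        | (qc["nCount"] > t.max_nCount)
        | (qc["pct_mito"] > t.max_pct_mito)
    )
    return list(qc.index[~removed])


def _subset_cells(m: CountMatrix, idx: np.ndarray) -> CountMatrix:
    return CountMatrix(
        counts=m.counts[:, idx],
        gene_ids=list(m.gene_ids),
        cell_ids=[m.cell_ids[i] for i in idx],
        sample=m.sample,
        clusters=None if m.clusters is None else m.clusters[idx],
        mito_genes=m.mito_genes,
    )


def select_cells(m: CountMatrix, cell_ids: Sequence[str]) -> CountMatrix:
    """Subset a matrix to the named cells (e.g. QC survivors), keeping order."""
    pos = {c: i for i, c in enumerate(m.cell_ids)}
    idx = np.array([pos[c] for c in cell_ids], dtype=int)
    return _subset_cells(m, idx)


def downsample_cells(
    m: CountMatrix, n: int = 6400, seed: int = 0, allow_smaller: bool = False
) -> CountMatrix:
    """Uniform seeded sample of exactly ``n`` cells without replacement.

    Fixed-size subsets put every sample on an equal cell-count footing before
    aggregate comparison.  With ``n`` equal to the matrix size all cells are
    kept in their original order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if m.n_cells < n:
        if not allow_smaller:
            raise ValueError(f"matrix has {m.n_cells} cells < requested {n}")
        import warnings

        warnings.warn(f"only {m.n_cells} cells available; keeping all", stacklevel=2)
        return _subset_cells(m, np.arange(m.n_cells))
    if m.n_cells == n:
        return _subset_cells(m, np.arange(m.n_cells))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m.n_cells, size=n, replace=False))
    return _subset_cells(m, idx)


def _normalized(m: CountMatrix) -> np.ndarray:
    totals = m.counts.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    return m.counts / totals * NORMALIZATION_SCALE


def cluster_aggregate_log2ratio(
    a: CountMatrix,
    b: CountMatrix,
    pseudocount: float = 0.01,
    pseudobulk: bool = False,
) -> pd.DataFrame:
    """Per (gene, cluster) log2 adjusted sample ratio between two samples.

    Cluster means are arithmetic means of library-size-normalized counts
    (counts / cell total × 10,000); the ratio is
    ``log2((mean_A + ε) / (mean_B + ε))``.  ``pseudobulk=True`` collapses all
    cells into a single pseudo-cluster ``"all"``.  Clusters present in only
    one sample are emitted with a null ratio and ``flag='missing_in_one'``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if list(a.gene_ids) != list(b.gene_ids):
        raise ValueError("samples must share an identical gene axis")
    if not pseudobulk and (a.clusters is None or b.clusters is None):
        raise ValueError("per-cluster ratios require cluster labels on both samples")

    na, nb = _normalized(a), _normalized(b)
    cl_a = np.full(a.n_cells, "all") if pseudobulk else np.asarray(a.clusters).astype(str)
    cl_b = np.full(b.n_cells, "all") if pseudobulk else np.asarray(b.clusters).astype(str)
    clusters = sorted(set(cl_a) | set(cl_b))

    rows = []
    for cluster in clusters:
        in_a, in_b = cl_a == cluster, cl_b == cluster
        mean_a = na[:, in_a].mean(axis=1) if in_a.any() else np.full(a.n_genes, np.nan)
        mean_b = nb[:, in_b].mean(axis=1) if in_b.any() else np.full(b.n_genes, np.nan)
        missing = not (in_a.any() and in_b.any())
        if missing:
            ratio = np.full(a.n_genes, np.nan)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
        rows.append(
            pd.DataFrame(
                {
                    "gene": a.gene_ids,
                    "cluster": cluster,
                    "mean_a": mean_a,
                    "mean_b": mean_b,
                    "log2_ratio": ratio,
                    "flag": "missing_in_one" if missing else "",
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def select_de_genes(table: pd.DataFrame, threshold: float = 1.0) -> dict[str, list[str]]:
    """Genes with |log2 ratio| strictly above the fold-change cutoff, per
    cluster, in deterministic (sorted) gene-id order."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out: dict[str, list[str]] = {}
    for cluster, sub in table.groupby("cluster", sort=True):
        hits = sub.loc[
            (sub["log2_ratio"] > threshold) | (sub["log2_ratio"] < -threshold), "gene"
        ]
        out[str(cluster)] = sorted(hits)
    return out


def filter_enrichment(enrichment: pd.DataFrame, cutoff: float = 7.5) -> pd.DataFrame:
    """Per-cluster cell-type assignment from an NES table.

    Rows with NES >= cutoff are significant; the assignment is the gene set
    with the maximum kept NES (lexicographically first set id on ties, with
    the tie flagged).  Clusters with no significant set are 'unassigned'.
    """
    required = {"cluster", "set", "NES"}
    if not required <= set(enrichment.columns):
        raise ValueError(f"enrichment table needs columns {sorted(required)}")
    rows = []
    for cluster, sub in enrichment.groupby("cluster", sort=True):
        kept = sub[sub["NES"] >= cutoff]
        if kept.empty:
            rows.append({"cluster": cluster, "assignment": "unassigned", "NES": np.nan, "tie": False})
            continue
        best = kept["NES"].max()
        winners = sorted(kept.loc[kept["NES"] == best, "set"])
        rows.append(
            {"cluster": cluster, "assignment": winners[0], "NES": float(best), "tie": len(winners) > 1}
        )
    return pd.DataFrame(rows)


def overrepresentation_test(
    query: Iterable[str],
    background: Iterable[str],
    sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided binomial overrepresentation with Bonferroni correction.

    For each gene set S (intersected with the background first):
    ``p0 = |S ∩ background| / |background|``, ``k = |query ∩ S|``,
    ``n = |query|`` and the raw p-value is ``P(X >= k)`` for
    ``X ~ Binomial(n, p0)``.  The adjusted p is ``min(1, m · raw)`` with m the
    number of sets tested.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    q = set(query)
    if not q <= bg:
        raise ValueError("query must be a subset of the background")
    n = len(q)
    m_sets = len(sets)
    rows = []
    for name in sets:
        s = set(sets[name]) & bg
        p0 = len(s) / len(bg)
        k = len(q & s)
        raw = 1.0 if n == 0 else float(sps.binom.sf(k - 1, n, p0))
        rows.append(
            {
                "set": name,
                "k": k,
                "n": n,
                "set_size_in_background": len(s),
                "p0": p0,
                "p_raw": min(1.0, raw),
                "p_bonferroni": min(1.0, m_sets * raw),
            }
        )
    return pd.DataFrame(rows)


__all__.append("select_cells")
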