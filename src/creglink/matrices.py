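"""Normalization, variable features, reductions, pseudobulks and the ATAC
feature matrix.

Matrices are features x cells throughout.  Log-normalization is
``ln(1 + v * scale / cell_total)`` with scale 10,000; TF-IDF is
``ln(1 + TF * IDF * 10^4)`` with TF the within-cell frequency and IDF the
inverse feature frequency.  Variable features are ranked by plain variance
of the log-normalized values (deterministic; ties broken by feature order).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .genomics_io import CountMatrix, FragmentSet, GenomicInterval

__all__ = [
    "Pseudobulk",
    "ReducedMatrix",
    "lognormalize",
    "select_variable_features",
    "scale_features",
    "pca_reduce",
    "feature_matrix",
    "filter_top_features",
    "tfidf",
    "lsi_reduce",
    "pseudobulk_mean",
    "bin_genome_counts",
]

DEFAULT_SCALE = 10_000.0
DEFAULT_BIN_SIZE = 100_000


@dataclass
class Pseudobulk:
    """Per-group mean of log-normalized feature values."""

    group_id: str
    values: np.ndarray
    feature_ids: list
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if len(self.values) != len(self.feature_ids):
            raise ValueError("values and feature_ids lengths differ")


@dataclass
class ReducedMatrix:
    """Cells x components embedding from PCA or LSI."""

    embedding: np.ndarray
    method: str
    component_range: Tuple[int, int]  # 1-based inclusive range used downstream
    singular_values: np.ndarray

    @property
    def used(self) -> np.ndarray:
        lo, hi = self.component_range
        return self.embedding[:, lo - 1 : hi]


def lognormalize(raw: CountMatrix, scale: float = DEFAULT_SCALE) -> CountMatrix:
    """Library-size normalize and log-transform: v -> ln(1 + v*scale/T)."""
    if raw.layer != "raw":
        raise ValueError(f"expected raw layer, got {raw.layer!r}")
    totals = raw.cell_totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total counts: {raw.cell_barcodes[zero[0]]}"
        )
    if sp.issparse(raw.values):
        mat = raw.values.tocsc(copy=True).astype(float)
        mat.data *= scale / np.repeat(totals, np.diff(mat.indptr))
        mat.data = np.log1p(mat.data)
        values = mat.tocsr()
    else:
        values = np.log1p(raw.values * (scale / totals)[None, :])
    return CountMatrix(values, list(raw.feature_ids), list(raw.cell_barcodes), "lognorm")


def _row_variances(values) -> np.ndarray:
    if sp.issparse(values):
        m = np.asarray(values.mean(axis=1)).ravel()
        m2 = np.asarray(values.multiply(values).mean(axis=1)).ravel()
        return m2 - m**2
    return values.var(axis=1)


def select_variable_features(m: CountMatrix, n: int) -> List[str]:
    """Top-n features by variance, descending; ties keep feature-list order."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if n > len(m.feature_ids):
        raise ValueError(f"n={n} exceeds feature count {len(m.feature_ids)}")
    var = _row_variances(m.values)
    order = np.argsort(-var, kind="stable")
    return [m.feature_ids[i] for i in order[:n]]


def scale_features(m: CountMatrix) -> CountMatrix:
    """Center each feature to mean 0 and sd 1; constant features become zeros."""
    dense = m.dense().astype(float)
    mean = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return CountMatrix(
        (dense - mean) / sd, list(m.feature_ids), list(m.cell_barcodes), "scaled"
    )


def _svd_embedding(cells_by_features: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic truncated SVD with a fixed sign convention.

    Each component's sign is chosen so its largest-magnitude feature
    loading is positive.
    """
    u, s, vt = np.linalg.svd(cells_by_features, full_matrices=False)
    k = min(k, len(s))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    return (u * flip[None, :]) * s[None, :], s


def pca_reduce(m: CountMatrix, k: int = 50) -> ReducedMatrix:
    """PCA of the scaled matrix; embedding rows are cells."""
    if m.layer != "scaled":
        raise ValueError(f"expected scaled layer, got {m.layer!r}")
    emb, s = _svd_embedding(m.dense().T, k)
    return ReducedMatrix(emb, "pca", (1, emb.shape[1]), s)


def lsi_reduce(m: CountMatrix, k: int = 40) -> ReducedMatrix:
    """Truncated SVD of the TF-IDF matrix; component 1 tracks depth and is
    dropped downstream (component range 2..k)."""
    if m.layer != "tfidf":
        raise ValueError(f"expected tfidf layer, got {m.layer!r}")
    emb, s = _svd_embedding(m.dense().T, k)
    return ReducedMatrix(emb, "lsi", (min(2, emb.shape[1]), emb.shape[1]), s)


def feature_matrix(
    fragments: FragmentSet,
    peaks: Sequence[GenomicInterval],
    cells: Sequence[str],
) -> CountMatrix:
    """Peak x cell count matrix from fragment-peak half-open overlaps.

    A fragment contributes its duplicate count to every peak it overlaps.
    Peaks must be non-overlapping within the sample.
    """
    cell_index = {bc: j for j, bc in enumerate(cells)}
    peak_ids = [str(p) for p in peaks]
    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []

    by_chrom: Dict[str, List[int]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append(i)

    frag_cell = fragments.barcode_codes(cell_index)
    for chrom, idx in by_chrom.items():
        idx_arr = np.array(idx, dtype=np.int64)
        order = np.argsort([peaks[i].start for i in idx])
        idx_arr = idx_arr[order]
        p_starts = np.array([peaks[i].start for i in idx_arr])
        p_ends = np.array([peaks[i].end for i in idx_arr])
        on = (fragments.chroms == chrom) & (frag_cell >= 0)
        if not on.any():
            continue
        f_start = fragments.starts[on]
        f_end = fragments.ends[on]
        f_count = fragments.counts[on]
        f_cell = frag_cell[on]
        # peaks sorted & disjoint: overlapping peaks form the contiguous run
        # [lo, hi) with peak.end > frag.start and peak.start < frag.end
        lo = np.searchsorted(p_ends, f_start, side="right")
        hi = np.searchsorted(p_starts, f_end, side="left")
        span = hi - lo
        for offset in range(int(span.max(initial=0))):
            hit = span > offset
            rows.append(idx_arr[lo[hit] + offset])
            cols.append(f_cell[hit])
            vals.append(f_count[hit])

    if rows:
        data = (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols)))
    else:
        data = ([], ([], []))
    mat = sp.coo_matrix(
        data, shape=(len(peaks), len(cells)), dtype=np.int64
    ).tocsr()
    mat.sum_duplicates()
    return CountMatrix(mat, peak_ids, list(cells), "raw")


def filter_top_features(m: CountMatrix, min_cutoff: int = 5) -> CountMatrix:
    """Keep features whose total count across cells is >= min_cutoff."""
    totals = m.feature_totals()
    keep = [f for f, t in zip(m.feature_ids, totals) if t >= min_cutoff]
    return m.subset_features(keep)


def tfidf(m: CountMatrix, scale: float = DEFAULT_SCALE) -> CountMatrix:
    """TF-IDF normalize: ln(1 + (count/cell_total) * (n_cells/feature_total) * scale)."""
    if m.layer != "raw":
        raise ValueError(f"expected raw layer, got {m.layer!r}")
    cell_totals = m.cell_totals()
    if (cell_totals == 0).any():
        bad = m.cell_barcodes[int(np.flatnonzero(cell_totals == 0)[0])]
        raise ValueError(f"cell with zero total counts: {bad}")
    feature_totals = m.feature_totals()
    n_cells = len(m.cell_barcodes)
    idf = np.zeros_like(feature_totals, dtype=float)
    nz = feature_totals > 0
    idf[nz] = n_cells / feature_totals[nz]
    if sp.issparse(m.values):
        mat = m.values.tocoo().astype(float)
        tf = mat.data / cell_totals[mat.col]
        mat.data = np.log1p(tf * idf[mat.row] * scale)
        values = mat.tocsr()
    else:
        tf = m.values / cell_totals[None, :]
        values = np.log1p(tf * idf[:, None] * scale)
    return CountMatrix(values, list(m.feature_ids), list(m.cell_barcodes), "tfidf")


def pseudobulk_mean(m: CountMatrix, groups: Dict[str, str]) -> List[Pseudobulk]:
    """Per-group arithmetic mean of (log-normalized) values.

    ``groups`` maps barcode -> group id; barcodes missing from the map are
    ignored.  Output order follows first appearance in the cell list.
    """
    if m.layer not in ("lognorm", "tfidf"):
        raise ValueError(f"expected a normalized layer, got {m.layer!r}")
    order: List[str] = []
    members: Dict[str, List[int]] = {}
    for j, bc in enumerate(m.cell_barcodes):
        g = groups.get(bc)
        if g is None:
            continue
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(j)
    out = []
    csc = m.values.tocsc() if sp.issparse(m.values) else m.values
    for g in order:
        cols = members[g]
        sub = csc[:, cols]
        mean = np.asarray(sub.mean(axis=1)).ravel()
        out.append(Pseudobulk(g, mean, list(m.feature_ids), len(cols)))
    return out


def bin_genome_counts(
    fragments: FragmentSet,
    chrom_sizes: Dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> Tuple[List[str], np.ndarray]:
    """Total fragment counts per non-overlapping genomic bin.

    Bins are [i*B, (i+1)*B) per chromosome; a fragment contributes its
    count to every bin it overlaps.  Returns bin labels and the count
    vector, suitable for assembling a bins x samples matrix.
    """
    labels: List[str] = []
    chunks: List[np.ndarray] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_bins = int(np.ceil(size / bin_size))
        counts = np.zeros(n_bins, dtype=np.int64)
        on = fragments.chroms == chrom
        if on.any():
            s = fragments.starts[on]
            e = fragments.ends[on]
            c = fragments.counts[on]
            lo = s // bin_size
            hi = (e - 1) // bin_size  # last overlapped bin (end exclusive)
            span = hi - lo + 1
            for offset in range(int(span.max(initial=0))):
                hit = span > offset
                target = lo[hit] + offset
                inside = target < n_bins
                np.add.at(counts, target[inside], c[hit][inside])
        labels.extend(
            f"{chrom}:{i * bin_size}-{min((i + 1) * bin_size, size)}"
            for i in range(n_bins)
        )
        chunks.append(counts)
    return labels, np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.int64)
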