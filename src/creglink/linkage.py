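"""CRE-gene linkage: candidate windowing, observed Pearson correlation,
matched-background null, z-score and upper-tail p-value.

For each gene, candidate peaks are those intersecting a +/-50 kb window
around the TSS.  The observed correlation between log-normalized gene
expression and log-normalized peak accessibility is compared against the
correlations of background peaks matched on (optionally GC content,)
log1p total accessibility and log width: z = (r_obs - mean_bg) / sd_bg,
p = 1 - Phi(z).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm

from .genomics_io import CountMatrix, GeneModel, GenomicInterval, LinkageRecord
from .matrices import lognormalize

__all__ = [
    "PeakFeatures",
    "LinkageConfig",
    "candidate_peaks",
    "pearson_link_score",
    "matched_background",
    "linkage_ztest",
    "link_peaks",
    "compute_peak_features",
    "gc_fraction_from_fasta",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakFeatures:
    """Matching covariates of one peak for background selection."""

    peak: GenomicInterval
    total_accessibility: float
    gc_fraction: Optional[float] = None

    @property
    def width(self) -> int:
        return self.peak.width


@dataclass(frozen=True)
class LinkageConfig:
    window_bp: int = 50_000
    n_background: int = 200
    min_cells: int = 10
    pvalue_cutoff: float = 0.05
    score_cutoff: float = 0.05
    two_sided: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.window_bp, self.n_background, self.min_cells) <= 0:
            raise ValueError("window_bp, n_background and min_cells must be positive")
        if not (0 < self.pvalue_cutoff < 1):
            raise ValueError("pvalue_cutoff must be in (0, 1)")
        if self.score_cutoff < 0:
            raise ValueError("score_cutoff must be non-negative")


def candidate_peaks(
    gene: GeneModel,
    peaks: Sequence[GenomicInterval],
    window_bp: int = 50_000,
) -> List[int]:
    """Indices of peaks intersecting [tss - window, tss + window] (closed
    in base terms, i.e. the half-open window [tss - w, tss + w + 1))."""
    lo = gene.tss - window_bp
    hi = gene.tss + window_bp + 1
    return [
        i
        for i, p in enumerate(peaks)
        if p.chrom == gene.body.chrom and p.start < hi and p.end > lo
    ]


def pearson_link_score(expr: np.ndarray, acc: np.ndarray) -> Optional[float]:
    """Pearson correlation; None (skipped) for constant input."""
    expr = np.asarray(expr, dtype=float)
    acc = np.asarray(acc, dtype=float)
    if expr.shape != acc.shape or expr.ndim != 1:
        raise ValueError("expr and acc must be equal-length vectors")
    if len(expr) < 3:
        raise ValueError("need at least 3 cells")
    se, sa = expr.std(), acc.std()
    if se == 0 or sa == 0:
        logger.debug("constant vector; correlation undefined")
        return None
    return float(np.mean((expr - expr.mean()) * (acc - acc.mean())) / (se * sa))


def _feature_matrix_of(features: Sequence[PeakFeatures], use_gc: bool) -> np.ndarray:
    cols = []
    if use_gc:
        cols.append([f.gc_fraction for f in features])
    cols.append([np.log1p(f.total_accessibility) for f in features])
    cols.append([np.log(f.width) for f in features])
    return np.array(cols, dtype=float).T


def matched_background(
    target: PeakFeatures,
    pool: Sequence[PeakFeatures],
    n: int = 200,
    seed: int = 0,
) -> List[int]:
    """Indices of the n pool peaks nearest the target in feature space.

    Features (gc fraction when available throughout, log1p accessibility,
    log width) are standardized over the pool.  Selection is deterministic;
    ties resolve by pool order.
    """
    if not pool:
        raise ValueError("background pool is empty")
    use_gc = target.gc_fraction is not None and all(
        f.gc_fraction is not None for f in pool
    )
    mat = _feature_matrix_of(pool, use_gc)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    mat = (mat - mean) / sd
    tvec = (_feature_matrix_of([target], use_gc)[0] - mean) / sd
    dist = np.linalg.norm(mat - tvec[None, :], axis=1)
    if len(pool) < n:
        warnings.warn(
            f"background pool ({len(pool)}) smaller than requested n={n}; using all"
        )
        n = len(pool)
    order = np.argsort(dist, kind="stable")
    return [int(i) for i in order[:n]]


def linkage_ztest(
    r_obs: float, r_background: Sequence[float], two_sided: bool = False
) -> Optional[Tuple[float, float]]:
    """z-score of the observed correlation against the background set.

    Returns (z, p) with p the upper-tail normal probability, or None when
    the background has zero spread (pair skipped).
    """
    bg = np.asarray(r_background, dtype=float)
    if len(bg) < 2:
        raise ValueError("need at least 2 background correlations")
    sd = bg.std(ddof=1)
    if sd <= 1e-10 * (np.abs(bg).max() + 1.0):  # all-equal up to float noise
        logger.debug("degenerate background (sd=0); pair skipped")
        return None
    z = (r_obs - bg.mean()) / sd
    p = 2 * norm.sf(abs(z)) if two_sided else norm.sf(z)
    return float(z), float(p)


def compute_peak_features(
    peaks: Sequence[GenomicInterval],
    atac_raw: CountMatrix,
    gc_fractions: Optional[Sequence[float]] = None,
) -> List[PeakFeatures]:
    totals = atac_raw.feature_totals()
    if len(peaks) != len(totals):
        raise ValueError("peaks and ATAC matrix rows disagree")
    return [
        PeakFeatures(
            p,
            float(totals[i]),
            None if gc_fractions is None else float(gc_fractions[i]),
        )
        for i, p in enumerate(peaks)
    ]


def gc_fraction_from_fasta(
    peaks: Sequence[GenomicInterval], fasta_path: str
) -> List[float]:
    """Per-peak GC fraction from a genome FASTA."""
    from pyfaidx import Fasta

    genome = Fasta(fasta_path)
    out = []
    for p in peaks:
        seq = str(genome[p.chrom][p.start : p.end]).upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        out.append((seq.count("G") + seq.count("C")) / acgt if acgt else 0.0)
    return out


def _zscore_rows(values) -> Tuple[np.ndarray, np.ndarray]:
    """Dense row-wise z-scores plus a validity mask (sd > 0)."""
    dense = np.asarray(values.todense()) if sp.issparse(values) else np.asarray(values, dtype=float)
    mean = dense.mean(axis=1, keepdims=True)
    sd = dense.std(axis=1)
    ok = sd > 0
    safe = np.where(ok, sd, 1.0)[:, None]
    return (dense - mean) / safe, ok


def link_peaks(
    rna_lognorm: CountMatrix,
    atac_raw: CountMatrix,
    peaks: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    sample_id: str,
    config: LinkageConfig = LinkageConfig(),
    genes: Optional[Sequence[str]] = None,
    gc_fractions: Optional[Sequence[float]] = None,
) -> List[LinkageRecord]:
    """Score CRE-gene linkages for one (QC-filtered) sample.

    Genes/peaks detected in fewer than ``min_cells`` cells are dropped.
    A record is retained when p < pvalue_cutoff and |r| > score_cutoff.
    Deterministic for fixed inputs and config.
    """
    if rna_lognorm.layer != "lognorm":
        raise ValueError("RNA matrix must be log-normalized")
    if list(rna_lognorm.cell_barcodes) != list(atac_raw.cell_barcodes):
        raise ValueError("RNA and ATAC matrices must share the same cell order")
    if len(peaks) != len(atac_raw.feature_ids):
        raise ValueError("peak list and ATAC matrix rows disagree")

    atac_lognorm = lognormalize(atac_raw)
    n_cells = len(rna_lognorm.cell_barcodes)

    gene_by_id = {g.gene_id: g for g in gene_models}
    wanted = list(genes) if genes is not None else [g.gene_id for g in gene_models]
    rna_index = {f: i for i, f in enumerate(rna_lognorm.feature_ids)}

    rna_vals = rna_lognorm.values
    rna_detected = (
        np.asarray((rna_vals != 0).sum(axis=1)).ravel()
        if sp.issparse(rna_vals)
        else (rna_vals != 0).sum(axis=1)
    )
    peak_detected = np.asarray((atac_raw.values != 0).sum(axis=1)).ravel()

    z_peaks, peak_ok = _zscore_rows(atac_lognorm.values)
    peak_valid = peak_ok & (peak_detected >= config.min_cells)
    features = compute_peak_features(peaks, atac_raw, gc_fractions)

    rna_dense = (
        np.asarray(rna_vals.todense()) if sp.issparse(rna_vals) else np.asarray(rna_vals)
    )

    records: List[LinkageRecord] = []
    any_gene = False
    for gene_id in wanted:
        gene = gene_by_id.get(gene_id)
        if gene is None or gene_id not in rna_index:
            continue
        gi = rna_index[gene_id]
        if rna_detected[gi] < config.min_cells:
            continue
        expr = rna_dense[gi].astype(float)
        if expr.std() == 0:
            continue
        any_gene = True
        cands = candidate_peaks(gene, peaks, config.window_bp)
        cands = [c for c in cands if peak_valid[c]]
        if not cands:
            continue
        zg = (expr - expr.mean()) / expr.std()
        r_all = z_peaks @ zg / n_cells  # gene vs every peak in one pass
        cand_set = set(cands)
        pool_idx = [
            i for i in range(len(peaks)) if peak_valid[i] and i not in cand_set
        ]
        if not pool_idx:
            logger.warning("gene %s: no background pool; skipped", gene_id)
            continue
        pool_features = [features[i] for i in pool_idx]
        for ci in cands:
            r_obs = float(np.clip(r_all[ci], -1.0, 1.0))
            bg_local = matched_background(
                features[ci], pool_features, config.n_background, config.seed
            )
            bg_r = r_all[[pool_idx[i] for i in bg_local]]
            zt = linkage_ztest(r_obs, bg_r, config.two_sided)
            if zt is None:
                continue
            zscore, pvalue = zt
            if pvalue < config.pvalue_cutoff and abs(r_obs) > config.score_cutoff:
                records.append(
                    LinkageRecord(
                        gene_id=gene_id,
                        peak=peaks[ci],
                        score=r_obs,
                        zscore=zscore,
                        pvalue=pvalue,
                        sample_id=sample_id,
                    )
                )
    if not any_gene:
        warnings.warn("no genes passed detection filters; empty linkage result")
    return records
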