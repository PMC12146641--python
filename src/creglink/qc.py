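"""Per-cell QC metrics and the six-criteria cell filter.

Metrics: RNA read total, ATAC fragment total, nucleosome signal
(mononucleosome [147, 294] bp over nucleosome-free < 147 bp), and TSS
enrichment (center-to-flank coverage ratio over +/-1000 bp TSS windows).
All filter inequalities are strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genomics_io import FragmentRecord, FragmentSet, GeneModel, SampleBundle

__all__ = [
    "CellQCMetrics",
    "QCThresholds",
    "nucleosome_signal",
    "tss_enrichment",
    "compute_cell_qc",
    "apply_cell_filters",
    "write_qc_report",
    "read_qc_report",
]

# Fragment-length bands (bp): nucleosome-free strictly below 147,
# mononucleosome band inclusive on both ends.
NFR_MAX = 147
MONO_MIN = 147
MONO_MAX = 294

TSS_WINDOW = 1000  # half-width of the TSS-centered window
TSS_CENTER_HALF = 50  # center bin = [tss - 50, tss + 50] inclusive
TSS_FLANK = 100  # outermost flank width on each side
DEFAULT_TSS_CAP = 20.0


@dataclass(frozen=True)
class CellQCMetrics:
    barcode: str
    rna_reads: int
    atac_reads: int
    nucleosome_signal: Optional[float]  # None when no sub-147 bp fragments
    tss_enrichment: float


@dataclass(frozen=True)
class QCThresholds:
    """Cell-retention thresholds; every comparison is strict."""

    rna_min: float = 1000
    rna_max: float = 25000
    atac_min: float = 1000
    atac_max: float = 100000
    nuc_max: float = 2.0
    tss_min: float = 1.0

    def __post_init__(self) -> None:
        if self.rna_min >= self.rna_max:
            raise ValueError("rna_min must be < rna_max")
        if self.atac_min >= self.atac_max:
            raise ValueError("atac_min must be < atac_max")


def nucleosome_signal(
    fragments_of_cell: Iterable[FragmentRecord],
) -> Optional[float]:
    """Mono-nucleosome to nucleosome-free fragment ratio for one cell.

    Count-weighted; returns None when the cell has no nucleosome-free
    (< 147 bp) fragments, in which case the metric is undefined and the
    cell fails the filter.
    """
    mono = 0
    nfr = 0
    for frag in fragments_of_cell:
        length = frag.interval.width
        if length < NFR_MAX:
            nfr += frag.count
        elif MONO_MIN <= length <= MONO_MAX:
            mono += frag.count
    if nfr == 0:
        return None
    return mono / nfr


def _band_overlap(starts, ends, lo, hi):
    """Vectorized overlap length of [starts, ends) with closed base band [lo, hi]."""
    return np.maximum(0, np.minimum(ends, hi + 1) - np.maximum(starts, lo))


def tss_enrichment(
    fragments_of_cell: Iterable[FragmentRecord],
    gene_models: Sequence[GeneModel],
    cap: float = DEFAULT_TSS_CAP,
) -> float:
    """Center-to-flank coverage ratio over all TSS-centered windows.

    Per-base fragment coverage is aggregated over every window
    [tss - 1000, tss + 1000]; the score is the mean per-base coverage in
    the center bin ([tss - 50, tss + 50]) divided by the mean per-base
    coverage in the two outermost 100 bp flanks.  Zero flanks with zero
    center give 1.0; zero flanks with signal in the center give ``cap``.
    """
    if not gene_models:
        raise ValueError("tss_enrichment requires at least one gene model")
    frags = (
        fragments_of_cell
        if isinstance(fragments_of_cell, FragmentSet)
        else FragmentSet.from_records(fragments_of_cell)
    )
    center_cov = 0.0
    flank_cov = 0.0
    for gene in gene_models:
        tss = gene.tss
        on_chrom = frags.chroms == gene.body.chrom
        if not on_chrom.any():
            continue
        s = frags.starts[on_chrom]
        e = frags.ends[on_chrom]
        c = frags.counts[on_chrom]
        center_cov += float(
            np.sum(c * _band_overlap(s, e, tss - TSS_CENTER_HALF, tss + TSS_CENTER_HALF))
        )
        flank_cov += float(
            np.sum(c * _band_overlap(s, e, tss - TSS_WINDOW, tss - TSS_WINDOW + TSS_FLANK - 1))
        )
        flank_cov += float(
            np.sum(c * _band_overlap(s, e, tss + TSS_WINDOW - TSS_FLANK + 1, tss + TSS_WINDOW))
        )
    center_mean = center_cov / (2 * TSS_CENTER_HALF + 1)
    flank_mean = flank_cov / (2 * TSS_FLANK)
    if flank_mean == 0.0:
        return 1.0 if center_mean == 0.0 else cap
    return center_mean / flank_mean


def compute_cell_qc(
    sample: SampleBundle, cap: float = DEFAULT_TSS_CAP
) -> list:
    """QC metrics for every barcode of the sample's RNA matrix.

    ATAC metrics come from the fragments of the same barcode; barcodes
    with no fragments get zero ATAC reads and an undefined nucleosome
    signal.
    """
    rna_barcodes = list(sample.rna.cell_barcodes)
    frag_barcodes = set(sample.fragments.barcodes.tolist())
    if not frag_barcodes.intersection(rna_barcodes):
        raise ValueError("RNA matrix and fragments share no barcodes")

    rna_totals = sample.rna.cell_totals()
    frags = sample.fragments
    lengths = frags.lengths()
    nfr_mask = lengths < NFR_MAX
    mono_mask = (lengths >= MONO_MIN) & (lengths <= MONO_MAX)

    bc_index = {bc: i for i, bc in enumerate(rna_barcodes)}
    frag_idx = frags.barcode_codes(bc_index)
    keep = frag_idx >= 0
    n = len(rna_barcodes)
    atac_reads = np.bincount(frag_idx[keep], weights=frags.counts[keep], minlength=n)
    nfr = np.bincount(
        frag_idx[keep & nfr_mask], weights=frags.counts[keep & nfr_mask], minlength=n
    )
    mono = np.bincount(
        frag_idx[keep & mono_mask], weights=frags.counts[keep & mono_mask], minlength=n
    )

    # TSS coverage, vectorized over all fragments then split per barcode.
    # Fragments are pre-sorted per chromosome so each TSS window only
    # touches the fragments that can reach it.
    center = np.zeros(n)
    flank = np.zeros(n)
    by_chrom = {}
    for chrom in np.unique(frags.chroms[keep]):
        on = np.flatnonzero((frags.chroms == chrom) & keep)
        order = np.argsort(frags.starts[on], kind="stable")
        by_chrom[chrom] = on[order]
    for gene in sample.genes:
        idx = by_chrom.get(gene.body.chrom)
        if idx is None or not len(idx):
            continue
        tss = gene.tss
        starts_sorted = frags.starts[idx]
        max_len = int(lengths[idx].max())
        lo = np.searchsorted(starts_sorted, tss - TSS_WINDOW - max_len, side="left")
        hi = np.searchsorted(starts_sorted, tss + TSS_WINDOW + 1, side="right")
        if lo == hi:
            continue
        sub = idx[lo:hi]
        s, e, c, bi = frags.starts[sub], frags.ends[sub], frags.counts[sub], frag_idx[sub]
        np.add.at(
            center,
            bi,
            c * _band_overlap(s, e, tss - TSS_CENTER_HALF, tss + TSS_CENTER_HALF),
        )
        fl = c * _band_overlap(s, e, tss - TSS_WINDOW, tss - TSS_WINDOW + TSS_FLANK - 1)
        fl += c * _band_overlap(s, e, tss + TSS_WINDOW - TSS_FLANK + 1, tss + TSS_WINDOW)
        np.add.at(flank, bi, fl)
    center_mean = center / (2 * TSS_CENTER_HALF + 1)
    flank_mean = flank / (2 * TSS_FLANK)

    metrics = []
    for i, bc in enumerate(rna_barcodes):
        if flank_mean[i] == 0.0:
            tss_score = 1.0 if center_mean[i] == 0.0 else cap
        else:
            tss_score = center_mean[i] / flank_mean[i]
        metrics.append(
            CellQCMetrics(
                barcode=bc,
                rna_reads=int(rna_totals[i]),
                atac_reads=int(atac_reads[i]),
                nucleosome_signal=(mono[i] / nfr[i]) if nfr[i] > 0 else None,
                tss_enrichment=float(tss_score),
            )
        )
    return metrics


def passes_filters(m: CellQCMetrics, thresholds: QCThresholds) -> bool:
    return (
        m.rna_reads > thresholds.rna_min
        and m.rna_reads < thresholds.rna_max
        and m.atac_reads > thresholds.atac_min
        and m.atac_reads < thresholds.atac_max
        and m.nucleosome_signal is not None
        and m.nucleosome_signal < thresholds.nuc_max
        and m.tss_enrichment > thresholds.tss_min
    )


def apply_cell_filters(
    metrics: Iterable[CellQCMetrics], thresholds: QCThresholds = QCThresholds()
) -> list:
    """Barcodes retained under the six strict criteria, in input order."""
    return [m.barcode for m in metrics if passes_filters(m, thresholds)]


def write_qc_report(
    metrics: Sequence[CellQCMetrics],
    thresholds: QCThresholds,
    path: Union[str, Path],
) -> None:
    df = pd.DataFrame(
        {
            "barcode": [m.barcode for m in metrics],
            "rna_reads": [m.rna_reads for m in metrics],
            "atac_reads": [m.atac_reads for m in metrics],
            "nucleosome_signal": [
                m.nucleosome_signal if m.nucleosome_signal is not None else math.nan
                for m in metrics
            ],
            "tss_enrichment": [m.tss_enrichment for m in metrics],
            "pass": [passes_filters(m, thresholds) for m in metrics],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_qc_report(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
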