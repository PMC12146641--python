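"""TF ChIP-seq peak-overlap enrichment for a query CRE set.

Each TF's peak set is tested for over-representation among the query CREs
relative to a background CRE universe with a one-sided Fisher exact test
(a CRE counts as a single binary hit regardless of how many peaks of the
TF overlap it); results are BH-adjusted and ranked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .genomics_io import GenomicInterval, read_bed

__all__ = [
    "TFPeakSet",
    "EnrichmentResult",
    "overlap_counts",
    "fisher_enrichment",
    "rank_tfs",
    "enrich_tfs",
    "load_tf_peak_sets",
    "write_enrichment_table",
]


@dataclass(frozen=True)
class TFPeakSet:
    tf_name: str
    sample_label: str
    peaks: tuple

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"TF {self.tf_name!r} has no peaks")


@dataclass(frozen=True)
class EnrichmentResult:
    tf_name: str
    overlap_in_query: int
    overlap_in_background: int
    odds_ratio: float
    pvalue: float

    @property
    def score(self) -> float:
        return -math.log10(self.pvalue) if self.pvalue > 0 else math.inf


def _hits(cres: Sequence[GenomicInterval], tf_peaks: Sequence[GenomicInterval]) -> int:
    """Number of CREs half-open-overlapping >= 1 TF peak (binary per CRE)."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for p in tf_peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    n = 0
    for cre in cres:
        entries = by_chrom.get(cre.chrom)
        if not entries:
            continue
        starts = [s for s, _ in entries]
        lo = int(np.searchsorted(starts, cre.end, side="left"))
        if any(e > cre.start for _, e in entries[:lo]):
            n += 1
    return n


def overlap_counts(
    query_cres: Sequence[GenomicInterval],
    background_cres: Sequence[GenomicInterval],
    tf: TFPeakSet,
) -> List[List[int]]:
    """2x2 table [[hits in query, misses], [hits in rest, misses]] where
    rest is the background universe minus the query."""
    if not query_cres:
        raise ValueError("query CRE set is empty")
    query_keys = {(c.chrom, c.start, c.end) for c in query_cres}
    rest = [c for c in background_cres if (c.chrom, c.start, c.end) not in query_keys]
    if not rest:
        raise ValueError("background minus query is empty")
    a = _hits(query_cres, tf.peaks)
    c = _hits(rest, tf.peaks)
    return [[a, len(query_cres) - a], [c, len(rest) - c]]


def fisher_enrichment(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """One-sided (enrichment) Fisher exact test; odds ratio is ad/bc with
    the conventional 0 and inf limits."""
    (a, b), (c, d) = table
    if a * d == 0:
        odds = 0.0
    elif b * c == 0:
        odds = math.inf
    else:
        odds = (a * d) / (b * c)
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return odds, float(p)


def rank_tfs(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """BH-adjust p-values across TFs; sort by adjusted p, then odds ratio
    descending, then name."""
    results = list(results)
    if not results:
        return pd.DataFrame(
            columns=["tf_name", "overlap_in_query", "overlap_in_background",
                     "odds_ratio", "pvalue", "adjusted_pvalue", "score"]
        )
    pvals = [r.pvalue for r in results]
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    df = pd.DataFrame(
        {
            "tf_name": [r.tf_name for r in results],
            "overlap_in_query": [r.overlap_in_query for r in results],
            "overlap_in_background": [r.overlap_in_background for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "pvalue": pvals,
            "adjusted_pvalue": adj,
            "score": [r.score for r in results],
        }
    )
    df["_neg_or"] = -df["odds_ratio"].fillna(-np.inf)
    df = df.sort_values(
        ["adjusted_pvalue", "_neg_or", "tf_name"], kind="stable"
    ).drop(columns="_neg_or")
    return df.reset_index(drop=True)


def enrich_tfs(
    query_cres: Sequence[GenomicInterval],
    background_cres: Sequence[GenomicInterval],
    tf_sets: Sequence[TFPeakSet],
) -> pd.DataFrame:
    results = []
    for tf in tf_sets:
        table = overlap_counts(query_cres, background_cres, tf)
        odds, p = fisher_enrichment(table)
        results.append(
            EnrichmentResult(
                tf_name=tf.tf_name,
                overlap_in_query=table[0][0],
                overlap_in_background=table[1][0],
                odds_ratio=odds,
                pvalue=p,
            )
        )
    return rank_tfs(results)


def load_tf_peak_sets(source: Union[str, Path]) -> List[TFPeakSet]:
    """TF peak sets from a directory of per-TF BED files (filename stem =
    TF name) or a single 4-column BED with the TF name in column 4."""
    source = Path(source)
    sets: List[TFPeakSet] = []
    if source.is_dir():
        for bed in sorted(source.glob("*.bed")):
            peaks = read_bed(bed)
            if peaks:
                sets.append(TFPeakSet(bed.stem, bed.stem, tuple(peaks)))
        return sets
    by_tf: Dict[str, List[GenomicInterval]] = {}
    for iv in read_bed(source):
        if not iv.annotations:
            raise ValueError(f"{source}: 4th column (TF name) required")
        by_tf.setdefault(iv.annotations[0], []).append(iv)
    return [TFPeakSet(tf, tf, tuple(peaks)) for tf, peaks in sorted(by_tf.items())]


def write_enrichment_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)
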