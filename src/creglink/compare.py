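"""Cross-sample layer: union CREs, linkage remapping, tissue-presence
statistics, tissue-specific gene-linked CREs, and the single-sample
region view.

Union CREs are the maximal transitive merge of all samples' peaks under
half-open overlap (bookended intervals stay separate).  A linkage is
"present in a tissue" when it is present in at least one sample of that
tissue; a union CRE is tissue-specific when its presence fraction exceeds
1/2 in the target tissue and stays below 1/2 in every other tissue (both
strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genomics_io import (
    GenomicInterval,
    LinkageRecord,
    SampleBundle,
)
from .matrices import lognormalize

__all__ = [
    "UnionCREMap",
    "PresenceMatrix",
    "TissueSpecRule",
    "RemappedLinkage",
    "RegionView",
    "build_union_cres",
    "remap_linkages",
    "tissue_presence_distribution",
    "gene_linked_cre_matrix",
    "restrict_to_celltype",
    "tissue_specific_cres",
    "region_view",
    "write_region_view",
]


class RemappedLinkage(NamedTuple):
    gene_id: str
    cre_index: int
    sample_id: str
    score: float
    pvalue: float


@dataclass
class UnionCREMap:
    """Merged cross-sample CRE set plus peak -> union CRE lookup."""

    union_cres: List[GenomicInterval]
    mapping: Dict[Tuple[str, Tuple[str, int, int]], int]

    def lookup(self, sample_id: str, peak: GenomicInterval) -> int:
        key = (sample_id, (peak.chrom, peak.start, peak.end))
        if key not in self.mapping:
            raise KeyError(
                f"peak {peak} of sample {sample_id!r} is not in the union map"
            )
        return self.mapping[key]


@dataclass
class PresenceMatrix:
    """Boolean presence of (gene-linked) union CREs across samples.

    ``scores`` carries the remapped linkage score where present (NaN
    elsewhere); ``row_keys`` are union CRE indices (single-gene view) or
    (gene, CRE-index) pairs.
    """

    row_keys: list
    sample_ids: List[str]
    present: np.ndarray  # bool, rows x samples
    sample_tissues: Dict[str, str]
    scores: Optional[np.ndarray] = None
    mean_expression: Optional[Dict[str, float]] = None
    union_cres: Optional[List[GenomicInterval]] = None

    def __post_init__(self) -> None:
        if self.present.shape != (len(self.row_keys), len(self.sample_ids)):
            raise ValueError("presence matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.present, index=[str(k) for k in self.row_keys], columns=self.sample_ids
        )


@dataclass(frozen=True)
class TissueSpecRule:
    target_tissue: str
    in_fraction_threshold: float = 0.5  # presence fraction must exceed this
    out_fraction_threshold: float = 0.5  # and stay below this elsewhere

    def __post_init__(self) -> None:
        for t in (self.in_fraction_threshold, self.out_fraction_threshold):
            if not (0 < t < 1):
                raise ValueError("thresholds must be in (0, 1)")


def _merge_sorted(intervals: List[GenomicInterval]) -> List[GenomicInterval]:
    """Transitive merge of (chrom, start)-sorted intervals; half-open, so
    bookended intervals are not merged."""
    merged: List[GenomicInterval] = []
    for iv in intervals:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def build_union_cres(
    peak_sets: Dict[str, Sequence[GenomicInterval]],
    species: Optional[Dict[str, str]] = None,
) -> UnionCREMap:
    """Pool all samples' peaks and merge overlapping ones into maximal
    union CREs; each original peak maps to the unique CRE containing it.

    ``species`` (sample -> species) guards against mixing species in one
    union set.
    """
    if species is not None:
        distinct = {species[s] for s in peak_sets if s in species}
        if len(distinct) > 1:
            raise ValueError(
                f"refusing to merge peaks across species: {sorted(distinct)}"
            )
    pooled: List[Tuple[GenomicInterval, str]] = [
        (p, sid) for sid, peaks in peak_sets.items() for p in peaks
    ]
    pooled.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    union = _merge_sorted([p for p, _ in pooled])

    starts_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for i, cre in enumerate(union):
        starts_by_chrom.setdefault(cre.chrom, []).append((cre.start, i))
    mapping: Dict[Tuple[str, Tuple[str, int, int]], int] = {}
    for p, sid in pooled:
        entries = starts_by_chrom[p.chrom]
        starts = [s for s, _ in entries]
        pos = int(np.searchsorted(starts, p.start, side="right")) - 1
        idx = entries[pos][1]
        assert union[idx].contains(p), f"peak {p} not contained in its union CRE"
        mapping[(sid, (p.chrom, p.start, p.end))] = idx
    return UnionCREMap(union, mapping)


def remap_linkages(
    linkages: Iterable[LinkageRecord], cre_map: UnionCREMap
) -> List[RemappedLinkage]:
    """Replace each linkage's peak with its union CRE index; duplicate
    (gene, CRE, sample) rows collapse to the smallest p-value."""
    best: Dict[Tuple[str, int, str], RemappedLinkage] = {}
    for rec in linkages:
        idx = cre_map.lookup(rec.sample_id, rec.peak)
        key = (rec.gene_id, idx, rec.sample_id)
        row = RemappedLinkage(rec.gene_id, idx, rec.sample_id, rec.score, rec.pvalue)
        if key not in best or row.pvalue < best[key].pvalue:
            best[key] = row
    return [best[k] for k in sorted(best)]


def tissue_presence_distribution(
    remapped: Iterable[RemappedLinkage],
    sample_tissues: Dict[str, str],
) -> Tuple[Dict[int, int], Dict[int, float]]:
    """Histogram k -> number of distinct (gene, union CRE) linkages present
    in exactly k tissues, plus cumulative fractions P(<= k)."""
    tissues_of: Dict[Tuple[str, int], set] = {}
    for row in remapped:
        if row.sample_id not in sample_tissues:
            raise KeyError(f"sample {row.sample_id!r} has no tissue label")
        tissues_of.setdefault((row.gene_id, row.cre_index), set()).add(
            sample_tissues[row.sample_id]
        )
    hist: Dict[int, int] = {}
    for tset in tissues_of.values():
        hist[len(tset)] = hist.get(len(tset), 0) + 1
    total = sum(hist.values())
    cumulative: Dict[int, float] = {}
    running = 0
    for k in sorted(hist):
        running += hist[k]
        cumulative[k] = running / total
    return hist, cumulative


def restrict_to_celltype(
    linkages: Iterable[LinkageRecord],
    celltype_peaks: Sequence[GenomicInterval],
) -> List[LinkageRecord]:
    """Keep linkages whose peak overlaps at least one cell-type-level peak."""
    return [
        rec
        for rec in linkages
        if any(rec.peak.overlaps(cp) for cp in celltype_peaks)
    ]


def gene_linked_cre_matrix(
    gene: str,
    sample_ids: Sequence[str],
    cre_map: UnionCREMap,
    remapped: Iterable[RemappedLinkage],
    sample_tissues: Dict[str, str],
    mean_expression: Optional[Dict[str, float]] = None,
) -> PresenceMatrix:
    """Union CREs ever linked to ``gene`` in the selected samples, ordered
    by genomic position, with the linkage score where present."""
    selected = set(sample_ids)
    rows = sorted(
        {r.cre_index for r in remapped if r.gene_id == gene and r.sample_id in selected},
        key=lambda i: (cre_map.union_cres[i].chrom, cre_map.union_cres[i].start),
    )
    row_pos = {idx: r for r, idx in enumerate(rows)}
    col_pos = {sid: c for c, sid in enumerate(sample_ids)}
    present = np.zeros((len(rows), len(sample_ids)), dtype=bool)
    scores = np.full((len(rows), len(sample_ids)), np.nan)
    for r in remapped:
        if r.gene_id != gene or r.sample_id not in selected:
            continue
        i, j = row_pos[r.cre_index], col_pos[r.sample_id]
        present[i, j] = True
        scores[i, j] = r.score
    return PresenceMatrix(
        row_keys=rows,
        sample_ids=list(sample_ids),
        present=present,
        sample_tissues={s: sample_tissues[s] for s in sample_ids},
        scores=scores,
        mean_expression=mean_expression,
        union_cres=[cre_map.union_cres[i] for i in rows],
    )


def tissue_specific_cres(
    matrix: PresenceMatrix, rule: TissueSpecRule
) -> List:
    """Row keys specific to the rule's target tissue.

    A CRE qualifies iff its presence fraction is strictly above 1/2 in the
    target tissue and strictly below 1/2 in every other tissue.
    """
    tissues = sorted(set(matrix.sample_tissues.values()))
    if rule.target_tissue not in tissues:
        raise ValueError(f"unknown tissue {rule.target_tissue!r}")
    cols_by_tissue = {
        t: [j for j, s in enumerate(matrix.sample_ids) if matrix.sample_tissues[s] == t]
        for t in tissues
    }
    if not cols_by_tissue[rule.target_tissue]:
        raise ValueError(f"tissue {rule.target_tissue!r} has no samples")
    out = []
    for i, key in enumerate(matrix.row_keys):
        frac_in = matrix.present[i, cols_by_tissue[rule.target_tissue]].mean()
        if not frac_in > rule.in_fraction_threshold:
            continue
        ok = True
        for t in tissues:
            if t == rule.target_tissue or not cols_by_tissue[t]:
                continue
            if not matrix.present[i, cols_by_tissue[t]].mean() < rule.out_fraction_threshold:
                ok = False
                break
        if ok:
            out.append(key)
    return out


# ---------------------------------------------------------------------------
# Mode 3: region view


@dataclass
class RegionView:
    """Per-group accessibility tracks plus expression and annotation for a
    gene-centered window."""

    gene_id: str
    region: GenomicInterval
    bin_size: int
    bin_starts: np.ndarray
    tracks: Dict[str, np.ndarray]  # group -> normalized per-base coverage per bin
    expression: Dict[str, np.ndarray]  # group -> per-cell lognorm expression
    genes_in_region: list
    cres_in_region: list
    linkages: list


def region_view(
    sample: SampleBundle,
    gene: str,
    linkages: Sequence[LinkageRecord] = (),
    groups: Optional[Dict[str, str]] = None,
    flank: int = 10_000,
    bin_size: int = 100,
    scale: float = 1e4,
) -> RegionView:
    """Normalized per-group accessibility over the gene's flanked window,
    with per-group expression, local gene/CRE annotation and linkage arcs.

    Coverage is per-base mean per bin, divided by the group's total
    fragment count and multiplied by ``scale`` (depth normalization).
    """
    gene_model = next((g for g in sample.genes if g.gene_id == gene), None)
    if gene_model is None:
        raise ValueError(f"gene {gene!r} not in the sample annotation")
    if groups is None:
        groups = dict(sample.cell_types) or {
            bc: sample.sample_id for bc in sample.rna.cell_barcodes
        }
    start = max(0, gene_model.body.start - flank)
    end = gene_model.body.end + flank
    region = GenomicInterval(gene_model.body.chrom, start, end)
    bin_starts = np.arange(start, end, bin_size)
    n_bins = len(bin_starts)

    frags = sample.fragments
    group_names = sorted(set(groups.values()))
    group_of = np.array(
        [groups.get(bc, "") for bc in frags.barcodes], dtype=object
    )
    tracks: Dict[str, np.ndarray] = {}
    for gname in group_names:
        member = group_of == gname
        total = float(frags.counts[member].sum())
        cov = np.zeros(n_bins)
        on = member & (frags.chroms == region.chrom) & (frags.starts < end) & (frags.ends > start)
        if on.any():
            s, e, c = frags.starts[on], frags.ends[on], frags.counts[on]
            for b in range(n_bins):
                b_lo = bin_starts[b]
                b_hi = min(b_lo + bin_size, end)
                ov = np.maximum(0, np.minimum(e, b_hi) - np.maximum(s, b_lo))
                cov[b] = float(np.sum(c * ov)) / (b_hi - b_lo)
        tracks[gname] = (cov / total * scale) if total > 0 else cov

    rna_log = lognormalize(sample.rna) if sample.rna.layer == "raw" else sample.rna
    expr_row = None
    if gene in rna_log.feature_ids:
        gi = rna_log.feature_ids.index(gene)
        expr_row = np.asarray(
            rna_log.values[gi].todense()
        ).ravel() if hasattr(rna_log.values, "todense") else rna_log.values[gi]
    expression = {}
    for gname in group_names:
        cells = [j for j, bc in enumerate(rna_log.cell_barcodes) if groups.get(bc) == gname]
        expression[gname] = (
            expr_row[cells] if expr_row is not None else np.zeros(len(cells))
        )

    genes_in_region = [g for g in sample.genes if g.body.overlaps(region)]
    cres_in_region = [p for p in sample.peaks if p.overlaps(region)]
    gene_links = [r for r in linkages if r.gene_id == gene]
    return RegionView(
        gene_id=gene,
        region=region,
        bin_size=bin_size,
        bin_starts=bin_starts,
        tracks=tracks,
        expression=expression,
        genes_in_region=genes_in_region,
        cres_in_region=cres_in_region,
        linkages=gene_links,
    )


def write_region_view(view: RegionView, outdir: Union[str, Path]) -> None:
    """Export tracks as one bedGraph per group plus TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gname, cov in view.tracks.items():
        safe = gname.replace("/", "_").replace(" ", "_")
        with open(outdir / f"track_{safe}.bedGraph", "w") as fh:
            for b, v in zip(view.bin_starts, cov):
                b_hi = min(int(b) + view.bin_size, view.region.end)
                fh.write(f"{view.region.chrom}\t{int(b)}\t{b_hi}\t{v:.6g}\n")
    expr_rows = [
        (g, float(v)) for g, vals in view.expression.items() for v in vals
    ]
    pd.DataFrame(expr_rows, columns=["group", "expression"]).to_csv(
        outdir / "expression.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(g.gene_id, g.body.chrom, g.body.start, g.body.end, g.body.strand)
         for g in view.genes_in_region],
        columns=["gene", "chrom", "start", "end", "strand"],
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(p.chrom, p.start, p.end) for p in view.cres_in_region],
        columns=["chrom", "start", "end"],
    ).to_csv(outdir / "cres.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(r.gene_id, r.peak.chrom, r.peak.start, r.peak.end, r.score, r.pvalue)
         for r in view.linkages],
        columns=["gene_id", "chrom", "start", "end", "score", "pvalue"],
    ).to_csv(outdir / "linkages.tsv", sep="\t", index=False)
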