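"""Synthetic multiome samples and multi-tissue corpora with planted,
known structure.

Counts follow a Poisson-lognormal model: every (feature, cell) entry is
Poisson with a lognormal rate multiplier.  A planted CRE-gene link shares
one latent activity per cell between the gene and its peak; the peak-side
exponent gamma is calibrated so the realized Pearson correlation of the
log-normalized values approximates the requested target.  Fragments are
written one-per-unit-count, fully inside their peak, with lengths drawn
from both nucleosome bands so QC metrics are exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp

from .genomics_io import (
    CountMatrix,
    FragmentSet,
    GeneModel,
    GenomicInterval,
    LinkageRecord,
    SampleBundle,
    write_bed,
    write_counts_mtx,
    write_fragments,
    write_gene_models,
)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_sample",
    "simulate_corpus",
    "simulate_tf_peaks",
    "write_sample_bundle",
    "read_sample_bundle",
    "PRESETS",
]

GENE_SPACING = 120_000
GENE_LENGTH = 2_000
PROMOTER_HALF = 250
DISTAL_WIDTH = 400
# distal peak offsets from the TSS; all within the 50 kb linkage window and
# clear of the +/-1000 bp TSS QC window
DISTAL_OFFSETS = (8_000, -15_000, 22_000, -30_000, 38_000, -44_000)
NFR_LENGTHS = (60, 140)
MONO_LENGTHS = (160, 280)
P_NFR = 0.6  # keeps per-cell nucleosome signal ~0.67, well under 2


@dataclass(frozen=True)
class SimulationSpec:
    n_tissues: int = 3
    samples_per_tissue: int = 2
    n_cells_per_sample: int = 300
    n_genes: int = 200
    n_peaks: int = 600
    fraction_linked_peaks: float = 0.25
    planted_link_r: float = 0.6
    fraction_tissue_specific: float = 0.5
    # None -> derived so per-cell totals land near 2,500 reads per modality
    # (comfortably inside the QC windows) at any spec size
    gene_mean_mu: Optional[float] = None
    gene_mean_sigma: float = 0.2
    peak_mean_mu: Optional[float] = None
    peak_mean_sigma: float = 0.15
    latent_sigma: float = 0.5
    gamma: Optional[float] = None  # calibrated from planted_link_r when None
    species: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.fraction_linked_peaks, self.fraction_tissue_specific):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must be in [0, 1]")
        for c in (
            self.n_tissues,
            self.samples_per_tissue,
            self.n_cells_per_sample,
            self.n_genes,
            self.n_peaks,
        ):
            if c < 1:
                raise ValueError("all counts must be >= 1")
        if self.n_peaks % self.n_genes != 0 or self.n_peaks // self.n_genes < 2:
            raise ValueError(
                "n_peaks must be a multiple of n_genes with >= 2 peaks per gene"
            )
        if self.n_peaks // self.n_genes - 1 > len(DISTAL_OFFSETS):
            raise ValueError("too many peaks per gene for the genome layout")
        if self.gene_mean_mu is None:
            object.__setattr__(self, "gene_mean_mu", float(np.log(2500 / self.n_genes)))
        if self.peak_mean_mu is None:
            object.__setattr__(self, "peak_mean_mu", float(np.log(2500 / self.n_peaks)))


PRESETS: Dict[str, SimulationSpec] = {
    "tiny": SimulationSpec(
        n_tissues=2,
        samples_per_tissue=2,
        n_cells_per_sample=60,
        n_genes=30,
        n_peaks=90,
        fraction_linked_peaks=0.5,
    ),
    "default": SimulationSpec(),
}


@dataclass
class GroundTruth:
    """What the generator planted, keyed so downstream results can be
    checked exactly."""

    spec: SimulationSpec
    gamma: float
    sample_tissues: Dict[str, str] = field(default_factory=dict)
    # sample_id -> list of (gene_id, peak interval) planted in that sample
    true_links: Dict[str, List[Tuple[str, GenomicInterval]]] = field(default_factory=dict)
    # (gene_id, (chrom, start, end)) -> intended number of tissues
    tissue_counts: Dict[Tuple[str, Tuple[str, int, int]], int] = field(default_factory=dict)
    # (gene_id, (chrom, start, end)) -> its target tissue, for specific links
    tissue_specific: Dict[Tuple[str, Tuple[str, int, int]], str] = field(default_factory=dict)
    # planted ubiquitous (shared) link keys
    shared: List[Tuple[str, Tuple[str, int, int]]] = field(default_factory=list)
    cell_types: Dict[str, Dict[str, str]] = field(default_factory=dict)
    tf_truth: Dict[str, bool] = field(default_factory=dict)
    # sample_id -> intended peak-by-cell count matrix (fragments reconstruct it)
    intended_atac: Dict[str, np.ndarray] = field(default_factory=dict)

    def intended_histogram(self) -> Dict[int, int]:
        hist: Dict[int, int] = {}
        for k in self.tissue_counts.values():
            hist[k] = hist.get(k, 0) + 1
        return hist

    def linkage_records(self, sample_id: str) -> List[LinkageRecord]:
        """Idealized linkage table for one sample, straight from the truth."""
        return [
            LinkageRecord(
                gene_id=g,
                peak=p,
                score=self.spec.planted_link_r,
                zscore=10.0,
                pvalue=1e-9,
                sample_id=sample_id,
            )
            for g, p in self.true_links.get(sample_id, [])
        ]


# ---------------------------------------------------------------------------
# Genome layout


def build_gene_models(spec: SimulationSpec) -> List[GeneModel]:
    genes = []
    per_chrom = (spec.n_genes + 1) // 2
    for i in range(spec.n_genes):
        chrom = "chr1" if i < per_chrom else "chr2"
        slot = i if i < per_chrom else i - per_chrom
        tss = 60_000 + slot * GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            body = GenomicInterval(chrom, tss, tss + GENE_LENGTH, "+")
        else:
            body = GenomicInterval(chrom, tss - GENE_LENGTH + 1, tss + 1, "-")
        genes.append(GeneModel(f"gene{i:04d}", body))
    return genes


def build_peaks(spec: SimulationSpec, genes: Sequence[GeneModel]) -> Tuple[List[GenomicInterval], Dict[int, int], List[int]]:
    """Peaks for every gene: one promoter peak plus distal peaks.

    Returns (peaks, gene index -> first distal peak index, promoter peak
    indices).
    """
    per_gene = spec.n_peaks // spec.n_genes
    peaks: List[GenomicInterval] = []
    first_distal: Dict[int, int] = {}
    promoters: List[int] = []
    for gi, gene in enumerate(genes):
        tss = gene.tss
        promoters.append(len(peaks))
        peaks.append(
            GenomicInterval(gene.body.chrom, tss - PROMOTER_HALF, tss + PROMOTER_HALF)
        )
        for d in range(per_gene - 1):
            off = DISTAL_OFFSETS[d]
            start = tss + off
            if d == 0:
                first_distal[gi] = len(peaks)
            peaks.append(GenomicInterval(gene.body.chrom, start, start + DISTAL_WIDTH))
    return peaks, first_distal, promoters


def chrom_sizes_for(genes: Sequence[GeneModel]) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    for g in genes:
        sizes[g.body.chrom] = max(
            sizes.get(g.body.chrom, 0), g.body.end + GENE_SPACING
        )
    return sizes


# ---------------------------------------------------------------------------
# Count model


def _lognormal_mean(sigma: float, power: float = 1.0) -> float:
    return float(np.exp(0.5 * (power * sigma) ** 2))


def calibrate_gamma(spec: SimulationSpec, n_cells: int = 4000) -> float:
    """Grid-search the peak-side latent exponent so the realized Pearson
    correlation of log1p counts for a planted pair matches the target."""
    if spec.gamma is not None:
        return spec.gamma
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(spec.seed, 0xCA11B)))
    lam_g = float(np.exp(spec.gene_mean_mu))
    lam_p = float(np.exp(spec.peak_mean_mu))
    # apply the pipeline's log-normalization at the expected library sizes
    # so the calibration sees the same value transform as the linkage stage
    scale_g = 1e4 / (spec.n_genes * np.exp(spec.gene_mean_mu + spec.gene_mean_sigma**2 / 2))
    scale_p = 1e4 / (spec.n_peaks * np.exp(spec.peak_mean_mu + spec.peak_mean_sigma**2 / 2))
    u = rng.lognormal(0.0, spec.latent_sigma, n_cells)
    g_counts = rng.poisson(lam_g * u / _lognormal_mean(spec.latent_sigma))
    lg = np.log1p(g_counts * scale_g)
    best_gamma, best_err = 1.0, np.inf
    for gamma in np.arange(0.2, 4.01, 0.1):
        rate = lam_p * u**gamma / _lognormal_mean(spec.latent_sigma, gamma)
        p_counts = rng.poisson(rate)
        lp = np.log1p(p_counts * scale_p)
        if lp.std() == 0 or lg.std() == 0:
            continue
        r = float(np.corrcoef(lg, lp)[0, 1])
        err = abs(r - spec.planted_link_r)
        if err < best_err:
            best_gamma, best_err = float(gamma), err
    return best_gamma


def _plan_links(spec: SimulationSpec, genes, first_distal, rng) -> Tuple[List[int], List[int], Dict[int, int]]:
    """Choose linked genes and split them into shared vs tissue-specific.

    Returns (shared gene indices, specific gene indices, gene -> tissue
    index for the specific ones).
    """
    n_distal_per_gene = spec.n_peaks // spec.n_genes - 1
    n_linked = int(round(spec.fraction_linked_peaks * spec.n_genes * n_distal_per_gene))
    n_linked = min(n_linked, spec.n_genes)  # at most one planted link per gene
    linked = sorted(rng.choice(spec.n_genes, size=n_linked, replace=False).tolist())
    n_specific = int(round(spec.fraction_tissue_specific * n_linked))
    specific = sorted(rng.choice(linked, size=n_specific, replace=False).tolist())
    shared = [g for g in linked if g not in set(specific)]
    tissue_of = {g: int(rng.integers(spec.n_tissues)) for g in specific}
    return shared, specific, tissue_of


def _simulate_counts(
    spec: SimulationSpec,
    gamma: float,
    lam_g: np.ndarray,
    lam_p: np.ndarray,
    active_links: Dict[int, int],  # gene index -> linked peak index
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    n_cells = spec.n_cells_per_sample
    sig = spec.latent_sigma
    e1 = _lognormal_mean(sig)
    eg = _lognormal_mean(sig, gamma)

    v_g = rng.lognormal(0.0, sig, size=(spec.n_genes, n_cells))
    rna = rng.poisson(lam_g[:, None] * v_g / e1)
    v_p = rng.lognormal(0.0, sig, size=(spec.n_peaks, n_cells))
    atac = rng.poisson(lam_p[:, None] * v_p / e1)

    for gi, pi in sorted(active_links.items()):
        u = rng.lognormal(0.0, sig, n_cells)
        rna[gi] = rng.poisson(lam_g[gi] * u / e1)
        atac[pi] = rng.poisson(lam_p[pi] * u**gamma / eg)
    return rna.astype(np.int64), atac.astype(np.int64)


def _fragments_from_counts(
    atac: np.ndarray,
    peaks: Sequence[GenomicInterval],
    barcodes: Sequence[str],
    rng: np.random.Generator,
) -> FragmentSet:
    """One fragment per unit count, fully inside its peak."""
    pk_idx, cell_idx = np.nonzero(atac)
    reps = atac[pk_idx, cell_idx]
    pk_rep = np.repeat(pk_idx, reps)
    cell_rep = np.repeat(cell_idx, reps)
    k = len(pk_rep)
    nfr = rng.random(k) < P_NFR
    lengths = np.where(
        nfr,
        rng.integers(NFR_LENGTHS[0], NFR_LENGTHS[1] + 1, k),
        rng.integers(MONO_LENGTHS[0], MONO_LENGTHS[1] + 1, k),
    )
    p_start = np.array([p.start for p in peaks])
    p_width = np.array([p.width for p in peaks])
    slack = p_width[pk_rep] - lengths
    if (slack < 0).any():
        raise ValueError("peak narrower than a fragment; infeasible layout")
    starts = p_start[pk_rep] + rng.integers(0, slack + 1)
    chrom_arr = np.array([p.chrom for p in peaks], dtype=object)[pk_rep]
    bc_arr = np.array(list(barcodes), dtype=object)[cell_rep]
    return FragmentSet(
        chrom_arr,
        starts,
        starts + lengths,
        bc_arr,
        np.ones(k, dtype=np.int64),
    )


def simulate_sample(
    spec: SimulationSpec,
    tissue: str = "tissue0",
    sample_id: str = "sample0",
    sample_index: int = 0,
    active_links: Optional[Dict[int, int]] = None,
) -> Tuple[SampleBundle, GroundTruth]:
    """Simulate one multiome sample; planted links default to the spec's
    shared+specific plan restricted to this tissue."""
    genes = build_gene_models(spec)
    peaks, first_distal, _ = build_peaks(spec, genes)
    gamma = calibrate_gamma(spec)

    plan_rng = np.random.default_rng(np.random.SeedSequence(entropy=(spec.seed, 0x91A9)))
    lam_g = plan_rng.lognormal(spec.gene_mean_mu, spec.gene_mean_sigma, spec.n_genes)
    lam_p = plan_rng.lognormal(spec.peak_mean_mu, spec.peak_mean_sigma, spec.n_peaks)
    if active_links is None:
        shared, specific, tissue_of = _plan_links(spec, genes, first_distal, plan_rng)
        tissue_idx = int(tissue[len("tissue"):]) if tissue.startswith("tissue") else 0
        active_links = {g: first_distal[g] for g in shared}
        active_links.update(
            {g: first_distal[g] for g in specific if tissue_of[g] == tissue_idx}
        )

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(spec.seed, 1 + sample_index))
    )
    rna, atac = _simulate_counts(spec, gamma, lam_g, lam_p, active_links, rng)
    barcodes = [f"{sample_id}-C{j:04d}" for j in range(spec.n_cells_per_sample)]
    feature_ids = [g.gene_id for g in genes]
    rna_cm = CountMatrix(sp.csr_matrix(rna), feature_ids, barcodes, "raw")
    fragments = _fragments_from_counts(atac, peaks, barcodes, rng)
    cell_types = {
        bc: ("typeA" if j % 2 == 0 else "typeB") for j, bc in enumerate(barcodes)
    }
    bundle = SampleBundle(
        sample_id=sample_id,
        rna=rna_cm,
        fragments=fragments,
        peaks=list(peaks),
        genes=genes,
        tissue=tissue,
        species=spec.species,
        source_name=tissue,
        cell_types=cell_types,
    )
    truth = GroundTruth(spec=spec, gamma=gamma)
    truth.sample_tissues[sample_id] = tissue
    truth.true_links[sample_id] = [
        (genes[g].gene_id, peaks[p]) for g, p in sorted(active_links.items())
    ]
    truth.cell_types[sample_id] = cell_types
    truth.intended_atac[sample_id] = atac
    return bundle, truth


def simulate_corpus(spec: SimulationSpec) -> Tuple[List[SampleBundle], GroundTruth]:
    """A multi-tissue corpus with shared links planted everywhere and
    tissue-specific links planted only in their tissue's samples."""
    genes = build_gene_models(spec)
    peaks, first_distal, _ = build_peaks(spec, genes)
    gamma = calibrate_gamma(spec)
    plan_rng = np.random.default_rng(np.random.SeedSequence(entropy=(spec.seed, 0x91A9)))
    # same lambda draws as simulate_sample: keep the RNG call order identical
    _ = plan_rng.lognormal(spec.gene_mean_mu, spec.gene_mean_sigma, spec.n_genes)
    _ = plan_rng.lognormal(spec.peak_mean_mu, spec.peak_mean_sigma, spec.n_peaks)
    shared, specific, tissue_of = _plan_links(spec, genes, first_distal, plan_rng)

    truth = GroundTruth(spec=spec, gamma=gamma)
    bundles: List[SampleBundle] = []
    sample_index = 0
    for t in range(spec.n_tissues):
        tissue = f"tissue{t}"
        for s in range(spec.samples_per_tissue):
            sample_id = f"{tissue}_s{s}"
            active = {g: first_distal[g] for g in shared}
            active.update(
                {g: first_distal[g] for g in specific if tissue_of[g] == t}
            )
            bundle, st = simulate_sample(
                spec,
                tissue=tissue,
                sample_id=sample_id,
                sample_index=sample_index,
                active_links=active,
            )
            bundles.append(bundle)
            truth.sample_tissues[sample_id] = tissue
            truth.true_links[sample_id] = st.true_links[sample_id]
            truth.cell_types[sample_id] = st.cell_types[sample_id]
            truth.intended_atac[sample_id] = st.intended_atac[sample_id]
            sample_index += 1

    def key_of(g: int) -> Tuple[str, Tuple[str, int, int]]:
        p = peaks[first_distal[g]]
        return (genes[g].gene_id, (p.chrom, p.start, p.end))

    for g in shared:
        truth.tissue_counts[key_of(g)] = spec.n_tissues
        truth.shared.append(key_of(g))
    for g in specific:
        truth.tissue_counts[key_of(g)] = 1
        truth.tissue_specific[key_of(g)] = f"tissue{tissue_of[g]}"
    return bundles, truth


def simulate_tf_peaks(
    target_cres: Sequence[GenomicInterval],
    background_cres: Sequence[GenomicInterval],
    n_enriched: int = 1,
    n_decoys: int = 5,
    enrichment_fraction_in: float = 0.8,
    enrichment_fraction_out: float = 0.05,
    seed: int = 0,
) -> Tuple[Dict[str, List[GenomicInterval]], Dict[str, bool]]:
    """Planted-enriched TFs hit the stated fraction of target/background
    CREs; decoy TFs hit all CREs at the background rate.

    Returns (tf name -> peaks, tf name -> is planted-enriched).
    """
    rng = np.random.default_rng(seed)
    target_keys = {(c.chrom, c.start, c.end) for c in target_cres}
    rest = [c for c in background_cres if (c.chrom, c.start, c.end) not in target_keys]

    def peak_inside(cre: GenomicInterval) -> GenomicInterval:
        w = min(100, cre.width)
        start = cre.start + int(rng.integers(0, cre.width - w + 1))
        return GenomicInterval(cre.chrom, start, start + w)

    sets: Dict[str, List[GenomicInterval]] = {}
    truth: Dict[str, bool] = {}
    for i in range(n_enriched):
        name = f"TF_enriched{i}"
        peaks = [peak_inside(c) for c in target_cres if rng.random() < enrichment_fraction_in]
        peaks += [peak_inside(c) for c in rest if rng.random() < enrichment_fraction_out]
        if not peaks:
            peaks = [peak_inside(target_cres[0])]
        sets[name] = peaks
        truth[name] = True
    for i in range(n_decoys):
        name = f"TF_decoy{i}"
        peaks = [
            peak_inside(c)
            for c in background_cres
            if rng.random() < enrichment_fraction_out
        ]
        if not peaks:
            peaks = [peak_inside(rest[0] if rest else background_cres[0])]
        sets[name] = peaks
        truth[name] = False
    return sets, truth


# ---------------------------------------------------------------------------
# On-disk bundles


def write_sample_bundle(bundle: SampleBundle, outdir: Union[str, Path]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts_mtx(
        bundle.rna,
        outdir / "matrix.mtx",
        outdir / "features.tsv",
        outdir / "barcodes.tsv",
    )
    write_fragments(bundle.fragments, outdir / "fragments.tsv")
    write_bed(bundle.peaks, outdir / "peaks.bed")
    write_gene_models(bundle.genes, outdir / "genes.tsv")
    meta = {
        "sample_id": bundle.sample_id,
        "tissue": bundle.tissue,
        "species": bundle.species,
        "source_name": bundle.source_name,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    if bundle.cell_types:
        with open(outdir / "cell_types.tsv", "w") as fh:
            fh.write("barcode\tcell_type\n")
            for bc, ct in bundle.cell_types.items():
                fh.write(f"{bc}\t{ct}\n")


def read_sample_bundle(indir: Union[str, Path]) -> SampleBundle:
    from .genomics_io import read_counts_mtx, read_bed, read_gene_models

    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    cell_types: Dict[str, str] = {}
    ct_path = indir / "cell_types.tsv"
    if ct_path.exists():
        for line in ct_path.read_text().splitlines()[1:]:
            bc, ct = line.split("\t")
            cell_types[bc] = ct
    return SampleBundle(
        sample_id=meta["sample_id"],
        rna=read_counts_mtx(
            indir / "matrix.mtx", indir / "features.tsv", indir / "barcodes.tsv"
        ),
        fragments=FragmentSet.from_file(indir / "fragments.tsv"),
        peaks=read_bed(indir / "peaks.bed"),
        genes=read_gene_models(indir / "genes.tsv", dialect="tsv"),
        tissue=meta["tissue"],
        species=meta["species"],
        source_name=meta.get("source_name", meta["tissue"]),
        cell_types=cell_types,
    )
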