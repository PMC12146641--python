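"""Statistical self-checks of the linkage test and the end-to-end pipeline.

These routines generate data with known structure, run the package's own
methods over it, and measure calibration, power and recovery.  They back
both the acceptance test suite and the standalone acceptance report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from . import compare, matrices, qc
from .genomics_io import CountMatrix, GenomicInterval
from .linkage import (
    LinkageConfig,
    PeakFeatures,
    link_peaks,
    linkage_ztest,
    matched_background,
)
from .synthetic import SimulationSpec, calibrate_gamma, simulate_corpus

__all__ = [
    "null_calibration",
    "planted_power",
    "end_to_end_recovery",
    "annotation_recovery",
]


def _poisson_lognormal(rng, lam: np.ndarray, n_cells: int, sigma: float) -> np.ndarray:
    v = rng.lognormal(0.0, sigma, size=(len(lam), n_cells))
    return rng.poisson(lam[:, None] * v / np.exp(sigma**2 / 2))


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mean) / sd


def _peak_features(raw_counts: np.ndarray, width: int = 400) -> list:
    return [
        PeakFeatures(GenomicInterval("chrX", i * 1000, i * 1000 + width), float(t))
        for i, t in enumerate(raw_counts.sum(axis=1))
    ]


def null_calibration(
    seed: int = 0,
    n_cells: int = 500,
    n_pairs: int = 500,
    n_pool: int = 2000,
    n_background: int = 200,
    alpha: float = 0.05,
) -> float:
    """Fraction of independent gene-peak pairs rejected at ``alpha`` by the
    matched-background z-test (should sit near ``alpha``)."""
    rng = np.random.default_rng(seed)
    lam_g = rng.lognormal(np.log(10), 0.2, n_pairs)
    lam_t = rng.lognormal(np.log(4), 0.15, n_pairs)
    lam_pool = rng.lognormal(np.log(4), 0.15, n_pool)

    genes = _poisson_lognormal(rng, lam_g, n_cells, 0.5)
    targets = _poisson_lognormal(rng, lam_t, n_cells, 0.5)
    pool = _poisson_lognormal(rng, lam_pool, n_cells, 0.5)

    gene_cm = CountMatrix(
        sp.csr_matrix(genes), [f"g{i}" for i in range(n_pairs)],
        [f"c{j}" for j in range(n_cells)], "raw",
    )
    peak_cm = CountMatrix(
        sp.csr_matrix(np.vstack([targets, pool])),
        [f"p{i}" for i in range(n_pairs + n_pool)],
        [f"c{j}" for j in range(n_cells)], "raw",
    )
    zg = _zscore_rows(matrices.lognormalize(gene_cm).dense())
    zp = _zscore_rows(matrices.lognormalize(peak_cm).dense())
    zt, zpool = zp[:n_pairs], zp[n_pairs:]

    r_target = np.einsum("ij,ij->i", zg, zt) / n_cells
    r_pool = zg @ zpool.T / n_cells  # pair x pool correlations

    target_features = _peak_features(targets)
    pool_features = _peak_features(pool)
    rejected = 0
    for i in range(n_pairs):
        bg_idx = matched_background(target_features[i], pool_features, n_background)
        zt_p = linkage_ztest(float(r_target[i]), r_pool[i, bg_idx])
        if zt_p is not None and zt_p[1] < alpha:
            rejected += 1
    return rejected / n_pairs


def planted_power(
    seed: int = 0,
    n_cells: int = 500,
    n_replicates: int = 200,
    n_pool: int = 2000,
    n_background: int = 200,
    target_r: float = 0.6,
    alpha: float = 0.05,
    score_cutoff: float = 0.05,
) -> float:
    """Fraction of planted correlated pairs recovered (p < alpha and
    |r| > score cutoff) by the matched-background z-test."""
    rng = np.random.default_rng(seed)
    spec = SimulationSpec(planted_link_r=target_r, seed=seed)
    gamma = calibrate_gamma(spec)
    sigma = spec.latent_sigma
    lam_g, lam_p = float(np.exp(spec.gene_mean_mu)), float(np.exp(spec.peak_mean_mu))
    scale_g = 1e4 / (spec.n_genes * lam_g)
    scale_p = 1e4 / (spec.n_peaks * lam_p)

    lam_pool = rng.lognormal(np.log(lam_p), 0.15, n_pool)
    pool = _poisson_lognormal(rng, lam_pool, n_cells, sigma)
    zpool = _zscore_rows(np.log1p(pool * scale_p))
    pool_features = _peak_features(pool)

    recovered = 0
    for _ in range(n_replicates):
        u = rng.lognormal(0.0, sigma, n_cells)
        g = rng.poisson(lam_g * u / np.exp(sigma**2 / 2))
        p = rng.poisson(lam_p * u**gamma / np.exp((gamma * sigma) ** 2 / 2))
        lg = np.log1p(g * scale_g)
        lp = np.log1p(p * scale_p)
        if lg.std() == 0 or lp.std() == 0:
            continue
        r_obs = float(np.corrcoef(lg, lp)[0, 1])
        zg = (lg - lg.mean()) / lg.std()
        r_bg_all = zpool @ zg / n_cells
        target_feat = _peak_features(p[None, :])[0]
        bg_idx = matched_background(target_feat, pool_features, n_background)
        zt_p = linkage_ztest(r_obs, r_bg_all[bg_idx])
        if zt_p is not None and zt_p[1] < alpha and abs(r_obs) > score_cutoff:
            recovered += 1
    return recovered / n_replicates


@dataclass
class RecoveryResult:
    sensitivity: float
    specificity: float
    histogram_exact: bool
    observed_histogram: Dict[int, int]
    intended_histogram: Dict[int, int]
    n_specific: int
    n_shared: int


def end_to_end_recovery(
    seed: int = 0,
    spec: Optional[SimulationSpec] = None,
    pvalue_cutoff: float = 1e-4,
) -> RecoveryResult:
    """Simulate a multi-tissue corpus, run QC -> matrices -> linkage ->
    comparison, and score recovery of planted tissue-specific CREs.

    Sensitivity: planted tissue-specific gene-linked CREs called specific
    for their tissue.  Specificity: planted ubiquitous (shared) linked
    CREs not called specific for any tissue.  The histogram check replays
    the generator's idealized linkage tables through the remap/presence
    machinery and compares with the planted per-linkage tissue counts.
    """
    if spec is None:
        spec = SimulationSpec(seed=seed)
    bundles, truth = simulate_corpus(spec)
    config = LinkageConfig(pvalue_cutoff=pvalue_cutoff, seed=seed)

    all_records = []
    for bundle in bundles:
        metrics = qc.compute_cell_qc(bundle)
        kept = qc.apply_cell_filters(metrics)
        rna_log = matrices.lognormalize(bundle.rna.subset_cells(kept))
        atac = matrices.feature_matrix(bundle.fragments, bundle.peaks, kept)
        all_records.extend(
            link_peaks(rna_log, atac, bundle.peaks, bundle.genes, bundle.sample_id, config)
        )

    cre_map = compare.build_union_cres({b.sample_id: b.peaks for b in bundles})
    remapped = compare.remap_linkages(all_records, cre_map)
    samples = sorted(truth.sample_tissues)
    tissues = truth.sample_tissues

    def cre_index_of(pk: Tuple[str, int, int]) -> int:
        return cre_map.lookup(samples[0], GenomicInterval(*pk))

    tp = 0
    for (gene, pk), tissue in truth.tissue_specific.items():
        pm = compare.gene_linked_cre_matrix(gene, samples, cre_map, remapped, tissues)
        hits = compare.tissue_specific_cres(pm, compare.TissueSpecRule(tissue))
        if cre_index_of(pk) in hits:
            tp += 1
    n_specific = len(truth.tissue_specific)

    all_tissues = sorted(set(tissues.values()))
    fp = 0
    for gene, pk in truth.shared:
        pm = compare.gene_linked_cre_matrix(gene, samples, cre_map, remapped, tissues)
        idx = cre_index_of(pk)
        if any(
            idx in compare.tissue_specific_cres(pm, compare.TissueSpecRule(t))
            for t in all_tissues
        ):
            fp += 1
    n_shared = len(truth.shared)

    import itertools

    ideal = itertools.chain.from_iterable(
        truth.linkage_records(sid) for sid in samples
    )
    hist, _ = compare.tissue_presence_distribution(
        compare.remap_linkages(ideal, cre_map), tissues
    )
    intended = truth.intended_histogram()
    return RecoveryResult(
        sensitivity=tp / n_specific if n_specific else 1.0,
        specificity=1.0 - (fp / n_shared if n_shared else 0.0),
        histogram_exact=hist == intended,
        observed_histogram=hist,
        intended_histogram=intended,
        n_specific=n_specific,
        n_shared=n_shared,
    )


def annotation_recovery(
    seed: int = 0, n_clusters: int = 100, n_genes: int = 500,
    n_labels: int = 10, noise_sd: float = 0.01,
) -> float:
    """Fraction of noisy reference copies re-annotated with their own label."""
    from .cluster_annotate import ReferencePseudobulks, annotate_clusters
    from .matrices import Pseudobulk

    rng = np.random.default_rng(seed)
    features = [f"g{i}" for i in range(n_genes)]
    ref = ReferencePseudobulks(
        features,
        {f"type{k}": rng.uniform(0, 5, n_genes) for k in range(n_labels)},
    )
    correct = 0
    for i in range(n_clusters):
        label = f"type{i % n_labels}"
        query = Pseudobulk(
            f"cl{i}",
            ref.profiles[label] + rng.normal(0, noise_sd, n_genes),
            features,
            5,
        )
        got, _ = annotate_clusters([query], ref, n_var=n_genes)[f"cl{i}"]
        correct += got == label
    return correct / n_clusters
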