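import numpy as np
import pytest

from creglink.compare import (
    PresenceMatrix,
    TissueSpecRule,
    build_union_cres,
    gene_linked_cre_matrix,
    region_view,
    remap_linkages,
    restrict_to_celltype,
    tissue_presence_distribution,
    tissue_specific_cres,
    write_region_view,
)
from creglink.genomics_io import GenomicInterval, LinkageRecord

from conftest import random_intervals


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def link(gene, peak, sample, p=0.01, score=0.5):
    return LinkageRecord(gene, peak, score, 3.0, p, sample)


def merge_oracle(intervals):
    """O(n^2) repeated pairwise merging until fixpoint."""
    items = [(i.chrom, i.start, i.end) for i in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                ci, si, ei = items[i]
                cj, sj, ej = items[j]
                if ci == cj and si < ej and sj < ei:
                    items[i] = (ci, min(si, sj), max(ei, ej))
                    items.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(items)


class TestUnionCres:
    def test_transitive_merge(self):
        m = build_union_cres({"s1": [iv(100, 200)], "s2": [iv(150, 250)]})
        assert [(c.start, c.end) for c in m.union_cres] == [(100, 250)]

    def test_bookended_not_merged(self):
        m = build_union_cres({"s1": [iv(100, 200), iv(200, 300)]})
        assert len(m.union_cres) == 2

    def test_disjoint_identity(self):
        peaks = [iv(0, 10), iv(50, 60)]
        m = build_union_cres({"s1": peaks})
        assert [(c.start, c.end) for c in m.union_cres] == [(0, 10), (50, 60)]

    def test_mapping_containment_and_uniqueness(self, rng):
        sets = {
            f"s{k}": random_intervals(rng, 60, span=20_000) for k in range(3)
        }
        m = build_union_cres(sets)
        for sid, peaks in sets.items():
            for p in peaks:
                cre = m.union_cres[m.lookup(sid, p)]
                assert cre.contains(p)
        # disjointness of union CREs
        by_chrom = {}
        for c in m.union_cres:
            by_chrom.setdefault(c.chrom, []).append(c)
        for cres in by_chrom.values():
            cres.sort(key=lambda c: c.start)
            for a, b in zip(cres, cres[1:]):
                assert a.end <= b.start

    def test_equals_quadratic_oracle(self, rng):
        intervals = random_intervals(rng, 200, span=30_000)
        m = build_union_cres({"s": intervals})
        got = sorted((c.chrom, c.start, c.end) for c in m.union_cres)
        assert got == merge_oracle(intervals)

    def test_idempotent(self, rng):
        intervals = random_intervals(rng, 100, span=10_000)
        once = build_union_cres({"s": intervals}).union_cres
        twice = build_union_cres({"u": once}).union_cres
        assert [(c.chrom, c.start, c.end) for c in once] == [
            (c.chrom, c.start, c.end) for c in twice
        ]

    def test_species_mixing_rejected(self):
        with pytest.raises(ValueError, match="species"):
            build_union_cres(
                {"s1": [iv(0, 10)], "s2": [iv(0, 10)]},
                species={"s1": "human", "s2": "mouse"},
            )


class TestRemap:
    def test_containment_lookup(self):
        m = build_union_cres({"s1": [iv(100, 200)], "s2": [iv(90, 250)]})
        out = remap_linkages([link("gA", iv(100, 200), "s1")], m)
        assert len(out) == 1
        assert m.union_cres[out[0].cre_index].start == 90

    def test_duplicate_collapse_keeps_min_p(self):
        m = build_union_cres({"s1": [iv(100, 200), iv(190, 300)]})
        assert len(m.union_cres) == 1
        out = remap_linkages(
            [
                link("gA", iv(100, 200), "s1", p=0.04),
                link("gA", iv(190, 300), "s1", p=0.001),
            ],
            m,
        )
        assert len(out) == 1
        assert out[0].pvalue == 0.001

    def test_empty(self):
        m = build_union_cres({"s1": [iv(0, 10)]})
        assert remap_linkages([], m) == []

    def test_unmapped_peak_error(self):
        m = build_union_cres({"s1": [iv(0, 10)]})
        with pytest.raises(KeyError, match="s1"):
            remap_linkages([link("gA", iv(5000, 6000), "s1")], m)


class TestPresenceDistribution:
    def test_direct_count(self):
        m = build_union_cres(
            {s: [iv(100, 200), iv(300, 400), iv(500, 600)] for s in ("a", "b", "c")}
        )
        tissues = {"a": "t1", "b": "t2", "c": "t3"}
        links = [
            link("g1", iv(100, 200), "a"),  # 1 tissue
            link("g2", iv(300, 400), "b"),  # 1 tissue
            link("g3", iv(500, 600), "a"),
            link("g3", iv(500, 600), "b"),
            link("g3", iv(500, 600), "c"),  # 3 tissues
        ]
        hist, cum = tissue_presence_distribution(remap_linkages(links, m), tissues)
        assert hist == {1: 2, 3: 1}
        assert cum[1] == pytest.approx(2 / 3)
        assert cum[3] == pytest.approx(1.0)

    def test_single_tissue_corpus(self):
        m = build_union_cres({"a": [iv(0, 10)], "b": [iv(0, 10)]})
        tissues = {"a": "t", "b": "t"}
        links = [link("g", iv(0, 10), "a"), link("g", iv(0, 10), "b")]
        hist, _ = tissue_presence_distribution(remap_linkages(links, m), tissues)
        assert hist == {1: 1}

    def test_histogram_sums_to_distinct_keys(self, rng):
        peaks = [iv(i * 100, i * 100 + 50) for i in range(20)]
        m = build_union_cres({f"s{k}": peaks for k in range(4)})
        tissues = {f"s{k}": f"t{k % 2}" for k in range(4)}
        links = [
            link(f"g{rng.integers(5)}", peaks[rng.integers(20)], f"s{rng.integers(4)}")
            for _ in range(200)
        ]
        remapped = remap_linkages(links, m)
        hist, _ = tissue_presence_distribution(remapped, tissues)
        assert sum(hist.values()) == len({(r.gene_id, r.cre_index) for r in remapped})


class TestGeneLinkedMatrix:
    def _map_and_links(self):
        peaks = [iv(100, 200), iv(300, 400, "chr2"), iv(500, 600)]
        m = build_union_cres({s: peaks for s in ("s1", "s2")})
        return m, peaks

    def test_no_links_empty(self):
        m, _ = self._map_and_links()
        pm = gene_linked_cre_matrix("gX", ["s1", "s2"], m, [], {"s1": "t", "s2": "t"})
        assert pm.present.shape == (0, 2)

    def test_single_link(self):
        m, peaks = self._map_and_links()
        remapped = remap_linkages([link("gA", peaks[0], "s1", score=0.7)], m)
        pm = gene_linked_cre_matrix("gA", ["s1", "s2"], m, remapped, {"s1": "t", "s2": "t"})
        assert pm.present.shape == (1, 2)
        assert pm.present[0, 0] and not pm.present[0, 1]
        assert pm.scores[0, 0] == pytest.approx(0.7)

    def test_rows_sorted_genomically(self):
        m, peaks = self._map_and_links()
        remapped = remap_linkages(
            [link("gA", p, "s1") for p in peaks], m
        )
        pm = gene_linked_cre_matrix("gA", ["s1"], m, remapped, {"s1": "t"})
        coords = [(c.chrom, c.start) for c in pm.union_cres]
        assert coords == sorted(coords)


class TestRestrictToCelltype:
    def test_no_celltype_peaks(self):
        assert restrict_to_celltype([link("g", iv(0, 10), "s")], []) == []

    def test_identical_peak_kept(self):
        l = link("g", iv(0, 10), "s")
        assert restrict_to_celltype([l], [iv(0, 10)]) == [l]

    def test_bookended_dropped(self):
        l = link("g", iv(0, 10), "s")
        assert restrict_to_celltype([l], [iv(10, 20)]) == []


def presence(rows, sample_tissues):
    sample_ids = list(sample_tissues)
    return PresenceMatrix(
        row_keys=list(range(len(rows))),
        sample_ids=sample_ids,
        present=np.array(rows, dtype=bool),
        sample_tissues=sample_tissues,
    )


class TestTissueSpecificRule:
    tissues = {"H1": "heart", "H2": "heart", "B1": "brain", "B2": "brain"}

    def test_strict_edge_not_specific(self):
        # heart 2/2 present, brain 1/2 = 0.5 which is NOT < 0.5
        pm = presence([[1, 1, 1, 0]], self.tissues)
        assert tissue_specific_cres(pm, TissueSpecRule("heart")) == []

    def test_specific_when_absent_elsewhere(self):
        pm = presence([[1, 1, 0, 0]], self.tissues)
        assert tissue_specific_cres(pm, TissueSpecRule("heart")) == [0]

    def test_ubiquitous_specific_nowhere(self):
        pm = presence([[1, 1, 1, 1]], self.tissues)
        for t in ("heart", "brain"):
            assert tissue_specific_cres(pm, TissueSpecRule(t)) == []

    def test_unknown_tissue_error(self):
        pm = presence([[1, 1, 0, 0]], self.tissues)
        with pytest.raises(ValueError):
            tissue_specific_cres(pm, TissueSpecRule("liver"))

    def test_exhaustive_oracle_fuzz(self, rng):
        tissues = {f"s{k}": f"t{k % 3}" for k in range(7)}
        for _ in range(200):
            rows = rng.integers(0, 2, size=(8, 7))
            pm = presence(rows, tissues)
            target = f"t{rng.integers(3)}"
            got = set(tissue_specific_cres(pm, TissueSpecRule(target)))
            expected = set()
            for i in range(8):
                fracs = {}
                for t in ("t0", "t1", "t2"):
                    cols = [j for j, s in enumerate(tissues) if tissues[s] == t]
                    fracs[t] = rows[i, cols].mean()
                if fracs[target] > 0.5 and all(
                    fracs[t] < 0.5 for t in fracs if t != target
                ):
                    expected.add(i)
            assert got == expected


class TestRegionView:
    def test_tracks_and_normalization(self, tiny_sample, tmp_path):
        bundle, truth = tiny_sample
        gene = bundle.genes[0].gene_id
        view = region_view(bundle, gene, flank=5000)
        assert view.region.chrom == bundle.genes[0].body.chrom
        assert set(view.tracks) == {"typeA", "typeB"}
        for track in view.tracks.values():
            assert len(track) == len(view.bin_starts)
            assert np.all(track >= 0)
        assert gene in [g.gene_id for g in view.genes_in_region]
        write_region_view(view, tmp_path / "rv")
        assert (tmp_path / "rv" / "expression.tsv").exists()
        assert len(list((tmp_path / "rv").glob("track_*.bedGraph"))) == 2

    def test_depth_normalization_invariance(self, tiny_sample):
        import dataclasses

        bundle, _ = tiny_sample
        gene = bundle.genes[0].gene_id
        doubled = dataclasses.replace(bundle)
        doubled.fragments = bundle.fragments.subset(
            np.ones(len(bundle.fragments), dtype=bool)
        )
        doubled.fragments.counts = doubled.fragments.counts * 2
        a = region_view(bundle, gene, flank=2000)
        b = region_view(doubled, gene, flank=2000)
        for g in a.tracks:
            np.testing.assert_allclose(a.tracks[g], b.tracks[g])

    def test_zero_fragment_group_zero_track(self, tiny_sample):
        bundle, _ = tiny_sample
        gene = bundle.genes[0].gene_id
        groups = {bc: "rest" for bc in bundle.rna.cell_barcodes}
        groups["ghost-barcode"] = "empty"  # no fragments carry this barcode
        view = region_view(bundle, gene, groups=groups, flank=1000)
        assert np.all(view.tracks["empty"] == 0)

    def test_flank_zero_equals_gene_body(self, tiny_sample):
        bundle, _ = tiny_sample
        g = bundle.genes[1]
        view = region_view(bundle, g.gene_id, flank=0)
        assert view.region.start == g.body.start
        assert view.region.end == g.body.end

    def test_unknown_gene_error(self, tiny_sample):
        bundle, _ = tiny_sample
        with pytest.raises(ValueError):
            region_view(bundle, "nope")
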