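"""Readers/writers for the standard formats the toolkit touches.

All internal coordinates are 0-based half-open (BED convention).  GTF input
(1-based, inclusive) is converted at the boundary and converted back on
export.  Peaks and CREs may carry strand ``"."``; gene models require an
explicit ``+``/``-`` strand because the TSS is otherwise undefined.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "GenomicInterval",
    "FragmentRecord",
    "FragmentSet",
    "GeneModel",
    "CountMatrix",
    "LinkageRecord",
    "SampleBundle",
    "ParseError",
    "SchemaError",
    "read_bed",
    "write_bed",
    "read_fragments",
    "write_fragments",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_gene_models",
    "write_gene_models",
    "read_linkage_table",
    "write_linkage_table",
    "intervals_overlap",
]

LINKAGE_COLUMNS = [
    "gene_id",
    "chrom",
    "start",
    "end",
    "score",
    "zscore",
    "pvalue",
    "sample_id",
]


class ParseError(ValueError):
    """Malformed line in a genomic text format."""


class SchemaError(ValueError):
    """Structural problem: missing columns, dimension mismatch, bad ids."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates.

    ``strand`` is one of ``+``, ``-``, ``.``; extra BED columns survive a
    read/write round trip in ``annotations``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    annotations: tuple = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: shared bases required; bookending is not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.overlaps(b)


@dataclass(frozen=True)
class FragmentRecord:
    """One ATAC fragment: interval, cell barcode, duplicate count."""

    interval: GenomicInterval
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValueError("barcode must be non-empty")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


class FragmentSet:
    """Columnar container for a sample's fragments.

    Modules operate on this for speed; :func:`read_fragments` provides the
    record-stream view of the same data.
    """

    def __init__(
        self,
        chroms: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        barcodes: np.ndarray,
        counts: np.ndarray,
    ) -> None:
        n = len(starts)
        if not (len(chroms) == len(ends) == len(barcodes) == len(counts) == n):
            raise ValueError("column lengths differ")
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.barcodes = np.asarray(barcodes, dtype=object)
        self.counts = np.asarray(counts, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.starts)

    @classmethod
    def from_records(cls, records: Iterable[FragmentRecord]) -> "FragmentSet":
        rows = [
            (r.interval.chrom, r.interval.start, r.interval.end, r.barcode, r.count)
            for r in records
        ]
        if not rows:
            empty = np.empty(0, dtype=object)
            zeros = np.empty(0, dtype=np.int64)
            return cls(empty, zeros, zeros.copy(), empty.copy(), zeros.copy())
        chroms, starts, ends, bcs, counts = zip(*rows)
        return cls(
            np.array(chroms, dtype=object),
            np.array(starts, dtype=np.int64),
            np.array(ends, dtype=np.int64),
            np.array(bcs, dtype=object),
            np.array(counts, dtype=np.int64),
        )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "FragmentSet":
        return cls.from_records(read_fragments(path))

    def to_records(self) -> Iterator[FragmentRecord]:
        for i in range(len(self)):
            yield FragmentRecord(
                GenomicInterval(self.chroms[i], int(self.starts[i]), int(self.ends[i])),
                self.barcodes[i],
                int(self.counts[i]),
            )

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        return FragmentSet(
            self.chroms[mask],
            self.starts[mask],
            self.ends[mask],
            self.barcodes[mask],
            self.counts[mask],
        )

    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def barcode_codes(self, index: dict) -> np.ndarray:
        """Map each fragment's barcode through ``index`` (-1 when absent)."""
        uniq, inverse = np.unique(self.barcodes, return_inverse=True)
        lut = np.array([index.get(bc, -1) for bc in uniq], dtype=np.int64)
        return lut[inverse]

    def counts_per_barcode(self) -> dict:
        """Total fragment count (count-weighted) per barcode."""
        out: dict = {}
        bcs, inverse = np.unique(self.barcodes, return_inverse=True)
        sums = np.bincount(inverse, weights=self.counts, minlength=len(bcs))
        for bc, s in zip(bcs, sums):
            out[bc] = int(s)
        return out


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand-aware transcription start site."""

    gene_id: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.body.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, got {self.body.strand!r}"
            )

    @property
    def tss(self) -> int:
        """TSS: body start on +, last base (end - 1) on -."""
        if self.body.strand == "+":
            return self.body.start
        return self.body.end - 1


@dataclass
class CountMatrix:
    """A features-by-cells matrix with a named normalization layer.

    ``values`` is a scipy sparse matrix (raw/lognorm/tfidf layers) or a
    dense ndarray (scaled layer).
    """

    values: Union[sp.spmatrix, np.ndarray]
    feature_ids: list
    cell_barcodes: list
    layer: str = "raw"

    _LAYERS = ("raw", "lognorm", "tfidf", "scaled")

    def __post_init__(self) -> None:
        if self.layer not in self._LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        nf, nc = self.values.shape
        if nf != len(self.feature_ids) or nc != len(self.cell_barcodes):
            raise SchemaError(
                f"matrix shape {self.values.shape} does not match id lists "
                f"({len(self.feature_ids)} features, {len(self.cell_barcodes)} cells)"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise SchemaError("duplicate feature ids")
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise SchemaError("duplicate cell barcodes")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def get(self, feature_id: str, barcode: str) -> float:
        i = self.feature_ids.index(feature_id)
        j = self.cell_barcodes.index(barcode)
        return float(self.values[i, j])

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def feature_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def subset_cells(self, barcodes: Sequence[str]) -> "CountMatrix":
        index = {bc: j for j, bc in enumerate(self.cell_barcodes)}
        cols = [index[bc] for bc in barcodes]
        vals = self.values.tocsc()[:, cols] if sp.issparse(self.values) else self.values[:, cols]
        return CountMatrix(vals, list(self.feature_ids), list(barcodes), self.layer)

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[f] for f in feature_ids]
        vals = self.values.tocsr()[rows, :] if sp.issparse(self.values) else self.values[rows, :]
        return CountMatrix(vals, list(feature_ids), list(self.cell_barcodes), self.layer)


@dataclass(frozen=True)
class LinkageRecord:
    """One CRE-gene linkage with its Pearson score, z-score and p-value."""

    gene_id: str
    peak: GenomicInterval
    score: float
    zscore: float
    pvalue: float
    sample_id: str

    def __post_init__(self) -> None:
        if abs(self.score) > 1 + 1e-9:
            raise ValueError(f"|score| must be <= 1, got {self.score}")
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"pvalue must be in [0, 1], got {self.pvalue}")


@dataclass
class SampleBundle:
    """One multiome sample: RNA counts, fragments, peaks, gene models, metadata."""

    sample_id: str
    rna: CountMatrix
    fragments: FragmentSet
    peaks: list
    genes: list
    tissue: str = ""
    species: str = ""
    source_name: str = ""
    cell_types: dict = field(default_factory=dict)  # barcode -> cell type


# ---------------------------------------------------------------------------
# BED


def _open_text(path: Union[str, Path]):
    path = Path(path)
    raw = open(path, "rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":  # gzip/bgzip magic
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def read_bed(path: Union[str, Path]) -> list:
    """Read a BED file (>=3 columns) into GenomicIntervals in file order.

    Columns beyond the third are preserved in ``annotations``; column 6, if
    present and a valid strand, is also parsed into ``strand``.
    """
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = "."
            if len(parts) >= 6 and parts[5] in ("+", "-", "."):
                strand = parts[5]
            try:
                intervals.append(
                    GenomicInterval(
                        parts[0], start, end, strand, tuple(parts[3:])
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), *iv.annotations]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Fragments


def read_fragments(path: Union[str, Path]) -> Iterator[FragmentRecord]:
    """Stream a 5-column fragments TSV (plain or gzip/bgzip compressed)."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            try:
                start, end, count = int(parts[1]), int(parts[2]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            if count < 1:
                raise ParseError(f"{path}:{lineno}: count must be >= 1, got {count}")
            try:
                yield FragmentRecord(
                    GenomicInterval(parts[0], start, end), parts[3], count
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc


def write_fragments(fragments: FragmentSet, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        {
            "chrom": fragments.chroms,
            "start": fragments.starts,
            "end": fragments.ends,
            "barcode": fragments.barcodes,
            "count": fragments.counts,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# MTX count matrices


def read_counts_mtx(
    mtx: Union[str, Path],
    features: Union[str, Path],
    barcodes: Union[str, Path],
) -> CountMatrix:
    """Read a MatrixMarket triplet plus line-aligned feature/barcode lists."""
    mat = scipy.io.mmread(str(mtx)).tocsr()
    feature_ids = Path(features).read_text().splitlines()
    cell_barcodes = Path(barcodes).read_text().splitlines()
    if mat.shape != (len(feature_ids), len(cell_barcodes)):
        raise SchemaError(
            f"matrix is {mat.shape} but id files give "
            f"({len(feature_ids)}, {len(cell_barcodes)})"
        )
    return CountMatrix(mat, feature_ids, cell_barcodes, layer="raw")


def write_counts_mtx(
    m: CountMatrix,
    mtx: Union[str, Path],
    features: Union[str, Path],
    barcodes: Union[str, Path],
) -> None:
    vals = m.values if sp.issparse(m.values) else sp.coo_matrix(m.values)
    scipy.io.mmwrite(str(mtx), vals.tocoo(), field="integer" if m.layer == "raw" else "real")
    Path(features).write_text("\n".join(m.feature_ids) + "\n")
    Path(barcodes).write_text("\n".join(m.cell_barcodes) + "\n")


# ---------------------------------------------------------------------------
# Gene models

_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_gene_models(path: Union[str, Path], dialect: str = "tsv") -> list:
    """Read gene models from GTF (gene features) or a minimal TSV.

    GTF coordinates are 1-based inclusive and converted to 0-based
    half-open; the TSV dialect is already half-open with header
    ``gene,chrom,start,end,strand``.
    """
    if dialect == "gtf":
        genes = []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
                if parts[2] != "gene":
                    continue
                m = _GTF_GENE_ID.search(parts[8])
                if m is None:
                    raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
                strand = parts[6]
                if strand not in ("+", "-"):
                    raise ParseError(
                        f"{path}:{lineno}: gene strand must be + or -, got {strand!r}"
                    )
                genes.append(
                    GeneModel(
                        m.group(1),
                        GenomicInterval(
                            parts[0], int(parts[3]) - 1, int(parts[4]), strand
                        ),
                    )
                )
        return genes
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"gene", "chrom", "start", "end", "strand"}
        if not required.issubset(df.columns):
            raise SchemaError(
                f"gene TSV missing columns {sorted(required - set(df.columns))}"
            )
        genes = []
        for row in df.itertuples(index=False):
            if row.strand not in ("+", "-"):
                raise ParseError(
                    f"gene {row.gene}: strand must be + or -, got {row.strand!r}"
                )
            genes.append(
                GeneModel(
                    str(row.gene),
                    GenomicInterval(
                        str(row.chrom), int(row.start), int(row.end), str(row.strand)
                    ),
                )
            )
        return genes
    raise ValueError(f"unknown dialect {dialect!r}")


def write_gene_models(
    genes: Iterable[GeneModel], path: Union[str, Path], dialect: str = "tsv"
) -> None:
    if dialect == "tsv":
        df = pd.DataFrame(
            [
                (g.gene_id, g.body.chrom, g.body.start, g.body.end, g.body.strand)
                for g in genes
            ],
            columns=["gene", "chrom", "start", "end", "strand"],
        )
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "gtf":
        with open(path, "w") as fh:
            for g in genes:
                fh.write(
                    "\t".join(
                        [
                            g.body.chrom,
                            "creglink",
                            "gene",
                            str(g.body.start + 1),
                            str(g.body.end),
                            ".",
                            g.body.strand,
                            ".",
                            f'gene_id "{g.gene_id}";',
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Linkage tables


def write_linkage_table(records: Iterable[LinkageRecord], path: Union[str, Path]) -> None:
    rows = [
        (
            r.gene_id,
            r.peak.chrom,
            r.peak.start,
            r.peak.end,
            f"{r.score:.6g}",
            f"{r.zscore:.6g}",
            f"{r.pvalue:.6g}",
            r.sample_id,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=LINKAGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_linkage_table(path: Union[str, Path]) -> list:
    df = pd.read_csv(path, sep="\t")
    missing = set(LINKAGE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"linkage table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            LinkageRecord(
                gene_id=str(row.gene_id),
                peak=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                score=float(row.score),
                zscore=float(row.zscore),
                pvalue=float(row.pvalue),
                sample_id=str(row.sample_id),
            )
        )
    return records
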