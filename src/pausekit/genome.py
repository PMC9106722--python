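"""Gene-model and coverage primitives.

Coordinates are 0-based half-open throughout (BED convention); GTF input is
converted on read. A gene's TSS is its 5' end in transcription direction
(``start`` on ``+``, ``end - 1`` on ``-``), the TES its 3' end.

Densities are reported as mean per-base fragment coverage per million mapped
fragments (per-bp BPM), which makes promoter and gene-body signal directly
comparable -- the property the traveling ratio relies on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "GenomicInterval",
    "RegionPair",
    "CoverageTrack",
    "MetageneProfile",
    "load_gene_models",
    "gene_regions",
    "coverage_from_fragments",
    "region_density",
    "metagene_profile",
    "genes_near_peaks",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "write_bed12",
    "write_fragments_bed",
    "write_bedgraph",
    "read_bedgraph",
    "read_bed_intervals",
]


class GenomeFormatError(ValueError):
    """Malformed annotation or track input; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start > self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def empty(self) -> bool:
        return self.end == self.start


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid coordinates "
                f"[{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionPair:
    """Promoter / gene-body partition of a gene, strand-aware.

    ``eligible`` is False when the gene is too short to have a non-empty body
    (gene length <= downstream window); such genes are flagged, not rejected.
    """

    gene_id: str
    promoter: GenomicInterval
    body: GenomicInterval
    eligible: bool = True


@dataclass
class CoverageTrack:
    """Per-base fragment coverage per chromosome plus the library size."""

    coverage: dict[str, np.ndarray]
    total_fragments: int
    condition: str = ""

    def __post_init__(self) -> None:
        for chrom, arr in self.coverage.items():
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"coverage on {chrom} must be finite and >= 0")

    def chrom_length(self, chrom: str) -> int:
        return len(self.coverage[chrom])

    def region_sum(self, region: GenomicInterval) -> float:
        if region.chrom not in self.coverage:
            raise KeyError(f"unknown chromosome {region.chrom!r}")
        return float(self.coverage[region.chrom][region.start : region.end].sum())


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------

_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def _parse_gtf(lines: Iterable[str]) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, list[tuple[str, int, int, str]]] = {}
    saw_gene_feature = False
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise GenomeFormatError(f"GTF line {lineno}: expected 9 fields")
        chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
        if feature not in ("gene", "transcript", "mRNA"):
            continue
        m = _GTF_GENE_ID.search(attrs)
        if m is None:
            raise GenomeFormatError(f"GTF line {lineno}: missing gene_id attribute")
        gene_id = m.group(1)
        try:
            start_i, end_i = int(start) - 1, int(end)  # 1-based inclusive -> half-open
        except ValueError as exc:
            raise GenomeFormatError(f"GTF line {lineno}: bad coordinates") from exc
        if strand not in ("+", "-"):
            raise GenomeFormatError(
                f"GTF line {lineno}: gene {gene_id}: unknown strand {strand!r}"
            )
        if feature == "gene":
            saw_gene_feature = True
            if gene_id in genes:
                raise GenomeFormatError(
                    f"GTF line {lineno}: duplicate gene_id {gene_id!r}"
                )
            genes[gene_id] = GeneModel(gene_id, chrom, start_i, end_i, strand)
        else:
            transcripts.setdefault(gene_id, []).append((chrom, start_i, end_i, strand))
    if not saw_gene_feature and transcripts:
        # no gene features: take min-start/max-end over each gene's transcripts
        for gene_id, recs in transcripts.items():
            chroms = {r[0] for r in recs}
            strands = {r[3] for r in recs}
            if len(chroms) > 1 or len(strands) > 1:
                raise GenomeFormatError(
                    f"gene {gene_id!r}: transcripts disagree on chrom/strand"
                )
            genes[gene_id] = GeneModel(
                gene_id,
                recs[0][0],
                min(r[1] for r in recs),
                max(r[2] for r in recs),
                recs[0][3],
            )
    return list(genes.values())


def _parse_bed12(lines: Iterable[str]) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise GenomeFormatError(
                f"BED line {lineno}: need at least 6 columns (name + strand)"
            )
        chrom, start, end, name, _score, strand = fields[:6]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise GenomeFormatError(f"BED line {lineno}: bad coordinates") from exc
        if strand not in ("+", "-"):
            raise GenomeFormatError(
                f"BED line {lineno}: gene {name!r}: unknown strand {strand!r}"
            )
        if name in genes:
            raise GenomeFormatError(f"BED line {lineno}: duplicate gene_id {name!r}")
        genes[name] = GeneModel(name, chrom, start_i, end_i, strand)
    return list(genes.values())


def load_gene_models(path: str | Path, dialect: str | None = None) -> list[GeneModel]:
    """Read gene models from GTF or BED12 (any BED with name+strand works).

    ``dialect`` is ``"GTF"`` or ``"BED12"``; when None it is inferred from the
    file suffix. GTF gene features win; if absent, each gene is the
    min-start/max-end union of its transcripts. Output is sorted by
    (chrom, start, gene_id).
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = "GTF" if suffix in (".gtf", ".gff", ".gff3") else "BED12"
    with open(path) as fh:
        if dialect.upper() == "GTF":
            genes = _parse_gtf(fh)
        elif dialect.upper() in ("BED12", "BED"):
            genes = _parse_bed12(fh)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


# ---------------------------------------------------------------------------
# regions and densities
# ---------------------------------------------------------------------------


def gene_regions(
    gene: GeneModel,
    upstream: int = 30,
    downstream: int = 300,
    chrom_length: int | None = None,
) -> RegionPair:
    """Split a gene into promoter (−upstream/+downstream around the TSS, in
    transcription direction) and body (the remaining gene length).

    A gene whose length is <= ``downstream`` has an empty body and comes back
    flagged ineligible rather than raising.
    """
    if gene.strand == "+":
        prom_start, prom_end = gene.tss - upstream, gene.tss + downstream
        body_start, body_end = gene.tss + downstream, gene.end
    else:
        # mirror of -upstream/+downstream in transcription direction
        prom_start, prom_end = gene.end - downstream, gene.end + upstream
        body_start, body_end = gene.start, gene.end - downstream
    prom_start = max(prom_start, 0)
    if chrom_length is not None:
        prom_end = min(prom_end, chrom_length)
    eligible = body_end > body_start
    if not eligible:
        body_start = body_end = gene.start  # explicit empty sentinel
    return RegionPair(
        gene_id=gene.gene_id,
        promoter=GenomicInterval(gene.chrom, prom_start, prom_end),
        body=GenomicInterval(gene.chrom, body_start, body_end),
        eligible=eligible,
    )


def coverage_from_fragments(
    fragments: Iterable[tuple[str, int, int]] | str | Path,
    chrom_sizes: Mapping[str, int],
    condition: str = "",
) -> CoverageTrack:
    """Pile up fragment intervals into per-base coverage.

    ``fragments`` is an iterable of (chrom, start, end) or a BED3+ path.
    Fragments are clipped to chromosome bounds; a fragment on a chromosome not
    in ``chrom_sizes`` is an error.
    """
    if isinstance(fragments, (str, Path)):
        df = pd.read_csv(
            fragments,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
        chroms = df["chrom"].to_numpy()
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
    else:
        frags = list(fragments)
        chroms = np.array([f[0] for f in frags], dtype=object)
        starts = np.array([f[1] for f in frags], dtype=np.int64)
        ends = np.array([f[2] for f in frags], dtype=np.int64)
    unknown = set(np.unique(chroms).tolist()) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"fragment on unknown chromosome: {sorted(unknown)}")
    coverage = {}
    for chrom, n in chrom_sizes.items():
        mask = chroms == chrom
        s = np.clip(starts[mask], 0, n)
        e = np.clip(ends[mask], 0, n)
        valid = e > s
        diff = np.zeros(n + 1, dtype=np.float64)
        np.add.at(diff, s[valid], 1.0)
        np.add.at(diff, e[valid], -1.0)
        coverage[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(
        coverage=coverage, total_fragments=len(chroms), condition=condition
    )


def region_density(track: CoverageTrack, region: GenomicInterval) -> float:
    """Mean per-base coverage over ``region``, per million mapped fragments."""
    if region.empty:
        raise ValueError(f"empty region {region.chrom}:{region.start}-{region.end}")
    if track.total_fragments <= 0:
        raise ValueError("library size is zero; cannot compute density")
    mean_cov = track.region_sum(region) / len(region)
    return mean_cov * 1e6 / track.total_fragments


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------


@dataclass
class MetageneProfile:
    """Per-gene binned occupancy, oriented TSS -> TES, plus its column mean."""

    matrix: np.ndarray  # genes x (flank + body + flank) bins, per-bp BPM
    gene_ids: list[str]
    n_flank_bins: int
    body_bins: int
    mean: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.matrix.mean(axis=0) if len(self.matrix) else np.array([])


def _oriented_base_coverage(
    track: CoverageTrack, gene: GeneModel, flank: int
) -> np.ndarray:
    """Per-base coverage over [start-flank, end+flank), zero-padded at
    chromosome edges, reversed for ``-`` genes so it reads TSS -> TES."""
    arr = track.coverage[gene.chrom]
    lo, hi = gene.start - flank, gene.end + flank
    out = np.zeros(hi - lo, dtype=np.float64)
    s, e = max(lo, 0), min(hi, len(arr))
    out[s - lo : e - lo] = arr[s:e]
    if gene.strand == "-":
        out = out[::-1]
    return out


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    flank: int = 3000,
    body_bins: int = 100,
    flank_bin: int = 50,
) -> MetageneProfile:
    """Average-occupancy matrix over genes: upstream flank at ``flank_bin``
    resolution, gene body rescaled to ``body_bins`` bins, downstream flank.

    Values are per-bp BPM per bin; minus-strand rows are reversed so every row
    reads TSS -> TES left to right.
    """
    if flank <= 0 or body_bins <= 0 or flank_bin <= 0:
        raise ValueError("flank, body_bins and flank_bin must all be > 0")
    if flank % flank_bin:
        raise ValueError("flank must be a multiple of flank_bin")
    n_flank = flank // flank_bin
    scale = 1e6 / track.total_fragments
    rows = []
    for gene in genes:
        base = _oriented_base_coverage(track, gene, flank)
        up = base[:flank].reshape(n_flank, flank_bin).mean(axis=1)
        down = base[-flank:].reshape(n_flank, flank_bin).mean(axis=1)
        body = base[flank : flank + gene.length]
        edges = np.linspace(0, gene.length, body_bins + 1)
        lo = np.floor(edges[:-1]).astype(int)
        hi = np.ceil(edges[1:]).astype(int)
        hi = np.maximum(hi, lo + 1)  # zero-length bin -> nearest base
        csum = np.concatenate([[0.0], np.cumsum(body)])
        hi = np.minimum(hi, gene.length)
        lo = np.minimum(lo, hi - 1)
        body_means = (csum[hi] - csum[lo]) / (hi - lo)
        rows.append(np.concatenate([up, body_means, down]) * scale)
    matrix = np.vstack(rows) if rows else np.empty((0, 2 * n_flank + body_bins))
    return MetageneProfile(
        matrix=matrix,
        gene_ids=[g.gene_id for g in genes],
        n_flank_bins=n_flank,
        body_bins=body_bins,
    )


# ---------------------------------------------------------------------------
# peak-to-gene assignment
# ---------------------------------------------------------------------------


def genes_near_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    window: int = 100_000,
) -> dict[str, int]:
    """Genes whose interval lies within ``window`` bp of any peak (closed
    bound; overlap counts as distance 0). Returns gene_id -> nearest distance.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    sorted_peaks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ps in by_chrom.items():
        ps.sort(key=lambda p: p.start)
        starts = np.array([p.start for p in ps])
        ends = np.array([p.end for p in ps])
        run_max_end = np.maximum.accumulate(ends)
        sorted_peaks[chrom] = (starts, run_max_end)
    selected: dict[str, int] = {}
    for gene in genes:
        if gene.chrom not in sorted_peaks:
            continue
        starts, run_max_end = sorted_peaks[gene.chrom]
        idx = np.searchsorted(starts, gene.end)
        dist = None
        if idx < len(starts):  # nearest peak fully to the right
            dist = int(starts[idx] - gene.end)
        if idx > 0:
            left_end = int(run_max_end[idx - 1])
            left_dist = max(0, gene.start - left_end)
            dist = left_dist if dist is None else min(dist, left_dist)
        if dist is not None and dist <= window:
            selected[gene.gene_id] = dist
    return selected


# ---------------------------------------------------------------------------
# text IO
# ---------------------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenomeFormatError(f"chrom.sizes line {lineno}: need name\\tlength")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Single-block BED12, sorted by (chrom, start, gene_id)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        "1",
                        f"{g.length},",
                        "0,",
                    ]
                )
                + "\n"
            )


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenomeFormatError(f"BED line {lineno}: need 3 columns")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_fragments_bed(
    fragments: Iterable[tuple[str, int, int]], path: str | Path
) -> None:
    frags = list(fragments)
    pd.DataFrame(frags, columns=["chrom", "start", "end"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length encoded bedGraph; the library size is kept in a comment so
    the track round-trips through :func:`read_bedgraph`."""
    with open(path, "w") as fh:
        fh.write(f"#total_fragments={track.total_fragments}\n")
        fh.write("track type=bedGraph\n")
        for chrom in sorted(track.coverage):
            arr = track.coverage[chrom]
            if not len(arr):
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int], condition: str = ""
) -> CoverageTrack:
    coverage = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    total = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#total_fragments="):
                total = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise GenomeFormatError(f"bedGraph line {lineno}: need 4 columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in coverage:
                raise ValueError(f"bedGraph interval on unknown chromosome {chrom!r}")
            coverage[chrom][s:e] = v
    if total is None:
        raise GenomeFormatError(
            "bedGraph lacks the #total_fragments= header written by pausekit"
        )
    return CoverageTrack(coverage=coverage, total_fragments=total, condition=condition)
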