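"""Traveling-ratio scoring and tangent-based pause-gene classification.

The traveling ratio (TR, also called pausing index) of a gene is the Pol II
density in its promoter-proximal window (−30/+300 bp around the TSS by
default) divided by the density over the remaining gene body; TR >> 1 marks
promoter-proximal pausing. Comparing two conditions gene by gene gives a
ranked curve of TR differences whose two tails hold the genes that were
released from pausing (upper tail: TR dropped in condition 2) or newly paused
(lower tail: TR rose in condition 2). The tails are delimited geometrically:
after rescaling both axes of the ranked curve to the unit square, the
cutpoints are where a line of slope 1 becomes tangent to the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import CoverageTrack, GeneModel, gene_regions, region_density

__all__ = [
    "TR_COLUMNS",
    "RankedCurve",
    "TangentCuts",
    "PauseClasses",
    "GeneSetComparison",
    "compute_tr_table",
    "tr_difference_curve",
    "ranked_curve_from_deltas",
    "tangent_cutpoints",
    "classify_pause_genes",
    "compare_geneset_tr",
    "read_gene_set",
]

TR_COLUMNS = ["gene_id", "promoter_density", "body_density", "tr", "eligible", "reason"]


def compute_tr_table(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    upstream: int = 30,
    downstream: int = 300,
    min_promoter_density: float = 0.0,
    min_body_density: float = 0.0,
) -> pd.DataFrame:
    """Per-gene promoter/body densities and traveling ratio for one track.

    Ineligible genes are retained with ``reason`` in {empty_body,
    zero_body_density, low_promoter}; eligibility requires a non-empty body,
    body density strictly above ``min_body_density`` and promoter density of
    at least ``min_promoter_density``.
    """
    rows = []
    for gene in genes:
        regions = gene_regions(
            gene, upstream, downstream, chrom_length=track.chrom_length(gene.chrom)
        )
        promoter_density = region_density(track, regions.promoter)
        if not regions.eligible:
            rows.append((gene.gene_id, promoter_density, np.nan, np.nan, False, "empty_body"))
            continue
        body_density = region_density(track, regions.body)
        if body_density <= min_body_density:
            rows.append(
                (gene.gene_id, promoter_density, body_density, np.nan, False, "zero_body_density")
            )
        elif promoter_density < min_promoter_density:
            rows.append(
                (gene.gene_id, promoter_density, body_density, np.nan, False, "low_promoter")
            )
        else:
            rows.append(
                (
                    gene.gene_id,
                    promoter_density,
                    body_density,
                    promoter_density / body_density,
                    True,
                    "",
                )
            )
    table = pd.DataFrame(rows, columns=TR_COLUMNS)
    if not table["eligible"].any():
        raise ValueError(
            "no eligible genes in TR table; consider lowering min_promoter_density "
            "or min_body_density"
        )
    return table


@dataclass
class RankedCurve:
    """Genes ordered by ascending TR difference (condition 1 − condition 2).

    ``data`` columns: rank, gene_id, delta, scaled_x, scaled_y. ``degenerate``
    is True when all deltas are equal, in which case the unit-square rescaling
    (and hence tangent detection) is undefined.
    """

    data: pd.DataFrame
    degenerate: bool = False

    @property
    def n(self) -> int:
        return len(self.data)


def ranked_curve_from_deltas(
    deltas: Sequence[float], gene_ids: Sequence[str] | None = None
) -> RankedCurve:
    """Build a :class:`RankedCurve` from per-gene deltas; ties in delta are
    broken by gene_id so the ordering is deterministic."""
    deltas = np.asarray(deltas, dtype=float)
    n = len(deltas)
    if gene_ids is None:
        gene_ids = [f"g{i:06d}" for i in range(n)]
    df = pd.DataFrame({"gene_id": list(gene_ids), "delta": deltas})
    df = df.sort_values(["delta", "gene_id"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "rank", np.arange(n))
    span = df["delta"].iloc[-1] - df["delta"].iloc[0]
    degenerate = bool(span == 0)
    df["scaled_x"] = df["rank"] / max(n - 1, 1)
    df["scaled_y"] = 0.0 if degenerate else (df["delta"] - df["delta"].iloc[0]) / span
    return RankedCurve(data=df, degenerate=degenerate)


def tr_difference_curve(tr1: pd.DataFrame, tr2: pd.DataFrame) -> RankedCurve:
    """Ranked curve of TR(condition 1) − TR(condition 2) over genes eligible
    in both tables."""
    e1 = tr1[tr1["eligible"]].set_index("gene_id")["tr"]
    e2 = tr2[tr2["eligible"]].set_index("gene_id")["tr"]
    shared = e1.index.intersection(e2.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} genes eligible in both conditions; need >= 3"
        )
    delta = (e1.loc[shared] - e2.loc[shared]).to_numpy()
    return ranked_curve_from_deltas(delta, list(shared))


@dataclass
class TangentCuts:
    """Slope-1 tangent points of the unit-scaled ranked curve, in original
    rank coordinates; a missing crossing leaves the cut None."""

    cut_lo: int | None
    cut_hi: int | None
    slope: np.ndarray = field(repr=False)  # NaN where the window does not fit


def tangent_cutpoints(curve: RankedCurve, smooth_window: int = 11) -> TangentCuts:
    """Find where the unit-scaled ranked curve crosses slope 1 in each tail.

    The local slope at index i is the centered finite difference across
    ``smooth_window`` points. cut_hi is the smallest upper-half index where
    the slope crosses from <=1 to >1 and stays >1 for at least a window.
    cut_lo is the exact mirror: the crossing found by running the same rule
    on the reversed curve, i.e. the largest lower-half index whose slope is
    still >1 before the curve flattens, with the same persistence run. The
    mirror construction makes swapping the two conditions swap the two
    cutpoints (and hence the two pause classes) exactly.
    """
    if smooth_window < 3 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 3")
    if curve.degenerate:
        raise ValueError("degenerate curve (all deltas equal); cutpoints unavailable")
    n = curve.n
    if n < 2 * smooth_window:
        raise ValueError(f"curve has {n} points; need >= {2 * smooth_window}")
    x = curve.data["scaled_x"].to_numpy()
    y = curve.data["scaled_y"].to_numpy()
    h = smooth_window // 2
    slope = np.full(n, np.nan)
    slope[h : n - h] = (y[2 * h :] - y[: n - 2 * h]) / (x[2 * h :] - x[: n - 2 * h])

    def _first_sustained_crossing(above: np.ndarray) -> int | None:
        """Smallest upper-half index where ``above`` turns True and stays
        True for at least a window (clipped at the last valid slope)."""
        half = n // 2
        for i in range(max(half, h + 1), n - h):
            if above[i] and not above[i - 1]:
                stop = min(i + smooth_window, n - h)
                if stop > i and bool(np.all(above[i:stop])):
                    return i
        return None

    above = slope > 1.0  # False at the NaN edges
    cut_hi = _first_sustained_crossing(above)
    mirrored = _first_sustained_crossing(above[::-1])
    cut_lo = None if mirrored is None else n - 1 - mirrored
    return TangentCuts(cut_lo=cut_lo, cut_hi=cut_hi, slope=slope)


@dataclass
class PauseClasses:
    """Tail classes of the ranked TR-difference curve.

    pause_release: upper tail, TR reduced in condition 2 (delta strictly above
    the delta at cut_hi). pause: lower tail, TR increased in condition 2
    (delta strictly below the delta at cut_lo).
    """

    pause_release: set[str]
    pause: set[str]
    cut_hi: int | None
    cut_lo: int | None

    @property
    def n_pause_release(self) -> int:
        return len(self.pause_release)

    @property
    def n_pause(self) -> int:
        return len(self.pause)


def classify_pause_genes(curve: RankedCurve, cuts: TangentCuts) -> PauseClasses:
    delta = curve.data["delta"].to_numpy()
    ids = curve.data["gene_id"].to_numpy()
    release: set[str] = set()
    pause: set[str] = set()
    if cuts.cut_hi is not None:
        release = set(ids[delta > delta[cuts.cut_hi]])
    if cuts.cut_lo is not None:
        pause = set(ids[delta < delta[cuts.cut_lo]])
    return PauseClasses(
        pause_release=release, pause=pause, cut_hi=cuts.cut_hi, cut_lo=cuts.cut_lo
    )


@dataclass
class GeneSetComparison:
    gene_set: str
    test: str  # "KS" or "Welch-t"
    statistic: float
    p_value: float
    n1: int
    n2: int


def compare_geneset_tr(
    tr1: pd.DataFrame,
    tr2: pd.DataFrame,
    gene_set: Iterable[str],
    test: str = "KS",
    name: str = "gene_set",
) -> GeneSetComparison:
    """Two-sided two-sample test on the TR values of the set's eligible genes
    in the two conditions. KS uses the exact null when n1*n2 <= 1e4, the
    asymptotic one otherwise; Welch-t does not assume equal variances.
    """
    members = set(gene_set)
    v1 = tr1[tr1["eligible"] & tr1["gene_id"].isin(members)]["tr"].to_numpy()
    v2 = tr2[tr2["eligible"] & tr2["gene_id"].isin(members)]["tr"].to_numpy()
    if len(v1) < 3 or len(v2) < 3:
        raise ValueError(
            f"gene set {name!r}: only {len(v1)}/{len(v2)} eligible genes; need >= 3 per side"
        )
    test_norm = test.upper().replace("-", "").replace("_", "")
    if test_norm == "KS":
        method = "exact" if len(v1) * len(v2) <= 10_000 else "asymp"
        res = stats.ks_2samp(v1, v2, alternative="two-sided", method=method)
        label = "KS"
    elif test_norm in ("WELCHT", "T", "TTEST"):
        res = stats.ttest_ind(v1, v2, equal_var=False)
        label = "Welch-t"
    else:
        raise ValueError(f"unknown test {test!r}; use 'KS' or 'Welch-t'")
    return GeneSetComparison(
        gene_set=name,
        test=label,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=len(v1),
        n2=len(v2),
    )


def read_gene_set(path: str | Path, name: str | None = None) -> set[str]:
    """Gene set from GMT (first matching row, or the only row) or a
    one-id-per-line text file."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if path.suffix.lower() == ".gmt":
        for line in lines:
            fields = line.split("\t")
            if name is None or fields[0] == name:
                return set(fields[2:])
        raise ValueError(f"gene set {name!r} not found in {path}")
    return {ln.strip() for ln in lines}
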