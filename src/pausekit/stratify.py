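"""Signature scoring and survival stratification.

Samples are scored for a gene signature with a non-parametric rank statistic:
within each sample all genes are ranked ascending by expression (mean ranks
on ties) and the mean rank of the signature genes is rescaled to [0, 1] by
its attainable extremes, so a score of 1 means the signature genes occupy the
top of the sample's transcriptome. Scores feed a maximally-selected-rank-
statistic cutpoint (the candidate threshold maximizing the standardized
two-group log-rank statistic), crossing two dichotomized signatures yields
the four quadrant groups (e.g. AR_low/MYC_high), and groups are compared by
Kaplan-Meier estimation with log-rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, pairwise_logrank_test

__all__ = [
    "Signature",
    "AR_A",
    "QUADRANT_LABELS",
    "Cutpoint",
    "KMResult",
    "signature_score",
    "maxstat_cutpoint",
    "assign_quadrant_groups",
    "km_logrank",
    "logrank_z",
]


@dataclass(frozen=True)
class Signature:
    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"signature {self.name!r} has duplicate gene ids")


#: Nine canonical androgen-receptor transcriptional targets (AR activity).
AR_A = Signature(
    name="AR-A",
    gene_ids=(
        "KLK3", "KLK2", "FKBP5", "STEAP1", "STEAP2", "PPAP2A", "RAB3B",
        "ACSL3", "NKX3-1",
    ),
)

QUADRANT_LABELS = (
    "AR_high/MYC_high",
    "AR_high/MYC_low",
    "AR_low/MYC_high",
    "AR_low/MYC_low",
)


def signature_score(expression: pd.DataFrame, signature: Signature) -> pd.Series:
    """Rank-based signature score in [0, 1] per sample.

    ``expression`` is a genes x samples table (TPM or any per-sample monotone
    scale -- the score only uses within-sample ranks). Signature genes absent
    from the table are dropped with a warning; fewer than 2 present is an
    error. With mean rank m over n_sig genes among N total,
    score = (m - (n_sig+1)/2) / ((2N - n_sig + 1)/2 - (n_sig+1)/2).
    """
    present = [g for g in signature.gene_ids if g in expression.index]
    missing = [g for g in signature.gene_ids if g not in expression.index]
    if missing:
        warnings.warn(
            f"signature {signature.name!r}: missing gene expression data for "
            + ", ".join(missing),
            stacklevel=2,
        )
    if len(present) < 2:
        raise ValueError(
            f"signature {signature.name!r}: only {len(present)} genes present; need >= 2"
        )
    n_total = expression.shape[0]
    n_sig = len(present)
    ranks = expression.rank(axis=0, method="average", ascending=True)
    mean_rank = ranks.loc[present].mean(axis=0)
    lo = (n_sig + 1) / 2.0
    hi = (2 * n_total - n_sig + 1) / 2.0
    score = (mean_rank - lo) / (hi - lo)
    score.name = signature.name
    return score


def logrank_z(time: np.ndarray, event: np.ndarray, in_group: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O - E) / sqrt(V) for the
    ``in_group`` arm, with the hypergeometric variance at each event time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    in_group = np.asarray(in_group, dtype=bool)
    order = np.argsort(time, kind="mergesort")
    t, e, g = time[order], event[order], in_group[order]
    n = len(t)
    at_risk_total = n - np.arange(n)
    at_risk_group = g[::-1].cumsum()[::-1]
    uniq, start = np.unique(t, return_index=True)
    stop = np.append(start[1:], n)
    o_minus_e = 0.0
    var = 0.0
    for s, sp in zip(start, stop):
        d = int(e[s:sp].sum())
        if d == 0:
            continue
        d1 = int((e[s:sp] & g[s:sp]).sum())
        n_t = int(at_risk_total[s])
        n1_t = int(at_risk_group[s])
        frac = n1_t / n_t
        o_minus_e += d1 - d * frac
        if n_t > 1:
            var += d * frac * (1 - frac) * (n_t - d) / (n_t - 1)
    if var <= 0:
        return 0.0
    return o_minus_e / np.sqrt(var)


def _logrank_z_candidates(
    time: np.ndarray, event: np.ndarray, scores: np.ndarray, candidates: np.ndarray
) -> np.ndarray:
    """Standardized log-rank statistic of the split ``score > c`` for every
    candidate c at once (vectorized over the candidate axis)."""
    order = np.argsort(time, kind="mergesort")
    t, e, s = time[order], event[order].astype(bool), scores[order]
    n = len(t)
    member = s[None, :] > candidates[:, None]  # n_cand x n
    at_risk_group = member[:, ::-1].cumsum(axis=1)[:, ::-1]
    _, start = np.unique(t, return_index=True)
    d = np.add.reduceat(e.astype(float), start)
    has_event = d > 0
    n_t = (n - start).astype(float)
    d1 = np.add.reduceat(member & e[None, :], start, axis=1).astype(float)
    n1 = at_risk_group[:, start].astype(float)
    frac = n1 / n_t[None, :]
    o_minus_e = ((d1 - d[None, :] * frac)[:, has_event]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d[None, :] * frac * (1 - frac) * (n_t - d)[None, :] / np.maximum(
            n_t - 1, 1
        )[None, :]
    var = v_terms[:, has_event].sum(axis=1)
    z = np.zeros(len(candidates))
    ok = var > 0
    z[ok] = o_minus_e[ok] / np.sqrt(var[ok])
    return z


@dataclass
class Cutpoint:
    signature: str
    value: float
    statistic: float  # max |standardized log-rank| over candidates
    n_candidates: int


def maxstat_cutpoint(
    scores: pd.Series,
    survival: pd.DataFrame,
    quantile_range: tuple[float, float] = (0.10, 0.90),
) -> Cutpoint:
    """Maximally selected rank statistic cutpoint for a score.

    Candidates are the distinct score values whose empirical quantile lies in
    ``quantile_range``; for each, samples are split into score > c vs <= c
    and the standardized log-rank statistic computed. The cutpoint maximizes
    the absolute statistic, ties resolved toward the smaller value.
    ``survival`` needs ``time`` and ``event`` columns indexed like ``scores``.
    """
    aligned = survival.loc[scores.index]
    time = aligned["time"].to_numpy(dtype=float)
    event = aligned["event"].to_numpy(dtype=float).astype(bool)
    if not event.any():
        raise ValueError("no events in the survival table")
    s = scores.to_numpy(dtype=float)
    uniq = np.unique(s)
    ecdf = np.searchsorted(np.sort(s), uniq, side="right") / len(s)
    lo, hi = quantile_range
    candidates = uniq[(ecdf >= lo) & (ecdf <= hi)]
    candidates = candidates[candidates < uniq[-1]]  # a split needs both sides
    if len(candidates) == 0:
        raise ValueError(
            "no candidate cutpoints in the quantile range (constant scores?)"
        )
    z = np.abs(_logrank_z_candidates(time, event, s, candidates))
    best = int(np.argmax(z))  # argmax keeps the smallest candidate on ties
    return Cutpoint(
        signature=str(scores.name or "score"),
        value=float(candidates[best]),
        statistic=float(z[best]),
        n_candidates=len(candidates),
    )


def assign_quadrant_groups(
    ar_scores: pd.Series,
    myc_scores: pd.Series,
    ar_cut: Cutpoint | float,
    myc_cut: Cutpoint | float,
) -> pd.Series:
    """Label each sample by crossing high/low status of the two signatures;
    'high' is strictly above the cutpoint."""
    ar_value = ar_cut.value if isinstance(ar_cut, Cutpoint) else float(ar_cut)
    myc_value = myc_cut.value if isinstance(myc_cut, Cutpoint) else float(myc_cut)
    missing = ar_scores.index.symmetric_difference(myc_scores.index)
    if len(missing):
        raise ValueError(f"samples missing a score: {sorted(map(str, missing))}")
    ar_high = ar_scores > ar_value
    myc_high = myc_scores.loc[ar_scores.index] > myc_value
    labels = pd.Series(
        np.where(
            ar_high,
            np.where(myc_high, "AR_high/MYC_high", "AR_high/MYC_low"),
            np.where(myc_high, "AR_low/MYC_high", "AR_low/MYC_low"),
        ),
        index=ar_scores.index,
        name="group",
    )
    return labels


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> (time, survival, at_risk)
    chi2: float
    df: int
    p_value: float
    pairwise: pd.DataFrame | None = None


def km_logrank(cohort: pd.DataFrame, pairwise: bool = False) -> KMResult:
    """Kaplan-Meier curves per group plus the k-group log-rank test.

    ``cohort`` needs ``time``, ``event`` and ``group`` columns. Ties at equal
    times follow the product-limit convention of deaths before censorings.
    """
    groups = sorted(cohort["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    if not cohort["event"].astype(bool).any():
        raise ValueError("no events in the cohort")
    curves: dict[str, pd.DataFrame] = {}
    for grp in groups:
        sub = cohort[cohort["group"] == grp]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        table = kmf.event_table
        curves[grp] = pd.DataFrame(
            {
                "time": table.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                "at_risk": table["at_risk"].to_numpy(dtype=int),
            }
        )
    res = multivariate_logrank_test(cohort["time"], cohort["group"], cohort["event"])
    pw = None
    if pairwise:
        pw_res = pairwise_logrank_test(cohort["time"], cohort["group"], cohort["event"])
        pw = pw_res.summary.copy()
    return KMResult(
        curves=curves,
        chi2=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
        pairwise=pw,
    )


def read_signature(path, name: str | None = None) -> Signature:
    """Signature from GMT (row selected by name, else first) or one-id-per-
    line text."""
    from pathlib import Path

    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if path.suffix.lower() == ".gmt":
        for line in lines:
            fields = line.split("\t")
            if name is None or fields[0] == name:
                return Signature(name=fields[0], gene_ids=tuple(fields[2:]))
        raise ValueError(f"signature {name!r} not found in {path}")
    return Signature(name=name or path.stem, gene_ids=tuple(ln.strip() for ln in lines))
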