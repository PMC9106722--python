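"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the statistical structure of the study designs the
pipeline targets, each deterministic for a fixed seed:

* a two-condition Pol II ChIP-seq experiment in which each gene allocates its
  fragments between promoter and gene body by an explicit pause fraction, with
  planted gene sets whose condition-2 pause fraction shifts down (pause
  release) or up (pause);
* a two-condition single-cell UMI experiment in which an anchor gene co-varies
  with a planted gene set through a shared latent activity in condition 1
  only, with per-population transgene expression;
* a survival cohort in which two latent signature activities shift the ranks
  of their signature genes in a TPM table and jointly set the event hazard
  through quadrant groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import CoverageTrack, GeneModel, gene_regions
from .sc import CellMatrix
from .stratify import AR_A, QUADRANT_LABELS

__all__ = [
    "PolIISimConfig",
    "ScSimConfig",
    "SurvSimConfig",
    "simulate_gene_models",
    "simulate_polii_experiment",
    "simulate_sc_experiment",
    "simulate_survival_cohort",
]

SIM_CHROM = "chrSim"


def _as_delta_map(value, default_delta: float) -> dict[str, float]:
    if value is None:
        return {}
    if isinstance(value, Mapping):
        return {str(k): float(v) for k, v in value.items()}
    return {str(k): default_delta for k in value}


# ---------------------------------------------------------------------------
# Pol II two-condition experiment
# ---------------------------------------------------------------------------


@dataclass
class PolIISimConfig:
    """Two-condition Pol II coverage simulation.

    Gene lengths default to a narrow band around 2 kb: the traveling ratio
    scales linearly with body length, so holding length nearly constant makes
    planted pause-fraction shifts the dominant axis of the ranked
    TR-difference curve. ``planted_pause_release`` / ``planted_pause`` map
    gene ids (``g00000`` ...) to the condition-2 pause-fraction delta
    (negative for release, positive for pause); a bare id collection gets the
    default deltas −0.4 / +0.4. ``library_size``, when set, fixes the expected
    total fragment count instead of ``reads_per_gene_mean``.
    """

    n_genes: int
    chrom_length: int
    gene_length_range: tuple[int, int] = (1900, 2100)
    reads_per_gene_mean: float = 500.0
    pause_fraction_baseline: float = 0.54
    planted_pause_release: Mapping[str, float] | Sequence[str] | None = None
    planted_pause: Mapping[str, float] | Sequence[str] | None = None
    library_size: int | None = None
    fragment_length: int = 200
    inter_gene_gap: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_pause_release = _as_delta_map(self.planted_pause_release, -0.4)
        self.planted_pause = _as_delta_map(self.planted_pause, +0.4)
        lo, hi = self.gene_length_range
        if lo < 331:
            raise ValueError("gene lengths must be >= 331 bp so the body is non-empty")
        if lo > hi:
            raise ValueError("gene_length_range must be (low, high)")
        overlap = set(self.planted_pause_release) & set(self.planted_pause)
        if overlap:
            raise ValueError(f"planted sets must be disjoint; shared: {sorted(overlap)}")
        for gid, delta in self.planted_pause_release.items():
            if delta >= 0:
                raise ValueError(f"pause-release delta for {gid} must be negative")
        for gid, delta in self.planted_pause.items():
            if delta <= 0:
                raise ValueError(f"pause delta for {gid} must be positive")
        p = self.pause_fraction_baseline
        if not 0.0 <= p <= 1.0:
            raise ValueError("pause_fraction_baseline must be in [0, 1]")
        for gid, delta in {**self.planted_pause_release, **self.planted_pause}.items():
            if not 0.0 <= p + delta <= 1.0:
                raise ValueError(
                    f"pause fraction for {gid} leaves [0, 1]: {p} + {delta}"
                )

    @property
    def reads_mean(self) -> float:
        if self.library_size is not None:
            return self.library_size / max(self.n_genes, 1)
        return self.reads_per_gene_mean


def gene_id(i: int) -> str:
    return f"g{i:05d}"


def simulate_gene_models(config: PolIISimConfig) -> list[GeneModel]:
    """Place non-overlapping genes with random strands on a single synthetic
    chromosome; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    if n == 0:
        return []
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    required = int(lengths.sum()) + (n + 1) * config.inter_gene_gap
    if required > config.chrom_length:
        raise ValueError(
            f"cannot place {n} non-overlapping genes: need chrom_length >= "
            f"{required}, have {config.chrom_length}"
        )
    slack = config.chrom_length - required
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    gaps = config.inter_gene_gap + extra
    strands = rng.choice(np.array(["+", "-"]), size=n)
    genes = []
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        start = pos
        end = start + int(lengths[i])
        genes.append(GeneModel(gene_id(i), SIM_CHROM, start, end, str(strands[i])))
        pos = end
    return genes


def _pause_fractions(
    genes: Sequence[GeneModel], config: PolIISimConfig
) -> tuple[np.ndarray, np.ndarray]:
    p1 = np.full(len(genes), config.pause_fraction_baseline)
    p2 = p1.copy()
    index = {g.gene_id: i for i, g in enumerate(genes)}
    for gid, delta in {**config.planted_pause_release, **config.planted_pause}.items():
        if gid not in index:
            raise ValueError(f"planted gene {gid!r} not among the simulated genes")
        p2[index[gid]] += delta
    return p1, p2


def simulate_polii_experiment(
    genes: Sequence[GeneModel],
    config: PolIISimConfig,
    return_fragments: bool = False,
):
    """Simulate fragment coverage for two conditions over ``genes``.

    Per gene the fragment count is Poisson(reads mean); each fragment falls in
    the promoter with the condition's pause probability, else in the body, and
    is placed uniformly *within* its region (so promoter coverage comes only
    from promoter-allocated fragments and the pause fraction maps one-to-one
    onto the TR). Returns the two tracks and a per-gene truth table; with
    ``return_fragments`` also the raw (start, end) fragment arrays per
    condition, e.g. for writing BED files.
    """
    if not genes:
        raise ValueError("empty gene list")
    rng = np.random.default_rng(config.seed)
    p1, p2 = _pause_fractions(genes, config)
    regions = [
        gene_regions(g, chrom_length=config.chrom_length) for g in genes
    ]
    fl = config.fragment_length
    tracks = []
    frag_counts = []
    prom_counts = []
    fragment_arrays = []
    for cond_idx, pvec in enumerate((p1, p2), start=1):
        n_frag = rng.poisson(config.reads_mean, size=len(genes))
        n_prom = rng.binomial(n_frag, pvec)
        starts_all: list[np.ndarray] = []
        ends_all: list[np.ndarray] = []
        for g_i, (reg, nf, npz) in enumerate(zip(regions, n_frag, n_prom)):
            nb = nf - npz
            if npz:
                ps, pe = reg.promoter.start, reg.promoter.end
                span = max(pe - ps - fl, 0)
                s = ps + rng.integers(0, span + 1, size=npz)
                starts_all.append(s)
                ends_all.append(np.minimum(s + fl, pe))
            if nb:
                bs, be = reg.body.start, reg.body.end
                span = max(be - bs - fl, 0)
                s = bs + rng.integers(0, span + 1, size=nb)
                starts_all.append(s)
                ends_all.append(np.minimum(s + fl, be))
        diff = np.zeros(config.chrom_length + 1, dtype=np.float64)
        starts = np.concatenate(starts_all) if starts_all else np.empty(0, dtype=int)
        ends = np.concatenate(ends_all) if ends_all else np.empty(0, dtype=int)
        if len(starts):
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, ends, -1.0)
        coverage = np.cumsum(diff[:-1])
        fragment_arrays.append((starts, ends))
        tracks.append(
            CoverageTrack(
                coverage={SIM_CHROM: coverage},
                total_fragments=int(n_frag.sum()),
                condition=f"condition{cond_idx}",
            )
        )
        frag_counts.append(n_frag)
        prom_counts.append(n_prom)
    planted_class = []
    for g in genes:
        if g.gene_id in config.planted_pause_release:
            planted_class.append("pause_release")
        elif g.gene_id in config.planted_pause:
            planted_class.append("pause")
        else:
            planted_class.append("none")
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "pause_fraction_1": p1,
            "pause_fraction_2": p2,
            "planted_class": planted_class,
            "n_fragments_1": frag_counts[0],
            "n_fragments_2": frag_counts[1],
            "n_promoter_1": prom_counts[0],
            "n_promoter_2": prom_counts[1],
        }
    )
    if return_fragments:
        return tracks[0], tracks[1], truth, fragment_arrays[0], fragment_arrays[1]
    return tracks[0], tracks[1], truth


# ---------------------------------------------------------------------------
# single-cell two-condition experiment
# ---------------------------------------------------------------------------

MITO_GENES = ("mt-Nd1", "mt-Co1", "mt-Co2", "mt-Atp6", "mt-Cytb")


@dataclass
class ScSimConfig:
    """Two-condition single-cell UMI simulation.

    Every cell draws a latent activity a ~ N(0, 1); the mean count of gene g
    is base_g * exp(w_g * a) with the anchor loading always positive and the
    covarying-set loadings positive in condition 1 only. Counts are negative
    binomial (gamma-Poisson) with the given dispersion; Poisson is recovered
    as dispersion grows. The transgene is Bernoulli(per-population rate) x
    Poisson(mean 3) in condition 2 and absent in condition 1. The gene
    universe is deep (1000 genes) with bounded background base means so
    that, on the 1e4 total-count scale, null covariance-difference noise
    sits several standard errors below the default flag threshold of 30
    while planted shifts sit far above it.
    """

    n_genes: int = 1000
    n_cells_per_condition: int = 2000
    populations: Mapping[str, float] = dc_field(
        default_factory=lambda: {
            "luminal": 0.70,
            "basal": 0.20,
            "hematopoietic": 0.08,
            "vascular_endothelium": 0.02,
        }
    )
    anchor_gene: str = "Ar"
    anchor_base: float = 8.0
    anchor_loading: float = 0.6
    n_covarying: int = 20
    covarying_base: float = 4.0
    covarying_loading: float = 0.6
    transgene: str = "hg19MYC"
    transgene_rates: Mapping[str, float] = dc_field(
        default_factory=lambda: {
            "luminal": 0.60,
            "basal": 0.183,
            "hematopoietic": 0.086,
            "vascular_endothelium": 0.125,
        }
    )
    dispersion: float = 10.0
    background_base_range: tuple[float, float] = (1.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.populations.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population proportions must sum to 1, got {total}")
        for pop, rate in self.transgene_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"transgene rate for {pop} must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not np.isfinite([self.anchor_loading, self.covarying_loading]).all():
            raise ValueError("loadings must be finite")
        n_special = 1 + self.n_covarying + 1 + len(MITO_GENES)
        if self.n_genes < n_special + 1:
            raise ValueError(f"n_genes must be >= {n_special + 1}")

    @property
    def covarying_set(self) -> tuple[str, ...]:
        return tuple(f"cov{i:03d}" for i in range(self.n_covarying))

    def gene_universe(self) -> list[str]:
        n_bg = self.n_genes - 1 - self.n_covarying - 1 - len(MITO_GENES)
        return (
            [self.anchor_gene]
            + list(self.covarying_set)
            + list(MITO_GENES)
            + [f"bg{i:04d}" for i in range(n_bg)]
            + [self.transgene]
        )


def simulate_sc_experiment(
    config: ScSimConfig,
) -> tuple[CellMatrix, CellMatrix, pd.DataFrame]:
    """Two labelled cell matrices (condition 1 without, condition 2 with the
    transgene) plus a per-gene truth table of active loadings."""
    rng = np.random.default_rng(config.seed)
    genes = config.gene_universe()
    if config.anchor_gene not in genes:
        raise ValueError(f"anchor gene {config.anchor_gene!r} absent from gene universe")
    n_bg = config.n_genes - 1 - config.n_covarying - 1 - len(MITO_GENES)
    base = np.empty(config.n_genes)
    base[0] = config.anchor_base
    base[1 : 1 + config.n_covarying] = config.covarying_base
    mito_lo = 1 + config.n_covarying
    base[mito_lo : mito_lo + len(MITO_GENES)] = 8.0
    bg_lo = mito_lo + len(MITO_GENES)
    lo_b, hi_b = config.background_base_range
    base[bg_lo : bg_lo + n_bg] = rng.uniform(lo_b, hi_b, size=n_bg)
    base[-1] = 0.0  # transgene handled separately
    pop_names = list(config.populations)
    pop_probs = np.array([config.populations[p] for p in pop_names])
    matrices = []
    for cond_idx in (1, 2):
        n_cells = config.n_cells_per_condition
        labels = rng.choice(np.array(pop_names, dtype=object), size=n_cells, p=pop_probs)
        activity = rng.normal(0.0, 1.0, size=n_cells)
        w = np.zeros(config.n_genes)
        w[0] = config.anchor_loading
        if cond_idx == 1:
            w[1 : 1 + config.n_covarying] = config.covarying_loading
        mean = base[:, None] * np.exp(w[:, None] * activity[None, :])
        shape = config.dispersion
        lam = rng.gamma(shape, mean / shape)
        counts = rng.poisson(lam).astype(np.int64)
        if cond_idx == 2:
            rates = np.array([config.transgene_rates.get(p, 0.0) for p in labels])
            on = rng.random(n_cells) < rates
            counts[-1] = np.where(on, rng.poisson(3.0, size=n_cells), 0)
        else:
            counts[-1] = 0
        cells = [f"c{cond_idx}_{i:05d}" for i in range(n_cells)]
        matrices.append(
            CellMatrix(
                genes=list(genes),
                cells=cells,
                counts=sp.csr_matrix(counts),
                cell_labels=labels,
                condition=f"condition{cond_idx}",
            )
        )
    loading1 = np.zeros(config.n_genes)
    loading1[0] = config.anchor_loading
    loading1[1 : 1 + config.n_covarying] = config.covarying_loading
    loading2 = np.zeros(config.n_genes)
    loading2[0] = config.anchor_loading
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "base_mean": base,
            "loading_condition1": loading1,
            "loading_condition2": loading2,
            "is_covarying": [g in set(config.covarying_set) for g in genes],
        }
    )
    return matrices[0], matrices[1], truth


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------


@dataclass
class SurvSimConfig:
    """Cohort in which two signature activities jointly set the event hazard.

    Each sample draws latent AR and MYC activities ~ N(0, 1); signature genes'
    log-expression is shifted by effect x activity (a rank shift on the TPM
    scale), the quadrant group is the sign pattern of the activities, and the
    event time is Exponential(group hazard) right-censored by an independent
    Exponential(censor_rate).
    """

    n_samples: int = 200
    signature_sizes: tuple[int, int] = (9, 30)
    n_background_genes: int = 1000
    group_hazards: Mapping[str, float] = dc_field(
        default_factory=lambda: {
            "AR_high/MYC_low": 0.04,
            "AR_high/MYC_high": 0.08,
            "AR_low/MYC_low": 0.08,
            "AR_low/MYC_high": 0.16,
        }
    )
    censor_rate: float = 0.03
    effect: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        for grp in QUADRANT_LABELS:
            if grp not in self.group_hazards:
                raise ValueError(f"group_hazards missing quadrant {grp!r}")
        if any(h <= 0 for h in self.group_hazards.values()):
            raise ValueError("all hazards must be > 0")
        if self.censor_rate <= 0:
            raise ValueError("censor_rate must be > 0")

    def ar_signature_genes(self) -> list[str]:
        n_ar = self.signature_sizes[0]
        if n_ar == len(AR_A.gene_ids):
            return list(AR_A.gene_ids)
        return [f"ARSIG{i:03d}" for i in range(n_ar)]

    def myc_signature_genes(self) -> list[str]:
        return [f"MYCSIG{i:03d}" for i in range(self.signature_sizes[1])]


def simulate_survival_cohort(
    config: SurvSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (expression, cohort): a genes x samples TPM table and a truth
    table with sample_id, latent activities, quadrant group, observed time
    and event indicator."""
    rng = np.random.default_rng(config.seed)
    ar_genes = config.ar_signature_genes()
    myc_genes = config.myc_signature_genes()
    bg_genes = [f"gene{i:05d}" for i in range(config.n_background_genes)]
    genes = ar_genes + myc_genes + bg_genes
    n = config.n_samples
    samples = [f"s{i:04d}" for i in range(n)]
    s_ar = rng.normal(0.0, 1.0, size=n)
    s_myc = rng.normal(0.0, 1.0, size=n)
    log_expr = rng.normal(5.0, 1.0, size=(len(genes), n))
    log_expr[: len(ar_genes)] += config.effect * s_ar[None, :]
    log_expr[len(ar_genes) : len(ar_genes) + len(myc_genes)] += (
        config.effect * s_myc[None, :]
    )
    tpm = np.exp2(log_expr)
    tpm *= 1e6 / tpm.sum(axis=0, keepdims=True)
    expression = pd.DataFrame(tpm, index=genes, columns=samples)
    group = np.where(
        s_ar > 0,
        np.where(s_myc > 0, "AR_high/MYC_high", "AR_high/MYC_low"),
        np.where(s_myc > 0, "AR_low/MYC_high", "AR_low/MYC_low"),
    )
    hazards = np.array([config.group_hazards[g] for g in group])
    event_time = rng.exponential(1.0 / hazards)
    censor_time = rng.exponential(1.0 / config.censor_rate, size=n)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    cohort = pd.DataFrame(
        {
            "sample_id": samples,
            "latent_ar": s_ar,
            "latent_myc": s_myc,
            "group": group,
            "time": observed,
            "event": event,
        }
    ).set_index("sample_id", drop=False)
    cohort.index.name = None
    return expression, cohort
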