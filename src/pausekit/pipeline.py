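"""Config-driven orchestration of the three analysis tracks.

A :class:`PipelineConfig` names a track (``polii``, ``sc``, ``stratify`` or
``demo``), its input paths and parameter overrides; :func:`run_pipeline`
validates it, executes the track's stages in order, and writes every output
plus a ``manifest.json`` holding a sha256 per file, so identical config+seed
yields identical manifests. All randomness flows through the single seed
recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .genome import (
    load_gene_models,
    read_chrom_sizes,
    coverage_from_fragments,
    write_bed12,
    write_chrom_sizes,
)
from .sc import CellMatrix, anchor_covariance_shift, qc_filter_cells, transgene_census
from .simulate import (
    PolIISimConfig,
    ScSimConfig,
    SurvSimConfig,
    gene_id,
    simulate_gene_models,
    simulate_polii_experiment,
    simulate_sc_experiment,
    simulate_survival_cohort,
)
from .stratify import (
    AR_A,
    Signature,
    assign_quadrant_groups,
    km_logrank,
    maxstat_cutpoint,
    read_signature,
    signature_score,
)
from .traveling import (
    classify_pause_genes,
    compare_geneset_tr,
    compute_tr_table,
    read_gene_set,
    tangent_cutpoints,
    tr_difference_curve,
)

__all__ = ["PipelineConfig", "PipelineValidationError", "run_pipeline"]

logger = logging.getLogger("pausekit")

TRACKS = ("polii", "sc", "stratify", "demo")


class PipelineValidationError(ValueError):
    """Config failed validation; message names the offending fields."""


@dataclass
class PipelineConfig:
    track: str
    out: Path
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(
            track=raw.pop("track", "demo"),
            out=Path(raw.pop("out", "pausekit_out")),
            seed=int(raw.pop("seed", 0)),
            log_level=str(raw.pop("log_level", "INFO")),
            params=raw,
        )

    def validate(self) -> None:
        problems = []
        if self.track not in TRACKS:
            problems.append(f"track: unknown track {self.track!r} (use one of {TRACKS})")
        path_fields = {
            "polii": ["fragments1", "fragments2", "genes", "chrom_sizes"],
            "sc": ["matrix1", "matrix2"],
            "stratify": ["expr", "surv"],
            "demo": [],
        }.get(self.track, [])
        for name in path_fields:
            value = self.params.get(name)
            if value is None:
                problems.append(f"{name}: required input path missing")
            elif not Path(value).exists():
                problems.append(f"{name}: path does not exist: {value}")
        smooth = self.params.get("smooth_window")
        if smooth is not None and (int(smooth) < 3 or int(smooth) % 2 == 0):
            problems.append("smooth_window: must be an odd integer >= 3")
        if problems:
            raise PipelineValidationError(
                "invalid pipeline config: " + "; ".join(problems)
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


class _Outputs:
    """Tracks written files for the manifest / failure cleanup."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.files: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.files.append(p)
        return p


def _run_polii(cfg: PipelineConfig, out: _Outputs) -> None:
    p = cfg.params
    chrom_sizes = read_chrom_sizes(p["chrom_sizes"])
    genes = load_gene_models(p["genes"])
    logger.info("polii: %d genes, %d chromosomes", len(genes), len(chrom_sizes))
    track1 = coverage_from_fragments(p["fragments1"], chrom_sizes)
    track2 = coverage_from_fragments(p["fragments2"], chrom_sizes)
    tr1 = compute_tr_table(track1, genes)
    tr2 = compute_tr_table(track2, genes)
    tr1.to_csv(out.path("tr_condition1.tsv"), sep="\t", index=False)
    tr2.to_csv(out.path("tr_condition2.tsv"), sep="\t", index=False)
    curve = tr_difference_curve(tr1, tr2)
    smooth = int(p.get("smooth_window", 11))
    cuts = tangent_cutpoints(curve, smooth_window=smooth)
    curve_df = curve.data.copy()
    curve_df["slope"] = cuts.slope
    curve_df.to_csv(out.path("tr_difference_curve.tsv"), sep="\t", index=False)
    classes = classify_pause_genes(curve, cuts)
    logger.info(
        "polii: %d pause-release, %d pause genes",
        classes.n_pause_release,
        classes.n_pause,
    )
    rows = [("pause_release", g) for g in sorted(classes.pause_release)]
    rows += [("pause", g) for g in sorted(classes.pause)]
    pd.DataFrame(rows, columns=["class", "gene_id"]).to_csv(
        out.path("pause_classes.tsv"), sep="\t", index=False
    )
    if p.get("gene_set"):
        members = read_gene_set(p["gene_set"])
        results = {}
        for test in ("KS", "Welch-t"):
            cmp_res = compare_geneset_tr(tr1, tr2, members, test=test)
            results[cmp_res.test] = {
                "statistic": cmp_res.statistic,
                "p_value": cmp_res.p_value,
                "n1": cmp_res.n1,
                "n2": cmp_res.n2,
            }
        _write_json(results, out.path("geneset_comparison.json"))


def _run_sc(cfg: PipelineConfig, out: _Outputs) -> None:
    p = cfg.params
    m1 = CellMatrix.from_mtx(p["matrix1"])
    m2 = CellMatrix.from_mtx(p["matrix2"])
    logger.info("sc: %d/%d cells in conditions 1/2", m1.n_cells, m2.n_cells)
    m1, rep1 = qc_filter_cells(m1)
    m2, rep2 = qc_filter_cells(m2)
    logger.info("sc QC: kept %d and %d cells", rep1.n_kept, rep2.n_kept)
    shift = anchor_covariance_shift(
        m1,
        m2,
        anchor=p.get("anchor", "Ar"),
        threshold=float(p.get("threshold", 30.0)),
        cell_mask=p.get("cell_mask"),
    )
    shift.to_csv(out.path("covariance_shift.tsv"), sep="\t", index=False)
    if p.get("transgene"):
        census = transgene_census(m2, p["transgene"])
        census.to_csv(out.path("transgene_census.tsv"), sep="\t", index=False)


def _run_stratify(cfg: PipelineConfig, out: _Outputs) -> None:
    p = cfg.params
    expr = pd.read_csv(p["expr"], sep="\t", index_col=0)
    surv = pd.read_csv(p["surv"], sep="\t", index_col=0)
    if p.get("sig_ar"):
        sig_ar = read_signature(p["sig_ar"], p.get("sig_ar_name"))
    else:
        # default: the built-in AR-A target panel, else simulator AR ids
        present = tuple(g for g in AR_A.gene_ids if g in expr.index)
        if len(present) < 2:
            present = tuple(g for g in expr.index if g.startswith("ARSIG"))
        sig_ar = Signature("AR", present)
    sig_myc = (
        read_signature(p["sig_myc"], p.get("sig_myc_name"))
        if p.get("sig_myc")
        else Signature("MYC", tuple(g for g in expr.index if g.startswith("MYCSIG")))
    )
    qr = tuple(p.get("quantile_range", (0.10, 0.90)))
    ar_scores = signature_score(expr, sig_ar).rename("ar_score")
    myc_scores = signature_score(expr, sig_myc).rename("myc_score")
    scores = pd.concat([ar_scores, myc_scores], axis=1)
    scores.index.name = "sample_id"
    scores.to_csv(out.path("signature_scores.tsv"), sep="\t")
    ar_cut = maxstat_cutpoint(ar_scores, surv, quantile_range=qr)
    myc_cut = maxstat_cutpoint(myc_scores, surv, quantile_range=qr)
    _write_json(
        {
            "ar": {"value": ar_cut.value, "statistic": ar_cut.statistic,
                   "n_candidates": ar_cut.n_candidates},
            "myc": {"value": myc_cut.value, "statistic": myc_cut.statistic,
                    "n_candidates": myc_cut.n_candidates},
        },
        out.path("cutpoints.json"),
    )
    groups = assign_quadrant_groups(ar_scores, myc_scores, ar_cut, myc_cut)
    cohort = surv.loc[groups.index, ["time", "event"]].copy()
    cohort["group"] = groups
    cohort.index.name = "sample_id"
    cohort.to_csv(out.path("groups.tsv"), sep="\t")
    km = km_logrank(cohort, pairwise=bool(p.get("pairwise", False)))
    curves = pd.concat(
        [df.assign(group=grp) for grp, df in sorted(km.curves.items())],
        ignore_index=True,
    )
    curves.to_csv(out.path("km_curves.tsv"), sep="\t", index=False)
    _write_json(
        {"chi2": km.chi2, "df": km.df, "p_value": km.p_value},
        out.path("logrank.json"),
    )
    logger.info("stratify: log-rank chi2=%.3f p=%.3g", km.chi2, km.p_value)


def _run_demo(cfg: PipelineConfig, out: _Outputs) -> None:
    """End-to-end run of all three tracks on synthetic inputs with planted
    truth, at sizes small enough to finish in seconds."""
    seed = cfg.seed
    # --- Pol II pausing ---------------------------------------------------
    n_genes = int(cfg.params.get("n_genes", 400))
    release_ids = [gene_id(i) for i in range(0, 8)]
    pause_ids = [gene_id(i) for i in range(100, 116)]
    sim_cfg = PolIISimConfig(
        n_genes=n_genes,
        chrom_length=max(2_000_000, 3000 * n_genes),
        reads_per_gene_mean=float(cfg.params.get("reads_per_gene_mean", 300)),
        planted_pause_release=release_ids,
        planted_pause=pause_ids,
        seed=seed,
    )
    genes = simulate_gene_models(sim_cfg)
    track1, track2, truth = simulate_polii_experiment(genes, sim_cfg)
    write_bed12(genes, out.path("genes.bed12"))
    write_chrom_sizes({"chrSim": sim_cfg.chrom_length}, out.path("chrom.sizes"))
    truth.to_csv(out.path("polii_truth.tsv"), sep="\t", index=False)
    tr1 = compute_tr_table(track1, genes)
    tr2 = compute_tr_table(track2, genes)
    tr1.to_csv(out.path("tr_condition1.tsv"), sep="\t", index=False)
    tr2.to_csv(out.path("tr_condition2.tsv"), sep="\t", index=False)
    curve = tr_difference_curve(tr1, tr2)
    cuts = tangent_cutpoints(curve)
    classes = classify_pause_genes(curve, cuts)
    rows = [("pause_release", g) for g in sorted(classes.pause_release)]
    rows += [("pause", g) for g in sorted(classes.pause)]
    pd.DataFrame(rows, columns=["class", "gene_id"]).to_csv(
        out.path("pause_classes.tsv"), sep="\t", index=False
    )
    logger.info(
        "demo polii: %d/%d recovered pause-release/pause",
        classes.n_pause_release,
        classes.n_pause,
    )
    # --- single-cell covariance -------------------------------------------
    sc_cfg = ScSimConfig(
        n_genes=int(cfg.params.get("sc_genes", 150)),
        n_cells_per_condition=int(cfg.params.get("sc_cells", 400)),
        n_covarying=10,
        seed=seed + 1,
    )
    m1, m2, sc_truth = simulate_sc_experiment(sc_cfg)
    sc_truth.to_csv(out.path("sc_truth.tsv"), sep="\t", index=False)
    shift = anchor_covariance_shift(m1, m2, anchor=sc_cfg.anchor_gene)
    shift.to_csv(out.path("covariance_shift.tsv"), sep="\t", index=False)
    census = transgene_census(m2, sc_cfg.transgene)
    census.to_csv(out.path("transgene_census.tsv"), sep="\t", index=False)
    # --- stratification ----------------------------------------------------
    surv_cfg = SurvSimConfig(n_samples=int(cfg.params.get("n_samples", 160)), seed=seed + 2)
    expr, cohort_truth = simulate_survival_cohort(surv_cfg)
    sig_ar = Signature("AR", tuple(surv_cfg.ar_signature_genes()))
    sig_myc = Signature("MYC", tuple(surv_cfg.myc_signature_genes()))
    ar_scores = signature_score(expr, sig_ar).rename("ar_score")
    myc_scores = signature_score(expr, sig_myc).rename("myc_score")
    surv = cohort_truth[["time", "event"]]
    ar_cut = maxstat_cutpoint(ar_scores, surv)
    myc_cut = maxstat_cutpoint(myc_scores, surv)
    groups = assign_quadrant_groups(ar_scores, myc_scores, ar_cut, myc_cut)
    cohort = surv.copy()
    cohort["group"] = groups
    cohort.index.name = "sample_id"
    cohort.to_csv(out.path("groups.tsv"), sep="\t")
    km = km_logrank(cohort)
    _write_json(
        {
            "chi2": km.chi2,
            "df": km.df,
            "p_value": km.p_value,
            "cut_ar": ar_cut.value,
            "cut_myc": myc_cut.value,
        },
        out.path("logrank.json"),
    )
    logger.info("demo stratify: log-rank chi2=%.2f p=%.3g", km.chi2, km.p_value)


_RUNNERS = {
    "polii": _run_polii,
    "sc": _run_sc,
    "stratify": _run_stratify,
    "demo": _run_demo,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Validate, execute the configured track, and write the manifest.

    On a stage failure, partial outputs are removed and the run log retained.
    Returns the manifest dict (also written to ``<out>/manifest.json``).
    """
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    out = _Outputs(outdir)
    try:
        logger.info("track=%s seed=%d out=%s", config.track, config.seed, outdir)
        _RUNNERS[config.track](config, out)
    except Exception:
        logger.exception("stage failed; removing partial outputs")
        for f in out.files:
            f.unlink(missing_ok=True)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    manifest = {
        "package_version": __version__,
        "track": config.track,
        "seed": config.seed,
        "files": {f.name: _sha256(f) for f in sorted(out.files) if f.exists()},
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
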