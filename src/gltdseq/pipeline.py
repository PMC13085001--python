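"""End-to-end orchestration: filter -> normalize -> DE -> length trend ->
enrichment -> reproducibility, from a single config with one global seed.

The pipeline consumes the file formats in :mod:`gltdseq.io`, writes every
stage's TSV/JSON outputs into the output directory, and records a run
manifest (config echo, package version, seed, input digests, per-stage
counts).  Outputs are a pure function of config + seed: two runs with the
same config and seed produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import interaction_contrast, meta_analyze, nb_wald_test
from .enrichment import gsea, rank_genes
from .gltd import (
    GeneLengthTrendModel,
    cohort_interaction_regression,
    deg_length_shift_test,
)
from .io import (
    CountMatrix,
    read_counts,
    read_de_table,
    read_gene_lengths,
    read_gmt,
    write_de_table,
)
from .normalize import (
    expression_filter,
    median_of_ratios,
    tmm_abundance_filter,
    tmm_factors,
)
from .reproducibility import (
    directionality_consistency,
    overlap_analysis,
    profile_correlations,
)
from .simulate import SimulationConfig, simulate_two_group_experiment

logger = logging.getLogger("gltdseq")

__all__ = ["PipelineConfig", "run_pipeline", "run_simulation_study", "analyze_cohort"]


@dataclass
class PipelineConfig:
    """Inputs and stage parameters for one pipeline run."""

    counts_path: str
    meta_path: str
    annotation_path: str
    gmt_path: str | None = None
    de_tables: dict[str, str] = field(default_factory=dict)  # cohort -> external DE TSV
    contrast: tuple[str, str] = ("ELS", "control")
    min_count: float = 20.0
    min_replicates: int | None = None  # default: half the smallest group, rounded up
    tmm_threshold: float = 1.0
    bin_size: int = 500
    direction_mode: str = "all_genes"
    n_perm: int = 10000
    min_set_size: int = 1
    max_set_size: int = 5000
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "gltdseq_out"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        return cls(**raw)

    def echo(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "output_dir"}
        out["contrast"] = list(self.contrast)
        return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray, pd.Index)):
        return list(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def analyze_cohort(
    counts: CountMatrix,
    lengths: pd.Series,
    config: PipelineConfig,
    external_de: pd.DataFrame | None = None,
) -> dict:
    """Run the per-cohort stages: normalize, filter, DE, length trend.

    Returns a dict with keys factors, tmm, expressed, de, interaction
    (2x2 designs only), gltd (fitted results or None), universe.
    """
    out: dict = {}
    treat_label, ctrl_label = config.contrast
    vehicle = counts
    treatments = sorted(set(counts.sample_meta["treatment"]))
    if len(treatments) > 1:
        base = treatments[0] if "vehicle" not in treatments else "vehicle"
        vehicle = counts.subset_samples(
            counts.sample_meta.index[counts.sample_meta["treatment"] == base]
        )
    factors, normalized = median_of_ratios(vehicle)
    groups = vehicle.groups("condition")
    min_rep = config.min_replicates
    if min_rep is None:
        min_rep = max(2, math.ceil(min(len(s) for s in groups.values()) / 2))
    expressed = expression_filter(normalized, groups, min_rep, config.min_count)
    logger.info("expression filter retained %d genes", len(expressed))
    filtered = vehicle.subset_genes(expressed)
    if external_de is not None:
        de = external_de.copy()
        if "significant" not in de.columns:
            de["significant"] = de["padj"] < config.alpha
    else:
        f2, _ = median_of_ratios(filtered)
        de = nb_wald_test(filtered, factors=f2, contrast=config.contrast,
                          alpha=config.alpha)
    out["factors"] = factors
    out["expressed"] = expressed
    out["de"] = de
    # 2x2 designs: repeat the contrast under the second treatment, interaction
    out["interaction"] = None
    if len(treatments) > 1 and external_de is None:
        other = [t for t in treatments if t != (
            "vehicle" if "vehicle" in treatments else treatments[0])]
        if other:
            alt = counts.subset_samples(
                counts.sample_meta.index[counts.sample_meta["treatment"] == other[0]]
            ).subset_genes(expressed)
            try:
                f3, _ = median_of_ratios(alt)
                de_alt = nb_wald_test(alt, factors=f3, contrast=config.contrast,
                                      alpha=config.alpha)
                out["interaction"] = interaction_contrast(de, de_alt,
                                                          alpha=config.alpha)
                out["de_alt"] = de_alt
            except ValueError:
                logger.warning("interaction stage skipped (insufficient samples)")
    # length-trend universe: TMM-CPM filter on the vehicle samples
    tmm = tmm_factors(vehicle)
    out["tmm"] = tmm
    universe = tmm_abundance_filter(vehicle, tmm, config.tmm_threshold)
    universe = universe.intersection(lengths.index).intersection(de["gene_id"])
    out["universe"] = universe
    logger.info("length-trend universe: %d genes", len(universe))
    out["gltd"] = None
    if len(universe) >= config.bin_size * 3:
        model = GeneLengthTrendModel(
            de[de["gene_id"].isin(universe)],
            lengths.loc[universe],
            bin_size=config.bin_size,
            mode=config.direction_mode,
            alpha=config.alpha,
        )
        try:
            out["gltd"] = model.fit()
        except ValueError as err:
            logger.warning("length-trend regression skipped: %s", err)
    try:
        out["length_shift"] = deg_length_shift_test(
            de, lengths.reindex(de["gene_id"]).dropna(), alpha=config.alpha
        )
    except (ValueError, KeyError):
        out["length_shift"] = None
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to the output dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "gltdseq",
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "inputs": {},
        "stages": {},
    }
    stage = "read_inputs"
    try:
        counts = read_counts(config.counts_path, config.meta_path)
        lengths = read_gene_lengths(config.annotation_path)
        for key, path in (
            ("counts", config.counts_path),
            ("metadata", config.meta_path),
            ("annotation", config.annotation_path),
        ):
            manifest["inputs"][key] = _sha256(path)
        sets = None
        if config.gmt_path:
            sets = read_gmt(config.gmt_path)
            manifest["inputs"]["gene_sets"] = _sha256(config.gmt_path)
        externals = {
            cohort: read_de_table(path) for cohort, path in config.de_tables.items()
        }
        cohorts = sorted(set(counts.sample_meta["cohort"]))
        logger.info("cohorts: %s", cohorts)
        results: dict[str, dict] = {}
        for cohort in cohorts:
            stage = f"cohort:{cohort}"
            sub = counts.subset_samples(
                counts.sample_meta.index[counts.sample_meta["cohort"] == cohort]
            )
            res = analyze_cohort(sub, lengths, config, externals.get(cohort))
            results[cohort] = res
            write_de_table(res["de"], outdir / f"de_{cohort}.tsv")
            pd.DataFrame(
                {"sample_id": res["factors"].index,
                 "size_factor": res["factors"].to_numpy(),
                 "tmm_factor": res["tmm"].reindex(res["factors"].index).to_numpy()}
            ).to_csv(outdir / f"factors_{cohort}.tsv", sep="\t", index=False)
            (outdir / f"expressed_{cohort}.txt").write_text(
                "\n".join(res["expressed"]) + "\n", encoding="utf-8"
            )
            stats_block = {
                "n_expressed": len(res["expressed"]),
                "n_significant": int(res["de"]["significant"].sum()),
                "length_shift": res["length_shift"],
            }
            if res["gltd"] is not None:
                res["gltd"].bins.to_csv(outdir / f"bins_{cohort}.tsv", sep="\t",
                                        index=False)
                stats_block["gltd"] = res["gltd"].fit.to_dict()
            if res["interaction"] is not None:
                write_de_table(res["interaction"], outdir / f"interaction_{cohort}.tsv")
                stats_block["n_interaction_significant"] = int(
                    res["interaction"]["significant"].sum()
                )
            _dump_json(stats_block, outdir / f"gltd_{cohort}.json")
            if sets is not None:
                stage = f"gsea:{cohort}"
                ranked = rank_genes(res["de"])
                ranked.to_csv(outdir / f"ranked_{cohort}.tsv", sep="\t", index=False)
                enr = gsea(
                    ranked,
                    sets,
                    n_perm=config.n_perm,
                    min_size=config.min_set_size,
                    max_size=config.max_set_size,
                    seed=config.seed,
                )
                enr = enr.assign(leading_edge=[",".join(le) for le in enr["leading_edge"]])
                enr.to_csv(outdir / f"gsea_{cohort}.tsv", sep="\t", index=False)
                manifest["stages"][f"gsea:{cohort}"] = {"n_sets": len(enr)}
            manifest["stages"][f"cohort:{cohort}"] = {
                "n_samples": int(sub.counts.shape[1]),
                "n_expressed": len(res["expressed"]),
                "n_universe": len(res["universe"]),
                "n_significant": int(res["de"]["significant"].sum()),
            }
        stage = "reproducibility"
        if len(cohorts) >= 2:
            a, b = cohorts[0], cohorts[1]
            sub_a = counts.subset_samples(
                counts.sample_meta.index[counts.sample_meta["cohort"] == a])
            sub_b = counts.subset_samples(
                counts.sample_meta.index[counts.sample_meta["cohort"] == b])
            ctrl = config.contrast[1]
            corr = profile_correlations(
                sub_a, sub_b, sample_filter=lambda m: m["condition"] == ctrl
            )
            repro: dict = {"profile_correlations": corr.to_dict()}
            try:
                repro["directionality"] = directionality_consistency(
                    results[a]["de"], results[b]["de"], alpha=config.alpha
                )
            except ValueError as err:
                repro["directionality"] = {"skipped": str(err)}
            deg_sets = {
                c: set(r["de"].loc[r["de"]["significant"], "gene_id"])
                for c, r in results.items()
            }
            deg_sets = {c: s for c, s in deg_sets.items() if s}
            if len(deg_sets) >= 2:
                regions, _ = overlap_analysis(deg_sets)
                regions.to_csv(outdir / "overlap.tsv", sep="\t", index=False)
                repro["overlap_regions"] = len(regions)
            if results[a]["gltd"] is not None and results[b]["gltd"] is not None:
                comp = cohort_interaction_regression(
                    results[a]["gltd"].bin_table, results[b]["gltd"].bin_table
                )
                repro["cohort_interaction"] = comp.to_dict()
            try:
                meta = meta_analyze([results[a]["de"], results[b]["de"]])
                meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
                repro["n_meta_genes"] = len(meta)
            except ValueError as err:
                repro["meta"] = {"skipped": str(err)}
            _dump_json(repro, outdir / "reproducibility.json")
            manifest["stages"]["reproducibility"] = {"status": "done"}
        else:
            manifest["stages"]["reproducibility"] = {"status": "skipped",
                                                     "reason": "single cohort"}
    except Exception as err:
        (outdir / "FAILED").write_text(f"{stage}: {err}\n", encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    _dump_json(manifest, outdir / "manifest.json")
    return manifest


def run_simulation_study(
    grid: list[SimulationConfig],
    replicates: int,
    alpha: float = 0.05,
    bin_size: int = 500,
) -> pd.DataFrame:
    """Calibration/power table over a grid of generator configurations.

    For each grid point and replicate: simulate one cohort, run the
    normalization + DE + length-trend stages, and tabulate the
    length-slope rejection rate, the mean fitted slope, and DE type-I
    rate (on null genes) and power (on true effects).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for point in grid:
        slopes, rejections, type1, power = [], [], [], []
        for rep in range(replicates):
            cfg = point.with_(seed=point.seed + 7919 * rep)
            res = analyze_simulated_cohort(cfg, alpha=alpha, bin_size=bin_size)
            if res["gltd"] is not None:
                slopes.append(res["gltd"].slope)
                rejections.append(res["gltd"].pvalue < alpha)
            de, effects = res["de"], res["effects"]
            merged = de.merge(
                effects.reset_index()[["gene_id", "is_de"]], on="gene_id"
            )
            nulls = merged[~merged["is_de"]]
            trues = merged[merged["is_de"]]
            if len(nulls):
                type1.append(float((nulls["pvalue"] < alpha).mean()))
            if len(trues):
                power.append(float((trues["pvalue"] < alpha).mean()))
        rows.append(
            {
                "gltd_slope": point.gltd_slope,
                "de_fraction": point.de_fraction,
                "effect_scale": point.effect_scale,
                "n_per_group": point.n_per_group,
                "replicates": replicates,
                "slope_mean": float(np.mean(slopes)) if slopes else np.nan,
                "slope_rejection_rate": float(np.mean(rejections))
                if rejections
                else np.nan,
                "de_type1_rate": float(np.mean(type1)) if type1 else np.nan,
                "de_power": float(np.mean(power)) if power else np.nan,
            }
        )
    return pd.DataFrame(rows)


def analyze_simulated_cohort(
    config: SimulationConfig,
    alpha: float = 0.05,
    bin_size: int = 500,
    mode: str = "all_genes",
    cohort: str = "cohort1",
) -> dict:
    """Simulate one cohort and run the core analysis stages on it."""
    universe, effects, counts = simulate_two_group_experiment(config, cohort=cohort)
    factors, normalized = median_of_ratios(counts)
    groups = counts.groups("condition")
    expressed = expression_filter(
        normalized, groups, max(2, math.ceil(config.n_per_group / 2))
    )
    filtered = counts.subset_genes(expressed)
    f2, _ = median_of_ratios(filtered)
    de = nb_wald_test(filtered, factors=f2, contrast=("ELS", "control"), alpha=alpha)
    tmm = tmm_factors(counts)
    gltd_universe = tmm_abundance_filter(counts, tmm, 1.0).intersection(expressed)
    gltd_res = None
    if len(gltd_universe) >= 3 * bin_size:
        lengths = universe.loc[gltd_universe, "length_bp"]
        model = GeneLengthTrendModel(
            de[de["gene_id"].isin(gltd_universe)], lengths, bin_size=bin_size,
            mode=mode, alpha=alpha,
        )
        try:
            gltd_res = model.fit()
        except ValueError:
            gltd_res = None
    return {
        "universe": universe,
        "effects": effects,
        "counts": counts,
        "de": de,
        "gltd": gltd_res,
        "expressed": expressed,
        "gltd_universe": gltd_universe,
    }
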