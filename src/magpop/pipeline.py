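"""End-to-end orchestration: simulate/load -> SNVs -> F_ST -> clustering ->
shared variants -> PERMANOVA, with a machine-readable run manifest.

MAGs are processed independently and sequentially; every stage writes plain
files, and the manifest records a SHA-256 digest for each output so a rerun
with the same seed can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import MagpopError, PipelineStageError
from .fst import fst_matrix, ward_cluster
from .io import (
    PipelineConfig,
    logger,
    read_sample_metadata,
    read_variability_table,
    write_distance_matrix,
    write_newick,
)
from .permanova import permanova
from .shared import build_pair_comparisons, fit_fst_regressions, horizon_summary, intercore_vs_intracore_test
from .simulate import SimulationConfig, simulate_bundle, write_truth_bundle
from .snv import call_snvs, core_positions, samples_covering, select_mags, snv_density

PERMANOVA_FACTORS = ("realm", "trench_system", "site_id", "horizon")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _versions() -> dict:
    import scipy

    return {
        "magpop": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def load_bundle(indir):
    """Read a simulated (or equivalently structured) input bundle."""
    indir = Path(indir)
    counts = read_variability_table(indir / "counts.tsv")
    coverage = pd.read_csv(indir / "coverage.tsv", sep="\t")
    metadata = read_sample_metadata(indir / "metadata.tsv")
    return counts, coverage, metadata


def run_all(
    config: PipelineConfig,
    outdir,
    sim_config: SimulationConfig | None = None,
    indir=None,
) -> dict:
    """Run every stage for every selected MAG; returns the manifest dict.

    Either ``sim_config`` (simulate a bundle first) or ``indir`` (load an
    existing bundle) must be given. The manifest echoes the configuration,
    lists per-MAG selection outcomes, and digests every output file. A stage
    failure raises PipelineStageError after writing the manifest with a
    FAILED marker; already-written outputs are retained.
    """
    if (sim_config is None) == (indir is None):
        raise MagpopError("run_all needs exactly one of sim_config or indir")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "versions": _versions(),
        "mags": {},
        "files": {},
        "status": "ok",
    }

    if sim_config is not None:
        truth, counts, coverage = simulate_bundle(sim_config)
        paths = write_truth_bundle(truth, counts, coverage, outdir / "simulated")
        metadata = truth.samples
        manifest["files"].update({f"simulated/{k}": p for k, p in paths.items()})
        manifest["sim_config"] = sim_config.to_dict()
    else:
        counts, coverage, metadata = load_bundle(indir)
        manifest["input_dir"] = str(indir)

    meta_by_id = {rec.sample_id: rec for rec in metadata}

    # MAG selection: main threshold first, abyssal fallback for sparse MAGs
    selected = select_mags(coverage, config.min_coverage, config.min_samples_main)
    fallback = [
        m
        for m in select_mags(coverage, config.min_coverage, config.min_samples_abyssal)
        if m not in selected
    ]
    all_mags = sorted(coverage["mag_id"].unique())
    for mag in all_mags:
        if mag in selected:
            manifest["mags"][mag] = {"selected": True, "rule": "main"}
        elif mag in fallback:
            manifest["mags"][mag] = {"selected": True, "rule": "abyssal-fallback"}
        else:
            manifest["mags"][mag] = {"selected": False, "rule": "insufficient-samples"}

    failed: tuple[str, str, str] | None = None
    for mag in selected + fallback:
        mag_dir = outdir / mag
        mag_dir.mkdir(exist_ok=True)
        try:
            _run_mag(config, mag, counts, coverage, metadata, meta_by_id, mag_dir, manifest)
        except MagpopError as exc:
            stage = getattr(exc, "stage", "analysis")
            manifest["mags"][mag]["status"] = "FAILED"
            manifest["mags"][mag]["error"] = str(exc)
            manifest["status"] = "FAILED"
            failed = (stage, mag, str(exc))
            break
        manifest["mags"][mag]["status"] = "ok"

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(outdir))] = _sha256(path)

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if failed is not None:
        raise PipelineStageError(failed[0], failed[1], failed[2])
    return manifest


def _run_mag(config, mag, counts, coverage, metadata, meta_by_id, mag_dir: Path, manifest):
    mag_counts = counts[counts["mag_id"] == mag]
    sample_ids = samples_covering(coverage, mag, config.min_coverage)
    sample_ids = [s for s in sample_ids if s in set(mag_counts["sample_id"])]
    manifest["mags"][mag]["n_samples"] = len(sample_ids)
    if len(sample_ids) < 2:
        raise PipelineStageError("fst", mag, "fewer than 2 samples with sufficient coverage")

    snvs = call_snvs(mag_counts, config.min_coverage, config.min_departure)
    snvs.to_csv(mag_dir / "snvs.tsv", sep="\t", index=False, float_format="%.10g")

    matrix = fst_matrix(
        mag_counts,
        snvs,
        sample_ids,
        min_coverage=config.min_coverage,
        site_set=config.site_set,
        mag_id=mag,
    )
    write_distance_matrix(matrix, mag_dir / "fst_matrix.tsv")
    pd.DataFrame(matrix.n_positions, index=sample_ids, columns=sample_ids).to_csv(
        mag_dir / "fst_n_positions.tsv", sep="\t"
    )

    tree = ward_cluster(matrix)
    write_newick(tree, mag_dir / "dendrogram.nwk")

    pairs = build_pair_comparisons(
        mag_counts,
        snvs,
        matrix,
        metadata,
        min_coverage=config.min_coverage,
        shared_denominator=config.shared_denominator,
    )
    pairs.to_csv(mag_dir / "pair_comparisons.tsv", sep="\t", index=False, float_format="%.10g")

    report: dict = {"mag_id": mag, "n_samples": len(sample_ids)}
    inter = pairs[pairs["kind"] == "inter_core"]
    intra = pairs[pairs["kind"] == "intra_core"]
    if len(inter) and len(intra):
        h_stat, p_value, medians = intercore_vs_intracore_test(pairs)
        report["intercore_vs_intracore"] = {
            "H": h_stat,
            "p_value": p_value,
            "medians": medians,
        }
    if len(inter) >= 3 and inter["pct_shared"].nunique() > 1:
        fits = fit_fst_regressions(pairs)
        report["regressions"] = {
            name: dataclasses.asdict(fit) for name, fit in fits.items()
        }
        horizon_summary(pairs).to_csv(
            mag_dir / "horizon_summary.tsv", sep="\t", index=False, float_format="%.10g"
        )

    perm_rows = []
    for factor in PERMANOVA_FACTORS:
        grouping = {
            s: getattr(meta_by_id[s], factor) if factor != "horizon" else meta_by_id[s].horizon
            for s in sample_ids
        }
        if len(set(grouping.values())) < 2:
            logger.info("permanova: factor %s has < 2 levels for MAG %s; skipped", factor, mag)
            continue
        res = permanova(
            matrix,
            grouping,
            n_permutations=config.n_permutations,
            seed=config.seed,
            factor=factor,
        )
        perm_rows.append(
            {
                "factor": factor,
                "pseudo_F": res.pseudo_F,
                "p_value": res.p_value,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "n_permutations": res.n_permutations,
            }
        )
    if perm_rows:
        pd.DataFrame(perm_rows).to_csv(
            mag_dir / "permanova.tsv", sep="\t", index=False, float_format="%.10g"
        )

    # per-sample SNV density over the comparison group's core-position support
    # (positions covered >= min_coverage in every sample considered), so
    # coverage differences cannot influence the detection rate
    if config.density_denominator == "mag-length":
        denom = int(mag_counts["position"].nunique())
        core = None
    else:
        core_df = core_positions(mag_counts, sample_ids, config.min_coverage)
        core = set(zip(core_df["contig_id"], core_df["position"]))
        denom = len(core)
    dens_rows = []
    if denom > 0:
        for sample in sample_ids:
            rec = meta_by_id[sample]
            sample_snvs = snvs[snvs["sample_id"] == sample]
            if core is not None and len(sample_snvs):
                keys = list(zip(sample_snvs["contig_id"], sample_snvs["position"]))
                sample_snvs = sample_snvs[[k in core for k in keys]]
            dens_rows.append(
                {
                    "sample_id": sample,
                    "horizon": rec.horizon,
                    "n_snvs": len(sample_snvs),
                    "density_per_kbp": snv_density(sample_snvs, denom),
                }
            )
    if dens_rows:
        pd.DataFrame(dens_rows).to_csv(
            mag_dir / "snv_density.tsv", sep="\t", index=False, float_format="%.10g"
        )

    with open(mag_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
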