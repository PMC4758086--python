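"""End-to-end pipeline: filter -> frequencies -> diversity -> global Fst ->
neutral null -> highland scan -> annotation -> trees.

One seed in the run config fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn`` in a fixed stage order, so any
stage can be rerun in isolation with the same stream.  The manifest records
input hashes, the seed, per-stage output paths and the overlap counts, and
is byte-identical across reruns of the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotate as annotate_mod
from . import core_io, diversity, filtering, highland_scan, neutral_null, phylo

logger = logging.getLogger("poolscan")

#: fixed order in which stage seeds are spawned from the run seed
SEEDED_STAGES = ("null_simulation",)


@dataclass
class RunConfig:
    counts: str
    meta: str
    genes: str | None = None
    dialect: str = "native_tsv"
    filter: filtering.FilterConfig = field(default_factory=filtering.FilterConfig)
    null: neutral_null.NullSimConfig = field(default_factory=neutral_null.NullSimConfig)
    thresholds: highland_scan.ScanThresholds = field(
        default_factory=highland_scan.ScanThresholds
    )
    tree_measure: str = "Da"
    count_mode: str = "effective_alleles"
    outdir: str = "poolscan_out"
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        for key, typ in (
            ("filter", filtering.FilterConfig),
            ("null", neutral_null.NullSimConfig),
            ("thresholds", highland_scan.ScanThresholds),
        ):
            if key in raw and isinstance(raw[key], dict):
                sub = raw[key]
                if key == "filter" and "autosome_names" in sub:
                    sub["autosome_names"] = tuple(sub["autosome_names"])
                raw[key] = typ(**sub)
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seeds(seed: int) -> dict[str, int]:
    """Per-stage seeds spawned from the run seed in SEEDED_STAGES order."""
    children = np.random.SeedSequence(seed).spawn(len(SEEDED_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(SEEDED_STAGES, children)
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns (and writes) the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    manifest: dict = {
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "inputs": {},
        "outputs": {},
        "counts": {},
    }

    stage = "load"
    try:
        for key, path in (("counts", cfg.counts), ("meta", cfg.meta)):
            if not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
        populations = core_io.read_population_meta(cfg.meta)
        table = core_io.read_pool_counts(cfg.counts, populations, dialect=cfg.dialect)
        manifest["counts"]["n_input_snps"] = table.n_snps

        stage = "filter"
        filtered, report = filtering.apply_site_filters(table, cfg.filter)
        _write(outdir, manifest, "filter_report", _report_frame(report), stage="filter")
        manifest["counts"]["n_filtered_snps"] = filtered.n_snps
        subset = filtering.min_coverage_subset(
            filtered, cfg.filter.min_depth_per_pop_for_fst
        )
        manifest["counts"]["n_min_coverage_snps"] = subset.n_snps

        stage = "diversity"
        freqs_all = diversity.estimate_frequencies(filtered)
        summary = diversity.diversity_summary(freqs_all, filtered)
        _write(outdir, manifest, "diversity_per_population",
               summary.per_population.reset_index(), stage=stage)
        manifest["counts"]["mean_fst"] = summary.mean_fst
        manifest["counts"]["mean_Ht"] = summary.mean_Ht
        manifest["counts"]["mean_Hs"] = summary.mean_Hs

        stage = "fst"
        freqs = diversity.estimate_frequencies(subset)
        pairs = diversity.highland_lowland_pairs(populations)
        fst = diversity.fst_table(freqs, pairs)
        _write(outdir, manifest, "fst_per_snp", fst.frame, stage=stage)

        stage = "null_simulation"
        null_cfg = dataclasses.replace(
            cfg.null, n_loci=cfg.null.n_loci or subset.n_snps, seed=seeds["null_simulation"]
        )
        null = neutral_null.simulate_null(null_cfg)
        observed = fst.frame["fst_global"].to_numpy(float)
        top = neutral_null.empirical_top_quantile(
            observed, cfg.thresholds.global_fraction
        )
        exceed = neutral_null.exceedance_report(
            observed, null, thresholds=[0.05, top.cutoff, null.fst.max()]
        )
        _write(outdir, manifest, "exceedance", exceed.table, stage=stage)
        manifest["counts"]["null_mean_fst"] = float(null.fst.mean())
        manifest["counts"]["null_max_fst"] = exceed.max_null

        stage = "scan"
        moments = highland_scan.pair_moments(fst, populations)
        di = highland_scan.di_statistic(fst, moments)
        chi2 = highland_scan.chi2_allele_test(subset, count_mode=cfg.count_mode)
        scan = highland_scan.combine_outliers(fst, di, chi2, cfg.thresholds)
        _write(outdir, manifest, "scan_per_snp", scan.frame, stage=stage)
        manifest["counts"]["overlap"] = scan.overlap
        manifest["counts"]["global_cutoff"] = scan.global_cutoff

        stage = "annotate"
        if cfg.genes is not None:
            if not Path(cfg.genes).exists():
                raise FileNotFoundError(f"gene intervals file not found: {cfg.genes}")
            manifest["inputs"]["genes"] = {
                "path": str(cfg.genes),
                "sha256": _sha256(cfg.genes),
            }
            genes = core_io.read_gene_intervals(cfg.genes)
            annotated, per_gene = annotate_mod.map_snps_to_genes(scan.frame, genes)
            gene_sum = annotate_mod.gene_summary(annotated, scan)
            _write(outdir, manifest, "snp_annotation", annotated, stage=stage)
            _write(outdir, manifest, "gene_summary", gene_sum, stage=stage)
            manifest["counts"]["n_common_genes"] = int(
                (gene_sum["common"] > 0).sum()
            ) if len(gene_sum) else 0

        stage = "trees"
        tree_all = phylo.neighbor_joining(
            phylo.nei_distance(freqs_all, cfg.tree_measure)
        )
        path_all = outdir / "tree_all_snps.nwk"
        core_io.write_newick(tree_all, path_all)
        manifest["outputs"]["tree_all_snps"] = str(path_all)
        out_mask = scan.frame["global_outlier"].to_numpy(bool)
        if out_mask.sum() >= 1:
            freqs_out = diversity.FrequencyTable(
                freqs.frame[out_mask].reset_index(drop=True), freqs.populations
            )
            tree_out = phylo.neighbor_joining(
                phylo.nei_distance(freqs_out, cfg.tree_measure)
            )
            path_out = outdir / "tree_outlier_snps.nwk"
            core_io.write_newick(tree_out, path_out)
            manifest["outputs"]["tree_outlier_snps"] = str(path_out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest


def _report_frame(report: filtering.FilterReport):
    import pandas as pd

    rows = [{"rule": k, "removed": v} for k, v in report.removed.items()]
    rows.append({"rule": "input", "removed": report.n_input})
    rows.append({"rule": "output", "removed": report.n_output})
    return pd.DataFrame(rows)


def _write(outdir: Path, manifest: dict, name: str, frame, stage: str) -> None:
    path = outdir / f"{name}.tsv"
    frame.to_csv(path, sep="\t", index=False)
    manifest["outputs"][name] = str(path)
    logger.info("stage %s wrote %s", stage, path)
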