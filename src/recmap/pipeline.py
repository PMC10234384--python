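"""End-to-end pipeline: genotypes -> QC -> map -> rates -> hotspots -> extras.

Every stage writes its intermediate to the output directory and the run
finishes with a JSON manifest (config, seed, per-stage counts, spline
clamping diagnostics) plus a plain-text summary table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from recmap import io
from recmap.assoc import annotate_gene_region, logistic_assoc, make_feature_table
from recmap.hotspots import (
    call_coldspots,
    call_hotspots,
    classify_chromatin,
    compare_hotspots,
    summarize,
    tukey_filter,
)
from recmap.linkmap import build_map
from recmap.marey import MareyMap, fit_spline, isotonize, rate_profile, window_rate
from recmap.qc import run_qc

log = logging.getLogger("recmap")


@dataclass
class RunConfig:
    genotypes: str
    out_dir: str
    population: str = ""
    chromatin: str | None = None
    gff3: str | None = None
    te_bed: str | None = None
    fasta: str | None = None
    max_missing: float = 0.10
    alpha: float = 0.01
    distortion_df: int = 1
    mapping_function: str = "kosambi"
    # explicit roughness penalty (Mbp units): GCV under-smooths the
    # random-walk noise of cumulative maps and floods the peak caller
    rate_method: str = "spline"
    smoothing: str = "0.1"
    grid_step: int = 10_000
    peak_window: int = 5
    min_fold: float = 2.0
    boundary_frac: float = 0.5
    coldspot_max_frac: float = 0.2
    coldspot_min_len: int = 500_000
    assoc_window_bp: int = 100_000
    seed: int = 0
    stages: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 <= self.max_missing < 1:
            raise ValueError("max_missing out of range")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha out of range")
        if self.grid_step <= 0 or self.assoc_window_bp <= 0:
            raise ValueError("window sizes must be positive")
        if not 0 < self.boundary_frac < 1:
            raise ValueError("boundary_frac out of range")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")


def run_all(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest dict.

    Stage failures abort with the stage name and offending input attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed ({config.genotypes}): {exc}") from exc
        manifest["stages"].append(name)
        return result

    gm = stage("read_genotypes", io.read_genotypes, config.genotypes,
               config.population)
    pop = gm.population_label

    gm_qc, report = stage("qc", run_qc, gm, config.max_missing, config.alpha,
                          config.distortion_df)
    io.write_genotypes(gm_qc, out / "qc_genotypes.tsv")
    io.write_manifest(report.to_dict(), out / "qc_report.json")
    manifest["qc"] = {k: v for k, v in report.to_dict().items()
                      if k not in ("reasons", "bins")}
    log.info("qc: %d -> %d markers", report.n_input, report.n_retained)

    gmap = stage("map", build_map, gm_qc, config.mapping_function)
    io.write_genetic_map(gmap, out / "map.tsv")

    marey = isotonize(MareyMap.from_genetic_map(gmap))
    if config.rate_method == "spline":
        model = stage("spline", fit_spline, marey, config.smoothing)
        profile = stage("rates", rate_profile, model, config.grid_step)
        manifest["clamped_fraction"] = profile.clamped_fraction
    else:
        profile = stage("rates", window_rate, gmap, config.grid_step)
    io.write_bedgraph(profile, out / "rates.bedgraph")

    chromatin = io.read_chromatin_map(config.chromatin) if config.chromatin else None
    hs = stage("hotspots", call_hotspots, profile, chromatin,
               config.peak_window, config.min_fold, config.boundary_frac, pop)
    if chromatin is not None:
        hs = classify_chromatin(hs, chromatin)
    hs = stage("tukey_filter", tukey_filter, hs)
    io.write_hotspots_bed(hs, out / "hotspots.bed")
    manifest["n_hotspots"] = int(len(hs))

    cold = stage("coldspots", call_coldspots, profile, chromatin,
                 config.coldspot_max_frac, config.coldspot_min_len, pop)
    io.write_hotspots_bed(cold, out / "coldspots.bed")
    manifest["n_coldspots"] = int(len(cold))

    summary = summarize(hs) if len(hs) else None
    if summary is not None:
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        with open(out / "summary.txt", "w") as fh:
            fh.write(summary.to_string(index=False) + "\n")

    if config.gff3 and len(hs):
        gff = io.read_gff3(config.gff3)
        categories = stage("annotate", annotate_gene_region, hs, gff)
        annotated = hs.copy()
        annotated["gene_region"] = categories
        annotated.to_csv(out / "hotspots_gene_regions.tsv", sep="\t", index=False)
        manifest["gene_region_counts"] = categories.value_counts().to_dict()

    if config.te_bed and len(hs):
        te = io.read_bed(config.te_bed)
        te = te.rename(columns={"name": "feature"})
        genome = _genome_extent(gmap)
        ft = stage("feature_table", make_feature_table, hs, cold, te, genome,
                   config.assoc_window_bp)
        ft.to_csv(out / "feature_table.tsv", sep="\t", index=False)
        results = []
        for feature in sorted(set(te["feature"])):
            for contrast in ("hotspot", "coldspot"):
                try:
                    results.append(
                        stage(f"assoc:{feature}:{contrast}", logistic_assoc,
                              ft, feature, contrast).to_dict()
                    )
                except ValueError as exc:
                    log.warning("assoc %s/%s skipped: %s", feature, contrast, exc)
        if results:
            import pandas as pd
            pd.DataFrame(results).to_csv(out / "assoc.tsv", sep="\t", index=False)

    io.write_manifest(manifest, out / "manifest.json")
    return manifest


def _genome_extent(gmap) -> list[tuple[str, int]]:
    """Chromosome extents inferred from the marker span (last marker bp)."""
    return [
        (chrom, int(gmap.chromosome(chrom)["position"].iloc[-1]) + 1)
        for chrom in gmap.chromosomes()
    ]


def compare_populations(hs_a, hs_b, min_overlap_bp: int = 1) -> dict:
    shared, n_shared, frac_a, frac_b = compare_hotspots(hs_a, hs_b, min_overlap_bp)
    return {
        "shared": shared,
        "n_shared": n_shared,
        "frac_a": frac_a,
        "frac_b": frac_b,
    }
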