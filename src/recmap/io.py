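"""Readers and writers for the pipeline's text formats.

Conventions: internal coordinates are 0-based half-open everywhere; GFF3
(1-based inclusive) is converted at the boundary.  Genotype tables are TSV
with columns id, chromosome, position, then one column per line with calls
A/B/H/-.
"""

from __future__ import annotations

import json
import tomllib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from recmap.genotypes import CALL_SYMBOLS, GenotypeMatrix
from recmap.hotspots import HOTSPOT_COLUMNS, ChromatinMap, empty_hotspot_set
from recmap.linkmap import GeneticMap
from recmap.marey import RateProfile
from recmap.simulate import HotspotSpec, SimTruth, TrueLandscape, make_landscape


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, population_label: str = "") -> GenotypeMatrix:
    """Read a genotype TSV into a validated :class:`GenotypeMatrix`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["id", "chromosome", "position"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: first columns must be {required}")
    try:
        positions = df["position"].astype(int)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer position: {exc}") from exc
    line_cols = list(df.columns[3:])
    calls = df[line_cols].to_numpy(dtype="<U1")
    bad = ~np.isin(calls, list(CALL_SYMBOLS))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: unknown call {df[line_cols[j]].iloc[i]!r} at marker "
            f"{df['id'].iloc[i]!r}, line {line_cols[j]!r}"
        )
    markers = pd.DataFrame(
        {"id": df["id"], "chromosome": df["chromosome"], "position": positions}
    )
    order = markers.sort_values(["chromosome", "position"]).index.to_numpy()
    if not np.array_equal(order, np.arange(len(markers))):
        warnings.warn(f"{path}: rows not sorted by (chromosome, position); sorting")
        markers = markers.iloc[order].reset_index(drop=True)
        calls = calls[order]
    return GenotypeMatrix(
        markers=markers, lines=line_cols, calls=calls,
        population_label=population_label or Path(path).stem,
    )


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    calls = pd.DataFrame(gm.calls, columns=gm.lines)
    df = pd.concat([gm.markers.reset_index(drop=True), calls], axis=1)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals: BED and GFF3
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """BED (0-based half-open) -> DataFrame(chromosome, start, end, name, ...)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            start, end = int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            rows.append([parts[0], start, end] + parts[3:])
    ncols = max((len(r) for r in rows), default=3)
    names = ["chromosome", "start", "end", "name", "score", "strand"][:ncols]
    names += [f"extra{k}" for k in range(len(names), ncols)]
    df = pd.DataFrame([r + [""] * (ncols - len(r)) for r in rows], columns=names)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def read_gff3(path: str | Path) -> pd.DataFrame:
    """GFF3 -> DataFrame with internal 0-based half-open coordinates.

    Columns: chromosome, source, type, start, end, strand, attributes (raw
    string).  Malformed lines are skipped with a warning, except for
    coordinate violations which raise with the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                warnings.warn(f"{path}:{lineno}: malformed GFF3 line skipped")
                continue
            try:
                start1, end = int(parts[3]), int(parts[4])
            except ValueError:
                warnings.warn(f"{path}:{lineno}: non-integer coordinates skipped")
                continue
            start0 = start1 - 1
            if end <= start0:
                raise ValueError(f"{path}:{lineno}: end <= start after conversion")
            rows.append(
                (parts[0], parts[1], parts[2], start0, end, parts[6], parts[8])
            )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "source", "type", "start", "end", "strand", "attributes"],
    )


def read_intervals(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Dispatch BED/GFF3 by extension or explicit format tag."""
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "gff3" if suffix in (".gff", ".gff3") else "bed"
    if format.lower() == "bed":
        return read_bed(path)
    if format.lower() in ("gff", "gff3"):
        return read_gff3(path)
    raise ValueError(f"unknown interval format {format!r}")


def read_chromatin_map(path: str | Path) -> ChromatinMap:
    """BED with the chromatin class in the name column -> ChromatinMap."""
    df = read_bed(path)
    if "name" not in df.columns:
        raise ValueError(f"{path}: chromatin BED needs a name column with the class")
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    for row in df.itertuples():
        intervals.setdefault(row.chromosome, []).append(
            (int(row.start), int(row.end), str(row.name))
        )
    return ChromatinMap(intervals=intervals)


def write_chromatin_map(cm: ChromatinMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, ivals in cm.intervals.items():
            for s, e, cls in ivals:
                fh.write(f"{chrom}\t{s}\t{e}\t{cls}\n")


# ---------------------------------------------------------------------------
# genetic maps and rate profiles
# ---------------------------------------------------------------------------

def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    df = gmap.table.copy()
    df.to_csv(path, sep="\t", index=False)


def read_genetic_map(
    path: str | Path, mapping_function: str = "kosambi", ril_scheme: str = "F-inf-self"
) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "marker": str})
    return GeneticMap(table=df, mapping_function=mapping_function, ril_scheme=ril_scheme)


def write_bedgraph(profile: RateProfile, path: str | Path) -> None:
    """Rate track as 4-column BedGraph-style TSV (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in profile.chromosomes():
            pos = profile.positions[chrom]
            width = profile.widths[chrom]
            rate = profile.rates[chrom]
            for p, w, r in zip(pos, width, rate):
                fh.write(f"{chrom}\t{int(round(p - w / 2))}\t{int(round(p + w / 2))}\t{r:.6g}\n")


def read_bedgraph(path: str | Path, method: str = "file") -> RateProfile:
    df = pd.read_csv(
        path, sep="\t", names=["chromosome", "start", "end", "rate"], dtype={"chromosome": str}
    )
    positions, rates, widths = {}, {}, {}
    step = 0
    for chrom, sub in df.groupby("chromosome", sort=False):
        s = sub["start"].to_numpy(float)
        e = sub["end"].to_numpy(float)
        positions[chrom] = (s + e) / 2.0
        widths[chrom] = e - s
        rates[chrom] = sub["rate"].to_numpy(float)
        step = int(np.median(e - s))
    return RateProfile(
        positions=positions, rates=rates, widths=widths,
        grid_step=step, method=method,
    )


# ---------------------------------------------------------------------------
# hotspot sets
# ---------------------------------------------------------------------------

def write_hotspots_bed(hs: pd.DataFrame, path: str | Path) -> None:
    """BED6+ hotspot/coldspot records.

    Columns: chrom, start, end, name, score (peak_rate x 100, rounded),
    strand ".", then peak bp, mean_rate, chromatin class, population, kind,
    and full-precision peak_rate (so the set round-trips exactly).
    """
    with open(path, "w") as fh:
        for k, row in enumerate(hs.itertuples()):
            name = f"{row.kind}_{k:04d}"
            score = int(round(row.peak_rate * 100))
            fh.write(
                f"{row.chromosome}\t{row.start}\t{row.end}\t{name}\t{score}\t.\t"
                f"{row.peak}\t{row.mean_rate!r}\t{row.chromatin}\t"
                f"{row.population}\t{row.kind}\t{row.peak_rate!r}\n"
            )


def read_hotspots_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            rows.append({
                "chromosome": p[0], "start": int(p[1]), "end": int(p[2]),
                "peak": int(p[6]), "peak_rate": float(p[11]),
                "mean_rate": float(p[7]), "size": int(p[2]) - int(p[1]),
                "chromatin": p[8], "population": p[9], "kind": p[10],
            })
    if not rows:
        return empty_hotspot_set()
    return pd.DataFrame(rows, columns=HOTSPOT_COLUMNS)


# ---------------------------------------------------------------------------
# landscapes and truth
# ---------------------------------------------------------------------------

def read_landscape(path: str | Path) -> TrueLandscape:
    """TOML landscape spec -> TrueLandscape.

    Layout::

        [background_rate]
        euchromatic = 5.0
        heterochromatic = 0.3

        [[chromosome]]
        name = "chr1"
        length = 20000000

        [[chromatin]]
        chromosome = "chr1"
        start = 0
        end = 8000000
        class = "euchromatic"

        [[hotspot]]
        chromosome = "chr1"
        center = 4000000
        width = 200000
        peak_rate = 50.0
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    chrom_spec = [(c["name"], int(c["length"])) for c in cfg["chromosome"]]
    chromatin: dict[str, list[tuple[float, float, str]]] = {}
    for iv in cfg.get("chromatin", []):
        chromatin.setdefault(iv["chromosome"], []).append(
            (float(iv["start"]), float(iv["end"]), iv["class"])
        )
    hotspots = [
        HotspotSpec(h["chromosome"], float(h["center"]), float(h["width"]),
                    float(h["peak_rate"]))
        for h in cfg.get("hotspot", [])
    ]
    return make_landscape(
        chrom_spec=chrom_spec,
        chromatin_spec=chromatin or None,
        hotspot_spec=hotspots,
        background_rates={k: float(v) for k, v in cfg.get("background_rate", {}).items()} or None,
    )


def write_truth(truth: SimTruth, crossovers_path: str | Path, manifest_path: str | Path) -> None:
    truth.crossover_records.to_csv(crossovers_path, sep="\t", index=False)
    manifest = {
        "generation": truth.generation,
        "seed": truth.seed,
        "chromosomes": truth.landscape.chromosomes,
        "background_rate": truth.landscape.background_rate,
        "n_crossovers": int(len(truth.crossover_records)),
        "total_cM": {
            name: truth.landscape.total_cM(name)
            for name, _ in truth.landscape.chromosomes
        },
    }
    write_manifest(manifest, manifest_path)


def write_manifest(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
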