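"""Forward simulation of F_k-derived RIL populations by single seed descent.

The recombination landscape is piecewise constant in cM/Mbp: a per-chromatin
background with rectangular hotspot plateaus superimposed.  Crossover counts
per meiosis are Poisson with mean equal to the chromosome map length in
Morgans (no interference) and positions are drawn by inverse transform on the
exact cumulative map, so the simulator's truth is analytically known and
serves as the parameter-recovery oracle for every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from recmap.genotypes import GenotypeMatrix

EUCHROMATIC = "euchromatic"
HETEROCHROMATIC = "heterochromatic"


@dataclass(frozen=True)
class HotspotSpec:
    chromosome: str
    center: float  # bp
    width: float  # bp
    peak_rate: float  # cM/Mbp

    @property
    def start(self) -> float:
        return self.center - self.width / 2.0

    @property
    def end(self) -> float:
        return self.center + self.width / 2.0


@dataclass
class TrueLandscape:
    """Ground-truth recombination landscape.

    ``rate(chrom, x)`` is piecewise constant; ``map_cM(chrom, x)`` is its
    exact integral from the chromosome start (non-decreasing, cM), and
    ``inverse_map`` its (pseudo-)inverse used for crossover placement.
    """

    chromosomes: list[tuple[str, int]]
    background_rate: dict[str, float]
    chromatin_intervals: dict[str, list[tuple[float, float, str]]]
    hotspots: list[HotspotSpec]
    # per chromosome: breakpoints (bp), segment rate (cM/Mbp), cumulative cM
    _breaks: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _rates: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _cum: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def total_cM(self, chrom: str) -> float:
        return float(self._cum[chrom][-1])

    def rate(self, chrom: str, x) -> np.ndarray:
        """Local rate in cM/Mbp at physical position(s) x."""
        b, r = self._breaks[chrom], self._rates[chrom]
        idx = np.clip(np.searchsorted(b, x, side="right") - 1, 0, len(r) - 1)
        return r[idx]

    def map_cM(self, chrom: str, x) -> np.ndarray:
        """Cumulative genetic position (cM) at physical position(s) x."""
        return np.interp(x, self._breaks[chrom], self._cum[chrom])

    def inverse_map(self, chrom: str, c) -> np.ndarray:
        """Physical position at cumulative genetic position(s) c (cM)."""
        return np.interp(c, self._cum[chrom], self._breaks[chrom])

    def chromatin_class(self, chrom: str, x) -> np.ndarray:
        ivals = self.chromatin_intervals[chrom]
        starts = np.array([s for s, _, _ in ivals])
        classes = np.array([c for _, _, c in ivals])
        idx = np.clip(np.searchsorted(starts, x, side="right") - 1, 0, len(ivals) - 1)
        return classes[idx]


def make_landscape(
    chrom_spec: Sequence[tuple[str, int]],
    chromatin_spec: dict[str, list[tuple[float, float, str]]] | None = None,
    hotspot_spec: Iterable[HotspotSpec | tuple] = (),
    background_rates: dict[str, float] | None = None,
) -> TrueLandscape:
    """Build a piecewise-constant recombination landscape.

    The rate at x is the background rate of the chromatin class containing x;
    inside a hotspot interval it is the hotspot's plateau ``peak_rate``.
    Overlapping hotspots, or hotspots outside their chromosome, are rejected.
    """
    if background_rates is None:
        background_rates = {EUCHROMATIC: 4.0, HETEROCHROMATIC: 0.3}
    for cls, r in background_rates.items():
        if r < 0:
            raise ValueError(f"negative background rate for {cls!r}")
    chrom_spec = [(str(n), int(l)) for n, l in chrom_spec]
    lengths = dict(chrom_spec)
    for name, length in chrom_spec:
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length")

    if chromatin_spec is None:
        chromatin_spec = {n: [(0.0, float(l), EUCHROMATIC)] for n, l in chrom_spec}
    for name, length in chrom_spec:
        ivals = sorted(chromatin_spec.get(name, []))
        if not ivals:
            raise ValueError(f"no chromatin intervals for chromosome {name!r}")
        if ivals[0][0] != 0 or ivals[-1][1] != length:
            raise ValueError(f"chromatin intervals must cover chromosome {name!r}")
        for (s0, e0, _), (s1, _, _) in zip(ivals, ivals[1:]):
            if e0 != s1:
                raise ValueError(f"chromatin intervals must tile chromosome {name!r}")
        for s, e, cls in ivals:
            if e <= s:
                raise ValueError(f"empty chromatin interval on {name!r}")
            if cls not in background_rates:
                raise ValueError(f"no background rate for chromatin class {cls!r}")
        chromatin_spec[name] = ivals

    hotspots = []
    for h in hotspot_spec:
        if not isinstance(h, HotspotSpec):
            h = HotspotSpec(*h)
        if h.width <= 0:
            raise ValueError("hotspot width must be > 0")
        if h.peak_rate < 0:
            raise ValueError("hotspot peak rate must be >= 0")
        if h.chromosome not in lengths:
            raise ValueError(f"hotspot on unknown chromosome {h.chromosome!r}")
        if h.start < 0 or h.end > lengths[h.chromosome]:
            raise ValueError(f"hotspot {h} lies outside chromosome bounds")
        hotspots.append(h)
    for i, a in enumerate(hotspots):
        for b in hotspots[i + 1:]:
            if a.chromosome == b.chromosome and a.start < b.end and b.start < a.end:
                raise ValueError(f"overlapping hotspots: {a} and {b}")

    ls = TrueLandscape(
        chromosomes=chrom_spec,
        background_rate=dict(background_rates),
        chromatin_intervals={n: list(chromatin_spec[n]) for n, _ in chrom_spec},
        hotspots=hotspots,
    )
    for name, length in chrom_spec:
        cuts = {0.0, float(length)}
        cuts.update(s for s, _, _ in chromatin_spec[name])
        cuts.update(e for _, e, _ in chromatin_spec[name])
        for h in hotspots:
            if h.chromosome == name:
                cuts.update((h.start, h.end))
        breaks = np.array(sorted(cuts))
        mids = (breaks[:-1] + breaks[1:]) / 2.0
        rates = np.empty(len(mids))
        for k, m in enumerate(mids):
            rates[k] = background_rates[_class_at(chromatin_spec[name], m)]
        for h in hotspots:
            if h.chromosome == name:
                inside = (mids > h.start) & (mids < h.end)
                rates[inside] = h.peak_rate
        seg_cM = rates * np.diff(breaks) / 1e6
        ls._breaks[name] = breaks
        ls._rates[name] = rates
        ls._cum[name] = np.concatenate([[0.0], np.cumsum(seg_cM)])
    return ls


def _class_at(ivals: list[tuple[float, float, str]], x: float) -> str:
    for s, e, cls in ivals:
        if s <= x < e:
            return cls
    return ivals[-1][2]


# ---------------------------------------------------------------------------
# Haplotypes and meiosis
# ---------------------------------------------------------------------------

# A chromosome haplotype is a step function over bp: `breaks` (ascending,
# interior switch points) and `origins` (len(breaks)+1 founder labels 0/1).
Haplotype = dict[str, tuple[np.ndarray, np.ndarray]]


def founder_haplotype(landscape: TrueLandscape, origin: int) -> Haplotype:
    return {
        name: (np.empty(0), np.array([origin], dtype=np.int8))
        for name, _ in landscape.chromosomes
    }


def _origin_at(hap: tuple[np.ndarray, np.ndarray], pos) -> np.ndarray:
    breaks, origins = hap
    return origins[np.searchsorted(breaks, pos, side="right")]


def _mosaic(
    hap0: tuple[np.ndarray, np.ndarray],
    hap1: tuple[np.ndarray, np.ndarray],
    xovers: np.ndarray,
    start: int,
    length: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Splice two parental haplotypes, switching source at each crossover."""
    haps = (hap0, hap1)
    bounds = np.concatenate([[0.0], xovers, [length]])
    out_breaks: list[float] = []
    out_origins: list[int] = []
    for k in range(len(bounds) - 1):
        s, e = bounds[k], bounds[k + 1]
        if s >= e:
            continue
        breaks, origins = haps[(start + k) % 2]
        i0 = np.searchsorted(breaks, s, side="right")
        i1 = np.searchsorted(breaks, e, side="left")
        piece_starts = [s, *breaks[i0:i1]]
        piece_origins = list(origins[i0:i1 + 1])
        for ps, po in zip(piece_starts, piece_origins):
            if out_origins and po == out_origins[-1]:
                continue  # merge runs of the same founder
            if out_origins:
                out_breaks.append(float(ps))
            out_origins.append(int(po))
    return np.array(out_breaks), np.array(out_origins, dtype=np.int8)


def simulate_meiosis(
    parent_pair: tuple[Haplotype, Haplotype],
    landscape: TrueLandscape,
    rng: np.random.Generator,
) -> tuple[Haplotype, list[tuple[str, float]]]:
    """One meiosis: returns a gamete haplotype and its crossover positions.

    Crossover counts per chromosome are Poisson(map length in Morgans);
    positions come from inverse-transform sampling on the cumulative map.
    """
    hapA, hapB = parent_pair
    gamete: Haplotype = {}
    crossovers: list[tuple[str, float]] = []
    for name, length in landscape.chromosomes:
        total = landscape.total_cM(name)
        n = int(rng.poisson(total / 100.0)) if total > 0 else 0
        if n > 0:
            u = np.sort(rng.uniform(0.0, total, size=n))
            xovers = landscape.inverse_map(name, u)
        else:
            xovers = np.empty(0)
        start = int(rng.integers(2))
        gamete[name] = _mosaic(hapA[name], hapB[name], xovers, start, float(length))
        crossovers.extend((name, float(x)) for x in xovers)
    return gamete, crossovers


@dataclass
class SimTruth:
    """Ground truth for a simulated population."""

    landscape: TrueLandscape
    generation: int
    seed: int
    # rows: line index, generation, gamete index (0/1), chromosome, position
    crossover_records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["line", "generation", "gamete", "chromosome", "position"]
        )
    )


@dataclass(frozen=True)
class DistortionLocus:
    """Gamete-viability distortion at one locus.

    A gamete carrying an allele other than ``favored`` at (chromosome,
    position) survives with probability ``weight`` (rejected and redrawn
    otherwise).
    """

    chromosome: str
    position: float
    favored: int  # founder label 0 (A) or 1 (B)
    weight: float  # survival probability of the disfavored gamete

    def __post_init__(self):
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("distortion weight must be in [0, 1]")
        if self.favored not in (0, 1):
            raise ValueError("favored allele must be 0 (A) or 1 (B)")


def _draw_surviving_gamete(plant, landscape, rng, distortion, max_tries=1000):
    for _ in range(max_tries):
        gamete, xovers = simulate_meiosis(plant, landscape, rng)
        ok = True
        for d in distortion:
            allele = int(_origin_at(gamete[d.chromosome], d.position))
            if allele != d.favored and rng.uniform() > d.weight:
                ok = False
                break
        if ok:
            return gamete, xovers
    raise RuntimeError("no viable gamete drawn; distortion weights too extreme")


def simulate_ril_population(
    landscape: TrueLandscape,
    marker_positions: Sequence[tuple[str, str, int]],
    n_lines: int,
    final_generation: int = 5,
    missing_rate: float = 0.0,
    distortion_spec: Sequence[DistortionLocus] = (),
    rng: np.random.Generator | int | None = None,
    population_label: str = "sim",
) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate ``n_lines`` F_k-derived RILs by single seed descent.

    Each line descends from one F1 plant by ``final_generation - 1`` selfing
    rounds, keeping a single offspring (two gametes of one plant) per
    generation.  Genotypes are read off at ``marker_positions`` (triples of
    marker id, chromosome, bp); missing calls are injected i.i.d.

    Residual heterozygotes are retained: expected per-locus H frequency at
    F_k is 2^-(k-1).
    """
    if final_generation < 2:
        raise ValueError("final_generation must be >= 2")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    lengths = dict(landscape.chromosomes)
    markers = pd.DataFrame(marker_positions, columns=["id", "chromosome", "position"])
    markers["position"] = markers["position"].astype(int)
    for _, row in markers.iterrows():
        if row["chromosome"] not in lengths:
            raise ValueError(f"marker {row['id']!r} on unknown chromosome")
        if not 0 <= row["position"] < lengths[row["chromosome"]]:
            raise ValueError(f"marker {row['id']!r} outside chromosome bounds")
    markers = markers.sort_values(["chromosome", "position"], ignore_index=True)

    fA = founder_haplotype(landscape, 0)
    fB = founder_haplotype(landscape, 1)
    distortion = list(distortion_spec)

    by_chrom = {c: markers.index[markers["chromosome"] == c].to_numpy()
                for c in markers["chromosome"].unique()}
    pos_by_chrom = {c: markers.loc[by_chrom[c], "position"].to_numpy()
                    for c in by_chrom}

    calls = np.empty((len(markers), n_lines), dtype="<U1")
    records: list[tuple[int, int, int, str, float]] = []
    for li in range(n_lines):
        plant = (fA, fB)  # the F1
        for gen in range(2, final_generation + 1):
            g0, x0 = _draw_surviving_gamete(plant, landscape, rng, distortion)
            g1, x1 = _draw_surviving_gamete(plant, landscape, rng, distortion)
            records.extend((li, gen, 0, c, p) for c, p in x0)
            records.extend((li, gen, 1, c, p) for c, p in x1)
            plant = (g0, g1)
        for chrom, idx in by_chrom.items():
            pos = pos_by_chrom[chrom]
            a0 = _origin_at(plant[0][chrom], pos)
            a1 = _origin_at(plant[1][chrom], pos)
            col = np.where(a0 == a1, np.where(a0 == 0, "A", "B"), "H")
            calls[idx, li] = col
    if missing_rate > 0:
        calls[rng.uniform(size=calls.shape) < missing_rate] = "-"

    gm = GenotypeMatrix(
        markers=markers,
        lines=[f"{population_label}_L{li:05d}" for li in range(n_lines)],
        calls=calls,
        population_label=population_label,
    )
    truth = SimTruth(
        landscape=landscape,
        generation=final_generation,
        seed=-1 if seed is None else int(seed),
        crossover_records=pd.DataFrame(
            records, columns=["line", "generation", "gamete", "chromosome", "position"]
        ),
    )
    return gm, truth


def default_marker_grid(
    landscape: TrueLandscape, spacing_bp: int, prefix: str = "m"
) -> list[tuple[str, str, int]]:
    """Evenly spaced markers every ``spacing_bp`` along every chromosome."""
    out = []
    for name, length in landscape.chromosomes:
        positions = np.arange(spacing_bp // 2, length, spacing_bp, dtype=int)
        out.extend(
            (f"{prefix}_{name}_{k:05d}", name, int(p))
            for k, p in enumerate(positions)
        )
    return out
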