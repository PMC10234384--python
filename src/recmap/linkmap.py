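"""Per-chromosome genetic maps from two-point recombination fractions.

Marker order is fixed to physical (reference) order.  Adjacent-marker
recombinant fractions are corrected for generations of inbreeding and
converted to additive map distance with the Kosambi (default) or Haldane
mapping function, accumulated from 0 cM per chromosome.

Two RIL corrections are available.  ``correct_ril`` is the
Haldane-Waddington fixation limit, inverting R = 2r/(1+2r).  For finite
generations it under-corrects badly (at F5 and small r the observed
recombinant-homozygote fraction is ~1.48r, not 2r, so the F-infinity
inversion shrinks the map by ~26%); ``correct_ril_finite`` therefore inverts
the exact two-locus selfing Markov chain for the stated generation and is
the default used by ``build_map`` (scheme "F5-self").
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from recmap.genotypes import GenotypeMatrix

R_CAP = 0.4999


@dataclass
class GeneticMap:
    """Ordered markers with cumulative genetic position per chromosome.

    ``table`` columns: chromosome, marker, position (bp), cM.
    """

    table: pd.DataFrame
    mapping_function: str = "kosambi"
    ril_scheme: str = "F-inf-self"

    def __post_init__(self) -> None:
        required = {"chromosome", "marker", "position", "cM"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"genetic map needs columns {sorted(required)}")
        for chrom, sub in self.table.groupby("chromosome", sort=False):
            cm = sub["cM"].to_numpy()
            if len(cm) and (cm[0] != 0.0 or np.any(np.diff(cm) < 0) or not np.isfinite(cm).all()):
                raise ValueError(f"invalid cM column for chromosome {chrom!r}")

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom].reset_index(drop=True)

    def total_cM(self, chrom: str) -> float:
        return float(self.chromosome(chrom)["cM"].iloc[-1])


def two_point_R(calls_i: np.ndarray, calls_j: np.ndarray) -> tuple[float, int]:
    """Observed recombinant fraction between two markers' call vectors.

    Lines heterozygous or missing at either marker are excluded; R is the
    discordant fraction among lines homozygous at both markers, capped at
    0.4999 so downstream distances stay finite.
    """
    calls_i = np.asarray(calls_i)
    calls_j = np.asarray(calls_j)
    if calls_i.shape != calls_j.shape:
        raise ValueError("call vectors must have equal length")
    hom_i = (calls_i == "A") | (calls_i == "B")
    hom_j = (calls_j == "A") | (calls_j == "B")
    informative = hom_i & hom_j
    n = int(informative.sum())
    if n == 0:
        raise ValueError("no informative lines")
    discordant = int((calls_i[informative] != calls_j[informative]).sum())
    return min(discordant / n, R_CAP), n


def correct_ril(R: float) -> float:
    """Invert R = 2r/(1+2r): meiotic r from the observed RIL fraction."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or np.any(R >= 0.5):
        raise ValueError("R must lie in [0, 0.5)")
    out = R / (2.0 - 2.0 * R)
    return float(out) if out.ndim == 0 else out


def _selfing_chain_R(r: np.ndarray, generation: int) -> np.ndarray:
    """Exact recombinant-homozygote fraction at F_generation under selfing.

    Two-locus chain over unordered haplotype pairs; haplotypes are
    0=AB, 1=ab, 2=Ab, 3=aB.  Vectorized over r.
    """
    r = np.asarray(r, dtype=float)
    pairs = [(i, j) for i in range(4) for j in range(i, 4)]  # 10 states
    pair_index = {p: k for k, p in enumerate(pairs)}
    loci = {0: (0, 0), 1: (1, 1), 2: (0, 1), 3: (1, 0)}
    hap_of = {v: k for k, v in loci.items()}

    def gamete_dist(h1, h2):
        """4 x len(r) gamete probabilities for parent (h1, h2)."""
        g = np.zeros((4, r.size))
        a, b = loci[h1], loci[h2]
        for p1, p2, w in (
            (a, a, (1 - r) / 2), (b, b, (1 - r) / 2),
            (a, b, r / 2), (b, a, r / 2),
        ):
            g[hap_of[(p1[0], p2[1])]] += w
        return g

    state = np.zeros((10, r.size))
    state[pair_index[(0, 1)]] = 1.0  # F1 = AB/ab
    gametes = {p: gamete_dist(*p) for p in pairs}
    for _ in range(generation - 1):
        new = np.zeros_like(state)
        for p in pairs:
            g = gametes[p]
            w = state[pair_index[p]]
            for x in range(4):
                for y in range(x, 4):
                    mult = 1.0 if x == y else 2.0
                    new[pair_index[(x, y)]] += w * mult * g[x] * g[y]
        state = new
    hom = sum(state[pair_index[(h, h)]] for h in range(4))
    rec = state[pair_index[(2, 2)]] + state[pair_index[(3, 3)]]
    return rec / hom


@lru_cache(maxsize=8)
def _finite_correction_table(generation: int) -> tuple[np.ndarray, np.ndarray]:
    r_grid = np.linspace(0.0, 0.4999, 4000)
    return _selfing_chain_R(r_grid, generation), r_grid


def correct_ril_finite(R, generation: int = 5):
    """Meiotic r from the observed fraction R at a finite selfing generation.

    Inverts the exact chain by monotone interpolation; converges to
    :func:`correct_ril` as generation grows.
    """
    if generation < 2:
        raise ValueError("generation must be >= 2")
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or np.any(R >= 0.5):
        raise ValueError("R must lie in [0, 0.5)")
    R_grid, r_grid = _finite_correction_table(generation)
    out = np.interp(R, R_grid, r_grid)
    return float(out) if out.ndim == 0 else out


def map_distance(r: float, function: str = "kosambi") -> float:
    """Map distance (cM) for meiotic recombination fraction r."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("r must lie in [0, 0.5)")
    if function == "kosambi":
        out = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    elif function == "haldane":
        out = -50.0 * np.log(1.0 - 2.0 * r)
    else:
        raise ValueError(f"unknown mapping function {function!r}")
    return float(out) if out.ndim == 0 else out


def _ril_correction(ril_scheme: str):
    """Scheme string -> correction callable.  Accepts F-inf-self, F<k>-self, none."""
    if ril_scheme == "none":
        return lambda R: R
    if ril_scheme == "F-inf-self":
        return correct_ril
    m = re.fullmatch(r"F(\d+)-self", ril_scheme)
    if m:
        gen = int(m.group(1))
        return lambda R: correct_ril_finite(R, gen)
    raise ValueError(f"unknown RIL scheme {ril_scheme!r}")


def build_map(
    gm: GenotypeMatrix,
    mapping_function: str = "kosambi",
    ril_scheme: str = "F5-self",
) -> GeneticMap:
    """Accumulate adjacent-interval distances into a per-chromosome map.

    Intervals with no informative line pairs contribute 0 cM (warned).
    Single-marker chromosomes yield a single point at 0 cM (warned).
    """
    correct = _ril_correction(ril_scheme)
    rows = []
    for chrom in gm.chromosomes():
        idx = np.flatnonzero((gm.markers["chromosome"] == chrom).to_numpy())
        sub = gm.markers.iloc[idx]
        if len(idx) == 1:
            warnings.warn(f"chromosome {chrom!r} has a single marker; map is one point")
        cum = 0.0
        rows.append((chrom, sub["id"].iloc[0], int(sub["position"].iloc[0]), 0.0))
        for k in range(1, len(idx)):
            try:
                R, _ = two_point_R(gm.calls[idx[k - 1]], gm.calls[idx[k]])
                d = map_distance(correct(R), mapping_function)
            except ValueError:
                warnings.warn(
                    f"no informative lines between {sub['id'].iloc[k-1]!r} and "
                    f"{sub['id'].iloc[k]!r}; interval set to 0 cM"
                )
                d = 0.0
            cum += d
            rows.append((chrom, sub["id"].iloc[k], int(sub["position"].iloc[k]), cum))
    table = pd.DataFrame(rows, columns=["chromosome", "marker", "position", "cM"])
    return GeneticMap(table=table, mapping_function=mapping_function, ril_scheme=ril_scheme)
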