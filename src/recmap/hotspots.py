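"""Hotspot and coldspot calling on recombination-rate profiles.

A hotspot is a sliding-window local peak of the rate profile: a grid point
whose rate strictly exceeds every rate within +/- `window` grid points and is
at least `min_fold` times the background (per-chromosome, per-chromatin-class
median rate).  Interval boundaries extend outward from the peak until the
rate falls below max(background, boundary_frac * peak rate).  Size outliers
are removed per chromatin class with the Tukey fence (> Q3 + 1.5 IQR, type-7
quantiles).  All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from recmap.marey import RateProfile

HOTSPOT_COLUMNS = [
    "chromosome", "start", "end", "peak", "peak_rate", "mean_rate",
    "size", "chromatin", "population", "kind",
]


def empty_hotspot_set() -> pd.DataFrame:
    return pd.DataFrame(columns=HOTSPOT_COLUMNS)


@dataclass
class ChromatinMap:
    """Per-chromosome chromatin-state intervals (0-based half-open).

    Intervals must be sorted, non-overlapping and tile each chromosome.
    """

    intervals: dict[str, list[tuple[int, int, str]]]

    def __post_init__(self) -> None:
        for chrom, ivals in self.intervals.items():
            ivals = sorted(ivals)
            for (s0, e0, _), (s1, _, _) in zip(ivals, ivals[1:]):
                if e0 > s1:
                    raise ValueError(f"overlapping chromatin intervals on {chrom!r}")
            for s, e, _ in ivals:
                if e <= s:
                    raise ValueError(f"empty chromatin interval on {chrom!r}")
            self.intervals[chrom] = ivals

    def class_at(self, chrom: str, pos) -> np.ndarray:
        """Chromatin class at position(s); half-open interval convention."""
        ivals = self.intervals.get(chrom)
        if not ivals:
            return np.full(np.shape(pos) or (), "euchromatic", dtype=object)
        starts = np.array([s for s, _, _ in ivals], dtype=float)
        classes = np.array([c for _, _, c in ivals], dtype=object)
        idx = np.clip(np.searchsorted(starts, pos, side="right") - 1, 0, len(ivals) - 1)
        return classes[idx]


def _class_background(rates: np.ndarray, classes: np.ndarray) -> dict[str, float]:
    """Per-chromatin-class median rate (the peak-calling background)."""
    return {
        cls: float(np.median(rates[classes == cls]))
        for cls in np.unique(classes)
    }


def call_hotspots(
    profile: RateProfile,
    chromatin_map: ChromatinMap | None = None,
    window: int = 5,
    min_fold: float = 2.0,
    boundary_frac: float = 0.5,
    population: str = "",
) -> pd.DataFrame:
    """Call hotspots as sliding-window local maxima of the rate profile.

    Returns a BED-like DataFrame (columns ``HOTSPOT_COLUMNS``); a flat
    profile yields an empty set.
    """
    if window < 1:
        raise ValueError("window must be >= 1 grid point")
    records = []
    for chrom in profile.chromosomes():
        pos = profile.positions[chrom]
        rate = profile.rates[chrom]
        width = profile.widths[chrom]
        n = len(pos)
        if n < 2 * window + 1:
            continue
        if chromatin_map is not None:
            classes = chromatin_map.class_at(chrom, pos)
        else:
            classes = np.full(n, "euchromatic", dtype=object)
        background = _class_background(rate, classes)

        candidates = []
        for i in range(n):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            neigh = np.concatenate([rate[lo:i], rate[i + 1:hi]])
            if len(neigh) == 0 or not np.all(rate[i] > neigh):
                continue
            bg = background[classes[i]]
            if rate[i] <= 0 or rate[i] < min_fold * bg:
                continue
            thr = max(bg, boundary_frac * rate[i])
            j0 = i
            while j0 > 0 and rate[j0 - 1] >= thr:
                j0 -= 1
            j1 = i
            while j1 < n - 1 and rate[j1 + 1] >= thr:
                j1 += 1
            start = pos[j0] - width[j0] / 2.0
            end = pos[j1] + width[j1] / 2.0
            candidates.append((start, end, i, j0, j1))

        # merge overlapping candidate intervals, keeping the higher peak
        candidates.sort()
        merged: list[list] = []
        for start, end, i, j0, j1 in candidates:
            if merged and start < merged[-1][1]:
                m = merged[-1]
                m[1] = max(m[1], end)
                m[4] = max(m[4], j1)
                if rate[i] > rate[m[2]]:
                    m[2] = i
            else:
                merged.append([start, end, i, j0, j1])
        for start, end, i, j0, j1 in merged:
            records.append({
                "chromosome": chrom,
                "start": int(round(start)),
                "end": int(round(end)),
                "peak": int(round(pos[i])),
                "peak_rate": float(rate[i]),
                "mean_rate": float(np.average(rate[j0:j1 + 1], weights=width[j0:j1 + 1])),
                "size": int(round(end)) - int(round(start)),
                "chromatin": classes[i],
                "population": population,
                "kind": "hotspot",
            })
    if not records:
        return empty_hotspot_set()
    return pd.DataFrame(records, columns=HOTSPOT_COLUMNS)


def tukey_filter(hs: pd.DataFrame, by: str = "chromatin") -> pd.DataFrame:
    """Drop size outliers above Q3 + 1.5 IQR within each ``by`` group.

    Quantiles are linear-interpolation ("type 7").  Groups with fewer than 4
    records are left unfiltered.
    """
    if len(hs) == 0:
        return hs.copy()
    keep = np.ones(len(hs), dtype=bool)
    sizes = hs["size"].to_numpy(float)
    groups = hs[by].to_numpy() if by else np.zeros(len(hs))
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 4:
            continue
        q1, q3 = np.quantile(sizes[idx], [0.25, 0.75])  # numpy default = type 7
        fence = q3 + 1.5 * (q3 - q1)
        keep[idx[sizes[idx] > fence]] = False
    return hs.loc[keep].reset_index(drop=True)


def call_coldspots(
    profile: RateProfile,
    chromatin_map: ChromatinMap | None = None,
    max_frac: float = 0.2,
    min_len_bp: int = 500_000,
    population: str = "",
) -> pd.DataFrame:
    """Maximal runs of grid points with rate < max_frac x class background."""
    if not 0.0 < max_frac < 1.0:
        raise ValueError("max_frac must be in (0, 1)")
    records = []
    for chrom in profile.chromosomes():
        pos = profile.positions[chrom]
        rate = profile.rates[chrom]
        width = profile.widths[chrom]
        n = len(pos)
        if n == 0:
            continue
        if chromatin_map is not None:
            classes = chromatin_map.class_at(chrom, pos)
        else:
            classes = np.full(n, "euchromatic", dtype=object)
        background = _class_background(rate, classes)
        thr = np.array([max_frac * background[c] for c in classes])
        low = rate < thr
        i = 0
        while i < n:
            if not low[i]:
                i += 1
                continue
            j = i
            while j < n - 1 and low[j + 1]:
                j += 1
            start = pos[i] - width[i] / 2.0
            end = pos[j] + width[j] / 2.0
            if end - start >= min_len_bp:
                imin = i + int(np.argmin(rate[i:j + 1]))
                records.append({
                    "chromosome": chrom,
                    "start": int(round(start)),
                    "end": int(round(end)),
                    "peak": int(round(pos[imin])),
                    "peak_rate": float(rate[imin]),
                    "mean_rate": float(np.average(rate[i:j + 1], weights=width[i:j + 1])),
                    "size": int(round(end)) - int(round(start)),
                    "chromatin": classes[imin],
                    "population": population,
                    "kind": "coldspot",
                })
            i = j + 1
    if not records:
        return empty_hotspot_set()
    return pd.DataFrame(records, columns=HOTSPOT_COLUMNS)


def classify_chromatin(hs: pd.DataFrame, chromatin_map: ChromatinMap) -> pd.DataFrame:
    """Assign chromatin class by the interval containing each record's peak."""
    out = hs.copy()
    if len(out):
        out["chromatin"] = [
            str(chromatin_map.class_at(row.chromosome, row.peak))
            for row in out.itertuples()
        ]
    return out


def compare_hotspots(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap_bp: int = 1
) -> tuple[pd.DataFrame, int, float, float]:
    """Shared hotspots between two sets by interval overlap.

    Returns (shared-pair table, number of a-records with a partner,
    fraction of a shared, fraction of b shared).  Intervals are half-open;
    a pair is shared iff same-chromosome overlap >= ``min_overlap_bp``.
    """
    pairs = []
    a_hit = np.zeros(len(a), dtype=bool)
    b_hit = np.zeros(len(b), dtype=bool)
    a_idx = a.reset_index(drop=True)
    b_idx = b.reset_index(drop=True)
    for i, ra in a_idx.iterrows():
        same = b_idx[b_idx["chromosome"] == ra["chromosome"]]
        for j, rb in same.iterrows():
            overlap = min(ra["end"], rb["end"]) - max(ra["start"], rb["start"])
            if overlap >= min_overlap_bp:
                a_hit[i] = True
                b_hit[j] = True
                pairs.append({
                    "chromosome": ra["chromosome"],
                    "a_start": ra["start"], "a_end": ra["end"],
                    "b_start": rb["start"], "b_end": rb["end"],
                    "overlap_bp": int(overlap),
                })
    shared = pd.DataFrame(
        pairs,
        columns=["chromosome", "a_start", "a_end", "b_start", "b_end", "overlap_bp"],
    )
    n_shared = int(a_hit.sum())
    frac_a = n_shared / len(a) if len(a) else 0.0
    frac_b = int(b_hit.sum()) / len(b) if len(b) else 0.0
    return shared, n_shared, frac_a, frac_b


def summarize(hs: pd.DataFrame) -> pd.DataFrame:
    """Count / size / intensity summary per (population, chromatin) plus totals."""
    rows = []

    def _row(label_pop, label_cls, sub):
        return {
            "population": label_pop,
            "chromatin": label_cls,
            "count": len(sub),
            "mean_size_bp": float(sub["size"].mean()) if len(sub) else np.nan,
            "median_size_bp": float(sub["size"].median()) if len(sub) else np.nan,
            "min_size_bp": float(sub["size"].min()) if len(sub) else np.nan,
            "max_size_bp": float(sub["size"].max()) if len(sub) else np.nan,
            "mean_peak_rate": float(sub["peak_rate"].mean()) if len(sub) else np.nan,
            "mean_intensity": float(sub["mean_rate"].mean()) if len(sub) else np.nan,
        }

    for (pop, cls), sub in hs.groupby(["population", "chromatin"], sort=True):
        rows.append(_row(pop, cls, sub))
    for pop, sub in hs.groupby("population", sort=True):
        rows.append(_row(pop, "all", sub))
    rows.append(_row("all", "all", hs))
    return pd.DataFrame(rows)
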