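"""Marey maps and local recombination-rate profiles.

A Marey map plots cumulative genetic position (cM) against physical position
(bp); its derivative is the local recombination rate.  Two estimators are
provided: a cubic spline (interpolating, or smoothing with generalized
cross-validation) evaluated on a uniform grid, and a fixed-window ratio of
genetic to physical distance ("frequency metric").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.optimize import isotonic_regression

from recmap.linkmap import GeneticMap

MBP = 1e6


@dataclass
class MareyMap:
    """Per-chromosome (bp, cM) point sets, sorted by bp."""

    points: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (bp, cm) in self.points.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.shape != cm.shape:
                raise ValueError(f"bp/cM length mismatch on {chrom!r}")
            order = np.argsort(bp, kind="stable")
            clean[chrom] = (bp[order], cm[order])
        self.points = clean

    @classmethod
    def from_genetic_map(cls, gmap: GeneticMap) -> "MareyMap":
        pts = {}
        for chrom in gmap.chromosomes():
            sub = gmap.chromosome(chrom)
            pts[chrom] = (sub["position"].to_numpy(float), sub["cM"].to_numpy(float))
        return cls(points=pts)

    def is_monotone(self, chrom: str) -> bool:
        _, cm = self.points[chrom]
        return bool(np.all(np.diff(cm) >= 0))


def isotonize(marey: MareyMap) -> MareyMap:
    """Replace each chromosome's cM by its least-squares non-decreasing fit.

    Already-monotone chromosomes are returned unchanged (exact copy).
    """
    out = {}
    for chrom, (bp, cm) in marey.points.items():
        if np.all(np.diff(cm) >= 0):
            out[chrom] = (bp.copy(), cm.copy())
        else:
            out[chrom] = (bp.copy(), isotonic_regression(cm).x)
    return MareyMap(points=out)


@dataclass
class SplineModel:
    """Fitted per-chromosome cubic splines, evaluable with first derivative.

    x is internally in Mbp so the derivative is directly cM/Mbp.
    """

    splines: dict[str, object]
    span: dict[str, tuple[float, float]]  # fitted bp range per chromosome
    smoothing: str = "gcv"

    def __call__(self, chrom: str, bp) -> np.ndarray:
        return np.asarray(self.splines[chrom](np.asarray(bp, float) / MBP))

    def derivative(self, chrom: str, bp) -> np.ndarray:
        """d(cM)/d(Mbp) at physical position(s) bp — i.e. cM/Mbp."""
        return np.asarray(self.splines[chrom].derivative()(np.asarray(bp, float) / MBP))


def fit_spline(marey: MareyMap, smoothing: str | float = "gcv") -> SplineModel:
    """Fit a cubic spline per chromosome.

    smoothing="interpolating" passes through every point (not-a-knot cubic
    interpolant); "gcv" is a smoothing spline with the penalty chosen by
    generalized cross-validation; a float is an explicit penalty lambda.
    Duplicate physical positions are averaged before fitting.
    """
    splines: dict[str, object] = {}
    span: dict[str, tuple[float, float]] = {}
    for chrom, (bp, cm) in marey.points.items():
        x, inv = np.unique(bp, return_inverse=True)
        y = np.zeros_like(x)
        counts = np.bincount(inv)
        np.add.at(y, inv, cm)
        y = y / counts
        if len(x) < 4:
            raise ValueError(f"insufficient markers on {chrom!r} (need >= 4)")
        xm = x / MBP
        if smoothing == "interpolating":
            splines[chrom] = CubicSpline(xm, y)
        elif smoothing == "gcv":
            splines[chrom] = make_smoothing_spline(xm, y)
        else:
            splines[chrom] = make_smoothing_spline(xm, y, lam=float(smoothing))
        span[chrom] = (float(x[0]), float(x[-1]))
    return SplineModel(splines=splines, span=span, smoothing=str(smoothing))


@dataclass
class RateProfile:
    """Local recombination rate on per-chromosome position grids.

    positions are interval midpoints (bp); ``widths`` are the interval
    lengths so that sum(rate * width / 1e6) recovers map length. For the
    spline estimator the grid is uniform with width == grid_step.
    """

    positions: dict[str, np.ndarray]
    rates: dict[str, np.ndarray]  # cM/Mbp, >= 0
    widths: dict[str, np.ndarray]
    grid_step: int
    method: str
    smoothing: str = ""
    clamped_fraction: dict[str, float] = field(default_factory=dict)

    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def integral_cM(self, chrom: str) -> float:
        return float(np.sum(self.rates[chrom] * self.widths[chrom]) / MBP)


def rate_profile(spline: SplineModel, grid_step: int = 10_000) -> RateProfile:
    """Evaluate the spline derivative on a uniform grid, clamped at 0.

    The grid covers the fitted marker span of each chromosome; the fraction
    of grid points clamped (negative derivative) is recorded as a
    fit-quality diagnostic.  After clamping, rates are rescaled so the track
    integrates to the spline's own map length (clamping alone would
    over-count by the removed negative mass).
    """
    positions, rates, widths, clamped = {}, {}, {}, {}
    for chrom, (lo, hi) in spline.span.items():
        edges = np.arange(lo, hi, grid_step, dtype=float)
        edges = np.append(edges, hi)
        mids = (edges[:-1] + edges[1:]) / 2.0
        d = spline.derivative(chrom, mids)
        clamped[chrom] = float((d < 0).mean()) if len(d) else 0.0
        r = np.maximum(d, 0.0)
        total = float(spline(chrom, hi) - spline(chrom, lo))
        integral = float(np.sum(r * np.diff(edges)) / MBP)
        if integral > 0 and total > 0:
            r = r * (total / integral)
        rates[chrom] = r
        positions[chrom] = mids
        widths[chrom] = np.diff(edges)
    return RateProfile(
        positions=positions,
        rates=rates,
        widths=widths,
        grid_step=grid_step,
        method="spline",
        smoothing=spline.smoothing,
        clamped_fraction=clamped,
    )


def window_rate(gmap: GeneticMap, window_bp: int) -> RateProfile:
    """Fixed-window genetic/physical distance ratio ("frequency metric").

    Windows tile each chromosome's marker span; the Marey map is linearly
    interpolated at window edges, so sum(rate x width) telescopes exactly to
    the chromosome map length.  Rates are reported at window midpoints.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    marey = MareyMap.from_genetic_map(gmap)
    positions, rates, widths = {}, {}, {}
    for chrom, (bp, cm) in marey.points.items():
        lo, hi = bp[0], bp[-1]
        edges = np.arange(lo, hi, window_bp, dtype=float)
        edges = np.append(edges, hi)
        if len(edges) < 2:  # window larger than the chromosome span
            edges = np.array([lo, hi], dtype=float)
        cm_at = np.interp(edges, bp, cm)
        w = np.diff(edges)
        positions[chrom] = (edges[:-1] + edges[1:]) / 2.0
        rates[chrom] = np.diff(cm_at) / (w / MBP)
        widths[chrom] = w
    return RateProfile(
        positions=positions,
        rates=rates,
        widths=widths,
        grid_step=window_bp,
        method="window",
    )
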