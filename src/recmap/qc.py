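"""Marker quality control: missingness, segregation distortion, duplicate collapse.

Filters are applied in that order; the report partitions the input markers so
``n_input = n_retained + n_removed_missing + n_removed_distortion +
n_collapsed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from recmap.genotypes import GenotypeMatrix


@dataclass
class QCReport:
    n_input: int = 0
    n_removed_missing: int = 0
    n_removed_distortion: int = 0
    n_collapsed: int = 0
    n_retained: int = 0
    alpha: float = 0.01
    max_missing: float = 0.10
    reasons: dict[str, str] = field(default_factory=dict)
    bins: dict[str, list[str]] = field(default_factory=dict)

    def check(self) -> None:
        parts = (self.n_retained + self.n_removed_missing
                 + self.n_removed_distortion + self.n_collapsed)
        if parts != self.n_input:
            raise AssertionError("QC report does not partition the input")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_missing": self.n_removed_missing,
            "n_removed_distortion": self.n_removed_distortion,
            "n_collapsed": self.n_collapsed,
            "n_retained": self.n_retained,
            "alpha": self.alpha,
            "max_missing": self.max_missing,
            "reasons": self.reasons,
            "bins": self.bins,
        }


def filter_missing(
    gm: GenotypeMatrix, max_missing: float = 0.10, report: QCReport | None = None
) -> GenotypeMatrix:
    """Drop markers whose missing fraction is strictly greater than ``max_missing``."""
    if not 0.0 <= max_missing < 1.0:
        raise ValueError("max_missing must be in [0, 1)")
    if gm.n_markers == 0:
        raise ValueError("empty genotype matrix")
    frac = gm.missing_fraction()
    keep = frac <= max_missing
    if report is not None:
        report.max_missing = max_missing
        report.n_removed_missing += int((~keep).sum())
        for mid in gm.markers.loc[~keep, "id"]:
            report.reasons[mid] = "missing"
    return gm.subset_markers(keep)


def distortion_pvalues(gm: GenotypeMatrix, df: int = 1) -> np.ndarray:
    """Per-marker segregation-distortion chi-square P-values.

    df=1 (default): homozygote counts A vs B against 1:1, heterozygotes and
    missing excluded.  df=2: AA:H:BB against the F5 expectation
    0.46875 : 0.0625 : 0.46875 over non-missing calls.
    Markers with fewer than 2 informative calls get P = nan.
    """
    nA = (gm.calls == "A").sum(axis=1).astype(float)
    nB = (gm.calls == "B").sum(axis=1).astype(float)
    if df == 1:
        n = nA + nB
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = (nA - n / 2) ** 2 / (n / 2) + (nB - n / 2) ** 2 / (n / 2)
        p = stats.chi2.sf(chi2, df=1)
        p[n < 2] = np.nan
        return p
    if df == 2:
        nH = (gm.calls == "H").sum(axis=1).astype(float)
        n = nA + nB + nH
        expect = np.array([0.46875, 0.0625, 0.46875])
        obs = np.stack([nA, nH, nB], axis=1)
        exp = n[:, None] * expect[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = ((obs - exp) ** 2 / exp).sum(axis=1)
        p = stats.chi2.sf(chi2, df=2)
        p[n < 2] = np.nan
        return p
    raise ValueError("df must be 1 or 2")


def filter_segregation(
    gm: GenotypeMatrix,
    alpha: float = 0.01,
    df: int = 1,
    report: QCReport | None = None,
) -> GenotypeMatrix:
    """Drop markers with significant segregation distortion (P < alpha).

    Markers with fewer than 2 informative calls are removed with reason
    "uninformative".
    """
    p = distortion_pvalues(gm, df=df)
    uninformative = np.isnan(p)
    distorted = ~uninformative & (p < alpha)
    keep = ~(uninformative | distorted)
    if report is not None:
        report.alpha = alpha
        report.n_removed_distortion += int((~keep).sum())
        for mid in gm.markers.loc[distorted, "id"]:
            report.reasons[mid] = "distortion"
        for mid in gm.markers.loc[uninformative, "id"]:
            report.reasons[mid] = "uninformative"
    return gm.subset_markers(keep)


def collapse_identical(
    gm: GenotypeMatrix, report: QCReport | None = None
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Collapse markers with byte-identical call vectors (missing included).

    The physically first marker of each group (smallest chromosome/position,
    i.e. the first in matrix order) is retained; ``bins`` maps each retained
    id to every id it absorbed (including itself for multi-member groups).
    """
    seen: dict[bytes, int] = {}
    keep_idx: list[int] = []
    bins: dict[str, list[str]] = {}
    ids = gm.markers["id"].to_numpy()
    for i in range(gm.n_markers):
        key = gm.calls[i].tobytes()
        if key in seen:
            rep = ids[seen[key]]
            bins.setdefault(rep, [rep]).append(ids[i])
        else:
            seen[key] = i
            keep_idx.append(i)
    if report is not None:
        n_absorbed = sum(len(v) - 1 for v in bins.values())
        report.n_collapsed += n_absorbed
        for rep, members in bins.items():
            for mid in members[1:]:
                report.reasons[mid] = f"collapsed_into:{rep}"
        report.bins.update(bins)
    return gm.subset_markers(np.array(keep_idx, dtype=int)), bins


def run_qc(
    gm: GenotypeMatrix,
    max_missing: float = 0.10,
    alpha: float = 0.01,
    df: int = 1,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC chain: missingness -> segregation distortion -> collapse."""
    report = QCReport(n_input=gm.n_markers, alpha=alpha, max_missing=max_missing)
    gm = filter_missing(gm, max_missing=max_missing, report=report)
    gm = filter_segregation(gm, alpha=alpha, df=df, report=report)
    gm, _ = collapse_identical(gm, report=report)
    report.n_retained = gm.n_markers
    report.check()
    return gm, report
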