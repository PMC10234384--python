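"""Genomic-feature association for hotspots and coldspots.

Hotspot peaks are annotated with gene-region categories from a GFF3; the
genome is tiled into fixed windows labelled hotspot / coldspot / background,
feature coverage is computed per window, and association is tested by
binomial logistic regression (IRLS) with a Wald test on the covariate —
labelled "wald_t" since with window-scale sample sizes z and t coincide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# gene-region categories in precedence order; "intergenic" completes the
# partition of any hotspot set
GENE_CATEGORIES = ("5'UTR/CDS", "3'UTR/CDS", "5'UTR", "3'UTR", "CDS", "intron")


def _overlapping(features: pd.DataFrame, chrom: str, pos: int) -> pd.DataFrame:
    sub = features[features["chromosome"] == chrom]
    return sub[(sub["start"] <= pos) & (pos < sub["end"])]


def annotate_gene_region(hs: pd.DataFrame, gff3: pd.DataFrame) -> pd.Series:
    """Gene-region category of each hotspot's peak position.

    ``gff3`` is the internal 0-based half-open feature table from
    :func:`recmap.io.read_gff3` (columns chromosome, start, end, type).
    Composite UTR/CDS labels take precedence, then UTRs, then CDS, then
    intron (inside a gene but in no exon), else intergenic.
    """
    categories = []
    for row in hs.itertuples():
        hits = _overlapping(gff3, row.chromosome, int(row.peak))
        types = set(hits["type"])
        in_5utr = "five_prime_UTR" in types
        in_3utr = "three_prime_UTR" in types
        in_cds = "CDS" in types
        if in_5utr and in_cds:
            cat = "5'UTR/CDS"
        elif in_3utr and in_cds:
            cat = "3'UTR/CDS"
        elif in_5utr:
            cat = "5'UTR"
        elif in_3utr:
            cat = "3'UTR"
        elif in_cds:
            cat = "CDS"
        elif "gene" in types or "mRNA" in types:
            cat = "intron" if "exon" not in types else "exon_other"
        else:
            cat = "intergenic"
        categories.append(cat)
    return pd.Series(categories, index=hs.index, name="gene_region")


def make_feature_table(
    hs: pd.DataFrame,
    coldspots: pd.DataFrame,
    features: pd.DataFrame,
    genome: list[tuple[str, int]],
    window_bp: int = 100_000,
    feature_column: str = "feature",
) -> pd.DataFrame:
    """Tile the genome into windows with status labels and feature coverage.

    ``features`` columns: chromosome, start, end, plus ``feature_column``
    naming the feature class.  Status is hotspot if the window overlaps any
    hotspot interval (hotspot takes precedence over coldspot), coldspot
    likewise, else background.  Coverage is intersection bp / window bp.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    rows = []
    for chrom, length in genome:
        edges = np.arange(0, length, window_bp, dtype=int)
        for s in edges:
            rows.append((chrom, int(s), int(min(s + window_bp, length))))
    table = pd.DataFrame(rows, columns=["chromosome", "start", "end"])
    table["status"] = "background"

    def _mark(spots: pd.DataFrame, label: str):
        for row in spots.itertuples():
            m = (
                (table["chromosome"] == row.chromosome)
                & (table["start"] < row.end)
                & (row.start < table["end"])
            )
            table.loc[m, "status"] = label

    _mark(coldspots, "coldspot")
    _mark(hs, "hotspot")  # hotspot precedence

    classes = sorted(set(features[feature_column])) if len(features) else []
    for cls in classes:
        cov = np.zeros(len(table))
        sub = features[features[feature_column] == cls]
        starts = table["start"].to_numpy()
        ends = table["end"].to_numpy()
        chroms = table["chromosome"].to_numpy()
        for row in sub.itertuples():
            m = np.flatnonzero(
                (chroms == row.chromosome) & (starts < row.end) & (row.start < ends)
            )
            cov[m] += (
                np.minimum(ends[m], row.end) - np.maximum(starts[m], row.start)
            )
        table[cls] = cov / (ends - starts)
    return table


@dataclass
class AssocResult:
    feature: str
    contrast: str
    beta: float
    se: float
    statistic: float
    p: float
    n: int
    converged: bool = True
    flag: str = ""

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _irls_logistic(x: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50):
    """Two-parameter logistic fit by IRLS; returns (beta, cov, converged)."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    dev_old = np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X, XtW @ z)
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))
        if abs(dev - dev_old) < tol:
            converged = True
            break
        dev_old = dev
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov, converged


def _separated(x: np.ndarray, y: np.ndarray) -> bool:
    """Perfect (monotone) separation of a scalar covariate."""
    x1, x0 = x[y == 1], x[y == 0]
    return bool(x1.min() > x0.max() or x1.max() < x0.min())


def logistic_assoc(
    feature_table: pd.DataFrame,
    feature: str,
    contrast: str = "hotspot",
    min_group: int = 10,
) -> AssocResult:
    """Binomial logistic regression of window status on one feature covariate.

    ``contrast`` is "hotspot" (hotspot vs rest) or "coldspot" (coldspot vs
    rest).  Reports the covariate slope (log-odds per unit), its Wald
    statistic and a two-sided normal-reference P value.
    """
    if contrast not in ("hotspot", "coldspot"):
        raise ValueError("contrast must be 'hotspot' or 'coldspot'")
    x = feature_table[feature].to_numpy(float)
    y = (feature_table["status"] == contrast).to_numpy().astype(float)
    n1 = int(y.sum())
    if min(n1, len(y) - n1) < min_group:
        raise ValueError(
            f"need >= {min_group} windows in each status group (got {n1} vs {len(y) - n1})"
        )
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {feature!r} is constant")
    if _separated(x, y):
        return AssocResult(
            feature=feature, contrast=contrast, beta=np.nan, se=np.nan,
            statistic=np.nan, p=np.nan, n=len(y), converged=False,
            flag="separation",
        )
    beta, cov, converged = _irls_logistic(x, y)
    se = float(np.sqrt(cov[1, 1]))
    stat = float(beta[1] / se)
    p = float(2.0 * stats.norm.sf(abs(stat)))
    if not converged:
        warnings.warn(f"IRLS did not converge for feature {feature!r}")
    return AssocResult(
        feature=feature, contrast=contrast, beta=float(beta[1]), se=se,
        statistic=stat, p=p, n=len(y), converged=converged,
    )


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted P values (optional; raw P is the default report)."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def motif_intensity_test(
    hs: pd.DataFrame, motif_presence: np.ndarray
) -> tuple[float, float, float]:
    """Welch t-test of hotspot intensity with vs without a motif.

    Returns (mean_with, mean_without, P).  Degenerate identical groups give
    P = 1.
    """
    presence = np.asarray(motif_presence, bool)
    if len(presence) != len(hs):
        raise ValueError("presence vector length must match hotspot set")
    with_m = hs.loc[presence, "mean_rate"].to_numpy(float)
    without = hs.loc[~presence, "mean_rate"].to_numpy(float)
    mean_w = float(with_m.mean()) if len(with_m) else np.nan
    mean_wo = float(without.mean()) if len(without) else np.nan
    if len(with_m) < 2 or len(without) < 2:
        return mean_w, mean_wo, np.nan
    if np.ptp(with_m) == 0 and np.ptp(without) == 0 and mean_w == mean_wo:
        return mean_w, mean_wo, 1.0
    t, p = stats.ttest_ind(with_m, without, equal_var=False)
    return mean_w, mean_wo, float(p)
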