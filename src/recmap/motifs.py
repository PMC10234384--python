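"""Motif scanning in hotspot flank sequences with a permutation background.

Two fixed motif classes are supported: homopolymer runs (e.g. poly-A,
minimum run length) and IUPAC consensus patterns with a mismatch budget
(N in the pattern matches any base; N in the sequence matches nothing).
Enrichment relative to length- and chromatin-matched background windows is
assessed with a label-permutation test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """A motif to scan: either a homopolymer run or an IUPAC consensus."""

    name: str
    pattern: str = ""  # IUPAC consensus; empty for run specs
    run_base: str = ""  # e.g. "A" for a poly-A run spec
    min_run: int = 8
    max_mismatches: int = 0
    both_strands: bool = True

    def __post_init__(self):
        if not self.pattern and not self.run_base:
            raise ValueError("motif needs a pattern or a run base")
        if self.pattern and self.max_mismatches >= len(self.pattern):
            raise ValueError("max_mismatches must be < pattern length")


POLY_A = MotifSpec(name="poly_A", run_base="A", min_run=8, both_strands=True)
CCN_LIKE = MotifSpec(
    name="CCN_like",
    pattern="CNCCNCCACAACCAANNCANNA",
    max_mismatches=4,
    both_strands=True,
)


@dataclass
class MotifHits:
    """Scan result: per-sequence hit lists and per-sequence presence."""

    spec: MotifSpec
    hits: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)

    def presence(self, order: list[str] | None = None) -> np.ndarray:
        keys = order if order is not None else list(self.hits)
        return np.array([len(self.hits[k]) > 0 for k in keys], dtype=bool)

    def n_hits(self, seq_id: str) -> int:
        return len(self.hits[seq_id])


def extract_flanks(
    hs: pd.DataFrame,
    fasta_path: str,
    upstream_bp: int = 200,
    both_flanks: bool = False,
) -> dict[str, str]:
    """Hotspot sequences including ``upstream_bp`` of upstream flank.

    Returns {hotspot id: uppercase sequence} where the id is
    "chrom:start-end".  The extracted interval is
    [max(0, start - upstream_bp), end), extended past ``end`` as well when
    ``both_flanks`` is set; clipped at chromosome bounds.
    """
    fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    out: dict[str, str] = {}
    for row in hs.itertuples():
        chrom = str(row.chromosome)
        if chrom not in fa:
            raise KeyError(f"chromosome {chrom!r} missing from FASTA {fasta_path}")
        chrom_len = len(fa[chrom])
        lo = max(0, int(row.start) - upstream_bp)
        hi = int(row.end) + (upstream_bp if both_flanks else 0)
        hi = min(hi, chrom_len)
        out[f"{chrom}:{int(row.start)}-{int(row.end)}"] = str(fa[chrom][lo:hi])
    return out


def _scan_runs(seq: str, base: str, min_run: int) -> list[tuple[int, str, str]]:
    pat = re.compile(f"{re.escape(base)}{{{min_run},}}")
    return [(m.start(), "+", m.group(0)) for m in pat.finditer(seq)]


def _scan_iupac(seq: str, pattern: str, max_mm: int) -> list[tuple[int, str, str]]:
    m = len(pattern)
    n = len(seq)
    if n < m:
        return []
    s = np.frombuffer(seq.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    informative = np.array([c != "N" for c in pattern])
    mismatches = np.zeros(len(windows), dtype=int)
    for k in np.flatnonzero(informative):
        col = windows[:, k]
        mismatches += (col != pattern[k].encode()) | (col == b"N")
    offs = np.flatnonzero(mismatches <= max_mm)
    return [(int(o), "+", seq[o:o + m]) for o in offs]


def scan_motif(seqs: dict[str, str], spec: MotifSpec) -> MotifHits:
    """Scan every sequence for the motif; reverse strand optional.

    Reverse-strand hit offsets are reported in forward-strand coordinates
    (position of the match's leftmost base).
    """
    result = MotifHits(spec=spec)
    for sid, seq in seqs.items():
        seq = seq.upper()
        if spec.run_base:
            hits = _scan_runs(seq, spec.run_base, spec.min_run)
            if spec.both_strands:
                comp = spec.run_base.translate(COMPLEMENT)
                hits += [
                    (off, "-", sub)
                    for off, _, sub in _scan_runs(seq, comp, spec.min_run)
                ]
        else:
            hits = _scan_iupac(seq, spec.pattern, spec.max_mismatches)
            if spec.both_strands:
                rc = reverse_complement(seq)
                for off, _, sub in _scan_iupac(rc, spec.pattern, spec.max_mismatches):
                    fwd_off = len(seq) - off - len(spec.pattern)
                    hits.append((fwd_off, "-", sub))
        result.hits[sid] = sorted(hits)
    return result


def sample_background_windows(
    fasta_path: str,
    hs: pd.DataFrame,
    lengths: list[int],
    rng: np.random.Generator,
    chromatin_map=None,
    chromatin_classes: list[str] | None = None,
    max_tries: int = 1000,
) -> dict[str, str]:
    """Length-matched background windows from the non-hotspot genome.

    One window is drawn per requested length, avoiding hotspot intervals and
    (when a chromatin map and per-window classes are given) matching each
    window's chromatin class.
    """
    fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    chroms = [(name, len(fa[name])) for name in fa.keys()]
    hot = {
        c: [(int(r.start), int(r.end)) for r in hs.itertuples() if r.chromosome == c]
        for c in {r.chromosome for r in hs.itertuples()}
    }
    out: dict[str, str] = {}
    for k, length in enumerate(lengths):
        want_class = chromatin_classes[k] if chromatin_classes is not None else None
        for _ in range(max_tries):
            name, clen = chroms[int(rng.integers(len(chroms)))]
            if clen <= length:
                continue
            s = int(rng.integers(0, clen - length))
            e = s + length
            if any(s < he and hs_ < e for hs_, he in hot.get(name, [])):
                continue
            if want_class is not None and chromatin_map is not None:
                if str(chromatin_map.class_at(name, (s + e) // 2)) != want_class:
                    continue
            out[f"bg{k}:{name}:{s}-{e}"] = str(fa[name][s:e])
            break
        else:
            raise RuntimeError("could not place a background window; genome too full")
    return out


def enrichment_test(
    hotspot_presence: np.ndarray,
    background_presence: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float, float]:
    """Permutation test of motif presence in hotspots vs background.

    Returns (frac_hotspots, frac_background, fold, empirical_P) with
    P = (1 + #{permuted hotspot fractions >= observed}) / (1 + n_perm).
    """
    if rng is None:
        rng = np.random.default_rng()
    hot = np.asarray(hotspot_presence, bool)
    bg = np.asarray(background_presence, bool)
    if len(bg) < 20:
        raise ValueError("need >= 20 background windows")
    frac_h = float(hot.mean()) if len(hot) else 0.0
    frac_b = float(bg.mean())
    if not hot.any() and not bg.any():
        return 0.0, 0.0, 1.0, 1.0
    pool = np.concatenate([hot, bg])
    n_h = len(hot)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        if perm[:n_h].mean() >= frac_h:
            count += 1
    p = (1 + count) / (1 + n_perm)
    fold = frac_h / max(frac_b, 1.0 / (2 * len(bg)))
    return frac_h, frac_b, fold, float(p)
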