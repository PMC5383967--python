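"""Per-base conservation score aggregation and the Steel-Dwass all-pairs
rank test.

Conservation scores (phastCons-style, in [0, 1]) are consumed from
fixedStep wiggle or bedGraph files.  Positions absent from the track are
*missing* (unalignable), not zero, and are excluded from region means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, studentized_range

__all__ = [
    "ScoreTrack",
    "read_scores",
    "mean_region_score",
    "gene_cds_scores",
    "promoter_scores",
    "steel_dwass",
]


class ScoreTrack:
    """Missing-aware per-chromosome score arrays (NaN = missing)."""

    def __init__(self) -> None:
        self._chroms: dict[str, np.ndarray] = {}

    def set_values(self, chrom: str, start: int, values: np.ndarray,
                   check_overlap: bool = False) -> None:
        values = np.asarray(values, float)
        end = start + values.size
        arr = self._chroms.get(chrom)
        if arr is None or arr.size < end:
            new = np.full(max(end, 2 * (arr.size if arr is not None else 0)), np.nan)
            if arr is not None:
                new[: arr.size] = arr
            self._chroms[chrom] = arr = new
        if check_overlap and np.any(~np.isnan(arr[start:end])):
            raise ValueError(f"overlapping score intervals on {chrom} at {start}")
        arr[start:end] = values

    def values(self, chrom: str, interval: tuple[int, int]) -> np.ndarray:
        """Scores over a half-open interval; NaN where missing."""
        lo, hi = interval
        out = np.full(max(0, hi - lo), np.nan)
        arr = self._chroms.get(chrom)
        if arr is None or hi <= lo:
            return out
        s, e = max(lo, 0), min(hi, arr.size)
        if e > s:
            out[s - lo: e - lo] = arr[s:e]
        return out

    def chromosomes(self) -> list[str]:
        return sorted(self._chroms)


def read_scores(path: str) -> ScoreTrack:
    """Read a fixedStep wiggle or bedGraph file into a ScoreTrack.

    fixedStep ``start`` is 1-based per the wiggle specification;
    bedGraph intervals are 0-based half-open.  Overlapping bedGraph
    intervals raise an error.
    """
    track = ScoreTrack()
    mode = None
    chrom, pos, step, span = None, 0, 1, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "fixedstep"
                kv = dict(part.split("=") for part in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if line.startswith("variableStep"):
                raise ValueError(f"{path}:{lineno}: variableStep not supported")
            fields = line.split()
            if mode == "fixedstep" and len(fields) == 1:
                track.set_values(chrom, pos, np.full(span, float(fields[0])))
                pos += step
            elif len(fields) == 4:
                c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                track.set_values(c, s, np.full(e - s, v), check_overlap=True)
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized score line")
    return track


def mean_region_score(track: ScoreTrack, chrom: str,
                      intervals: list[tuple[int, int]]) -> float:
    """Mean score over the covered positions of non-overlapping
    intervals; NaN when nothing is covered."""
    if not intervals:
        return float("nan")
    vals = np.concatenate([track.values(chrom, iv) for iv in intervals])
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))


def gene_cds_scores(track: ScoreTrack, genes) -> pd.Series:
    """Per-gene mean score over the merged union of coding exons."""
    out = {}
    for g in genes:
        out[g.gene_id] = mean_region_score(track, g.chrom, g.cds_exons)
    return pd.Series(out, name="cds_score")


def promoter_scores(track: ScoreTrack, promoters) -> pd.Series:
    """Per-gene mean score over the promoter interval."""
    out = {}
    for p in promoters:
        out[p.gene_id] = mean_region_score(track, p.chrom, [p.interval])
    return pd.Series(out, name="promoter_score")


def steel_dwass(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """All-pairs nonparametric comparison via the Steel-Dwass procedure.

    Each pair (i, j) is compared with a Wilcoxon rank-sum on the two
    groups alone (mid-rank ties, tie-corrected variance); the
    standardized statistic t is referred to the studentized-range
    distribution with infinite df: p = P(Q_{k,inf} >= sqrt(2)|t|).  With
    k = 2 this reduces to the two-sided normal-approximation
    Mann-Whitney p-value.  A pair whose pooled values are all identical
    has undefined (NaN) p.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("steel_dwass needs at least two groups")
    groups = [np.asarray(g, float) for g in groups]
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    p = np.full((k, k), np.nan)
    np.fill_diagonal(p, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            pooled = np.concatenate([a, b])
            n1, n2 = a.size, b.size
            n = n1 + n2
            ranks = rankdata(pooled)
            R = ranks[:n1].sum()
            E = n1 * (n + 1) / 2.0
            _, counts = np.unique(pooled, return_counts=True)
            tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
            var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
            if var <= 0:
                continue
            t = (R - E) / np.sqrt(var)
            p[i, j] = p[j, i] = float(
                studentized_range.sf(np.sqrt(2) * abs(t), k, np.inf))
    return pd.DataFrame(p, index=labels, columns=labels)
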