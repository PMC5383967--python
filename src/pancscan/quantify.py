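"""Strand-aware read counting, strandedness QC, TMM/DEGES normalization,
and TSS metagene profiles.

Counting follows a union/ambiguous scheme: a uniquely mapped read is
assigned to a feature when it overlaps the feature's interval by at least
one base on the required strand; a read compatible with more than one
feature of the same kind is discarded as ambiguous.  mRNA counting
requires the read strand to equal the gene strand; pancRNA counting
requires it to equal the promoter's antisense strand.

Normalization is TMM (trimmed mean of M-values) wrapped in a DEG
elimination loop (DEGES): scaling factors are estimated, putatively
differentially expressed genes are flagged and removed, and the factors
are re-estimated on the remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotation import CLEAN, GeneModel, PromoterRegion
from .matrix import ExpressionMatrix, sample_table

__all__ = [
    "ReadEvidence",
    "reads_from_bed",
    "reads_from_sam",
    "count_mrna",
    "count_pancrna",
    "strandedness",
    "tmm_factors",
    "deges_normalize",
    "tss_profile",
]


@dataclass(frozen=True)
class ReadEvidence:
    """A single aligned read reduced to (chrom, interval, strand, unique)."""

    chrom: str
    interval: tuple[int, int]
    strand: str
    unique: bool = True

    def __post_init__(self) -> None:
        if self.interval[1] <= self.interval[0]:
            raise ValueError("read interval must be non-empty")


def reads_from_bed(path: str) -> list[ReadEvidence]:
    """Read strand-tagged read intervals from BED6 (score column unused)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(ReadEvidence(f[0], (int(f[1]), int(f[2])), f[5]))
    return out


def reads_from_sam(path: str, min_mapq: int = 20) -> list[ReadEvidence]:
    """Read alignments from SAM/BAM; uniqueness = MAPQ >= ``min_mapq``."""
    import pysam

    out = []
    with pysam.AlignmentFile(path) as af:
        for rec in af:
            if rec.is_unmapped:
                continue
            out.append(
                ReadEvidence(
                    rec.reference_name,
                    (rec.reference_start, rec.reference_end),
                    "-" if rec.is_reverse else "+",
                    unique=rec.mapping_quality >= min_mapq,
                )
            )
    return out


# ---------------------------------------------------------------------------
# counting


class _FeatureIndex:
    """Per-(chrom, strand) sorted interval lookup."""

    def __init__(self, feats: list[tuple[str, str, tuple[int, int], str]],
                 stranded: bool = True):
        # feats: (chrom, strand, interval, feature_id)
        import bisect

        self._bisect = bisect
        self.stranded = stranded
        self._by_key: dict = {}
        self._max_len: dict = {}
        for chrom, strand, iv, fid in feats:
            key = (chrom, strand) if stranded else chrom
            self._by_key.setdefault(key, []).append((iv, fid))
        for key, rows in self._by_key.items():
            rows.sort()
            self._max_len[key] = max((e - s for (s, e), _ in rows), default=0)

    def chroms(self) -> set[str]:
        return {k[0] if self.stranded else k for k in self._by_key}

    def overlapping(self, chrom: str, strand: str, iv: tuple[int, int]) -> list[str]:
        key = (chrom, strand) if self.stranded else chrom
        rows = self._by_key.get(key, [])
        lo = self._bisect.bisect_left(
            rows, (iv[0] - self._max_len.get(key, 0) - 1, -1),
            key=lambda r: (r[0][0], 0)) if rows else 0
        hits = []
        for (s, e), fid in rows[lo:]:
            if s >= iv[1]:
                break
            if e > iv[0]:
                hits.append(fid)
        return hits


def _count_features(
    reads_by_sample: Mapping[str, Iterable[ReadEvidence]],
    index: _FeatureIndex,
    feature_ids: list[str],
    known_chroms: set[str],
) -> ExpressionMatrix:
    qc = {"skipped_unknown_chrom": 0, "ambiguous": 0, "nonunique": 0}
    cols = {}
    for sample, reads in reads_by_sample.items():
        tally = dict.fromkeys(feature_ids, 0)
        for r in reads:
            if not r.unique:
                qc["nonunique"] += 1
                continue
            if r.chrom not in known_chroms:
                qc["skipped_unknown_chrom"] += 1
                continue
            hits = index.overlapping(r.chrom, r.strand, r.interval)
            if len(hits) == 1:
                tally[hits[0]] += 1
            elif len(hits) > 1:
                qc["ambiguous"] += 1
        cols[sample] = tally
    counts = pd.DataFrame(cols, dtype=int).reindex(feature_ids)
    samples = sample_table([("NA", c, "1") for c in counts.columns], ids=list(counts.columns))
    mat = ExpressionMatrix(counts, samples)
    mat.qc.update(qc)
    return mat


def _as_sample_map(reads) -> Mapping[str, Iterable[ReadEvidence]]:
    if isinstance(reads, Mapping):
        return reads
    return {"sample1": list(reads)}


def count_mrna(reads, genes: list[GeneModel]) -> ExpressionMatrix:
    """Count uniquely mapped sense reads per gene (any-overlap, ambiguous
    reads discarded).  ``reads`` is an iterable of :class:`ReadEvidence`
    or a mapping of sample id -> iterable."""
    feats = [(g.chrom, g.strand, g.gene_span, g.gene_id) for g in genes]
    index = _FeatureIndex(feats)
    chroms = {g.chrom for g in genes}
    return _count_features(_as_sample_map(reads), index,
                           [g.gene_id for g in genes], chroms)


def count_pancrna(reads, promoters: list[PromoterRegion]) -> ExpressionMatrix:
    """Count uniquely mapped reads on the promoter-antisense strand per
    CLEAN promoter (any-overlap, ambiguous reads discarded)."""
    clean = [p for p in promoters if p.promoter_class == CLEAN]
    feats = [(p.chrom, p.panc_strand, p.interval, p.gene_id) for p in clean]
    index = _FeatureIndex(feats)
    chroms = {p.chrom for p in clean}
    return _count_features(_as_sample_map(reads), index,
                           [p.gene_id for p in clean], chroms)


def strandedness(reads: Iterable[ReadEvidence], genes: list[GeneModel]) -> float:
    """Fraction of unique reads over unambiguous genes whose strand matches
    the gene strand.  NaN when no read qualifies."""
    index = _FeatureIndex([(g.chrom, "", g.gene_span, g.gene_id) for g in genes],
                          stranded=False)
    strand_of = {g.gene_id: g.strand for g in genes}
    n, match = 0, 0
    for r in reads:
        if not r.unique:
            continue
        hits = index.overlapping(r.chrom, "", r.interval)
        if len(hits) != 1:
            continue
        n += 1
        match += r.strand == strand_of[hits[0]]
    return match / n if n else float("nan")


# ---------------------------------------------------------------------------
# normalization


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def _tmm_pair(y: np.ndarray, yr: np.ndarray, trim_m: float, trim_a: float) -> float:
    """edgeR-style doubly trimmed, precision-weighted mean of M values."""
    N, Nr = y.sum(), yr.sum()
    pos = (y > 0) & (yr > 0)
    if not pos.any():
        raise ValueError("sample shares no positive gene with the reference")
    y, yr = y[pos].astype(float), yr[pos].astype(float)
    M = np.log2((y / N) / (yr / Nr))
    A = 0.5 * np.log2((y / N) * (yr / Nr))
    n = M.size
    rm, ra = rankdata(M), rankdata(A)
    keep = (rm > n * trim_m) & (rm <= n * (1 - trim_m)) \
        & (ra > n * trim_a) & (ra <= n * (1 - trim_a))
    if not keep.any():
        keep = np.ones(n, bool)
    w = 1.0 / ((N - y) / (N * y) + (Nr - yr) / (Nr * yr))
    return float(2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep])))


def tmm_factors(counts: ExpressionMatrix | pd.DataFrame,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Effective per-sample size factors (library size x TMM scaling),
    rescaled to geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction
    is closest to the across-sample mean.  M/A values are computed over
    genes positive in both sample and reference, doubly trimmed
    (``trim_m`` on M, ``trim_a`` on A), and combined with the usual
    delta-method precision weights.
    """
    Y = counts.values if isinstance(counts, ExpressionMatrix) else counts
    if Y.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    arr = Y.to_numpy(float)
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    f75 = np.array([np.quantile(arr[:, j] / lib[j], 0.75) for j in range(arr.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    tmm = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == ref:
            continue
        tmm[j] = _tmm_pair(arr[:, j], arr[:, ref], trim_m, trim_a)
    eff = lib * tmm
    return pd.Series(eff / _geomean(eff), index=Y.columns, name="factor")


def deges_normalize(counts: ExpressionMatrix, iterations: int = 1,
                    deg_fraction: float = 0.25, trim_m: float = 0.30,
                    trim_a: float = 0.05) -> ExpressionMatrix:
    """DEG-elimination TMM normalization; output is counts per million on
    the effective library scale.

    Step 1 estimates TMM factors on all genes.  Each iteration then (2)
    flags the top ``deg_fraction`` of genes ranked by the maximum
    absolute pairwise log2 fold change of factor-adjusted tissue means
    and (3) re-estimates the factors on the unflagged genes.  With
    ``deg_fraction=0`` or ``iterations=0`` the result equals plain TMM
    CPM.
    """
    if not 0 <= deg_fraction < 1:
        raise ValueError("deg_fraction must be in [0, 1)")
    Y = counts.values
    arr = Y.to_numpy(float)
    lib = arr.sum(axis=0)
    factors = tmm_factors(Y, trim_m, trim_a)
    n_flag = int(round(deg_fraction * Y.shape[0]))
    if n_flag > 0:
        tissues = counts.samples["tissue"]
        for _ in range(max(0, iterations)):
            adj = Y.div(factors, axis=1)
            means = adj.T.groupby(tissues).mean().T  # genes x tissues
            logm = np.log2(means + 0.5)
            stat = logm.max(axis=1) - logm.min(axis=1)
            flagged = stat.nlargest(n_flag).index
            keep = Y.index.difference(flagged)
            factors = tmm_factors(Y.loc[keep], trim_m, trim_a)
    # factors are effective per-sample scales (geometric mean 1); the
    # absolute CPM scale is anchored on the geometric-mean library size
    norm = Y * 1e6 / (factors.to_numpy() * _geomean(lib))
    return ExpressionMatrix(norm, counts.samples, normalized=True,
                            factors=factors.copy(), qc=dict(counts.qc))


# ---------------------------------------------------------------------------
# TSS metagene profile


def tss_profile(coverage: Mapping[str, np.ndarray],
                anchors: list[tuple[str, int, str]],
                flank: int = 2000, bin: int = 50) -> pd.DataFrame:
    """Mean and SEM of per-base depth in ``bin``-bp bins over +/-``flank``
    around TSS anchors, oriented 5'->3' by anchor strand.

    ``coverage`` maps chromosome -> per-base depth array.  Bases beyond
    the array are treated as missing and excluded from that bin's mean.
    Returns a frame indexed by the bin's 5' offset relative to the TSS.
    """
    if not anchors:
        raise ValueError("anchors must be non-empty")
    nbins = (2 * flank) // bin
    rows = []
    for chrom, tss, strand in anchors:
        arr = coverage.get(chrom)
        vec = np.full(2 * flank, np.nan)
        if arr is not None:
            if strand == "+":
                lo, hi = tss - flank, tss + flank
                src = np.arange(lo, hi)
            else:
                lo, hi = tss - flank + 1, tss + flank + 1
                src = np.arange(hi - 1, lo - 1, -1)
            valid = (src >= 0) & (src < arr.size)
            vec[valid] = np.asarray(arr, float)[src[valid]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows.append(np.nanmean(
                vec[: nbins * bin].reshape(nbins, bin), axis=1))
    stack = np.vstack(rows)
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        n = np.sum(~np.isnan(stack), axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    offsets = np.arange(-flank, flank, bin)
    return pd.DataFrame({"mean": mean, "sem": sem, "n": n}, index=pd.Index(offsets, name="offset"))
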