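"""Gene models, promoter construction and promoter filtering.

A *promoter region* is the interval covering the 2 kb immediately upstream
of a gene's transcription start site (TSS).  Transcription from the strand
opposite the gene within this window produces promoter-associated ncRNA
(pancRNA).  Before antisense reads can be attributed to a promoter, the
promoter set has to be cleaned: a promoter that contains part of another
gene would pick up ordinary sense transcription of that gene, and two
promoters that overlap or sit closer than ``min_gap`` would cross-count
each other's antisense signal.

All coordinates are 0-based, half-open.  GTF input (1-based, closed) is
converted on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GeneModel",
    "PromoterRegion",
    "read_gene_models",
    "promoter_interval",
    "select_promoters",
    "cpg_overlap_fraction",
    "read_bed_intervals",
    "write_promoters_bed",
    "CLEAN",
    "CONTAMINATED",
    "EXCLUDED",
]

CLEAN = "CLEAN"
CONTAMINATED = "CONTAMINATED"
EXCLUDED = "EXCLUDED"


@dataclass
class GeneModel:
    """One protein-coding gene.

    ``tss`` is the 0-based position of the first transcribed base of the
    representative (most upstream) transcript.  ``tss_alternatives`` lists
    the distinct transcript start sites, most upstream first; it always
    contains ``tss``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_span: tuple[int, int]
    cds_exons: list[tuple[int, int]] = field(default_factory=list)
    tss_alternatives: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.tss_alternatives:
            self.tss_alternatives = [self.tss]
        if self.tss not in self.tss_alternatives:
            raise ValueError(f"{self.gene_id}: tss not in tss_alternatives")
        s, e = self.gene_span
        if not (s <= self.tss < e):
            raise ValueError(f"{self.gene_id}: gene_span does not contain tss")
        self.cds_exons = sorted(self.cds_exons)
        for (a, b), (c, d) in zip(self.cds_exons, self.cds_exons[1:]):
            if b > c:
                raise ValueError(f"{self.gene_id}: overlapping CDS exons")


@dataclass
class PromoterRegion:
    """Per-gene upstream interval with a filtering label.

    ``panc_strand`` is the strand of the promoter-antisense transcript,
    i.e. the opposite of the gene strand.
    """

    gene_id: str
    chrom: str
    interval: tuple[int, int]
    panc_strand: str
    promoter_class: str
    gene_strand: str = ""
    tss: int = -1

    @property
    def length(self) -> int:
        return max(0, self.interval[1] - self.interval[0])


# ---------------------------------------------------------------------------
# annotation input


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _models_from_transcripts(transcripts: dict) -> list[GeneModel]:
    models = []
    for gene_id, info in transcripts.items():
        if not info["tx_starts"]:
            warnings.warn(f"gene {gene_id} has no transcript; skipped")
            continue
        strand = info["strand"]
        starts = sorted(set(info["tx_starts"]), reverse=(strand == "-"))
        span = (min(info["span_lo"]), max(info["span_hi"]))
        cds = _merge_intervals(info["cds"])
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=info["chrom"],
                strand=strand,
                tss=starts[0],
                gene_span=span,
                cds_exons=cds,
                tss_alternatives=starts,
            )
        )
    models.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return models


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_gene_models(path: str) -> list[GeneModel]:
    """Read gene models from a GTF (Ensembl dialect) or BED12 file.

    Transcripts are grouped by ``gene_id``; distinct transcript start
    sites become ``tss_alternatives`` (most upstream first).  Output is
    sorted by (chrom, tss, gene_id).
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    if not first:
        return []
    f = first.rstrip("\n").split("\t")
    if len(f) >= 9 and f[3].isdigit() and f[4].isdigit() and "gene_id" in f[8]:
        return _read_gtf(path)
    if len(f) >= 12:
        return _read_bed12(path)
    raise ValueError(f"{path}: neither GTF (9 columns) nor BED12 (12 columns)")


def _read_gtf(path: str) -> list[GeneModel]:
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF record")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields[:9]
            try:
                start_i, end_i = int(start) - 1, int(end)  # to 0-based half-open
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _parse_gtf_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            info = transcripts.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "tx_starts": [],
                 "span_lo": [], "span_hi": [], "cds": []},
            )
            info["span_lo"].append(start_i)
            info["span_hi"].append(end_i)
            if feature == "transcript":
                info["tx_starts"].append(start_i if strand == "+" else end_i - 1)
            elif feature == "exon" and "transcript_id" in attrs:
                # tolerate GTFs without explicit transcript lines
                pass
            elif feature == "CDS":
                info["cds"].append((start_i, end_i))
    # GTFs lacking transcript lines: derive one start per gene from span
    for gene_id, info in transcripts.items():
        if not info["tx_starts"]:
            lo, hi = min(info["span_lo"]), max(info["span_hi"])
            info["tx_starts"].append(lo if info["strand"] == "+" else hi - 1)
    return _models_from_transcripts(transcripts)


def _read_bed12(path: str) -> list[GeneModel]:
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            cds = [(max(a, thick_s), min(b, thick_e)) for a, b in blocks
                   if min(b, thick_e) > max(a, thick_s)]
            gene_id = name.split(".")[0]
            info = transcripts.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "tx_starts": [],
                 "span_lo": [], "span_hi": [], "cds": []},
            )
            info["span_lo"].append(start)
            info["span_hi"].append(end)
            info["tx_starts"].append(start if strand == "+" else end - 1)
            info["cds"].extend(cds)
    return _models_from_transcripts(transcripts)


def read_bed_intervals(path: str) -> dict[str, list[tuple[int, int]]]:
    """Read a BED3+ file into per-chromosome sorted interval lists."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    for chrom in out:
        out[chrom].sort()
    return out


# ---------------------------------------------------------------------------
# promoter construction


def promoter_interval(
    gene: GeneModel,
    upstream_len: int = 2000,
    chrom_length: int | None = None,
    tss: int | None = None,
) -> tuple[int, int]:
    """Upstream interval of length ``upstream_len`` ending 1 bp before the TSS.

    Plus strand, TSS at t: ``[t - L, t)``.  Minus strand: ``[t + 1, t + 1 + L)``.
    Clipped at chromosome bounds; a TSS with no upstream room yields an
    empty interval (promoter cannot be formed).
    """
    if upstream_len < 1:
        raise ValueError("upstream_len must be >= 1")
    t = gene.tss if tss is None else tss
    if gene.strand == "+":
        lo, hi = max(0, t - upstream_len), t
    else:
        lo = t + 1
        hi = t + 1 + upstream_len
        if chrom_length is not None:
            hi = min(hi, chrom_length)
    if hi <= lo:
        return (t, t)
    return (lo, hi)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Edge-to-edge gap between half-open intervals; 0 when overlapping."""
    if _overlaps(a, b):
        return 0
    return max(a[0], b[0]) - min(a[1], b[1])


class _NeighborLookup:
    """Sorted-by-start interval lookup with bounded backward scan."""

    def __init__(self, items) -> None:
        import numpy as np

        self._np = np
        self._by_chrom: dict[str, tuple] = {}
        buckets: dict[str, list] = {}
        for chrom, iv, ident in items:
            buckets.setdefault(chrom, []).append((iv[0], iv[1], ident))
        for chrom, rows in buckets.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            ids = [r[2] for r in rows]
            max_len = int((ends - starts).max()) if len(rows) else 0
            self._by_chrom[chrom] = (starts, ends, ids, max_len)

    def overlaps_other(self, chrom: str, iv: tuple[int, int], own: str) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends, ids, max_len = entry
        np = self._np
        lo = int(np.searchsorted(starts, iv[0] - max_len, side="left"))
        hi = int(np.searchsorted(starts, iv[1], side="left"))
        for k in range(lo, hi):
            if ends[k] > iv[0] and ids[k] != own:
                return True
        return False


def select_promoters(
    genes: list[GeneModel],
    min_gap: int = 500,
    upstream_len: int = 2000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[PromoterRegion]:
    """Build and filter one promoter per gene.

    For every gene, one candidate promoter is formed per alternative TSS.
    Candidates overlapping another gene's span or another gene's candidate
    promoter are discarded; among the survivors the most distal one (the
    TSS farthest upstream of the gene body) is selected and labelled
    CLEAN.  A gene whose every candidate is dirty falls back to its most
    distal candidate: if that candidate overlaps another gene's span the
    gene is labelled CONTAMINATED (kept for gene-level analyses, excluded
    from pancRNA counting), otherwise EXCLUDED.  Finally, two selected
    CLEAN promoters closer than ``min_gap`` (edge to edge, strand
    ignored) are resolved in favour of the more distal one; the loser's
    gene becomes EXCLUDED.

    The result is a deterministic function of the gene *set*: permuting
    the input order changes nothing.  Every gene receives exactly one
    label, so CLEAN/CONTAMINATED/EXCLUDED partitions the input.
    """
    genes = sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id))
    chrom_lengths = chrom_lengths or {}

    cand: dict[str, list[tuple[int, tuple[int, int]]]] = {}
    for g in genes:
        lst = []
        for t in g.tss_alternatives:
            iv = promoter_interval(g, upstream_len, chrom_lengths.get(g.chrom), tss=t)
            if iv[1] > iv[0]:
                lst.append((t, iv))
        cand[g.gene_id] = lst

    span_lookup = _NeighborLookup(
        (g.chrom, g.gene_span, g.gene_id) for g in genes)
    cand_lookup = _NeighborLookup(
        (g.chrom, iv, g.gene_id) for g in genes for _t, iv in cand[g.gene_id])

    def hits_other_span(chrom: str, iv: tuple[int, int], own: str) -> bool:
        return span_lookup.overlaps_other(chrom, iv, own)

    def hits_other_candidate(chrom: str, iv: tuple[int, int], own: str) -> bool:
        return cand_lookup.overlaps_other(chrom, iv, own)

    def distality(g: GeneModel, t: int) -> int:
        """Upstream shift of TSS t relative to the gene's most proximal TSS."""
        prox = max(g.tss_alternatives) if g.strand == "+" else min(g.tss_alternatives)
        return (prox - t) if g.strand == "+" else (t - prox)

    def most_distal(g: GeneModel, pool: list[tuple[int, tuple[int, int]]]):
        # most upstream TSS: smallest coordinate on +, largest on -
        if g.strand == "+":
            return min(pool, key=lambda x: x[0])
        return max(pool, key=lambda x: x[0])

    selected: dict[str, PromoterRegion] = {}
    for g in genes:
        anti = "-" if g.strand == "+" else "+"
        pool = cand[g.gene_id]
        survivors = [
            (t, iv) for t, iv in pool
            if not hits_other_span(g.chrom, iv, g.gene_id)
            and not hits_other_candidate(g.chrom, iv, g.gene_id)
        ]
        if survivors:
            t, iv = most_distal(g, survivors)
            klass = CLEAN
        elif pool:
            t, iv = most_distal(g, pool)
            klass = CONTAMINATED if hits_other_span(g.chrom, iv, g.gene_id) else EXCLUDED
        else:
            t, iv = g.tss, (g.tss, g.tss)
            klass = EXCLUDED
        selected[g.gene_id] = PromoterRegion(
            gene_id=g.gene_id, chrom=g.chrom, interval=iv, panc_strand=anti,
            promoter_class=klass, gene_strand=g.strand, tss=t,
        )

    # min_gap resolution among CLEAN promoters, deterministic order
    by_id = {g.gene_id: g for g in genes}
    clean_ids = [gid for gid in selected if selected[gid].promoter_class == CLEAN]
    clean_ids.sort(key=lambda gid: (selected[gid].chrom, selected[gid].interval, gid))
    for i, gi in enumerate(clean_ids):
        for gj in clean_ids[i + 1:]:
            pi, pj = selected[gi], selected[gj]
            if pi.chrom != pj.chrom:
                break
            if pj.interval[0] >= pi.interval[1] + min_gap:
                break  # sorted by start; no later promoter can conflict
            if pi.promoter_class != CLEAN or pj.promoter_class != CLEAN:
                continue
            if _gap(pi.interval, pj.interval) < min_gap:
                di = distality(by_id[gi], pi.tss)
                dj = distality(by_id[gj], pj.tss)
                # keep the more distal promoter; ties fall to the longer one,
                # then to the lexicographically smaller gene id
                keep_i = (di, pi.length, gj) > (dj, pj.length, gi)
                loser = selected[gj if keep_i else gi]
                loser.promoter_class = EXCLUDED

    return [selected[g.gene_id] for g in genes]


# ---------------------------------------------------------------------------
# CpG islands


def cpg_overlap_fraction(
    promoters: list[PromoterRegion],
    islands: dict[str, list[tuple[int, int]]],
    classes: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Fraction of promoters overlapping (>=1 bp) any CpG island.

    Returns ``{"total": f}``; when a pair-classification table (columns
    ``gene_id``/``klass``) is supplied, ``PARTNERED`` and ``LACKING``
    subset fractions are added.  An empty promoter set yields NaN.
    """
    def frac(proms: list[PromoterRegion]) -> float:
        if not proms:
            return float("nan")
        n = sum(
            1 for p in proms
            if any(_overlaps(p.interval, iv) for iv in islands.get(p.chrom, []))
        )
        return n / len(proms)

    out = {"total": frac(promoters)}
    if classes is not None:
        klass = dict(zip(classes["gene_id"], classes["klass"]))
        for label in ("PARTNERED", "LACKING"):
            sub = [p for p in promoters if klass.get(p.gene_id) == label]
            out[label] = frac(sub)
    return out


def write_promoters_bed(promoters: list[PromoterRegion], path: str) -> None:
    """Emit promoters as BED6; name=gene_id, strand=panc_strand, score
    encodes the promoter class (0 CLEAN, 1 CONTAMINATED, 2 EXCLUDED)."""
    code = {CLEAN: 0, CONTAMINATED: 1, EXCLUDED: 2}
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(
                f"{p.chrom}\t{p.interval[0]}\t{p.interval[1]}\t{p.gene_id}\t"
                f"{code[p.promoter_class]}\t{p.panc_strand}\n"
            )
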