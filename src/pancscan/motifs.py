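"""PWM handling, relative-score scanning and TSS-relative motif profiles.

Scanning uses matchPWM-style *relative score*: for a window the raw score
is the sum of the matrix entries of the observed bases, and the relative
score rescales it between the smallest and largest score the matrix can
produce.  "70% identity" means relative score >= 0.70.  Sequences are
assumed pre-oriented 5'->3' on the gene strand, so scanning is
single-strand.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pwm",
    "AnchoredSequence",
    "read_meme_minimal",
    "write_meme_minimal",
    "pwm_scan",
    "frequency_profile",
    "motif_cooccurrence",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class Pwm:
    """Position probability matrix, width x 4 (columns A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.background = np.asarray(self.background, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        rows = self.matrix.sum(axis=1)
        if np.any(np.abs(rows - 1) > 1e-9):
            if np.any(rows <= 0):
                raise ValueError("PWM rows must have positive mass")
            if np.any(np.abs(rows - 1) > 1e-4):
                # genuine mis-specification rather than print precision
                warnings.warn(f"PWM {self.motif_id}: rows renormalized to sum 1")
            self.matrix = self.matrix / rows[:, None]

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass
class AnchoredSequence:
    """DNA oriented 5'->3' on the gene strand; ``anchor_offset`` is the
    index of the TSS base within ``seq``."""

    gene_id: str
    seq: str
    anchor_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.anchor_offset < len(self.seq):
            raise ValueError(f"{self.gene_id}: anchor_offset outside sequence")
        if re.search(r"[^ACGTN]", self.seq):
            raise ValueError(f"{self.gene_id}: sequence contains non-ACGTN characters")


# ---------------------------------------------------------------------------
# MEME minimal format


def read_meme_minimal(path: str) -> list[Pwm]:
    """Parse MEME minimal motif format; background defaults to uniform."""
    with open(path) as fh:
        text = fh.read()
    background = np.full(4, 0.25)
    bg_match = re.search(
        r"Background letter frequencies.*?\n\s*A\s+([\d.eE+-]+)\s+C\s+([\d.eE+-]+)"
        r"\s+G\s+([\d.eE+-]+)\s+T\s+([\d.eE+-]+)", text)
    if bg_match:
        background = np.array([float(bg_match.group(i)) for i in range(1, 5)])
    motifs = []
    blocks = re.split(r"(?m)^MOTIF\s+", text)[1:]
    for block in blocks:
        lines = block.splitlines()
        motif_id = lines[0].split()[0] if lines and lines[0].split() else None
        if motif_id is None:
            raise ValueError(f"{path}: MOTIF block without an identifier")
        rows = []
        in_matrix = False
        for line in lines[1:]:
            if line.strip().startswith("letter-probability matrix"):
                in_matrix = True
                continue
            if in_matrix:
                vals = line.split()
                if len(vals) == 4:
                    try:
                        rows.append([float(v) for v in vals])
                        continue
                    except ValueError:
                        pass
                if rows:
                    break
        if not rows:
            raise ValueError(f"{path}: motif {motif_id} has no probability matrix")
        motifs.append(Pwm(motif_id, np.array(rows), background.copy()))
    return motifs


def write_meme_minimal(pwms: list[Pwm], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width}\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# scanning


def _scores(seq: str, pwm: Pwm) -> tuple[np.ndarray, np.ndarray]:
    """Raw window scores and a validity mask (False where a window
    contains N)."""
    w, L = pwm.width, len(seq)
    npos = L - w + 1
    if npos <= 0:
        return np.empty(0), np.empty(0, bool)
    idx = np.frombuffer(seq.encode(), np.uint8)
    code = np.full(256, -1, np.int64)
    for b, i in _BASE_IDX.items():
        code[ord(b)] = i
    bidx = code[idx]
    valid_base = bidx >= 0
    scores = np.zeros(npos)
    valid = np.ones(npos, bool)
    safe = np.where(valid_base, bidx, 0)
    for j in range(w):
        scores += pwm.matrix[j, safe[j:j + npos]]
        valid &= valid_base[j:j + npos]
    return scores, valid


def pwm_scan(seq: str, pwm: Pwm, min_frac: float = 0.70) -> np.ndarray:
    """0-based start positions where the window's relative score reaches
    ``min_frac``.

    Relative score = (s - s_min) / (s_max - s_min) with s_min/s_max the
    sums of per-column minima/maxima.  Windows containing N are skipped.
    A degenerate matrix with s_max == s_min matches everywhere.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    scores, valid = _scores(seq.upper(), pwm)
    if scores.size == 0:
        return np.empty(0, int)
    s_min = pwm.matrix.min(axis=1).sum()
    s_max = pwm.matrix.max(axis=1).sum()
    if s_max == s_min:
        rel = np.ones_like(scores)
    else:
        rel = (scores - s_min) / (s_max - s_min)
    return np.nonzero(valid & (rel >= min_frac))[0]


def frequency_profile(anchored: list[AnchoredSequence], pwm: Pwm,
                      flank: int = 2000, window: int = 50,
                      min_frac: float = 0.70) -> pd.DataFrame:
    """Fraction of sequences with >= 1 hit starting in each TSS-relative
    window, tiling -flank..+flank.

    Windows are labelled by their 5' edge.  A window not fully contained
    in a sequence is missing for that sequence and excluded from the
    denominator; a window covered by no sequence has NaN frequency.
    """
    edges = np.arange(-flank, flank, window)
    hit_count = np.zeros(edges.size)
    cover_count = np.zeros(edges.size)
    for a in anchored:
        lo_rel = -a.anchor_offset
        hi_rel = len(a.seq) - a.anchor_offset
        covered = (edges >= lo_rel) & (edges + window <= hi_rel)
        cover_count += covered
        hits = pwm_scan(a.seq, pwm, min_frac) - a.anchor_offset
        if hits.size:
            which = np.unique((hits - (-flank)) // window)
            which = which[(which >= 0) & (which < edges.size)]
            sel = np.zeros(edges.size, bool)
            sel[which.astype(int)] = True
            hit_count += sel & covered
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(cover_count > 0, hit_count / np.maximum(cover_count, 1), np.nan)
    return pd.DataFrame({"window_start": edges, "frequency": freq,
                         "n_sequences": cover_count.astype(int)})


def motif_cooccurrence(seqs: list[str], pwm_c: Pwm, pwm_g: Pwm,
                       min_frac: float = 0.70) -> dict[str, float]:
    """Four-way fractions of sequences hit by a C-skewed and/or a
    G-skewed motif; the four fractions sum to 1.  Intended for the
    -200..-1 immediate-upstream subsequences."""
    if not seqs:
        return {"only_c": float("nan"), "only_g": float("nan"),
                "both": float("nan"), "neither": float("nan")}
    n = len(seqs)
    tallies = {"only_c": 0, "only_g": 0, "both": 0, "neither": 0}
    for s in seqs:
        has_c = pwm_scan(s, pwm_c, min_frac).size > 0
        has_g = pwm_scan(s, pwm_g, min_frac).size > 0
        key = ("both" if has_c and has_g else
               "only_c" if has_c else
               "only_g" if has_g else "neither")
        tallies[key] += 1
    return {k: v / n for k, v in tallies.items()}
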