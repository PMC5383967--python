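"""Cross-tissue pancRNA/mRNA pairing, tissue specificity, and
species-level gain/loss calls.

A protein-coding gene is *pancRNA-partnered* when the expression of the
antisense transcript from its promoter correlates positively with the
gene's own mRNA across tissues (Pearson r > 0.7 on tissue means), and
*pancRNA-lacking* when the correlation is below 0.4 or there is no
detectable promoter-antisense signal at all.  Genes in between are
*intermediate*; genes whose correlation is incomputable despite nonzero
pancRNA are *undefined*.  Classification is by r alone; p-values are
reported for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PARTNERED",
    "INTERMEDIATE",
    "LACKING",
    "UNDEFINED",
    "OrthologTable",
    "tissue_means",
    "pearson",
    "classify_pairs",
    "class_summary",
    "tsi",
    "tsi_frame",
    "tsi_by_class",
    "species_specific",
    "conserved_pancrna",
]

PARTNERED = "PARTNERED"
INTERMEDIATE = "INTERMEDIATE"
LACKING = "LACKING"
UNDEFINED = "UNDEFINED"


def tissue_means(norm) -> pd.DataFrame:
    """Average replicates to one column per tissue (features x tissues).

    Tissue order follows first appearance in the sample table and is
    preserved in the output columns.
    """
    values, samples = norm.values, norm.samples
    order = list(dict.fromkeys(samples["tissue"]))
    for t in order:
        if (samples["tissue"] == t).sum() == 0:
            raise ValueError(f"tissue {t} has no replicates")
    out = values.T.groupby(samples["tissue"]).mean().T
    return out[order]


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and two-sided p-value from the t
    distribution with n-2 df.  Zero variance in either vector yields
    (nan, nan) rather than an exception."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("pearson needs two equal-length vectors, n >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    sx = np.sqrt((xd**2).sum())
    sy = np.sqrt((yd**2).sum())
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    r = float(np.clip((xd * yd).sum() / (sx * sy), -1.0, 1.0))
    # exactly collinear input deserves exactly +/-1 despite roundoff
    if 1.0 - abs(r) < 1e-12 * n and np.allclose(
            xd * sy * np.sign(r), yd * sx, rtol=1e-9, atol=0):
        r = float(np.sign(r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[1]
    Xd = X - X.mean(axis=1, keepdims=True)
    Yd = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xd**2).sum(axis=1))
    sy = np.sqrt((Yd**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xd * Yd).sum(axis=1) / (sx * sy)
    r = np.where((sx == 0) | (sy == 0), np.nan, np.clip(r, -1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) == 1, 0.0, p))
    return r, p


def classify_pairs(mrna_means: pd.DataFrame, panc_means: pd.DataFrame,
                   r_high: float = 0.7, r_low: float = 0.4) -> pd.DataFrame:
    """Classify each gene by the correlation between its mRNA and pancRNA
    tissue-mean vectors.

    Returns a frame with columns gene_id, r, p, klass.  Genes with an
    all-zero pancRNA vector are LACKING with undefined r (no antisense
    signal *is* the lacking phenotype); other incomputable correlations
    are UNDEFINED.  Threshold ties (r exactly r_high or r_low) fall to
    INTERMEDIATE.
    """
    missing = mrna_means.index.symmetric_difference(panc_means.index)
    if len(missing):
        raise ValueError(
            "mRNA and pancRNA matrices must cover the same genes; "
            f"mismatched ids: {sorted(missing)[:10]}")
    common = mrna_means.index
    if list(mrna_means.columns) != list(panc_means.columns):
        raise ValueError("mRNA and pancRNA matrices must share the tissue axis")
    X = mrna_means.loc[common].to_numpy(float)
    Y = panc_means.loc[common].to_numpy(float)
    r, p = _rowwise_pearson(X, Y)
    panc_zero = (Y == 0).all(axis=1)
    klass = np.full(common.size, INTERMEDIATE, dtype=object)
    klass[np.isnan(r)] = UNDEFINED
    klass[~np.isnan(r) & (r > r_high)] = PARTNERED
    klass[~np.isnan(r) & (r < r_low)] = LACKING
    klass[panc_zero] = LACKING
    out = pd.DataFrame({"gene_id": common, "r": r, "p": p, "klass": klass})
    return out.reset_index(drop=True)


def class_summary(classes: pd.DataFrame, r_high: float = 0.7) -> dict:
    """Per-class counts plus the negative-correlation tally (r < -r_high)."""
    counts = classes["klass"].value_counts().to_dict()
    return {
        "total": int(len(classes)),
        "n_partnered": int(counts.get(PARTNERED, 0)),
        "n_intermediate": int(counts.get(INTERMEDIATE, 0)),
        "n_lacking": int(counts.get(LACKING, 0)),
        "n_undefined": int(counts.get(UNDEFINED, 0)),
        "n_negative": int((classes["r"] < -r_high).sum()),
    }


# ---------------------------------------------------------------------------
# tissue specificity


def tsi(expr) -> float:
    """Tissue-specificity index tau = sum(1 - x_i/x_max) / (N - 1).

    0 for uniform expression, 1 for single-tissue expression, invariant
    under positive scaling.  All-zero input yields NaN.
    """
    x = np.asarray(expr, float)
    if x.size < 2:
        raise ValueError("tsi needs at least two tissues")
    if (x < 0).any():
        raise ValueError("tsi requires non-negative expression")
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1 - x / m) / (x.size - 1))


def tsi_frame(means: pd.DataFrame) -> pd.DataFrame:
    """Per-gene TSI and argmax tissue from a features x tissues matrix."""
    arr = means.to_numpy(float)
    m = arr.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.sum(1 - arr / m[:, None], axis=1) / (arr.shape[1] - 1)
    vals = np.where(m == 0, np.nan, vals)
    argmax = means.columns.to_numpy()[arr.argmax(axis=1)]
    return pd.DataFrame({"gene_id": means.index, "tsi": vals,
                         "argmax_tissue": argmax}).reset_index(drop=True)


def tsi_by_class(tsi_records: pd.DataFrame, classes: pd.DataFrame,
                 promoter_classes: pd.DataFrame | None = None) -> dict:
    """Group TSI values into the four standard gene classes and compare.

    I: all genes; II: genes whose promoter contains part of another gene
    (CONTAMINATED); III: pancRNA-partnered; IV: pancRNA-lacking.
    Returns medians/quartiles per group, the argmax-tissue histogram per
    group, and Steel-Dwass all-pairs p-values.
    """
    import warnings

    from .conservation import steel_dwass

    t = tsi_records.set_index("gene_id")
    klass = classes.set_index("gene_id")["klass"]
    groups: dict[str, pd.Series] = {"I_total": t["tsi"].dropna()}
    if promoter_classes is not None:
        contam = promoter_classes.loc[
            promoter_classes["promoter_class"] == "CONTAMINATED", "gene_id"]
        groups["II_contaminated"] = t["tsi"].reindex(contam).dropna()
    groups["III_partnered"] = t["tsi"].reindex(klass.index[klass == PARTNERED]).dropna()
    groups["IV_lacking"] = t["tsi"].reindex(klass.index[klass == LACKING]).dropna()
    for name in [k for k, v in groups.items() if len(v) == 0]:
        warnings.warn(f"TSI group {name} is empty; dropped")
        del groups[name]
    summary = {
        name: {
            "n": int(len(v)),
            "median": float(np.median(v)),
            "q1": float(np.quantile(v, 0.25)),
            "q3": float(np.quantile(v, 0.75)),
        }
        for name, v in groups.items()
    }
    labels = list(groups)
    pmat = steel_dwass([groups[k].to_numpy() for k in labels], labels=labels) \
        if len(labels) >= 2 else None
    hist = {
        name: t.loc[t.index.intersection(v.index), "argmax_tissue"]
               .value_counts().to_dict()
        for name, v in groups.items()
    }
    return {"summary": summary, "steel_dwass_p": pmat, "argmax_hist": hist}


# ---------------------------------------------------------------------------
# orthology


@dataclass
class OrthologTable:
    """One-to-one ortholog pairs with complete singleton-group extraction.

    ``pairs`` holds rows (species_a, gene_a, species_b, gene_b).  A
    *complete group* links exactly one gene per species for every
    species under consideration.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["species_a", "gene_a", "species_b", "gene_b"]
        if list(self.pairs.columns) != need:
            self.pairs = self.pairs[need]
        dup = self.pairs.duplicated()
        if dup.any():
            self.pairs = self.pairs[~dup].reset_index(drop=True)
        # one-to-one constraint: a gene may appear in at most one pair per
        # species pair
        for side in ("a", "b"):
            key = self.pairs[[f"species_{side}", f"gene_{side}",
                              "species_a" if side == "b" else "species_b"]]
            if key.duplicated().any():
                raise ValueError("ortholog table is not one-to-one")

    @classmethod
    def from_groups(cls, groups: pd.DataFrame) -> "OrthologTable":
        """Build pairwise rows from a wide table (group rows, one column
        per species, NaN for missing members)."""
        rows = []
        species = list(groups.columns)
        for _, row in groups.iterrows():
            present = [(sp, row[sp]) for sp in species if pd.notna(row[sp])]
            for i in range(len(present)):
                for j in range(i + 1, len(present)):
                    rows.append((present[i][0], present[i][1],
                                 present[j][0], present[j][1]))
        return cls(pd.DataFrame(rows, columns=["species_a", "gene_a",
                                               "species_b", "gene_b"]))

    def to_tsv(self, path: str) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "OrthologTable":
        return cls(pd.read_csv(path, sep="\t"))

    def complete_groups(self, species: list[str]) -> pd.DataFrame:
        """Connected components restricted to exactly one gene per species.

        Returns a wide frame indexed by group id with one column per
        species holding the member gene id.
        """
        cache = self.__dict__.setdefault("_groups_cache", {})
        key = tuple(species)
        if key in cache:
            return cache[key]
        parent: dict[tuple[str, str], tuple[str, str]] = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

        for _, r in self.pairs.iterrows():
            a, b = (r["species_a"], r["gene_a"]), (r["species_b"], r["gene_b"])
            parent.setdefault(a, a)
            parent.setdefault(b, b)
            union(a, b)
        comps: dict[tuple[str, str], list[tuple[str, str]]] = {}
        for node in parent:
            comps.setdefault(find(node), []).append(node)
        rows = []
        for members in comps.values():
            by_sp: dict[str, list[str]] = {}
            for sp, gid in members:
                by_sp.setdefault(sp, []).append(gid)
            if set(by_sp) == set(species) and all(len(v) == 1 for v in by_sp.values()):
                rows.append({sp: by_sp[sp][0] for sp in species})
        out = pd.DataFrame(rows, columns=species)
        if len(out):
            out = out.sort_values(species[0]).reset_index(drop=True)
        out.index = [f"og{i:05d}" for i in range(len(out))]
        cache[key] = out
        return out


def species_specific(classes_by_species: dict[str, pd.DataFrame],
                     orthologs: OrthologTable) -> dict[str, dict[str, set]]:
    """Gain- and loss-side species-specific calls over complete groups.

    ``gain[s]``: genes PARTNERED in species s whose orthologs are
    LACKING in every other species.  ``loss[s]``: genes LACKING in s
    whose orthologs are PARTNERED everywhere else.  Genes without a
    complete singleton ortholog group are excluded.
    """
    species = sorted(classes_by_species)
    groups = orthologs.complete_groups(species)
    klass = {sp: classes_by_species[sp].set_index("gene_id")["klass"]
             for sp in species}
    lab = pd.DataFrame({sp: groups[sp].map(klass[sp]) for sp in species})
    complete = lab.notna().all(axis=1)
    gain: dict[str, set] = {}
    loss: dict[str, set] = {}
    for sp in species:
        others = [o for o in species if o != sp]
        g_mask = complete & (lab[sp] == PARTNERED) \
            & (lab[others] == LACKING).all(axis=1)
        l_mask = complete & (lab[sp] == LACKING) \
            & (lab[others] == PARTNERED).all(axis=1)
        gain[sp] = set(groups.loc[g_mask, sp])
        loss[sp] = set(groups.loc[l_mask, sp])
    return {"gain": gain, "loss": loss}


def conserved_pancrna(classes_by_species: dict[str, pd.DataFrame],
                      orthologs: OrthologTable) -> list[str]:
    """Ortholog groups PARTNERED in every species (conserved pancRNAs)."""
    species = sorted(classes_by_species)
    groups = orthologs.complete_groups(species)
    klass = {sp: classes_by_species[sp].set_index("gene_id")["klass"]
             for sp in species}
    lab = pd.DataFrame({sp: groups[sp].map(klass[sp]) for sp in species})
    return list(groups.index[(lab == PARTNERED).all(axis=1)])
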