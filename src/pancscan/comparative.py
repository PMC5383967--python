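"""Ortholog-restricted cross-species expression matrices, Spearman
correlation, average-linkage clustering, and segregation scoring.

Samples (one per species x tissue, replicate-averaged) are compared by
Spearman rank correlation; hierarchical clustering uses average linkage
(UPGMA) on the distance d = 1 - rho.  The segregation score condenses
the heat-map's visual claim into a number: for each sample, does its
nearest neighbour (highest rho) share the species, or the tissue?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pairing import PARTNERED, OrthologTable

__all__ = [
    "build_joint_matrix",
    "spearman_matrix",
    "Dendrogram",
    "average_linkage",
    "segregation_score",
]


def build_joint_matrix(expr_by_species: dict[str, pd.DataFrame],
                       orthologs: OrthologTable,
                       mode: str = "mrna",
                       classes_by_species: dict[str, pd.DataFrame] | None = None,
                       ) -> pd.DataFrame:
    """Ortholog-group x (species, tissue) expression matrix.

    ``expr_by_species`` maps species -> features x tissues tissue-mean
    matrix.  Modes: ``mrna`` keeps every complete 5-way group;
    ``panc_any`` keeps groups whose member is PARTNERED in at least one
    species; ``panc_conserved`` keeps groups PARTNERED in every species.
    Values are each species' own tissue means for its member gene; rows
    with any missing cell are dropped, so the matrix is complete.
    """
    species = sorted(expr_by_species)
    tissues = list(expr_by_species[species[0]].columns)
    for sp in species:
        missing = [t for t in tissues if t not in expr_by_species[sp].columns]
        if missing or len(expr_by_species[sp].columns) != len(tissues):
            raise ValueError(f"species {sp} is missing tissues: {missing}")
    groups = orthologs.complete_groups(species)
    if mode in ("panc_any", "panc_conserved"):
        if classes_by_species is None:
            raise ValueError(f"mode {mode} requires classes_by_species")
        klass = {sp: classes_by_species[sp].set_index("gene_id")["klass"]
                 for sp in species}
        flags = pd.DataFrame({
            sp: groups[sp].map(lambda g: klass[sp].get(g) == PARTNERED)
            for sp in species})
        keep = flags.any(axis=1) if mode == "panc_any" else flags.all(axis=1)
        groups = groups[keep]
    elif mode != "mrna":
        raise ValueError(f"unknown mode {mode!r}")

    cols = pd.MultiIndex.from_product([species, tissues],
                                      names=["species", "tissue"])
    out = pd.DataFrame(index=groups.index, columns=cols, dtype=float)
    for sp in species:
        expr = expr_by_species[sp]
        member = groups[sp]
        present = member.isin(expr.index)
        sub = expr.loc[member[present].to_numpy(), tissues].to_numpy()
        out.loc[present[present].index, sp] = sub
    out = out.dropna(axis=0)
    return out


def spearman_matrix(joint: pd.DataFrame) -> pd.DataFrame:
    """Mid-rank Spearman correlation between all sample columns."""
    if joint.shape[0] < 2:
        raise ValueError("need at least two features")
    ranks = joint.rank(axis=0, method="average").to_numpy(float)
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr[np.ix_(sd == 0, np.arange(sd.size))] = np.nan
    corr[np.ix_(np.arange(sd.size), sd == 0)] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=joint.columns, columns=joint.columns)


@dataclass
class _Node:
    height: float
    leaves: tuple[str, ...]
    children: tuple["_Node", ...] = ()

    def newick(self, parent_height: float | None = None) -> str:
        if not self.children:
            body = self.leaves[0]
        else:
            body = "(" + ",".join(
                c.newick(self.height) for c in
                sorted(self.children, key=lambda c: min(c.leaves))) + ")"
        if parent_height is None:
            return body + ";"
        return f"{body}:{parent_height - self.height:g}"


@dataclass
class Dendrogram:
    """Binary UPGMA merge tree; node heights are average-linkage
    distances (leaves at height 0)."""

    root: _Node
    labels: list[str]
    merges: list[tuple[frozenset, frozenset, float]]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        return self.root.newick()


def average_linkage(corr: pd.DataFrame) -> Dendrogram:
    """UPGMA on d = 1 - rho with deterministic tie-breaking.

    Ties in the minimum pairwise distance are broken by the
    lexicographically smallest pair of minimal leaf labels, so the tree
    is independent of input ordering.
    """
    if corr.isna().to_numpy().any():
        raise ValueError("correlation matrix contains undefined entries")
    labels = list(corr.index)
    d = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d[frozenset((a, b))] = 1.0 - float(corr.loc[a, b])
    clusters: dict[str, _Node] = {lab: _Node(0.0, (lab,)) for lab in labels}
    # cluster keys: minimal leaf label
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            dist[frozenset((a, b))] = d[frozenset((a, b))]
    merges = []
    while len(clusters) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0]))))
        (pair, h) = best
        a, b = sorted(pair)
        na, nb = clusters.pop(a), clusters.pop(b)
        merged = _Node(h, tuple(sorted(na.leaves + nb.leaves)), (na, nb))
        merges.append((frozenset(na.leaves), frozenset(nb.leaves), h))
        key = min(merged.leaves)
        sa, sb = len(na.leaves), len(nb.leaves)
        new_dist = {}
        for other in clusters:
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            new_dist[frozenset((key, other))] = (sa * da + sb * db) / (sa + sb)
        dist.pop(pair)
        dist.update(new_dist)
        clusters[key] = merged
    return Dendrogram(next(iter(clusters.values())), labels, merges)


def segregation_score(corr: pd.DataFrame, labels: pd.DataFrame) -> dict[str, float]:
    """Nearest-neighbour label agreement.

    ``labels`` is indexed by sample with columns ``species`` and
    ``tissue``.  For each sample the nearest neighbour is the other
    sample with the highest correlation (ties -> lexicographically first
    sample id).  Returns the fractions of samples whose neighbour shares
    the species / the tissue.
    """
    samples = list(corr.index)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if labels["species"].nunique() < 2 or labels["tissue"].nunique() < 2:
        raise ValueError("need at least two species and two tissues")
    by_species = by_tissue = 0
    for s in samples:
        row = corr.loc[s].drop(s)
        best = row[row == row.max()].index.min()
        by_species += labels.loc[best, "species"] == labels.loc[s, "species"]
        by_tissue += labels.loc[best, "tissue"] == labels.loc[s, "tissue"]
    n = len(samples)
    return {"by_species": by_species / n, "by_tissue": by_tissue / n}
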