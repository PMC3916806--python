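"""Community state typing: Ward clustering of community states and CST naming.

Community states (per-sample relative-abundance vectors) are grouped by
agglomerative hierarchical clustering with Ward linkage on a precomputed
Jensen-Shannon dissimilarity matrix, cut into ``k`` clusters (default 5).
Ward linkage on a non-Euclidean dissimilarity is formally heuristic; we
follow the convention standard in the CST literature and apply the
Lance-Williams Ward recurrence to the squared input dissimilarities (the
"ward.D2"-style reading), which is what scipy's ``linkage(..., 'ward')``
computes on a condensed distance matrix.

Clusters are then named by their centroid composition: a cluster dominated
by L. crispatus / L. gasseri / L. iners / L. jensenii becomes CST I / II /
III / V; of the remaining clusters the one with the larger combined
Atopobium + Gardnerella centroid share is IV-B and the rest IV-A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

from .divergence import DistanceMatrix, js_distance

__all__ = ["CSTModel", "ContingencyTable", "ward_cluster", "name_csts",
           "assign_nearest_cst", "cst_frequency_table"]

# centroid-dominance -> CST name, matched case-insensitively via aliases
LACTO_CST_NAMES = {
    "lactobacillus crispatus": "I",
    "lactobacillus gasseri": "II",
    "lactobacillus iners": "III",
    "lactobacillus jensenii": "V",
}
IVB_MARKERS = ("atopobium", "gardnerella")


@dataclass
class CSTModel:
    """Clustered (and optionally named) community state types.

    ``labels`` holds the integer cluster index per sample; after naming,
    ``cst_names`` maps cluster index -> CST name and ``centroids`` holds the
    per-cluster mean community state (rows sum to 1).
    """

    linkage_tree: np.ndarray            # scipy linkage matrix
    k: int
    labels: np.ndarray                  # per-sample cluster index, 0-based
    sample_ids: list[str]
    cst_names: dict[int, str] = field(default_factory=dict)
    centroids: pd.DataFrame | None = None   # cluster/CST x taxa

    @property
    def named(self) -> bool:
        return bool(self.cst_names)

    def label_names(self) -> list[str]:
        """Per-sample CST names (requires a named model)."""
        if not self.named:
            raise ValueError("model has no CST names; run name_csts first")
        return [self.cst_names[c] for c in self.labels]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"sample_id": self.sample_ids, "cluster": self.labels})
        if self.named:
            out["cst"] = self.label_names()
        return out

    def tree_newick(self) -> str:
        """Newick serialisation of the merge tree with sample-id leaves."""
        root = to_tree(self.linkage_tree)

        def render(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id].replace(" ", "_")
            left, right = node.get_left(), node.get_right()
            return (f"({render(left)}:{node.dist - left.dist:.6g},"
                    f"{render(right)}:{node.dist - right.dist:.6g})")

        return render(root) + ";"


def ward_cluster(dist: DistanceMatrix, k: int = 5) -> CSTModel:
    """Ward-linkage hierarchical clustering of a precomputed distance matrix."""
    n = len(dist)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    tree = linkage(dist.condensed(), method="ward")
    labels = fcluster(tree, t=k, criterion="maxclust") - 1
    return CSTModel(linkage_tree=tree, k=k, labels=labels, sample_ids=list(dist.ids))


def _centroids(model: CSTModel, states: pd.DataFrame) -> pd.DataFrame:
    """Mean community state of each cluster (rows indexed by cluster)."""
    states = states.loc[model.sample_ids]
    out = states.groupby(model.labels).mean()
    return out.div(out.sum(axis=1), axis=0)


def name_csts(model: CSTModel, states: pd.DataFrame,
              lacto_names: dict[str, str] | None = None) -> CSTModel:
    """Assign CST names (I, II, III, IV-A, IV-B, V) to a clustered model.

    ``states`` is the samples x taxa relative-abundance frame used for
    clustering.  Taxon names are matched case-insensitively against the
    alias map ``lacto_names`` (defaults to the four name-giving
    Lactobacillus species).
    """
    lacto_names = {k.lower(): v for k, v in (lacto_names or LACTO_CST_NAMES).items()}
    cents = _centroids(model, states)
    taxa_lower = [t.lower() for t in cents.columns]

    names: dict[int, str] = {}
    claimed: dict[str, int] = {}
    unnamed = []
    for cluster, row in cents.iterrows():
        top = taxa_lower[int(np.argmax(row.to_numpy()))]
        name = lacto_names.get(top)
        if name is None:
            unnamed.append(cluster)
        elif name in claimed:
            prev = claimed[name]
            # disambiguate by dominance of the shared top taxon
            if row.iloc[taxa_lower.index(top)] > cents.loc[prev].iloc[taxa_lower.index(top)]:
                warnings.warn(f"clusters {prev} and {cluster} both dominated by {top}; "
                              f"keeping name {name} on {cluster}", stacklevel=2)
                names[cluster] = name
                claimed[name] = cluster
                del names[prev]
                unnamed.append(prev)
            else:
                warnings.warn(f"clusters {prev} and {cluster} both dominated by {top}; "
                              f"keeping name {name} on {prev}", stacklevel=2)
                unnamed.append(cluster)
        else:
            names[cluster] = name
            claimed[name] = cluster

    if unnamed:
        marker_cols = [c for c, low in zip(cents.columns, taxa_lower)
                       if any(m in low for m in IVB_MARKERS)]
        share = cents.loc[unnamed, marker_cols].sum(axis=1) if marker_cols else \
            pd.Series(0.0, index=unnamed)
        ivb = share.idxmax() if len(unnamed) > 1 else unnamed[0]
        for cluster in unnamed:
            names[cluster] = "IV-B" if cluster == ivb and len(unnamed) > 1 else \
                ("IV-B" if len(unnamed) == 1 and share.loc[cluster] >= 0.2 else "IV-A")

    named_cents = cents.copy()
    named_cents.index = [names[c] for c in cents.index]
    return CSTModel(linkage_tree=model.linkage_tree, k=model.k, labels=model.labels,
                    sample_ids=model.sample_ids, cst_names=names, centroids=named_cents)


def assign_nearest_cst(state, model: CSTModel, log_base: float = 2.0) -> str:
    """CST label of the centroid nearest (JS distance) to a community state.

    Ties go to the lexicographically smallest label, with a warning.
    """
    if model.centroids is None:
        raise ValueError("model has no centroids; run name_csts first")
    state = np.asarray(state, dtype=float)
    if state.shape[0] != model.centroids.shape[1]:
        raise ValueError("state length does not match centroid taxa")
    dists = {name: js_distance(state, row.to_numpy(), log_base)
             for name, row in model.centroids.iterrows()}
    best = min(dists.values())
    winners = sorted(name for name, d in dists.items() if np.isclose(d, best, atol=1e-12))
    if len(winners) > 1:
        warnings.warn(f"state equidistant to CSTs {winners}; assigning {winners[0]}",
                      stacklevel=2)
    return winners[0]


@dataclass
class ContingencyTable:
    """CST x group sample counts with within-group percentages."""

    counts: pd.DataFrame        # cst x group
    percentages: pd.DataFrame   # within-group, one decimal

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        cells = self.counts.astype(str) + " (" + self.percentages.map(lambda v: f"{v:.1f}") + "%)"
        cells["Total"] = self.col_totals
        cells.T.to_csv(path, sep="\t", index_label="group")


def cst_frequency_table(labels, groups) -> ContingencyTable:
    """Cross-tabulate per-sample CST labels against study group.

    Percentages are within-group (each group's column sums to 100 up to
    rounding), printed to one decimal.
    """
    labels = list(labels)
    groups = list(groups)
    if len(labels) != len(groups):
        raise ValueError("labels and groups differ in length")
    if not labels:
        raise ValueError("empty input")
    counts = pd.crosstab(pd.Series(labels, name="cst"), pd.Series(groups, name="group"))
    counts = counts.sort_index()
    pct = (100.0 * counts / counts.sum(axis=0)).round(1)
    return ContingencyTable(counts=counts, percentages=pct)
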