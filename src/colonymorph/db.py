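"""Clustered colony database.

Builds the reference database against which new live colonies are
classified: standardize the selected parameters, run average-linkage
agglomerative clustering on the uncentred-correlation similarity,
prune the dendrogram at the no-correlation-test threshold, designate
major clusters, and order clusters into letter labels (A, B, ...).

The pruning threshold comes from inverting the test of no correlation:
with p selected parameters the critical Pearson r at two-sided level
alpha is r* = t* / sqrt(df + t*^2) with df = p - 2 and t* the Student-t
critical value.  For 27 parameters at alpha = 0.05 this gives
t* = 2.059539 and r* = 0.380863.  Clusters are the maximal subtrees
whose internal merge similarities all exceed r*, so every pair of
colonies joined inside a cluster passes the test of no correlation.

Major clusters are those containing strictly more than floor(0.05 * N)
colonies (more than 15 of 303); all others are minor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterTree",
    "ColonyDB",
    "standardize",
    "uncentred_correlation",
    "build_tree",
    "critical_r",
    "prune_tree",
    "designate_major",
    "order_clusters",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(
    matrix: np.ndarray,
    stats_: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Z-score each column (sample SD, ddof=1).

    When ``stats_`` (means, SDs) is supplied — e.g. when standardizing
    query colonies against the database — those statistics are applied
    unchanged.  Zero-SD columns raise, naming the offending column.
    """
    matrix = np.asarray(matrix, dtype=float)
    if stats_ is None:
        means = matrix.mean(axis=0)
        sds = matrix.std(axis=0, ddof=1)
    else:
        means, sds = (np.asarray(a, dtype=float) for a in stats_)
    bad = np.flatnonzero(sds <= _EPS)
    if bad.size:
        raise ValueError(f"zero-SD parameter at column(s) {bad.tolist()}")
    return (matrix - means) / sds, (means, sds)


def uncentred_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine-type similarity sum(x*y) / (||x|| * ||y||) in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("expected equal-length vectors of length >= 2")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx < _EPS or ny < _EPS:
        raise ValueError("zero-norm vector")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def _similarity_matrix(matrix: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(matrix, axis=1)
    if np.any(norms < _EPS):
        raise ValueError("zero-norm row in matrix")
    xn = matrix / norms[:, None]
    return np.clip(xn @ xn.T, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Average-linkage tree on uncentred-correlation distance
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    """Agglomerative dendrogram.

    ``merges`` lists (node_a, node_b, similarity) in agglomeration
    order; leaves are nodes 0..n-1, the k-th merge creates node n+k.
    Similarities are the average-linkage values actually used (1 minus
    the average pairwise uncentred-correlation distance).
    """

    merges: list[tuple[int, int, float]]
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + k: (a, b) for k, (a, b, _) in enumerate(self.merges)}

    def leaves_under(self, node: int) -> list[int]:
        kids = self.children()
        stack, out = [node], []
        while stack:
            cur = stack.pop()
            if cur < self.n_leaves:
                out.append(cur)
            else:
                stack.extend(kids[cur])
        return sorted(out)

    def to_newick(self) -> str:
        n = self.n_leaves
        reprs: dict[int, str] = {i: self.leaf_ids[i] for i in range(n)}
        heights: dict[int, float] = {i: 1.0 for i in range(n)}
        for k, (a, b, sim) in enumerate(self.merges):
            node = n + k
            h = sim
            ba = max(heights[a] - h, 0.0)
            bb = max(heights[b] - h, 0.0)
            reprs[node] = f"({reprs[a]}:{ba:.6f},{reprs[b]}:{bb:.6f})"
            heights[node] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return reprs[root] + ";"


def build_tree(matrix: np.ndarray, leaf_ids: list[str] | None = None) -> ClusterTree:
    """Average-linkage agglomeration on distance 1 - uncentred correlation.

    Lance–Williams update; ties in the minimum distance are broken by
    the lexicographically smallest (node_a, node_b) pair, node ids in
    creation order (leaves first), so the tree is fully deterministic.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least 2 colonies to build a tree")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    dist = 1.0 - _similarity_matrix(matrix)
    np.fill_diagonal(dist, np.inf)

    node_of = list(range(n))  # node id of each active row
    sizes = [1] * n
    active = list(range(n))  # active row indices into dist
    merges: list[tuple[int, int, float]] = []
    next_node = n
    for _ in range(n - 1):
        # Minimum-distance active pair; exact-equality ties broken by the
        # smallest (node_a, node_b) id pair.
        act = np.array(active)
        sub = dist[np.ix_(act, act)]
        iu = np.triu_indices(len(act), 1)
        vals = sub[iu]
        dmin = vals.min()
        ties = np.flatnonzero(vals == dmin)
        best = None
        for t in ties:
            i, j = act[iu[0][t]], act[iu[1][t]]
            na, nb = sorted((node_of[i], node_of[j]))
            if best is None or (na, nb) < best[:2]:
                best = (na, nb, i, j)
        na, nb, i, j = best
        merges.append((na, nb, 1.0 - float(dmin)))
        # Lance-Williams average-linkage update onto row i.
        si, sj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dist[i, k] = dist[k, i] = (si * dist[i, k] + sj * dist[j, k]) / (si + sj)
        sizes[i] = si + sj
        node_of[i] = next_node
        next_node += 1
        active.remove(j)
    return ClusterTree(merges=merges, leaf_ids=list(leaf_ids))


def critical_r(n_params: int, alpha: float = 0.05) -> float:
    """Pruning threshold from the test of no correlation.

    Two-sided Student-t critical value at level ``alpha`` with
    df = n_params - 2, converted to a correlation via
    r* = t* / sqrt(df + t*^2).  critical_r(27) = 0.380863.
    """
    if n_params < 3:
        raise ValueError("n_params must be >= 3 (df >= 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n_params - 2
    t_star = float(stats.t.ppf(1 - alpha / 2, df))
    return t_star / np.sqrt(df + t_star**2)


def prune_tree(tree: ClusterTree, r_threshold: float) -> dict[int, int]:
    """Cut the dendrogram at a correlation threshold.

    Clusters are the maximal subtrees whose internal merge similarities
    are all strictly greater than ``r_threshold``; every leaf receives
    exactly one integer label.  Labels are numbered by the smallest
    leaf index they contain.
    """
    if not -1.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must be in (-1, 1)")
    n = tree.n_leaves
    whole = {i: True for i in range(n)}
    for k, (a, b, sim) in enumerate(tree.merges):
        whole[n + k] = bool(sim > r_threshold and whole[a] and whole[b])
    # Roots: nodes that are never a child.
    child_nodes = {a for a, _, _ in tree.merges} | {b for _, b, _ in tree.merges}
    all_nodes = set(range(n)) | {n + k for k in range(len(tree.merges))}
    roots = sorted(all_nodes - child_nodes)
    kids = tree.children()
    clusters: list[list[int]] = []
    stack = list(roots)
    while stack:
        node = stack.pop()
        if whole[node]:
            clusters.append(tree.leaves_under(node))
        else:
            stack.extend(kids[node])
    clusters.sort(key=lambda leaves: leaves[0])
    labels: dict[int, int] = {}
    for lab, leaves in enumerate(clusters):
        for leaf in leaves:
            labels[leaf] = lab
    return labels


def designate_major(
    labels: dict, n_total: int, frac: float = 0.05
) -> tuple[list, list]:
    """Split cluster labels into (major, minor) by the >5% rule.

    A cluster is major iff its size strictly exceeds
    floor(frac * n_total); at n_total = 303 the threshold count is 15,
    so a 16-colony cluster is major and a 15-colony cluster is minor.
    """
    counts: dict = {}
    for lab in labels.values():
        counts[lab] = counts.get(lab, 0) + 1
    threshold = int(np.floor(frac * n_total + 1e-9))
    major = sorted(lab for lab, c in counts.items() if c > threshold)
    minor = sorted(lab for lab, c in counts.items() if c <= threshold)
    return major, minor


_LETTERS = "ABCDEFGHIJKLMNOPQRST"


def order_clusters(
    labels: dict[str, int],
    mean_area: dict[int, float],
    line_of: dict[str, str],
    reference_line: str,
    aberrant_line: str,
    major: list[int],
) -> dict[int, str]:
    """Order clusters into letter labels A..T.

    Composite key: (1) clusters whose within-line existence ratio is
    higher for the aberrant line than for the reference line come
    first; (2) major before minor; (3) descending mean colony area.
    More than 20 clusters is an error (the labelling stops at T).
    """
    cluster_ids = sorted(set(labels.values()))
    if len(cluster_ids) > len(_LETTERS):
        raise ValueError(
            f"{len(cluster_ids)} clusters exceed the A..T labelling range"
        )
    line_totals: dict[str, int] = {}
    for cid in labels:
        line = line_of.get(cid, "")
        line_totals[line] = line_totals.get(line, 0) + 1

    def ratio(cluster: int, line: str) -> float:
        total = line_totals.get(line, 0)
        if total == 0:
            return 0.0
        inside = sum(
            1
            for cid, lab in labels.items()
            if lab == cluster and line_of.get(cid, "") == line
        )
        return inside / total

    major_set = set(major)

    def key(cluster: int):
        enriched = ratio(cluster, aberrant_line) > ratio(cluster, reference_line)
        return (
            0 if enriched else 1,
            0 if cluster in major_set else 1,
            -mean_area.get(cluster, 0.0),
            cluster,
        )

    ordered = sorted(cluster_ids, key=key)
    return {cluster: _LETTERS[i] for i, cluster in enumerate(ordered)}


# ---------------------------------------------------------------------------
# The database object
# ---------------------------------------------------------------------------

@dataclass
class ColonyDB:
    """Colonies x selected-parameters reference database."""

    colony_ids: list[str]
    parameter_names: list[str]
    matrix: np.ndarray  # raw values, colonies x parameters
    standardization: tuple[np.ndarray, np.ndarray]  # (means, SDs)
    cluster_label_of: dict[str, str]  # colony_id -> letter label
    major_labels: list[str]
    provenance: dict = field(default_factory=dict)
    tree: ClusterTree | None = None

    @property
    def n_colonies(self) -> int:
        return len(self.colony_ids)

    def standardized_matrix(self) -> np.ndarray:
        z, _ = standardize(self.matrix, self.standardization)
        return z

    def standardize_query(self, vector: np.ndarray) -> np.ndarray:
        means, sds = self.standardization
        return (np.asarray(vector, dtype=float) - means) / sds

    def cluster_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.cluster_label_of.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return dict(sorted(sizes.items()))

    def line_existence_ratios(self, line_of: dict[str, str]) -> pd.DataFrame:
        """Per-line fraction of colonies falling in each cluster."""
        lines = sorted(set(line_of.values()))
        clusters = sorted(set(self.cluster_label_of.values()))
        out = pd.DataFrame(0.0, index=clusters, columns=lines)
        totals = {ln: 0 for ln in lines}
        for cid in self.colony_ids:
            totals[line_of[cid]] += 1
        for cid in self.colony_ids:
            out.loc[self.cluster_label_of[cid], line_of[cid]] += 1
        for ln in lines:
            if totals[ln]:
                out[ln] /= totals[ln]
        return out

    # -- persistence (directory of TSVs + provenance JSON) ------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.matrix, index=self.colony_ids, columns=self.parameter_names
        ).to_csv(d / "matrix.tsv", sep="\t", float_format="%.10g")
        means, sds = self.standardization
        pd.DataFrame(
            {"mean": means, "sd": sds}, index=self.parameter_names
        ).to_csv(d / "standardization.tsv", sep="\t", float_format="%.10g")
        labels = pd.DataFrame(
            {
                "cluster": [self.cluster_label_of[c] for c in self.colony_ids],
                "is_major": [
                    self.cluster_label_of[c] in self.major_labels
                    for c in self.colony_ids
                ],
            },
            index=self.colony_ids,
        )
        labels.to_csv(d / "labels.tsv", sep="\t")
        (d / "provenance.json").write_text(
            json.dumps(
                {**self.provenance, "major_labels": self.major_labels},
                indent=1,
                sort_keys=True,
                default=str,
            )
        )
        if self.tree is not None:
            (d / "tree.newick").write_text(self.tree.to_newick() + "\n")

    @staticmethod
    def load(directory) -> "ColonyDB":
        d = Path(directory)
        matrix = pd.read_csv(d / "matrix.tsv", sep="\t", index_col=0)
        std = pd.read_csv(d / "standardization.tsv", sep="\t", index_col=0)
        labels = pd.read_csv(d / "labels.tsv", sep="\t", index_col=0)
        prov = json.loads((d / "provenance.json").read_text())
        major = prov.pop("major_labels", [])
        return ColonyDB(
            colony_ids=[str(i) for i in matrix.index],
            parameter_names=list(matrix.columns),
            matrix=matrix.to_numpy(dtype=float),
            standardization=(
                std["mean"].to_numpy(dtype=float),
                std["sd"].to_numpy(dtype=float),
            ),
            cluster_label_of={
                str(i): str(lab) for i, lab in labels["cluster"].items()
            },
            major_labels=list(major),
            provenance=prov,
        )
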