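"""Expression-based validation of morphology clusters.

Statistical tail for single-colony expression profiles: per-colony
75th-percentile shift normalization, cluster-vs-rest differential
testing with Benjamini–Hochberg false-discovery control, fold-change
screens, uncentred-correlation expression clustering, and a principal
component projection.  A seedable synthetic expression generator
emulates the cluster-vs-rest spike structure so the whole tail runs
without real arrays.

Values are treated as log2-scale intensities throughout; fold changes
are reported on the linear scale after de-logging group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .db import ClusterTree, build_tree

__all__ = [
    "ExpressionMatrix",
    "DiffExpResult",
    "percentile_shift_normalize",
    "cluster_vs_rest",
    "fold_change_screen",
    "cluster_expression",
    "pca_project",
    "synth_expression",
    "marker_panel_report",
    "PLURIPOTENCY_MARKER_PANEL",
]

#: Default marker panel: canonical undifferentiated-state markers
#: (NANOG .. SSEA4) and early-differentiation markers (SSEA1, VIMENTIN).
PLURIPOTENCY_MARKER_PANEL = (
    "NANOG",
    "OCT-3/4",
    "SOX2",
    "C-MYC",
    "TRA-1-60",
    "SSEA4",
    "SSEA1",
    "VIMENTIN",
)

_EPS = 1e-12


@dataclass
class ExpressionMatrix:
    """Probes x colonies matrix of (log2) expression values."""

    probe_ids: list[str]
    colony_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.colony_ids)):
            raise ValueError("values shape does not match probe/colony ids")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not allowed")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.probe_ids, columns=self.colony_ids
        )

    @staticmethod
    def from_frame(frame: pd.DataFrame, normalized: bool = False) -> "ExpressionMatrix":
        return ExpressionMatrix(
            probe_ids=[str(i) for i in frame.index],
            colony_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            normalized=normalized,
        )


@dataclass
class DiffExpResult:
    probe_id: str
    mean_in: float
    mean_out: float
    fold_change: float  # linear-scale ratio in/out
    p_raw: float
    p_adjusted: float
    significant: bool


def percentile_shift_normalize(
    matrix: ExpressionMatrix, percentile: float = 75.0
) -> ExpressionMatrix:
    """Per-colony percentile shift on the log scale.

    Subtracts each colony's ``percentile``-th value (linear
    interpolation between order statistics) so every colony's
    percentile lands exactly at 0.  Constant columns are rejected.
    """
    vals = matrix.values
    col_sd = vals.std(axis=0)
    bad = np.flatnonzero(col_sd < _EPS)
    if bad.size:
        names = [matrix.colony_ids[i] for i in bad]
        raise ValueError(f"constant expression column(s): {names}")
    shifts = np.percentile(vals, percentile, axis=0, method="linear")
    return ExpressionMatrix(
        probe_ids=list(matrix.probe_ids),
        colony_ids=list(matrix.colony_ids),
        values=vals - shifts[None, :],
        normalized=True,
    )


def cluster_vs_rest(
    matrix: ExpressionMatrix,
    cluster_of: dict[str, str],
    target: str,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> list[DiffExpResult]:
    """Per-probe two-sample t-test of ``target`` colonies vs the rest.

    Welch's form by default (small, unbalanced single-colony groups);
    Benjamini–Hochberg adjustment across all tested probes; significance
    at adjusted p < ``alpha``.  Fold change is the linear-scale ratio of
    de-logged group means (values are log2).
    """
    in_cols = [i for i, c in enumerate(matrix.colony_ids) if cluster_of.get(c) == target]
    out_cols = [
        i
        for i, c in enumerate(matrix.colony_ids)
        if c in cluster_of and cluster_of[c] != target
    ]
    if len(in_cols) < 2 or len(out_cols) < 2:
        raise ValueError("each group needs at least 2 colonies")
    a = matrix.values[:, in_cols]
    b = matrix.values[:, out_cols]
    t_stat, p_raw = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    mean_in = a.mean(axis=1)
    mean_out = b.mean(axis=1)
    fold = 2.0 ** (mean_in - mean_out)
    return [
        DiffExpResult(
            probe_id=matrix.probe_ids[i],
            mean_in=float(mean_in[i]),
            mean_out=float(mean_out[i]),
            fold_change=float(fold[i]),
            p_raw=float(p_raw[i]),
            p_adjusted=float(p_adj[i]),
            significant=bool(reject[i]),
        )
        for i in range(len(matrix.probe_ids))
    ]


def fold_change_screen(
    results: list[DiffExpResult], min_fold: float
) -> tuple[list[DiffExpResult], list[DiffExpResult]]:
    """Partition significant probes by direction at |fold| > min_fold.

    Returns (higher, lower): significant probes with linear fold change
    > ``min_fold`` (higher in the target cluster) and < 1/``min_fold``
    (lower).  Screens at larger ``min_fold`` are nested within screens
    at smaller ``min_fold``.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must be > 1")
    sig = [r for r in results if r.significant]
    higher = [r for r in sig if r.fold_change > min_fold]
    lower = [r for r in sig if r.fold_change < 1.0 / min_fold]
    return higher, lower


def cluster_expression(
    matrix: ExpressionMatrix,
    probe_subset: list[str] | None = None,
    median_center: bool = False,
) -> ClusterTree:
    """Average-linkage (uncentred correlation) clustering of colonies.

    Same clustering engine as the colony database, applied to colony
    expression vectors restricted to ``probe_subset``.  Optional
    per-probe median centering mirrors a baseline shift.
    """
    if probe_subset is not None:
        if not probe_subset:
            raise ValueError("probe_subset must be non-empty")
        index = {p: i for i, p in enumerate(matrix.probe_ids)}
        rows = [index[p] for p in probe_subset]
        vals = matrix.values[rows]
    else:
        vals = matrix.values
    if median_center:
        vals = vals - np.median(vals, axis=1, keepdims=True)
    return build_tree(vals.T, leaf_ids=list(matrix.colony_ids))


def pca_project(
    matrix: ExpressionMatrix, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of colonies over all probes.

    Probe-centered SVD; returns (scores: colonies x k, explained
    variance fractions).  Sign convention: the largest-magnitude
    loading of each component is positive.  Identical colonies give
    all-zero scores and zero variance fractions.
    """
    x = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    if np.allclose(x, 0):
        k = min(n_components, len(matrix.colony_ids))
        return np.zeros((len(matrix.colony_ids), k)), np.zeros(k)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    total = float((s**2).sum())
    scores = (vt[:k].T * s[:k])  # colonies x k
    for j in range(k):
        lead = np.argmax(np.abs(u[:, j]))
        if u[lead, j] < 0:
            u[:, j] *= -1
            scores[:, j] *= -1
    fractions = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return scores, fractions


def marker_panel_report(
    matrix: ExpressionMatrix,
    cluster_of: dict[str, str],
    genes: tuple[str, ...] = PLURIPOTENCY_MARKER_PANEL,
) -> pd.DataFrame:
    """Per-cluster mean (log2) expression of a configurable marker panel.

    Probe ids are matched to gene names case-insensitively; genes absent
    from the matrix appear as all-NaN rows so the report always covers
    the requested panel.
    """
    index = {p.upper(): i for i, p in enumerate(matrix.probe_ids)}
    clusters = sorted(set(cluster_of.values()))
    cols = {
        lab: [j for j, c in enumerate(matrix.colony_ids) if cluster_of.get(c) == lab]
        for lab in clusters
    }
    rows = []
    for gene in genes:
        i = index.get(gene.upper())
        rows.append(
            [
                float(matrix.values[i, cols[lab]].mean())
                if i is not None and cols[lab]
                else float("nan")
                for lab in clusters
            ]
        )
    return pd.DataFrame(rows, index=list(genes), columns=clusters)


@dataclass
class SpikeTruth:
    spiked_probes: list[str] = field(default_factory=list)
    target_group: str = ""
    fold: float = 1.0


def synth_expression(
    n_probes: int,
    groups: dict[str, int],
    spike: tuple[int, float] = (100, 4.0),
    noise_sd: float = 0.5,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
) -> tuple[ExpressionMatrix, SpikeTruth]:
    """Synthetic log2 expression matrix with a cluster-vs-rest spike.

    Each probe gets a log-normal-style baseline; the first group listed
    in ``groups`` is the target and its colonies are shifted by
    +/- log2(fold) on ``n_spiked`` probes (alternating direction).
    Per-colony technical offsets are added so percentile normalization
    has work to do.  Deterministic given ``seed``.
    """
    n_spiked, fold = spike
    if n_probes <= 0 or n_spiked < 0 or fold <= 0 or noise_sd < 0:
        raise ValueError("invalid synthetic design parameters")
    if n_spiked > n_probes:
        raise ValueError("cannot spike more probes than exist")
    rng = np.random.default_rng(np.random.PCG64(seed))
    probe_ids = [f"probe_{i:05d}" for i in range(n_probes)]
    colony_ids, labels = [], []
    for g, n in groups.items():
        for i in range(n):
            colony_ids.append(f"{g}_{i:02d}")
            labels.append(g)
    target = next(iter(groups))
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_probes)
    vals = baseline[:, None] + noise_sd * rng.standard_normal(
        (n_probes, len(colony_ids))
    )
    spiked = list(rng.choice(n_probes, size=n_spiked, replace=False))
    shift = np.log2(fold)
    in_target = np.array([lab == target for lab in labels])
    for j, p in enumerate(spiked):
        sign = 1.0 if j % 2 == 0 else -1.0
        vals[p, in_target] += sign * shift
    # Per-colony technical offset (removed by percentile normalization).
    vals += rng.uniform(-1.0, 1.0, size=len(colony_ids))[None, :]
    matrix = ExpressionMatrix(
        probe_ids=probe_ids, colony_ids=colony_ids, values=vals
    )
    truth = SpikeTruth(
        spiked_probes=[probe_ids[p] for p in sorted(spiked)],
        target_group=target,
        fold=fold,
    )
    return matrix, truth
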