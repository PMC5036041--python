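"""Nearest-correlation classification of live colonies against the database.

A query colony's selected-parameter vector is standardized with the
database statistics and compared with every database colony by centered
Pearson correlation; the query inherits the cluster label of the single
best-matching colony (ties broken by database order).  Matching uses
Pearson r even though the database dendrogram uses uncentred
correlation — the two roles are deliberately kept distinct.

A nearest-centroid mode is available for robustness studies; no
rejection threshold is applied by default, but a minimum-r warning can
be enabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .db import ColonyDB
from .morphometrics import MorphProfile

__all__ = ["ClassificationResult", "classify_colony", "classify_batch"]

_EPS = 1e-12


@dataclass
class ClassificationResult:
    query_id: str
    best_match_colony_id: str | None
    best_r: float
    assigned_cluster: str | None
    is_major: bool
    runner_up: tuple[str | None, float]
    error: str | None = None


def _pearson_many(query: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Centered Pearson r of ``query`` against each row of ``rows``."""
    q = query - query.mean()
    qn = np.linalg.norm(q)
    if qn < _EPS:
        raise ValueError("zero-variance query vector")
    r = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(r, axis=1)
    norms[norms < _EPS] = np.nan  # constant DB row: correlation undefined
    vals = (r @ q) / (norms * qn)
    return np.nan_to_num(vals, nan=-np.inf)


def classify_colony(
    profile: MorphProfile | np.ndarray,
    db: ColonyDB,
    mode: str = "nearest",
    min_r_warning: float | None = None,
) -> ClassificationResult:
    """Assign the cluster of the highest-Pearson-correlation DB colony.

    ``profile`` may be a :class:`MorphProfile` (must contain every DB
    parameter; missing names raise with the parameter named) or an
    already-ordered raw vector.  ``mode='centroid'`` matches against
    per-cluster mean standardized vectors instead of single colonies.
    """
    if isinstance(profile, MorphProfile):
        query_id = profile.colony_id
        vector = profile.vector(db.parameter_names)
    else:
        query_id = "query"
        vector = np.asarray(profile, dtype=float)
        if vector.shape != (len(db.parameter_names),):
            raise ValueError("query vector length does not match DB parameters")
    zq = db.standardize_query(vector)
    zdb = db.standardized_matrix()

    if mode == "centroid":
        clusters = sorted(set(db.cluster_label_of.values()))
        centroids = np.array(
            [
                zdb[[db.cluster_label_of[c] == lab for c in db.colony_ids]].mean(axis=0)
                for lab in clusters
            ]
        )
        r = _pearson_many(zq, centroids)
        best = int(np.argmax(r))
        order = np.argsort(-r, kind="stable")
        runner = int(order[1]) if len(clusters) > 1 else best
        lab = clusters[best]
        return ClassificationResult(
            query_id=query_id,
            best_match_colony_id=None,
            best_r=float(r[best]),
            assigned_cluster=lab,
            is_major=lab in db.major_labels,
            runner_up=(clusters[runner], float(r[runner])),
        )
    if mode != "nearest":
        raise ValueError(f"unknown mode {mode!r}")

    r = _pearson_many(zq, zdb)
    best = int(np.argmax(r))  # argmax keeps the first (DB-order) tie
    order = np.argsort(-r, kind="stable")
    runner = int(order[1]) if len(r) > 1 else best
    best_id = db.colony_ids[best]
    lab = db.cluster_label_of[best_id]
    if min_r_warning is not None and r[best] < min_r_warning:
        warnings.warn(
            f"best match for {query_id} has r={r[best]:.3f} < {min_r_warning}",
            stacklevel=2,
        )
    return ClassificationResult(
        query_id=query_id,
        best_match_colony_id=best_id,
        best_r=float(r[best]),
        assigned_cluster=lab,
        is_major=lab in db.major_labels,
        runner_up=(db.colony_ids[runner], float(r[runner])),
    )


def classify_batch(
    profiles: list[MorphProfile],
    db: ColonyDB,
    mode: str = "nearest",
) -> tuple[list[ClassificationResult], dict]:
    """Classify a batch; per-colony errors become flagged rows.

    Returns the per-colony results (input order) and a summary with
    per-cluster counts and fractions, including the cluster-A fraction.
    """
    results: list[ClassificationResult] = []
    for p in profiles:
        try:
            results.append(classify_colony(p, db, mode=mode))
        except (ValueError, KeyError) as exc:
            results.append(
                ClassificationResult(
                    query_id=p.colony_id,
                    best_match_colony_id=None,
                    best_r=float("nan"),
                    assigned_cluster=None,
                    is_major=False,
                    runner_up=(None, float("nan")),
                    error=str(exc),
                )
            )
    counts: dict[str, int] = {}
    for res in results:
        if res.assigned_cluster is not None:
            counts[res.assigned_cluster] = counts.get(res.assigned_cluster, 0) + 1
    n_ok = sum(counts.values())
    fractions = {lab: c / n_ok for lab, c in counts.items()} if n_ok else {}
    summary = {
        "n": len(results),
        "n_classified": n_ok,
        "n_errors": len(results) - n_ok,
        "counts": dict(sorted(counts.items())),
        "fractions": dict(sorted(fractions.items())),
        "cluster_A_fraction": fractions.get("A", 0.0),
    }
    return results, summary
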