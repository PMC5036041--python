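"""End-to-end orchestration: images -> profiles -> database -> labels.

Convenience layer tying the modules together the way a screening run
would use them: train the texture recognizer on synthetic fixtures,
segment and profile every colony, build the clustered database with
the filter/threshold machinery, and classify held-out colonies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import synth
from .classifier import ClassificationResult, classify_batch
from .db import (
    ColonyDB,
    ClusterTree,
    build_tree,
    critical_r,
    designate_major,
    order_clusters,
    prune_tree,
    standardize,
)
from .morphometrics import (
    FilterReport,
    MorphProfile,
    apply_filters,
    compute_profile,
)
from .segment import SegmentationConfig, TextureModel, segment_image, train_texture_model

__all__ = [
    "train_default_texture_model",
    "training_scenes",
    "segment_and_profile",
    "profile_scenes",
    "build_colony_db",
    "TwoPopulationStudy",
    "run_two_population_study",
    "classification_accuracy",
    "run_rotation_study",
]

#: Line ids used for synthetic two-population studies: the reference
#: line produces esc_like colonies, the aberrant line collapsed-edge
#: colonies (mirroring a healthy parent line and its aberrant subclone).
REFERENCE_LINE = "parent"
ABERRANT_LINE = "subclone"
_LINE_OF_CLASS = {"esc_like": REFERENCE_LINE, "collapsed_edge": ABERRANT_LINE}


def training_scenes(
    seed: int, n_scenes: int = 6, image_size: tuple[int, int] = (512, 512)
) -> list[tuple[np.ndarray, "synth.GroundTruth"]]:
    """Small single-colony scenes with ground truth for texture training."""
    rng = np.random.default_rng(np.random.PCG64(seed).jumped(11))
    scenes = []
    for i in range(n_scenes):
        morph_class = "esc_like" if i % 2 == 0 else "collapsed_edge"
        edge = 0.04 if morph_class == "esc_like" else rng.uniform(0.25, 0.38)
        colony = synth.ColonySpec(
            center_px=(
                image_size[0] / 2 + rng.uniform(-10, 10),
                image_size[1] / 2 + rng.uniform(-10, 10),
            ),
            base_radius_px=rng.uniform(120, 170),
            edge_irregularity=edge,
            fibrousness=0.0 if morph_class == "esc_like" else rng.uniform(4, 8),
            halo_strength=45.0 if morph_class == "esc_like" else 20.0,
            interior_texture_sd=6.0 if morph_class == "esc_like" else 11.0,
            morph_class=morph_class,
        )
        spec = synth.SceneSpec(
            image_size_px=image_size,
            colonies=(colony,),
            debris_count=0,
            background_gradient_amplitude=10.0,
            noise_sd=3.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scenes.append(synth.render_scene(spec))
    return scenes


def train_default_texture_model(
    seed: int,
    n_candidates: int = 50,
    cfg: SegmentationConfig | None = None,
) -> TextureModel:
    """Train the texture recognizer on synthetic ground-truth fixtures."""
    scenes = training_scenes(seed)
    images = [img for img, _ in scenes]
    masks = [gt.label_image > 0 for _, gt in scenes]
    return train_texture_model(
        images, masks, n_candidates=n_candidates, seed=seed, cfg=cfg
    )


def segment_and_profile(
    image: np.ndarray,
    model: TextureModel,
    cfg: SegmentationConfig | None = None,
    image_id: str = "",
    um_per_px: float = 2.0,
    mature_only: bool = True,
) -> list[MorphProfile]:
    """Segment one image and profile every emitted colony."""
    colonies = segment_image(
        image, model, cfg, image_id=image_id, um_per_px=um_per_px,
        mature_only=mature_only,
    )
    return [compute_profile(c, image, um_per_px=um_per_px) for c in colonies]


def profile_scenes(
    scenes: list[tuple[np.ndarray, "synth.GroundTruth"]],
    model: TextureModel,
    cfg: SegmentationConfig | None = None,
    um_per_px: float = 2.0,
    id_prefix: str = "scene",
) -> list[MorphProfile]:
    """Profile single-colony benchmark scenes, carrying class/line truth.

    Each scene is expected to contain one mature colony; if several
    objects survive the gates, the largest is taken.  Scenes where
    recognition finds nothing are skipped (the caller can compare
    counts).
    """
    profiles: list[MorphProfile] = []
    for i, (image, gt) in enumerate(scenes):
        image_id = f"{id_prefix}{i:03d}"
        got = segment_and_profile(image, model, cfg, image_id, um_per_px)
        if not got:
            continue
        best = max(got, key=lambda p: p.values["area_px"])
        true_class = gt.class_of_label.get(1, "")
        best.true_class = true_class
        best.line_id = _LINE_OF_CLASS.get(true_class, "")
        best.colony_id = image_id
        profiles.append(best)
    return profiles


def build_colony_db(
    profiles: list[MorphProfile],
    line_of: dict[str, str] | None = None,
    reference_line: str = REFERENCE_LINE,
    aberrant_line: str = ABERRANT_LINE,
    alpha: float = 0.05,
    r_max: float = 0.98,
    cv_max: float = 30.0,
    include_border: bool = False,
    scale: bool = True,
) -> tuple[ColonyDB, ClusterTree, FilterReport]:
    """Build the clustered colony database from full-panel profiles.

    Applies the correlation filter then the CV filter, drops any
    residual zero-variance parameters, standardizes (optional),
    clusters with average linkage on uncentred correlation, prunes at
    the no-correlation-test threshold for the surviving parameter
    count, designates major clusters and assigns letter labels.
    """
    profiles = [p for p in profiles if include_border or not p.border]
    if len(profiles) < 3:
        raise ValueError("need at least 3 non-border profiles")
    if line_of is None:
        line_of = {p.colony_id: p.line_id for p in profiles}
    report = apply_filters(profiles, r_max=r_max, cv_max=cv_max)
    ids = [p.colony_id for p in profiles]
    raw = np.array(
        [[p.values[n] for n in report.kept] for p in profiles], dtype=float
    )
    # Reject residual constants (zero sample SD) before standardization.
    sds = raw.std(axis=0, ddof=1)
    keep_cols = np.flatnonzero(sds > 1e-12)
    names = [report.kept[i] for i in keep_cols]
    raw = raw[:, keep_cols]
    if len(names) < 3:
        raise ValueError("fewer than 3 informative parameters survive filtering")
    z, stats_ = standardize(raw) if scale else (raw, (raw.mean(0), raw.std(0, ddof=1)))
    tree = build_tree(z, leaf_ids=ids)
    r_star = critical_r(len(names), alpha=alpha)
    leaf_labels = prune_tree(tree, r_star)
    int_label_of = {ids[leaf]: lab for leaf, lab in leaf_labels.items()}
    major_int, _ = designate_major(int_label_of, len(ids))
    mean_area: dict[int, float] = {}
    for p in profiles:
        lab = int_label_of[p.colony_id]
        mean_area.setdefault(lab, 0.0)
    sums: dict[int, list[float]] = {}
    for p in profiles:
        sums.setdefault(int_label_of[p.colony_id], []).append(p.values["area_px"])
    mean_area = {lab: float(np.mean(v)) for lab, v in sums.items()}
    letter_of = order_clusters(
        int_label_of, mean_area, line_of, reference_line, aberrant_line, major_int
    )
    cluster_label_of = {cid: letter_of[lab] for cid, lab in int_label_of.items()}
    db = ColonyDB(
        colony_ids=ids,
        parameter_names=names,
        matrix=raw,
        standardization=stats_,
        cluster_label_of=cluster_label_of,
        major_labels=sorted(letter_of[lab] for lab in major_int),
        provenance={
            "alpha": alpha,
            "r_threshold": r_star,
            "n_parameters": len(names),
            "r_max": r_max,
            "cv_max": cv_max,
            "scaled": scale,
            "reference_line": reference_line,
            "aberrant_line": aberrant_line,
            "line_of": line_of,
            "dropped_correlated": [list(map(str, t)) for t in report.dropped_correlated],
            "dropped_high_cv": [[d, float(c)] for d, c in report.dropped_high_cv],
        },
        tree=tree,
    )
    return db, tree, report


def cluster_class_map(db: ColonyDB) -> dict[str, str]:
    """Majority true-line class of each DB cluster (for benchmarks)."""
    line_of = db.provenance.get("line_of", {})
    votes: dict[str, dict[str, int]] = {}
    for cid, lab in db.cluster_label_of.items():
        line = line_of.get(cid, "")
        votes.setdefault(lab, {}).setdefault(line, 0)
        votes[lab][line] += 1
    return {
        lab: max(sorted(v), key=lambda k: v[k]) for lab, v in votes.items()
    }


def classification_accuracy(
    results: list[ClassificationResult],
    true_lines: list[str],
    db: ColonyDB,
) -> float:
    """Fraction of queries whose assigned cluster's majority line matches."""
    cmap = cluster_class_map(db)
    ok = 0
    for res, truth in zip(results, true_lines):
        if res.assigned_cluster is not None and cmap.get(res.assigned_cluster) == truth:
            ok += 1
    return ok / len(results) if results else 0.0


@dataclass
class TwoPopulationStudy:
    """Everything the two-population benchmark produces."""

    model: TextureModel
    db: ColonyDB
    tree: ClusterTree
    report: FilterReport
    db_profiles: list[MorphProfile]
    holdout_profiles: list[MorphProfile] = field(default_factory=list)
    holdout_results: list[ClassificationResult] = field(default_factory=list)
    holdout_accuracy: float = float("nan")


def run_rotation_study(
    db: ColonyDB,
    model: TextureModel,
    n_colonies: int = 15,
    effect: float = 1.0,
    seed: int = 42,
    cfg: SegmentationConfig | None = None,
) -> dict:
    """Re-imaging reproducibility: classify colonies before and after a
    half-turn plate rotation.

    Renders ``n_colonies`` fresh single-colony scenes, classifies each
    against ``db``, then re-renders the same scenes rotated 180 degrees
    with freshly drawn pixel noise (a physically rotated plate is a new
    exposure) and classifies again.  Returns the per-colony labels and
    the concordance count.
    """
    n_per_class = (n_colonies + 1) // 2
    specs = synth.make_two_population_scene_specs(n_per_class, effect, seed)[:n_colonies]
    original, rotated = [], []
    for i, spec in enumerate(specs):
        image, gt = synth.render_scene(spec)
        rot_image, _ = synth.render_rotated(spec, half_turn=True)
        original.append((image, gt))
        rotated.append((rot_image, gt))
    prof_orig = profile_scenes(original, model, cfg, id_prefix="orig")
    prof_rot = profile_scenes(rotated, model, cfg, id_prefix="rot")
    res_orig, _ = classify_batch(prof_orig, db)
    res_rot, _ = classify_batch(prof_rot, db)
    by_scene_orig = {r.query_id[-3:]: r.assigned_cluster for r in res_orig}
    by_scene_rot = {r.query_id[-3:]: r.assigned_cluster for r in res_rot}
    pairs = {
        k: (by_scene_orig.get(k), by_scene_rot.get(k))
        for k in sorted(set(by_scene_orig) | set(by_scene_rot))
    }
    n_same = sum(1 for a, b in pairs.values() if a is not None and a == b)
    return {
        "n_colonies": n_colonies,
        "n_recognized": len(pairs),
        "n_same_cluster": n_same,
        "assignments": pairs,
    }


def run_two_population_study(
    n_per_class: int = 20,
    effect: float = 1.0,
    seed: int = 0,
    holdout: bool = True,
    model: TextureModel | None = None,
    cfg: SegmentationConfig | None = None,
) -> TwoPopulationStudy:
    """Full pipeline on the two-population benchmark.

    Builds a database from one benchmark draw and (optionally)
    classifies an independent draw against it, scoring accuracy by
    cluster-majority line.
    """
    if model is None:
        model = train_default_texture_model(seed)
    scenes = synth.make_two_population_benchmark(n_per_class, effect, seed)
    profiles = profile_scenes(scenes, model, cfg, id_prefix="db")
    db, tree, report = build_colony_db(profiles)
    study = TwoPopulationStudy(
        model=model, db=db, tree=tree, report=report, db_profiles=profiles
    )
    if holdout:
        ho_scenes = synth.make_two_population_benchmark(
            n_per_class, effect, seed + 1000003
        )
        ho_profiles = profile_scenes(ho_scenes, model, cfg, id_prefix="ho")
        results, _ = classify_batch(ho_profiles, db)
        study.holdout_profiles = ho_profiles
        study.holdout_results = results
        study.holdout_accuracy = classification_accuracy(
            results, [p.line_id for p in ho_profiles], db
        )
    return study
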