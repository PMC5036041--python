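"""Classify new live colonies against the colony database.

Builds a database from one benchmark draw, then classifies an
independent draw by nearest Pearson correlation: each query colony
inherits the cluster of its single best-matching database colony.
The cluster-A fraction is the screening readout for the unstable,
partially differentiated phenotype.
"""

import colonymorph as cm
from colonymorph.classifier import classify_batch
from colonymorph.pipeline import (
    build_colony_db,
    classification_accuracy,
    profile_scenes,
    train_default_texture_model,
)

model = train_default_texture_model(seed=7)
db_scenes = cm.make_two_population_benchmark(8, effect=1.0, seed=1)
db, _, _ = build_colony_db(profile_scenes(db_scenes, model, id_prefix="db"))

new_scenes = cm.make_two_population_benchmark(4, effect=1.0, seed=2)
queries = profile_scenes(new_scenes, model, id_prefix="live")
results, summary = classify_batch(queries, db)

for res in results:
    print(f"{res.query_id}: cluster {res.assigned_cluster} "
          f"(best match {res.best_match_colony_id}, r = {res.best_r:.3f}; "
          f"runner-up r = {res.runner_up[1]:.3f})")
print("per-cluster counts:", summary["counts"])
print(f"cluster-A fraction: {summary['cluster_A_fraction']:.2f} "
      "(the screening readout for unhealthy colonies)")
acc = classification_accuracy(results, [q.line_id for q in queries], db)
print(f"agreement with true phenotype: {acc:.2f}")
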