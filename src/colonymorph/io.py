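"""Reading and writing images and tables."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .morphometrics import MorphProfile, PANEL_FAMILIES
from .segment import ColonyObject
from .synth import GroundTruth

__all__ = [
    "read_image",
    "write_image",
    "write_ground_truth",
    "write_colony_table",
    "write_profiles",
    "read_profiles",
]


def read_image(path) -> np.ndarray:
    """8-bit grayscale PNG -> 2-D uint8 array."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img.astype(np.uint8)


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, image.astype(np.uint8))


def write_ground_truth(directory, stem: str, gt: GroundTruth) -> None:
    """16-bit label PNG plus a sidecar TSV of per-label specs."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    iio.imwrite(d / f"{stem}_labels.png", gt.label_image.astype(np.uint16))
    rows = []
    for label, spec in enumerate(gt.specs, start=1):
        row = {"label": label, "morph_class": gt.class_of_label.get(label, "")}
        row.update(
            {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(spec).items()
                if k != "morph_class"
            }
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(d / f"{stem}_truth.tsv", sep="\t", index=False)


def write_colony_table(path, colonies: list[ColonyObject], um_per_px: float = 2.0) -> None:
    rows = [
        {
            "image_id": c.source_image_id,
            "label": c.label,
            "area_px": c.area_px,
            "centroid_row": c.centroid_px[0],
            "centroid_col": c.centroid_px[1],
            "equivalent_diameter_um": c.equivalent_diameter_um(um_per_px),
        }
        for c in colonies
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_profiles(path, profiles: list[MorphProfile]) -> None:
    """Profiles as a TSV with a family header row."""
    if not profiles:
        raise ValueError("no profiles to write")
    names = list(profiles[0].values)
    frame = pd.DataFrame(
        [[p.values[n] for n in names] for p in profiles],
        index=[p.colony_id for p in profiles],
        columns=names,
    )
    frame.insert(0, "line_id", [p.line_id for p in profiles])
    frame.insert(1, "border", [p.border for p in profiles])
    with open(path, "w") as fh:
        families = [profiles[0].family_of.get(n, "") for n in names]
        # one field for the index column, two for line_id/border
        fh.write("\t".join(["#family", "", ""] + families) + "\n")
        frame.to_csv(fh, sep="\t", float_format="%.10g")


def read_profiles(path) -> list[MorphProfile]:
    with open(path) as fh:
        first = fh.readline()
        families = first.rstrip("\n").split("\t")[1:] if first.startswith("#family") else None
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    names = [c for c in frame.columns if c not in ("line_id", "border")]
    if families is not None:
        fam_of = dict(zip(["line_id", "border"] + names, families))
    else:
        fam_of = {}
    out = []
    for idx, row in frame.iterrows():
        out.append(
            MorphProfile(
                colony_id=str(idx),
                values={n: float(row[n]) for n in names},
                family_of={
                    n: fam_of.get(n) or PANEL_FAMILIES.get(n, "volume") for n in names
                },
                border=bool(row.get("border", False)),
                line_id=str(row.get("line_id", "") or ""),
            )
        )
    return out
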