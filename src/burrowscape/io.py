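"""Readers and writers for the package's file interfaces.

Points go to GeoJSON (Point features with a ``species`` property) and
CSV (``x, y, species``); plots to CSV/GeoJSON; rasters to single-band
TIFF with an ESRI world-file (``.tfw``) sidecar carrying the affine
geotransform; truth/prediction boxes to COCO-style JSON (``images`` /
``annotations`` with ``[x, y, width, height]`` pixel boxes, category
``mound``); regions to GeoJSON MultiPolygon.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping

from .detect_eval import DetectionBox
from .rangekde import GridRegion
from .types import PointSet2D, SamplePlot, Zone

__all__ = [
    "write_points_csv", "read_points_csv",
    "write_points_geojson", "read_points_geojson",
    "write_plots_csv", "read_plots_csv",
    "write_raster_tiff", "read_raster_tiff",
    "write_boxes_coco", "read_boxes_coco",
    "write_region_geojson",
]


def write_points_csv(path: str | Path, points: PointSet2D) -> None:
    pd.DataFrame({"x": points.x, "y": points.y, "species": points.label}).to_csv(
        path, index=False
    )


def read_points_csv(path: str | Path) -> PointSet2D:
    df = pd.read_csv(path)
    label = str(df["species"].iloc[0]) if len(df) and "species" in df else "point"
    return PointSet2D(df[["x", "y"]].to_numpy(dtype=float), label=label)


def write_points_geojson(path: str | Path, points: PointSet2D) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"species": points.label},
        }
        for x, y in points.xy
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_points_geojson(path: str | Path) -> PointSet2D:
    data = json.loads(Path(path).read_text())
    coords, label = [], "point"
    for f in data.get("features", []):
        coords.append(f["geometry"]["coordinates"][:2])
        label = f.get("properties", {}).get("species", label)
    return PointSet2D(np.asarray(coords, dtype=float).reshape(-1, 2), label=label)


def write_plots_csv(path: str | Path, plots: Sequence[SamplePlot]) -> None:
    pd.DataFrame(
        {
            "x": [p.x for p in plots],
            "y": [p.y for p in plots],
            "radius_m": [p.radius for p in plots],
            "zone": [p.zone.value for p in plots],
            "year": [p.year for p in plots],
            "presence": [p.presence if p.presence is not None else "" for p in plots],
        }
    ).to_csv(path, index=False)


def read_plots_csv(path: str | Path) -> list[SamplePlot]:
    df = pd.read_csv(path)
    plots = []
    for _, r in df.iterrows():
        pres = r.get("presence")
        presence = None if pres is None or (isinstance(pres, float) and np.isnan(pres)) or pres == "" else int(pres)
        plots.append(
            SamplePlot(float(r["x"]), float(r["y"]), float(r["radius_m"]),
                       Zone(r["zone"]), int(r["year"]), presence)
        )
    return plots


def write_raster_tiff(
    path: str | Path,
    image: np.ndarray,
    geotransform: Optional[tuple[float, float, float, float, float, float]] = None,
) -> None:
    """Write a single-band TIFF; the geotransform goes to a ``.tfw`` sidecar.

    The world file holds, one value per line: pixel x size, row rotation,
    column rotation, negative pixel y size, and the world coordinates of
    the centre of the top-left pixel.
    """
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    if geotransform is not None:
        x0, dx, _, y0, _, dy = geotransform
        lines = [dx, 0.0, 0.0, dy, x0 + dx / 2, y0 + dy / 2]
        path.with_suffix(".tfw").write_text("\n".join(f"{v:.10f}" for v in lines) + "\n")


def read_raster_tiff(path: str | Path):
    path = Path(path)
    img = tifffile.imread(path)
    tfw = path.with_suffix(".tfw")
    gt = None
    if tfw.exists():
        dx, _, _, dy, cx, cy = [float(v) for v in tfw.read_text().split()]
        gt = (cx - dx / 2, dx, 0.0, cy - dy / 2, 0.0, dy)
    return img, gt


def write_boxes_coco(
    path: str | Path,
    per_image: Sequence[tuple[str, Sequence[DetectionBox]]],
) -> None:
    """Write boxes as COCO-style JSON: one record per (image name, boxes)."""
    images, annotations = [], []
    ann_id = 1
    for img_id, (name, boxes) in enumerate(per_image, start=1):
        images.append({"id": img_id, "file_name": name})
        for b in boxes:
            ann = {
                "id": ann_id,
                "image_id": img_id,
                "category_id": 1,
                "bbox": [b.xmin, b.ymin, b.xmax - b.xmin, b.ymax - b.ymin],
                "area": b.area,
            }
            if b.score is not None:
                ann["score"] = b.score
            annotations.append(ann)
            ann_id += 1
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": "mound"}],
    }
    Path(path).write_text(json.dumps(payload))


def read_boxes_coco(path: str | Path) -> dict[str, list[DetectionBox]]:
    data = json.loads(Path(path).read_text())
    names = {img["id"]: img["file_name"] for img in data["images"]}
    out: dict[str, list[DetectionBox]] = {n: [] for n in names.values()}
    for ann in data["annotations"]:
        x, y, w, h = ann["bbox"]
        out[names[ann["image_id"]]].append(
            DetectionBox(x, y, x + w, y + h, score=ann.get("score"))
        )
    return out


def write_region_geojson(path: str | Path, region: GridRegion, properties: Optional[dict] = None) -> None:
    geom = mapping(region.to_polygons())
    feature = {
        "type": "Feature",
        "geometry": geom,
        "properties": {"area_ha": region.area_ha, **(properties or {})},
    }
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": [feature]}))
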