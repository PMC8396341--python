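"""On-disk formats: annotation CSV / VIA-2 JSON, manifests, density maps.

Annotations travel as CSV with header ``tile_id,x,y`` or as VIA-2
compatible JSON point regions; fractional coordinates are preserved in
both directions.  Write-then-read is the identity on valid files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "read_annotations_csv",
    "write_annotations_csv",
    "read_annotations_via",
    "write_annotations_via",
    "write_manifest_csv",
    "read_manifest_csv",
    "save_density_map",
    "load_density_map",
    "save_tile_png",
    "write_predictions_csv",
    "read_predictions_csv",
]

_CSV_HEADER = "tile_id,x,y"


def write_annotations_csv(annotations: dict[str, np.ndarray], path) -> None:
    """``annotations`` maps tile_id -> (n, 2) array of (x, y)."""
    lines = [_CSV_HEADER]
    for tile_id in annotations:
        for x, y in np.asarray(annotations[tile_id]).reshape(-1, 2):
            lines.append(f"{tile_id},{float(x)!r},{float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations_csv(path) -> dict[str, np.ndarray]:
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != _CSV_HEADER:
        raise ValueError(f"{path}: expected header '{_CSV_HEADER}'")
    out: dict[str, list] = {}
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
        tile_id, xs, ys = parts
        try:
            x, y = float(xs), float(ys)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
        out.setdefault(tile_id, []).append((x, y))
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}


def write_annotations_via(annotations: dict[str, np.ndarray], path) -> None:
    """VIA-2 project export: one file entry per tile, point regions."""
    payload = {}
    for tile_id, pts in annotations.items():
        fname = f"{tile_id}.png"
        regions = [
            {
                "shape_attributes": {"name": "point", "cx": float(x), "cy": float(y)},
                "region_attributes": {},
            }
            for x, y in np.asarray(pts).reshape(-1, 2)
        ]
        payload[f"{fname}-1"] = {
            "filename": fname,
            "size": -1,
            "regions": regions,
            "file_attributes": {},
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations_via(path) -> dict[str, np.ndarray]:
    data = json.loads(Path(path).read_text())
    if "_via_img_metadata" in data:  # full project file
        data = data["_via_img_metadata"]
    out = {}
    for entry in data.values():
        tile_id = Path(entry["filename"]).stem
        pts = []
        for region in entry.get("regions", []):
            sa = region["shape_attributes"]
            if sa.get("name") != "point":
                continue
            pts.append((float(sa["cx"]), float(sa["cy"])))
        out[tile_id] = np.asarray(pts, dtype=float).reshape(-1, 2)
    return out


def write_manifest_csv(manifest, path) -> None:
    manifest.to_frame().to_csv(path, index=False)


def read_manifest_csv(path):
    import pandas as pd

    return pd.read_csv(path)


def save_density_map(dm, path) -> None:
    """Documented container: NumPy ``.npz`` with values + parameters."""
    np.savez(path, values=dm.values, d=dm.d, sigma=dm.sigma, side=dm.side)


def load_density_map(path):
    from .density import DensityMap

    with np.load(path) as z:
        return DensityMap(
            values=z["values"], d=float(z["d"]), sigma=float(z["sigma"]), side=int(z["side"])
        )


def save_tile_png(tile, path) -> None:
    from PIL import Image

    Image.fromarray(tile.image).save(path)


def write_predictions_csv(rows, path) -> None:
    """``rows``: iterables of (tile_id, x, y, component_area, peak_value)."""
    lines = ["tile_id,x,y,component_area,peak_value"]
    for tile_id, x, y, area, peak in rows:
        lines.append(f"{tile_id},{float(x)!r},{float(y)!r},{int(area)},{float(peak)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictions_csv(path) -> dict[str, np.ndarray]:
    import pandas as pd

    df = pd.read_csv(path)
    out = {}
    for tile_id, grp in df.groupby("tile_id"):
        out[str(tile_id)] = grp[["x", "y"]].to_numpy(dtype=float)
    return out
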