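"""Scan and table I/O: PLY/OBJ point clouds, JSON landmark sidecars, CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .cohort import LabeledScan

__all__ = ["save_scan", "load_scan", "save_landmarks", "load_landmarks"]


def save_landmarks(scan_or_dict, path: str | Path) -> None:
    if isinstance(scan_or_dict, LabeledScan):
        payload = scan_or_dict.landmarks
    else:
        payload = dict(scan_or_dict)
    Path(path).write_text(json.dumps(payload))


def load_landmarks(path: str | Path) -> dict[str, float]:
    payload = json.loads(Path(path).read_text())
    return {"neck_height_mm": float(payload["neck_height_mm"]),
            "buttock_height_mm": float(payload["buttock_height_mm"])}


def save_scan(scan: LabeledScan, path: str | Path,
              sidecar: str | Path | None = None) -> None:
    """Write the point cloud (binary PLY via trimesh, or vertex-list OBJ)
    with its JSON landmark sidecar (default: same stem + ``.landmarks.json``)."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        trimesh.PointCloud(scan.points_mm).export(path)
    elif path.suffix.lower() == ".obj":
        with open(path, "w") as fh:
            fh.write(f"# torsoshape point cloud, subject {scan.subject_id}\n")
            np.savetxt(fh, scan.points_mm, fmt="v %.4f %.4f %.4f")
    else:
        raise ValueError(f"unsupported scan format {path.suffix!r}")
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".landmarks.json")
    save_landmarks(scan, sidecar)


def load_scan(path: str | Path, subject_id: int = -1,
              sidecar: str | Path | None = None) -> LabeledScan:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        cloud = trimesh.load(path, process=False)
        points = np.asarray(cloud.vertices, dtype=float)
    elif path.suffix.lower() == ".obj":
        rows = []
        for line in path.read_text().splitlines():
            if line.startswith("v "):
                rows.append([float(tok) for tok in line.split()[1:4]])
        points = np.asarray(rows, dtype=float)
    else:
        raise ValueError(f"unsupported scan format {path.suffix!r}")
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".landmarks.json")
    lm = load_landmarks(sidecar)
    return LabeledScan(points_mm=points, neck_height_mm=lm["neck_height_mm"],
                       buttock_height_mm=lm["buttock_height_mm"],
                       subject_id=subject_id)
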