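"""File I/O: TIFF stacks with a calibration sidecar, CSV tables, manifests."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .foci import Focus
from .lineage import CellTrack, DivisionEvent
from .render import ImageStack
from .segmentation import CellMask

__all__ = [
    "write_stack", "read_stack", "write_truth", "read_truth",
    "write_masks", "write_cells_csv", "write_foci_csv",
    "write_lineage_csvs", "write_histogram_csv", "write_manifest",
]

META_NAME = "stack_meta.json"


def write_stack(stack: ImageStack, out_dir: str | Path) -> None:
    """Write one multi-frame grayscale TIFF per channel plus a JSON sidecar
    holding the pixel size and frame interval."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "phase.tif", stack.phase)
    tifffile.imwrite(out / "fluor.tif", stack.fluor)
    with open(out / META_NAME, "w") as fh:
        json.dump({"pixel_size": stack.pixel_size,
                   "frame_interval": stack.frame_interval}, fh, indent=1)


def read_stack(in_dir: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack`."""
    src = Path(in_dir)
    for name in ("phase.tif", "fluor.tif", META_NAME):
        if not (src / name).exists():
            raise FileNotFoundError(f"missing {name} in {src}")
    phase = tifffile.imread(src / "phase.tif")
    fluor = tifffile.imread(src / "fluor.tif")
    if phase.ndim == 2:
        phase = phase[None]
    if fluor.ndim == 2:
        fluor = fluor[None]
    with open(src / META_NAME) as fh:
        meta = json.load(fh)
    return ImageStack(np.asarray(phase, np.float32),
                      np.asarray(fluor, np.float32),
                      float(meta["pixel_size"]),
                      float(meta["frame_interval"]))


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_masks(masks_by_frame: Sequence[Sequence[CellMask]],
                shape: tuple[int, int], path: str | Path) -> None:
    """Write per-frame 16-bit label images as a multi-frame TIFF."""
    stack = np.zeros((len(masks_by_frame), *shape), dtype=np.uint16)
    for t, masks in enumerate(masks_by_frame):
        for m in masks:
            stack[t, m.pixels[:, 0], m.pixels[:, 1]] = m.label
    tifffile.imwrite(path, stack)


def write_cells_csv(masks_by_frame: Sequence[Sequence[CellMask]],
                    path: str | Path) -> pd.DataFrame:
    rows = []
    for masks in masks_by_frame:
        for m in masks:
            rows.append({
                "frame": m.frame_index, "label": m.label,
                "measurable": m.measurable,
                "length_um": m.length_um, "width_um": m.width_um,
                "pole_a_row": None if m.pole_a is None else m.pole_a[0],
                "pole_a_col": None if m.pole_a is None else m.pole_a[1],
                "pole_b_row": None if m.pole_b is None else m.pole_b[0],
                "pole_b_col": None if m.pole_b is None else m.pole_b[1],
                "note": m.note,
            })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def write_foci_csv(foci_by_frame: dict[int, list[Focus]],
                   track_ids: dict[int, int] | None,
                   path: str | Path) -> pd.DataFrame:
    rows = []
    for frame in sorted(foci_by_frame):
        for f in foci_by_frame[frame]:
            rows.append({
                "frame": frame, "cell_label": f.cell_label,
                "row": f.pixel[0], "col": f.pixel[1],
                "intensity": f.intensity, "s_um": f.s_um,
                "p_norm": f.p_norm, "class": f.focus_class,
            })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def write_lineage_csvs(tracks: Sequence[CellTrack],
                       divisions: Sequence[DivisionEvent],
                       lengths: dict[tuple[int, int], float | None],
                       out_dir: str | Path) -> None:
    """Edge list (parent, daughter, frame) plus per-track per-frame table.

    ``lengths`` maps (frame, label) to measured length in µm.
    """
    out = Path(out_dir)
    edges = [{"parent_track": d.parent_track_id,
              "daughter_track": did,
              "division_frame": d.division_frame}
             for d in divisions for did in d.daughter_track_ids]
    pd.DataFrame(edges, columns=["parent_track", "daughter_track",
                                 "division_frame"]
                 ).to_csv(out / "lineage_edges.csv", index=False)
    rows = []
    for tr in tracks:
        for frame in tr.frames:
            lab = tr.labels[frame]
            rows.append({"track_id": tr.track_id, "frame": frame,
                         "label": lab,
                         "length_um": lengths.get((frame, lab))})
    pd.DataFrame(rows).to_csv(out / "tracks.csv", index=False)


def write_histogram_csv(values: Sequence[float], path: str | Path,
                        bins: int = 20) -> None:
    counts, edges = np.histogram(np.asarray(values, float), bins=bins)
    pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                  "count": counts}).to_csv(path, index=False)


def write_manifest(path: str | Path, *, config: dict, seed: int,
                   version: str, inputs: dict, outputs: dict,
                   counts: dict) -> None:
    """Run manifest: config snapshot, seed, version, paths, stage counts."""
    with open(path, "w") as fh:
        json.dump({"config": config, "seed": seed, "version": version,
                   "inputs": inputs, "outputs": outputs,
                   "stage_counts": counts}, fh, indent=1, default=str)
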