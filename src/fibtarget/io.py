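"""Readers and writers for stacks, projected images, picks and plans.

Stacks travel as OME-TIFF (preferred; voxel sizes in the OME pixel
metadata) or MRC2014 (single channel; voxel sizes from the header cell).
Projected images travel as TIFF with a JSON sidecar carrying pixel size,
modality, channel labels, plane origin and provenance — enough metadata
to reproduce every artifact from its inputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import tifffile

from .containers import ProjectedImage, VolumeStack
from .geometry import Frame3D
from .planner import MillingPlan, MillStep

__all__ = [
    "read_stack",
    "write_stack",
    "read_image",
    "write_image",
    "read_picks",
    "write_picks",
    "read_plan",
    "write_plan",
    "plan_report",
]

PICK_COLUMNS = ["image_id", "x_px", "y_px", "kind"]


def write_stack(stack: VolumeStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF (.tif/.tiff/.ome.tif) or MRC (.mrc)."""
    path = Path(path)
    if path.suffix.lower() == ".mrc":
        if stack.n_channels != 1:
            raise ValueError("MRC holds a single channel; split the stack first")
        sx, sy, sz = stack.frame.voxel_size_um
        nz, ny, nx = stack.shape_zyx
        m = gemmi.Ccp4Map()
        # MRC stores X fastest; gemmi grids are u-fastest with u = first axis
        m.grid = gemmi.FloatGrid(
            np.ascontiguousarray(stack.data[0].astype(np.float32).T)
        )
        m.grid.unit_cell.set(nx * sx, ny * sy, nz * sz, 90.0, 90.0, 90.0)
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))
        return
    sx, sy, sz = stack.frame.voxel_size_um
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": sx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": sy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": sz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": list(stack.channels)},
        },
    )


def read_stack(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    channels: tuple[str, ...] | None = None,
) -> VolumeStack:
    """Read an OME-TIFF or MRC stack; voxel sizes come from metadata.

    ``voxel_size_um`` overrides (and is required for files without voxel
    metadata — plain TIFFs raise otherwise).
    """
    path = Path(path)
    if path.suffix.lower() == ".mrc":
        m = gemmi.read_ccp4_map(str(path))
        arr = np.array(m.grid, copy=True).T  # (x,y,z) -> (z,y,x)
        if voxel_size_um is None:
            voxel_size_um = tuple(float(s) for s in m.grid.spacing)
        return VolumeStack(
            data=arr[None].astype(np.float32),
            frame=Frame3D(voxel_size_um=voxel_size_um),
            channels=channels or ("0",),
        )
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta_channels: tuple[str, ...] | None = None
        if voxel_size_um is None or channels is None:
            if tf.ome_metadata:
                px = tifffile.xml2dict(tf.ome_metadata)["OME"]["Image"]["Pixels"]
                if voxel_size_um is None:
                    try:
                        voxel_size_um = (
                            float(px["PhysicalSizeX"]),
                            float(px["PhysicalSizeY"]),
                            float(px["PhysicalSizeZ"]),
                        )
                    except KeyError as exc:
                        raise ValueError(
                            f"{path}: OME metadata lacks PhysicalSize{exc.args[0][-1]}; "
                            "pass voxel_size_um explicitly"
                        ) from None
                ch = px.get("Channel")
                if isinstance(ch, list):
                    meta_channels = tuple(c.get("Name", str(i)) for i, c in enumerate(ch))
                elif isinstance(ch, dict):
                    name = ch.get("Name")
                    if isinstance(name, list):
                        meta_channels = tuple(str(n) for n in name)
            elif voxel_size_um is None:
                raise ValueError(
                    f"{path}: no OME voxel-size metadata; pass voxel_size_um explicitly"
                )
    if arr.ndim == 3:
        arr = arr[None]
    if channels is None:
        channels = meta_channels or tuple(str(i) for i in range(arr.shape[0]))
    return VolumeStack(
        data=arr.astype(np.float32),
        frame=Frame3D(voxel_size_um=voxel_size_um),
        channels=channels,
    )


def write_image(img: ProjectedImage, path: str | Path) -> None:
    """Write a projected image as TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, img.data.astype(np.float32))
    sidecar = {
        "pixel_size_um": img.pixel_size_um,
        "modality": img.modality,
        "channels": list(img.channels),
        "origin_um": list(img.origin_um),
        "provenance": _jsonable(img.provenance),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_image(path: str | Path, pixel_size_um: float | None = None) -> ProjectedImage:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        return ProjectedImage(
            data=data,
            pixel_size_um=pixel_size_um or meta["pixel_size_um"],
            modality=meta["modality"],
            channels=tuple(meta["channels"]),
            origin_um=tuple(meta["origin_um"]),
            provenance=meta.get("provenance", {}),
        )
    if pixel_size_um is None:
        raise ValueError(f"{path}: no sidecar metadata; pass pixel_size_um explicitly")
    return ProjectedImage(data=data, pixel_size_um=pixel_size_um, modality="TEM")


def write_picks(picks: pd.DataFrame, path: str | Path) -> None:
    """Write clicked coordinates (image_id, x_px, y_px, kind in {TOI, RP})."""
    missing = [c for c in PICK_COLUMNS if c not in picks.columns]
    if missing:
        raise ValueError(f"picks table missing columns {missing}")
    picks[PICK_COLUMNS].to_csv(path, index=False)


def read_picks(path: str | Path) -> pd.DataFrame:
    picks = pd.read_csv(path)
    missing = [c for c in PICK_COLUMNS if c not in picks.columns]
    if missing:
        raise ValueError(f"{path}: picks table missing columns {missing}")
    bad = set(picks["kind"]) - {"TOI", "RP"}
    if bad:
        raise ValueError(f"{path}: unknown pick kinds {sorted(bad)}")
    return picks


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_plan(plan: MillingPlan, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(dataclasses.asdict(plan)), indent=2))


def read_plan(path: str | Path) -> MillingPlan:
    d = json.loads(Path(path).read_text())
    steps = [
        MillStep(
            box_px=tuple(s["box_px"]),
            side=s["side"],
            current_pA=s["current_pA"],
            duration_min=s["duration_min"],
        )
        for s in d["steps"]
    ]
    return MillingPlan(
        steps=steps,
        prelamella_thickness_nm=d["prelamella_thickness_nm"],
        final_thickness_nm=d["final_thickness_nm"],
        predicted_margins_nm=tuple(d["predicted_margins_nm"]),
        relief_cuts_px=[tuple(r) for r in d.get("relief_cuts_px", [])],
        provenance=d.get("provenance", {}),
    )


def plan_report(plan: MillingPlan) -> str:
    """Human-readable milling plan summary."""
    lines = [
        f"Milling plan ({plan.provenance.get('step', 'unknown step')})",
        f"  prelamella thickness: {plan.prelamella_thickness_nm:8.0f} nm",
        f"  final thickness:      {plan.final_thickness_nm:8.0f} nm",
        "  target clearance:     "
        f"{plan.predicted_margins_nm[0]:.0f} nm (upper) / {plan.predicted_margins_nm[1]:.0f} nm (lower)",
    ]
    for i, s in enumerate(plan.steps, 1):
        x0, y0, x1, y1 = s.box_px
        lines.append(
            f"  step {i}: {s.side:5s} box ({x0:7.1f},{y0:7.1f})-({x1:7.1f},{y1:7.1f}) px "
            f"@ {s.current_pA:.0f} pA, {s.duration_min:.2f} min"
        )
    return "\n".join(lines)
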