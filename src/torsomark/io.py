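"""File formats: OBJ/MTL textured meshes, PNG rasters, PLY clouds, sidecars.

The OBJ writer/reader is deliberately minimal (v/vt/f with a single
material) and formats floats with fixed precision, so a write→read→write
cycle is byte-stable — important for reproducible intermediate artifacts.
Texture coordinates are stored in the conventional normalized form (origin
bottom-left); in memory they are texture pixel coordinates (origin
top-left).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .electrodes import ElectrodeMap
from .markers import MarkerPointCloud
from .meshing import TexturedSurface

__all__ = [
    "write_depth_png",
    "read_depth_png",
    "write_color_png",
    "read_color_png",
    "write_mask_png",
    "read_mask_png",
    "write_obj",
    "read_obj",
    "write_ply",
    "write_electrode_map_csv",
    "write_electrode_map_json",
    "write_sidecar",
    "read_sidecar",
]


def write_depth_png(path, depth: np.ndarray) -> None:
    """16-bit grayscale PNG, values in millimetres, 0 = undefined."""
    iio.imwrite(Path(path), np.asarray(depth, dtype=np.uint16))


def read_depth_png(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.uint16)


def write_color_png(path, img: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def read_color_png(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))).astype(np.uint8)


def write_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask_png(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


class ObjFormatError(ValueError):
    pass


def write_obj(path, surface: TexturedSurface, texture_name: str | None = None) -> None:
    """Write a textured surface as OBJ + MTL + PNG triplet."""
    path = Path(path)
    stem = path.stem
    tex_name = texture_name or f"{stem}.png"
    th, tw = surface.texture.shape[:2]
    lines = [
        f"# torsomark surface; kw {surface.kw:.1f}; view {surface.view_id}",
        f"mtllib {stem}.mtl",
    ]
    for v in surface.vertices:
        lines.append(f"v {v[0]:.4f} {v[1]:.4f} {v[2]:.4f}")
    for uv in surface.uv:
        u = uv[0] / tw
        w = 1.0 - uv[1] / th
        lines.append(f"vt {u:.8f} {w:.8f}")
    lines.append(f"usemtl {stem}")
    for t in surface.triangles:
        a, b, c = (int(x) + 1 for x in t)
        lines.append(f"f {a}/{a} {b}/{b} {c}/{c}")
    path.write_text("\n".join(lines) + "\n")
    (path.parent / f"{stem}.mtl").write_text(
        f"newmtl {stem}\nKd 1.0 1.0 1.0\nmap_Kd {tex_name}\n"
    )
    write_color_png(path.parent / tex_name, surface.texture)


def read_obj(path) -> TexturedSurface:
    path = Path(path)
    verts: list[list[float]] = []
    uvs: list[list[float]] = []
    tris: list[list[int]] = []
    kw = 5500.0
    view_id = 0
    tex_name = f"{path.stem}.png"
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        tag = parts[0]
        try:
            if tag == "#" and len(parts) >= 4 and parts[1] == "torsomark":
                if "kw" in parts:
                    kw = float(parts[parts.index("kw") + 1].rstrip(";"))
                if "view" in parts:
                    view_id = int(parts[parts.index("view") + 1])
            elif tag == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif tag == "vt":
                uvs.append([float(x) for x in parts[1:3]])
            elif tag == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:4]]
                tris.append(idx)
            elif tag == "mtllib":
                mtl = path.parent / parts[1]
                if mtl.exists():
                    for mline in mtl.read_text().splitlines():
                        if mline.startswith("map_Kd"):
                            tex_name = mline.split()[1]
        except (ValueError, IndexError) as exc:
            raise ObjFormatError(f"{path.name}:{ln}: cannot parse {line!r}") from exc
    tex_path = path.parent / tex_name
    texture = read_color_png(tex_path) if tex_path.exists() else np.zeros((1, 1, 3), np.uint8)
    th, tw = texture.shape[:2]
    uv = np.asarray(uvs, dtype=np.float64).reshape(-1, 2)
    uv_px = np.stack([uv[:, 0] * tw, (1.0 - uv[:, 1]) * th], axis=1)
    v = np.asarray(verts, dtype=np.float64).reshape(-1, 3)
    t = np.asarray(tris, dtype=np.int64).reshape(-1, 3)
    if len(t) and (t.min() < 0 or t.max() >= len(v)):
        raise ObjFormatError(f"{path.name}: face index out of range")
    return TexturedSurface(vertices=v, triangles=t, uv=uv_px, texture=texture,
                           kw=kw, view_id=view_id)


def write_ply(path, cloud: MarkerPointCloud) -> None:
    """ASCII PLY with a per-point RGB color tag (red or blue)."""
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(cloud)}",
        "property float x",
        "property float y",
        "property float z",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
        "end_header",
    ]
    for p, b in zip(cloud.points, cloud.is_blue):
        col = "0 0 255" if b else "255 0 0"
        lines.append(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {col}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_electrode_map_csv(path, emap: ElectrodeMap) -> None:
    lines = ["channel,x,y,z,nx,ny,nz,patch"]
    for lbl, pos, n, patch in zip(emap.labels, emap.positions, emap.normals, emap.patches):
        lines.append(
            f"{lbl},{pos[0]:.3f},{pos[1]:.3f},{pos[2]:.3f},"
            f"{n[0]:.5f},{n[1]:.5f},{n[2]:.5f},{patch}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_electrode_map_json(path, emap: ElectrodeMap) -> None:
    data = {
        "electrodes": [
            {
                "channel": lbl,
                "position_mm": [round(float(x), 3) for x in pos],
                "normal": [round(float(x), 5) for x in n],
                "patch": patch,
            }
            for lbl, pos, n, patch in zip(
                emap.labels, emap.positions, emap.normals, emap.patches
            )
        ],
        "grid_edges": emap.grid_edges.tolist(),
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def write_cluster_report_csv(path, clusters) -> None:
    """Per-electrode cluster statistics (counts, fitted centre, residual)."""
    lines = ["cluster,n_red,n_blue,merged,x,y,z,residual"]
    for i, cl in enumerate(clusters):
        center = cl.center if cl.center is not None else (float("nan"),) * 3
        lines.append(
            f"{i},{cl.n_red},{cl.n_blue},{int(cl.merged)},"
            f"{center[0]:.3f},{center[1]:.3f},{center[2]:.3f},{cl.residual:.3f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_sidecar(path, **fields) -> None:
    """Per-view JSON sidecar (KW, intrinsics, pose for synthetic scenes)."""
    Path(path).write_text(json.dumps(fields, indent=1, sort_keys=True) + "\n")


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
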