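"""File formats: flat binary rasters/sinograms with JSON sidecars, CSV
exchange, lossy PNG export and run-provenance sidecars.

The native on-disk format for images and sinograms is a flat little-endian
float32 payload (row-major, C order) next to a JSON sidecar that carries
the shape and physical metadata.  Write-then-read round trips are
bit-exact for float32 data.  PNG export windows the data to 8 bits for
human inspection and is lossy by design.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
from PIL import Image as PILImage

from .phantoms import Ellipse, ImageGrid, Phantom
from .projection import Geometry, Sinogram

__all__ = [
    "sidecar_path",
    "write_image",
    "read_image",
    "write_sinogram",
    "read_sinogram",
    "sinogram_to_csv",
    "sinogram_from_csv",
    "write_png",
    "phantom_to_csv",
    "phantom_from_csv",
    "phantom_to_json",
    "phantom_from_json",
    "write_run_config",
]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def _check(sidecar: dict, key: str, expected: Any, path: Path) -> Any:
    if key not in sidecar:
        raise ValueError(f"{path}: sidecar is missing field {key!r}")
    if expected is not None and sidecar[key] != expected:
        raise ValueError(
            f"{path}: sidecar field {key!r} = {sidecar[key]!r}, expected {expected!r}")
    return sidecar[key]


def write_image(path: str | Path, image: ImageGrid, extra: dict | None = None) -> Path:
    """Write an ImageGrid as flat float32 plus a JSON sidecar."""
    path = Path(path)
    image.values.astype("<f4").tofile(path)
    meta = {"kind": "image", "N": image.n, "spacing": image.spacing,
            "dtype": "float32", "order": "C"}
    if extra:
        meta.update(extra)
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_image(path: str | Path) -> ImageGrid:
    path = Path(path)
    sc = sidecar_path(path)
    if not sc.exists():
        raise ValueError(f"{path}: sidecar {sc.name} not found")
    meta = json.loads(sc.read_text())
    _check(meta, "kind", "image", path)
    n = int(_check(meta, "N", None, path))
    spacing = float(_check(meta, "spacing", None, path))
    _check(meta, "dtype", "float32", path)
    data = np.fromfile(path, dtype="<f4")
    if data.size != n * n:
        raise ValueError(
            f"{path}: payload has {data.size} values but sidecar N={n} implies {n * n}")
    return ImageGrid(data.reshape(n, n).astype(float), spacing)


def write_sinogram(path: str | Path, sinogram: Sinogram, extra: dict | None = None) -> Path:
    path = Path(path)
    sinogram.values.astype("<f4").tofile(path)
    g = sinogram.geometry
    meta = {"kind": "sinogram", "M": g.M, "K": g.K, "Delta": g.Delta, "d": g.d,
            "dtype": "float32", "order": "C"}
    if extra:
        meta.update(extra)
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    sc = sidecar_path(path)
    if not sc.exists():
        raise ValueError(f"{path}: sidecar {sc.name} not found")
    meta = json.loads(sc.read_text())
    _check(meta, "kind", "sinogram", path)
    m = int(_check(meta, "M", None, path))
    k = int(_check(meta, "K", None, path))
    delta = float(_check(meta, "Delta", None, path))
    d = float(_check(meta, "d", None, path))
    _check(meta, "dtype", "float32", path)
    data = np.fromfile(path, dtype="<f4")
    if data.size != m * k:
        raise ValueError(
            f"{path}: payload has {data.size} values but sidecar M={m}, K={k} "
            f"implies {m * k}")
    return Sinogram(data.reshape(m, k).astype(float), Geometry(M=m, Delta=delta, K=k, d=d))


def sinogram_to_csv(path: str | Path, sinogram: Sinogram) -> Path:
    """One row per angle; geometry goes in the sidecar."""
    path = Path(path)
    np.savetxt(path, sinogram.values, delimiter=",", fmt="%.9g")
    g = sinogram.geometry
    sidecar_path(path).write_text(json.dumps(
        {"kind": "sinogram-csv", "M": g.M, "K": g.K, "Delta": g.Delta, "d": g.d}, indent=2))
    return path


def sinogram_from_csv(path: str | Path) -> Sinogram:
    path = Path(path)
    meta = json.loads(sidecar_path(path).read_text())
    _check(meta, "kind", "sinogram-csv", path)
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    geom = Geometry(M=int(meta["M"]), Delta=float(meta["Delta"]),
                    K=int(meta["K"]), d=float(meta["d"]))
    return Sinogram(values, geom)


def write_png(path: str | Path, array: np.ndarray | ImageGrid) -> Path:
    """Lossy 8-bit PNG export with min-max windowing, for inspection only.

    Rows are flipped so that +y points up in the rendered file.
    """
    a = array.values if isinstance(array, ImageGrid) else np.asarray(array, float)
    lo, hi = float(a.min()), float(a.max())
    scaled = np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)
    img = PILImage.fromarray((scaled[::-1] * 255).round().astype(np.uint8))
    img.save(Path(path))
    return Path(path)


_PHANTOM_HEADER = "cx,cy,a,b,phi_rot_deg,rho"


def phantom_to_csv(path: str | Path, phantom: Phantom) -> Path:
    lines = [_PHANTOM_HEADER]
    for e in phantom.ellipses:
        lines.append(f"{e.cx:.12g},{e.cy:.12g},{e.a:.12g},{e.b:.12g},"
                     f"{np.degrees(e.phi_rot):.12g},{e.rho:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def phantom_from_csv(path: str | Path, name: str | None = None) -> Phantom:
    lines = Path(path).read_text().strip().splitlines()
    if not lines or lines[0].replace(" ", "") != _PHANTOM_HEADER:
        raise ValueError(f"{path}: expected header {_PHANTOM_HEADER!r}")
    ells = []
    for line in lines[1:]:
        cx, cy, a, b, phi_deg, rho = (float(v) for v in line.split(","))
        ells.append(Ellipse(cx=cx, cy=cy, a=a, b=b,
                            phi_rot=float(np.radians(phi_deg)), rho=rho))
    return Phantom(tuple(ells), name=name or Path(path).stem)


def phantom_to_json(path: str | Path, phantom: Phantom) -> Path:
    payload = {
        "name": phantom.name,
        "ellipses": [dataclasses.asdict(e) for e in phantom.ellipses],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
    return Path(path)


def phantom_from_json(path: str | Path) -> Phantom:
    payload = json.loads(Path(path).read_text())
    ells = tuple(Ellipse(**e) for e in payload["ellipses"])
    return Phantom(ells, name=payload.get("name", Path(path).stem))


def write_run_config(path: str | Path, config: dict) -> Path:
    """Record the full parameter set of a run next to its outputs.

    The sidecar is plain JSON; any dataclass values are flattened first.
    A run is reproducible from this file alone.
    """
    def flatten(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: flatten(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: flatten(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [flatten(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, Path):
            return str(obj)
        return obj

    Path(path).write_text(json.dumps(flatten(config), indent=2))
    return Path(path)
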