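"""Image-stack and sidecar I/O.

Stacks are written as numbered binary slice images (PNG, TIFF or BMP; 0 =
background, 255 = cortical bone) together with a JSON sidecar recording
pixel size, Z range and slice spacing, which is what downstream commands
need to reconstruct physical coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .geometry import BoneVolume, CrossSection

__all__ = ["write_stack", "read_stack"]

SIDECAR = "stack.json"


def write_stack(volume: BoneVolume, directory, fmt: str = "png") -> None:
    ext = {"png": "png", "tiff": "tif", "bmp": "bmp"}[fmt]
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(volume.sections):
        img = (s.mask.astype(np.uint8)) * 255
        path = directory / f"slice_{i:04d}.{ext}"
        if fmt == "tiff":
            import tifffile
            tifffile.imwrite(path, img)
        else:
            Image.fromarray(img).save(path)
    meta = {
        "pixel_size_um": volume.pixel_size,
        "slice_spacing_um": volume.slice_spacing_um,
        "z_range": [float(volume.z[0]), float(volume.z[-1])],
        "n_slices": volume.n_slices,
        "z": [float(z) for z in volume.z],
    }
    (directory / SIDECAR).write_text(json.dumps(meta, indent=1))


def read_stack(directory) -> BoneVolume:
    directory = Path(directory)
    sidecar = directory / SIDECAR
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff", ".bmp"))
    if len(files) != meta["n_slices"]:
        raise ValueError(f"sidecar says {meta['n_slices']} slices, found "
                         f"{len(files)} images")
    zs = meta["z"]
    sections = []
    for path, z in zip(files, zs):
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
        sections.append(CrossSection(arr > 0, meta["pixel_size_um"],
                                     float(z)))
    return BoneVolume(sections, meta["pixel_size_um"],
                      meta["slice_spacing_um"])
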