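"""Image and sequence I/O: PNG (8/16-bit), TIFF (incl. 32-bit float and
multi-page), CSV kernel export, JSON sidecars.

Float TIFF round-trips bitwise; integer PNG round-trips exactly after
quantization (8-bit -> 255 levels, 16-bit -> 65535), with intensities
linearized to [0, 1] on read. Directory sequences are ordered by the integer
index embedded in the filename and must be gap-free.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError
from .spatial import Image2D
from .temporal import ImageSequence


def read_image(path) -> Image2D:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 3:
            raise FormatError(f"{path} is multi-page; use read_sequence")
        return Image2D(np.asarray(data, dtype=float))
    if suffix == ".png":
        data = iio.imread(path)
        if data.ndim == 3:
            data = data[..., :3].mean(axis=-1)
        if data.dtype == np.uint8:
            return Image2D(data.astype(float) / 255.0)
        if data.dtype == np.uint16:
            return Image2D(data.astype(float) / 65535.0)
        raise FormatError(f"unsupported PNG bit depth {data.dtype} in {path}")
    raise FormatError(f"unsupported image format {suffix!r}")


def write_image(path, image, bit_depth: int | None = None):
    """Write PNG (8/16-bit, values clipped to [0,1]) or TIFF (float32)."""
    path = Path(path)
    values = image.values if isinstance(image, Image2D) else np.asarray(image, float)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, values.astype(np.float32))
    elif suffix == ".png":
        depth = bit_depth or 16
        if depth == 8:
            iio.imwrite(path, np.clip(values, 0, 1).astype(np.float64).__mul__(255)
                        .round().astype(np.uint8))
        elif depth == 16:
            iio.imwrite(path, (np.clip(values, 0, 1) * 65535).round().astype(np.uint16))
        else:
            raise FormatError(f"unsupported PNG bit depth {depth}")
    else:
        raise FormatError(f"unsupported image format {suffix!r}")
    return path


_FRAME_INDEX = re.compile(r"(\d+)(?=\.\w+$)")


def read_sequence(path) -> ImageSequence:
    """Read a multi-page TIFF, or a directory of numbered PNG/TIFF frames."""
    path = Path(path)
    if path.is_dir():
        entries = []
        for p in sorted(path.iterdir()):
            if p.suffix.lower() not in (".png", ".tif", ".tiff"):
                continue
            m = _FRAME_INDEX.search(p.name)
            if not m:
                raise FormatError(f"frame file {p.name} has no numeric index")
            entries.append((int(m.group(1)), p))
        if not entries:
            raise FormatError(f"no frames found in {path}")
        entries.sort()
        indices = [i for i, _ in entries]
        if indices != list(range(indices[0], indices[0] + len(indices))):
            raise FormatError(f"frame numbering has gaps: {indices}")
        frames = np.stack([read_image(p).values for _, p in entries])
        return ImageSequence(frames)
    data = tifffile.imread(path)
    if data.ndim != 3:
        raise FormatError(f"{path} is not a multi-page TIFF sequence")
    return ImageSequence(np.asarray(data, dtype=float))


def write_sequence(path, seq):
    frames = seq.frames if isinstance(seq, ImageSequence) else np.asarray(seq, float)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, frames.astype(np.float32))
        return path
    raise FormatError("sequences are written as multi-page TIFF")


def write_kernel_csv(path, kernel):
    values = getattr(kernel, "values", kernel)
    np.savetxt(path, np.asarray(values, float), delimiter=",")
    return Path(path)


def write_sidecar(path, metadata: dict):
    """JSON sidecar (<path>.json) recording parameter provenance."""
    side = Path(str(path) + ".json")
    side.write_text(json.dumps(metadata, indent=2, default=_jsonable) + "\n")
    return side


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
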