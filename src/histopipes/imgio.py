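"""Image and table I/O: reading single-plane images, grouping multichannel
fluorescence files by suffix, writing the single summary CSV and overlays.

Batch discovery is a non-recursive scan of the target folder for
{.tif,.tiff,.png,.jpg,.jpeg} (case-insensitive), matching the one-folder
batch model of the pipelines. Inputs deeper than 8 bits are linearly
rescaled (image minimum -> 0, dtype maximum -> 255) because all downstream
histogram math is defined on 8-bit intensities.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelSet",
    "StackError",
    "read_image",
    "write_image",
    "list_images",
    "group_channels",
    "write_summary",
    "render_overlay",
]

IMAGE_EXTENSIONS = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}


class StackError(ValueError):
    """Raised for multi-plane inputs, which the pipelines do not process."""


@dataclass
class ChannelSet:
    """One multichannel fluorescence acquisition, grouped by filename suffix."""

    base_name: str
    foci: np.ndarray
    nuclei: np.ndarray
    cytoplasm: np.ndarray | None = None
    paths: dict[str, Path] | None = None

    def __post_init__(self) -> None:
        if not self.base_name:
            raise ValueError("ChannelSet base name must be non-empty")
        shapes = {self.foci.shape, self.nuclei.shape}
        if self.cytoplasm is not None:
            shapes.add(self.cytoplasm.shape)
        if len(shapes) != 1:
            raise ValueError(f"channel dimensions differ: {shapes}")


def _rescale_to_8bit(arr: np.ndarray) -> np.ndarray:
    """Map image min -> 0 and dtype max -> 255 for >8-bit integer data."""
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        dtype_max = float(np.iinfo(arr.dtype).max)
    else:
        dtype_max = float(arr.max()) if arr.size else 1.0
    lo = float(arr.min())
    span = dtype_max - lo
    if span <= 0:
        return np.zeros(arr.shape, dtype=np.uint8)
    scaled = (arr.astype(float) - lo) * (255.0 / span)
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def read_image(path: os.PathLike | str) -> np.ndarray:
    """Read a single-plane TIFF/PNG/JPEG as 8-bit gray (HxW) or RGB (HxWx3).

    Multi-page stacks are refused: the pipelines are designed for single
    images, split stacks first. RGBA alpha is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    suffix = path.suffix.lower()
    if suffix not in IMAGE_EXTENSIONS:
        raise ValueError(f"unsupported image format {suffix!r}: {path}")
    try:
        if suffix in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tif:
                if len(tif.pages) > 1:
                    raise StackError(
                        f"{path} is a {len(tif.pages)}-page stack; the pipelines "
                        "process single images — split stacks into single planes first"
                    )
                arr = tif.pages[0].asarray()
        else:
            arr = iio.imread(path)
    except (StackError, FileNotFoundError):
        raise
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise OSError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] not in (3,):
        raise StackError(
            f"{path} has shape {arr.shape}; the pipelines process single "
            "2-D planes — split stacks first"
        )
    if arr.ndim not in (2, 3):
        raise ValueError(f"{path}: unsupported image dimensionality {arr.shape}")
    return _rescale_to_8bit(arr)


def write_image(path: os.PathLike | str, image: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.floor(arr.astype(float) + 0.5), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def list_images(directory: os.PathLike | str) -> list[Path]:
    """Non-recursive, case-insensitive scan for supported image files."""
    directory = Path(directory)
    if not directory.is_dir():
        raise NotADirectoryError(f"not a directory: {directory}")
    return sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )


def group_channels(
    directory: os.PathLike | str,
    suffix_map: dict[str, str] | None = None,
) -> list[ChannelSet]:
    """Group per-channel files sharing a base name into ChannelSets.

    ``suffix_map`` maps roles ('foci', 'nuclei', optionally 'cytoplasm') to
    the filename suffix appearing immediately before the extension (the
    Ch00/Ch01/Ch02 convention). Files missing a required channel are
    reported with a warning and skipped; sets are returned in lexicographic
    base-name order.
    """
    suffix_map = dict(suffix_map or {"foci": "Ch00", "nuclei": "Ch01", "cytoplasm": "Ch02"})
    for role in ("foci", "nuclei"):
        if role not in suffix_map:
            raise ValueError(f"suffix map must define the {role!r} channel")
    groups: dict[str, dict[str, Path]] = {}
    for path in list_images(directory):
        stem = path.stem
        for role, suffix in suffix_map.items():
            if suffix and stem.endswith(suffix):
                base = stem[: -len(suffix)]
                groups.setdefault(base, {})[role] = path
                break
    sets: list[ChannelSet] = []
    for base in sorted(groups):
        found = groups[base]
        missing = [r for r in ("foci", "nuclei") if r not in found]
        if missing:
            logger.warning(
                "channel group %r skipped: missing %s channel(s)", base, ", ".join(missing)
            )
            continue
        cyto = None
        if "cytoplasm" in suffix_map and "cytoplasm" in found:
            cyto = read_image(found["cytoplasm"])
        sets.append(
            ChannelSet(
                base_name=base,
                foci=read_image(found["foci"]),
                nuclei=read_image(found["nuclei"]),
                cytoplasm=cyto,
                paths=found,
            )
        )
    if not sets:
        logger.warning("no complete channel sets found in %s", directory)
    return sets


def write_summary(table: pd.DataFrame, path: os.PathLike | str) -> None:
    """Write the single summary CSV (RFC-4180, UTF-8, header row) atomically.

    The file is replaced wholesale on each run — re-running a batch never
    appends.
    """
    if len(table) == 0:
        raise ValueError("summary table is empty")
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".csv.tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            table.to_csv(fh, index=False, lineterminator="\r\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _contour(mask: np.ndarray) -> np.ndarray:
    """1-px 8-connected inner contour: mask minus its 4-connected erosion."""
    import scipy.ndimage as ndi

    mask = np.asarray(mask, dtype=bool)
    eroded = ndi.binary_erosion(
        mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
        border_value=0,
    )
    return mask & ~eroded


def render_overlay(image: np.ndarray, layers) -> np.ndarray:
    """Paint mask contours / point markers over a copy of an RGB image.

    ``layers`` is a list of ``(mask_or_points, color)``: boolean masks are
    drawn as 1-px contours, point lists as 3x3 crosses centred on each
    (x, y). The input image is never modified.
    """
    base = np.asarray(image)
    if base.ndim == 2:
        base = np.stack([base] * 3, axis=2)
    out = base.astype(np.uint8).copy()
    h, w, _ = out.shape
    for layer, color in layers:
        color = np.asarray(color, dtype=np.uint8)
        if isinstance(layer, np.ndarray) and layer.dtype == bool:
            if layer.shape != (h, w):
                raise ValueError(
                    f"overlay mask shape {layer.shape} != image shape {(h, w)}"
                )
            out[_contour(layer)] = color
        else:
            for x, y in layer:
                r, c = int(round(y)), int(round(x))
                for dr, dc in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        out[rr, cc] = color
    return out
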