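"""Image standardisation: load, rescale to 8 bit, segment, orient, crop.

The pipeline mirrors the usual whole-breast radiomics front end: binary
masks from a fixed gray-level threshold (default 100 on the 8-bit scale,
with optional per-file overrides), right-sided views mirrored so every
image has its chest wall on the left, then a tight crop to the breast
bounding box.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import MetadataError, SegmentationError
from .images import BreastMask, GrayImage

logger = logging.getLogger(__name__)

#: filename tokens recognised when image metadata is absent, e.g.
#: ``case0007_RMLO.tiff`` -> laterality R, view MLO.
_VIEW_TOKEN = re.compile(r"(?:^|[_\-.])(L|R)(CC|MLO)(?:[_\-.]|$)", re.IGNORECASE)


def _view_from_filename(path: Path) -> tuple[str, str]:
    m = _VIEW_TOKEN.search(path.stem)
    if not m:
        raise MetadataError(
            f"cannot determine view/laterality for {path}: no DICOM metadata "
            "and filename does not contain an LCC/RCC/LMLO/RMLO token"
        )
    return m.group(1).upper(), m.group(2).upper()


def read_image(path: str | Path) -> GrayImage:
    """Load a DICOM, TIFF, or PNG mammogram.

    MONO1 DICOMs are inverted to the MONO2 convention (brighter = denser
    tissue). View and laterality come from DICOM metadata when present,
    otherwise from an ``LCC/RCC/LMLO/RMLO`` filename token.

    Raises
    ------
    OSError
        If the file is missing, empty, or not a readable image.
    MetadataError
        If view/laterality cannot be determined.
    """
    path = Path(path)
    if not path.is_file() or path.stat().st_size == 0:
        raise OSError(f"not a readable image file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return _read_dicom(path)
    if suffix in (".tif", ".tiff"):
        import tifffile

        pixels = np.asarray(tifffile.imread(path))
    elif suffix == ".png":
        from PIL import Image

        pixels = np.asarray(Image.open(path))
    else:
        raise OSError(f"unsupported image format {suffix!r}: {path}")
    if pixels.ndim == 3:  # collapse an accidental RGB export
        pixels = pixels[..., 0]
    laterality, view = _view_from_filename(path)
    bits = 8 if pixels.dtype.itemsize == 1 else 16
    return GrayImage(pixels=pixels, view=view, laterality=laterality,
                     bits_stored=bits, photometric="MONO2")


def _read_dicom(path: Path) -> GrayImage:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        pixels = ds.pixel_array
    except Exception as exc:  # pydicom raises a zoo of error types
        raise OSError(f"unreadable DICOM file {path}: {exc}") from exc
    bits = int(getattr(ds, "BitsStored", 8 * pixels.dtype.itemsize))
    photometric = str(getattr(ds, "PhotometricInterpretation", "unknown"))
    if photometric == "MONOCHROME1":
        pixels = (2**bits - 1) - pixels.astype(np.int64)
        pixels = pixels.astype(np.uint16 if bits > 8 else np.uint8)
        photometric = "MONO1"
    elif photometric == "MONOCHROME2":
        photometric = "MONO2"
    else:
        photometric = "unknown"
    laterality = str(getattr(ds, "ImageLaterality", "") or getattr(ds, "Laterality", ""))
    view = str(getattr(ds, "ViewPosition", ""))
    if laterality not in ("L", "R") or view not in ("CC", "MLO"):
        laterality, view = _view_from_filename(path)
    return GrayImage(pixels=pixels, view=view, laterality=laterality,
                     bits_stored=bits,
                     photometric="MONO2" if photometric == "MONO1" else photometric)


def to_8bit(img: GrayImage) -> GrayImage:
    """Linearly rescale intensities to [0, 255] (round half up).

    8-bit input passes through unchanged. A constant image has no intensity
    range to map, so it becomes all zeros (with a logged warning).
    """
    if img.bits_stored == 8 and img.pixels.dtype == np.uint8:
        return img
    p = img.pixels.astype(np.float64)
    lo, hi = p.min(), p.max()
    if hi == lo:
        logger.warning("to_8bit: constant image, returning all zeros")
        out = np.zeros(img.shape, dtype=np.uint8)
    else:
        out = np.floor((p - lo) * (255.0 / (hi - lo)) + 0.5).astype(np.uint8)
    return img.with_pixels(out, bits_stored=8)


def segment_breast(img: GrayImage, threshold: int = 100) -> BreastMask:
    """Threshold-based breast segmentation on the 8-bit scale.

    Pixels strictly greater than ``threshold`` are foreground; only the
    largest 8-connected component is kept (discarding labels and other
    disconnected bright artefacts) and interior holes are filled so the
    mask is usable by the inscribed-square search.
    """
    if img.bits_stored != 8:
        raise ValueError("segment_breast expects an 8-bit image; apply to_8bit first")
    fg = img.pixels > threshold
    if not fg.any():
        raise SegmentationError(
            f"no pixel exceeds threshold {threshold}; adjust the per-file override",
            threshold=threshold,
        )
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        fg = labels == keep
    fg = ndimage.binary_fill_holes(fg)
    return BreastMask(pixels=fg)


def standardize_orientation(img: GrayImage, mask: BreastMask) -> tuple[GrayImage, BreastMask]:
    """Mirror right-laterality views so the chest wall sits on the left.

    Left images pass through bit-identically; flipping an already flipped
    image is never done, so the operation is idempotent on its own output.
    """
    if img.laterality != "R":
        return img, mask
    flipped = img.with_pixels(np.ascontiguousarray(img.pixels[:, ::-1]),
                              laterality="flipped-R")
    return flipped, BreastMask(pixels=np.ascontiguousarray(mask.pixels[:, ::-1]))


def crop_to_breast(img: GrayImage, mask: BreastMask) -> tuple[GrayImage, BreastMask]:
    """Crop image and mask to the tight bounding box of mask foreground."""
    if not mask.pixels.any():
        raise ValueError("cannot crop with an empty mask")
    rows = np.flatnonzero(mask.pixels.any(axis=1))
    cols = np.flatnonzero(mask.pixels.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return (img.with_pixels(img.pixels[r0:r1, c0:c1]),
            BreastMask(pixels=mask.pixels[r0:r1, c0:c1]))


def preprocess_image(
    img: GrayImage,
    threshold: int = 100,
    threshold_override: int | None = None,
) -> tuple[GrayImage, BreastMask]:
    """Full front end: 8-bit rescale, segment, orient, crop."""
    img8 = to_8bit(img)
    mask = segment_breast(img8, threshold_override if threshold_override is not None else threshold)
    img8, mask = standardize_orientation(img8, mask)
    return crop_to_breast(img8, mask)
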