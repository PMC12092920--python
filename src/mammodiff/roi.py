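"""Region-of-interest delineation on a cropped breast mask.

Two schemes are produced:

* a lattice of non-overlapping square blocks (distinct-block tiling
  anchored at the image origin) covering the breast, each retained only if
  it holds enough breast tissue;
* the largest axis-aligned square fully inscribed in the breast mask
  (the "SQ" region), used as one large ROI.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateROIError
from .images import BreastMask

DEFAULT_BLOCK_SIZE = 214  # pixels, distinct-block tiling
DEFAULT_MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class Block:
    """A square tile: half-open pixel range [row0, row0+size) x [col0, col0+size)."""

    row0: int
    col0: int
    size: int

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.size),
                slice(self.col0, self.col0 + self.size))


class InscribedSquare(Block):
    """Largest all-foreground axis-aligned square inside a breast mask."""


def lattice_blocks(
    mask: BreastMask,
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[Block]:
    """Tile the mask with non-overlapping ``block_size`` squares.

    Tiles start at the top-left corner on a regular grid; partial edge
    tiles are discarded. A tile qualifies iff the fraction of its pixels
    that are mask foreground is at least ``min_coverage``. Blocks are
    returned in row-major order.

    Raises
    ------
    DegenerateROIError
        If no tile qualifies (mask smaller than one block, or coverage
        everywhere below the cutoff).
    """
    m = mask.pixels
    if not m.any():
        raise ValueError("mask is empty")
    h, w = m.shape
    n_rows, n_cols = h // block_size, w // block_size
    blocks: list[Block] = []
    area = block_size * block_size
    for i in range(n_rows):
        for j in range(n_cols):
            b = Block(i * block_size, j * block_size, block_size)
            cov = m[b.slices()].sum() / area
            if cov >= min_coverage:
                blocks.append(b)
    if not blocks:
        raise DegenerateROIError(
            f"no lattice block of size {block_size} reaches coverage "
            f"{min_coverage} in a {h}x{w} mask; reduce block_size"
        )
    return blocks


def largest_inscribed_square(mask: BreastMask) -> InscribedSquare:
    """Largest axis-aligned all-foreground square in the mask.

    Among maximal squares, ties break to the topmost then leftmost
    top-left corner. Implemented with an integral image and a binary
    search over the side length (a square of side k exists iff some k x k
    window sums to k^2; existence is monotone in k).
    """
    m = mask.pixels.astype(np.int64)
    if not m.any():
        raise ValueError("mask is empty")
    h, w = m.shape
    # summed-area table with a zero border: S[i, j] = sum of m[:i, :j]
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(m, axis=0), axis=1, out=sat[1:, 1:])

    def full_windows(k: int) -> np.ndarray:
        sums = (sat[k:, k:] - sat[:-k, k:] - sat[k:, :-k] + sat[:-k, :-k])
        return sums == k * k

    lo, hi = 1, min(h, w)  # lo always feasible once verified below
    if not full_windows(1).any():  # unreachable: mask nonempty
        raise ValueError("mask is empty")
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if full_windows(mid).any():
            lo = mid
        else:
            hi = mid - 1
    hits = full_windows(lo)
    r, c = np.unravel_index(int(np.argmax(hits)), hits.shape)
    return InscribedSquare(int(r), int(c), int(lo))
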