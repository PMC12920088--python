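"""Per-block SVD spatiotemporal clutter filtering.

Tissue signal is strong, spatially extended and temporally coherent, so it
concentrates in the largest singular values of the space×time Casorati
matrix of a block of frames; microbubbles are sparse and fast-moving and
spread over the remaining components.  Filtering zeroes the ``n_remove``
largest singular values of each block of ``block_size`` consecutive frames
(defaults: 200-frame blocks, cut 20 for ULM, 60 for power Doppler).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .stack import FrameStack

__all__ = ["FrameBlock", "iter_blocks", "svd_filter", "filter_stack"]

logger = logging.getLogger(__name__)


@dataclass
class FrameBlock:
    """One block of consecutive frames from a stack."""

    values: np.ndarray  # (n_z, n_x, block_size)
    index: int
    start_frame: int
    svd_cut: int | None = None  # cut already applied, if any

    @property
    def block_size(self) -> int:
        return self.values.shape[2]

    def energy(self) -> float:
        return float(np.sum(np.abs(self.values) ** 2))


def iter_blocks(stack: FrameStack, block_size: int):
    """Yield consecutive, non-overlapping FrameBlocks.

    A trailing remainder shorter than ``block_size`` is dropped with a
    logged warning; a stack shorter than one block is an error.
    """
    n = stack.n_frames
    if n < block_size:
        raise ValueError(
            f"stack has {n} frames, fewer than one block of {block_size}")
    n_blocks = n // block_size
    dropped = n - n_blocks * block_size
    if dropped:
        logger.warning("dropping trailing %d frames (< one block of %d)",
                       dropped, block_size)
    for b in range(n_blocks):
        start = b * block_size
        yield FrameBlock(values=stack.values[:, :, start:start + block_size],
                         index=b, start_frame=start)


def svd_filter(block: FrameBlock, n_remove: int) -> FrameBlock:
    """Remove the ``n_remove`` largest singular values of the block.

    The block is unfolded to a (space × time) Casorati matrix, the leading
    singular components are subtracted, and the residual refolded.  By
    orthogonality, output energy = input energy − removed energy.
    """
    if not 0 <= n_remove < block.block_size:
        raise ValueError(
            f"n_remove={n_remove} must lie in [0, block_size={block.block_size})")
    if not np.all(np.isfinite(block.values)):
        raise ValueError("block contains non-finite values")
    if n_remove == 0:
        return FrameBlock(values=block.values.copy(), index=block.index,
                          start_frame=block.start_frame, svd_cut=0)
    nz, nx, nt = block.values.shape
    casorati = block.values.reshape(nz * nx, nt)
    u, s, vh = np.linalg.svd(casorati, full_matrices=False)
    low_rank = (u[:, :n_remove] * s[:n_remove]) @ vh[:n_remove]
    filtered = (casorati - low_rank).reshape(nz, nx, nt)
    return FrameBlock(values=filtered, index=block.index,
                      start_frame=block.start_frame, svd_cut=n_remove)


def filter_stack(stack: FrameStack, block_size: int, n_remove: int) -> FrameStack:
    """SVD-filter every complete block of a stack; returns a filtered stack
    (trailing remainder dropped)."""
    blocks = [svd_filter(b, n_remove) for b in iter_blocks(stack, block_size)]
    values = np.concatenate([b.values for b in blocks], axis=2)
    return FrameStack(values=values, grid=stack.grid,
                      frame_rate_hz=stack.frame_rate_hz, provenance="filtered")
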