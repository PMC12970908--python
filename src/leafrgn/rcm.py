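"""Region confusion mechanism (RCM).

An image is partitioned into an N x N grid of regions and the regions are
shuffled under a locality constraint: for each row j a perturbed ramp
``q_{j,i} = i + r_i`` with ``r_i ~ U(-k, k)`` is drawn and the row's columns
are reordered by ``argsort(q_j)``; after all rows are shuffled the same
construction is applied to each column.  Sorting a ramp perturbed by at
most +-k moves no element more than 2k positions, so every region stays
within an adjustable neighbourhood of its origin while the global layout is
destroyed.  The stored permutation is exactly invertible and yields
region-alignment supervision targets (the normalized original coordinates
of the region occupying each grid slot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RegionGrid", "RegionPermutation", "make_permutation", "destroy",
           "restore", "alignment_targets", "alignment_loss"]


@dataclass(frozen=True)
class RegionGrid:
    """Partition geometry: N regions per side on a square image."""

    N: int = 8
    image_side: int = 128

    def __post_init__(self):
        if self.image_side % self.N:
            raise ValueError(f"N ({self.N}) must divide the image side ({self.image_side})")

    @property
    def region_side(self) -> int:
        return self.image_side // self.N


@dataclass(frozen=True)
class RegionPermutation:
    """A constrained row/column region shuffle.

    ``src_row[j, i]`` and ``src_col[j, i]`` give the original grid
    coordinates of the region placed at slot (j, i) of the shuffled image;
    ``row_perms[j]`` is the per-row column permutation sigma_j and
    ``col_perms[i]`` the per-column row permutation tau_i.
    """

    N: int
    k: int
    row_perms: np.ndarray   # (N, N) int, sigma_j = row_perms[j]
    col_perms: np.ndarray   # (N, N) int, tau_i = col_perms[i]
    src_row: np.ndarray     # (N, N) int
    src_col: np.ndarray     # (N, N) int

    def __post_init__(self):
        for perms in (self.row_perms, self.col_perms):
            if not np.array_equal(np.sort(perms, axis=1),
                                  np.tile(np.arange(self.N), (self.N, 1))):
                raise ValueError("each stored permutation must be a bijection on 0..N-1")

    @property
    def is_identity(self) -> bool:
        idx = np.arange(self.N)
        return (np.array_equal(self.src_row, np.tile(idx[:, None], (1, self.N)))
                and np.array_equal(self.src_col, np.tile(idx[None, :], (self.N, 1))))

    def inverse_slots(self) -> tuple[np.ndarray, np.ndarray]:
        """dst_row[r, c], dst_col[r, c]: the slot where original region (r, c) went."""
        dst_row = np.empty((self.N, self.N), dtype=np.int64)
        dst_col = np.empty((self.N, self.N), dtype=np.int64)
        dst_row[self.src_row, self.src_col] = np.arange(self.N)[:, None]
        dst_col[self.src_row, self.src_col] = np.arange(self.N)[None, :]
        return dst_row, dst_col


def make_permutation(N: int, k: int, rng: np.random.Generator) -> RegionPermutation:
    """Draw a constrained region permutation.

    Row permutations are applied first (columns within each row), then
    column permutations act on the already row-shuffled grid.  Ties in the
    perturbed ramp are broken by original index (stable sort); with a
    continuous uniform draw they have probability zero.
    """
    if not 1 <= k < N:
        raise ValueError(f"k must satisfy 1 <= k < N, got k={k}, N={N}")
    ramp = np.arange(N, dtype=np.float64)
    row_perms = np.empty((N, N), dtype=np.int64)
    for j in range(N):
        q = ramp + rng.uniform(-k, k, size=N)
        row_perms[j] = np.argsort(q, kind="stable")
    col_perms = np.empty((N, N), dtype=np.int64)
    for i in range(N):
        q = ramp + rng.uniform(-k, k, size=N)
        col_perms[i] = np.argsort(q, kind="stable")

    # final slot (j, i) holds intermediate (tau_i(j), i), which holds
    # original (tau_i(j), sigma_{tau_i(j)}(i))
    j_idx = np.arange(N)[:, None]
    i_idx = np.arange(N)[None, :]
    src_row = col_perms.T[j_idx, i_idx]          # tau_i(j)
    src_col = row_perms[src_row, i_idx]          # sigma_{tau_i(j)}(i)
    return RegionPermutation(N=N, k=k, row_perms=row_perms, col_perms=col_perms,
                             src_row=src_row, src_col=src_col)


def identity_permutation(N: int, k: int = 1) -> RegionPermutation:
    """The degenerate all-zero-draw shuffle (every region stays put)."""

    class _Zero:
        @staticmethod
        def uniform(lo, hi, size):
            return np.zeros(size)

    return make_permutation(N, k, _Zero())


def _blocks(image: np.ndarray, N: int) -> np.ndarray:
    side = image.shape[0]
    if image.ndim != 3 or image.shape[0] != image.shape[1]:
        raise ValueError(f"expected a square (H, W, C) image, got shape {image.shape}")
    if side % N:
        raise ValueError(f"image side ({side}) not divisible by N ({N})")
    s = side // N
    c = image.shape[2]
    return image.reshape(N, s, N, s, c).transpose(0, 2, 1, 3, 4)  # (N, N, s, s, C)


def _unblocks(blocks: np.ndarray) -> np.ndarray:
    N, _, s, _, c = blocks.shape
    return blocks.transpose(0, 2, 1, 3, 4).reshape(N * s, N * s, c)


def destroy(image: np.ndarray, perm: RegionPermutation) -> np.ndarray:
    """Apply the region shuffle to a channels-last square image."""
    blocks = _blocks(image, perm.N)
    return _unblocks(blocks[perm.src_row, perm.src_col])


def restore(shuffled: np.ndarray, perm: RegionPermutation) -> np.ndarray:
    """Exact inverse of :func:`destroy` for the same permutation."""
    blocks = _blocks(shuffled, perm.N)
    dst_row, dst_col = perm.inverse_slots()
    return _unblocks(blocks[dst_row, dst_col])


def alignment_targets(perm: RegionPermutation, origin_of_slot: bool = True) -> np.ndarray:
    """Supervision targets for the region-alignment head.

    Returns an (N, N, 2) array of normalized (row, col) coordinates in
    [0, 1] (region centres, i.e. ``(index + 0.5) / N``).  With the default
    convention each slot of the *shuffled* image is labelled with the
    original location of the region it now holds; ``origin_of_slot=False``
    gives the inverse convention (where each original region went).
    """
    if origin_of_slot:
        rows, cols = perm.src_row, perm.src_col
    else:
        rows, cols = perm.inverse_slots()
    return np.stack([(rows + 0.5) / perm.N, (cols + 0.5) / perm.N], axis=-1)


def alignment_loss(predicted: np.ndarray, targets: np.ndarray) -> float:
    """Mean absolute error over the 2*N^2 normalized coordinates."""
    predicted = np.asarray(predicted, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predicted.shape != targets.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {targets.shape}")
    return float(np.abs(predicted - targets).mean())
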