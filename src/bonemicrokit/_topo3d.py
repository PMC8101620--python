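"""Local 3×3×3 digital-topology primitives.

Everything here works on the 27-voxel neighborhood of a point, encoded as
a 27-bit integer so results can be memoized: neighborhood configurations
repeat massively during thinning, so the caches make the per-voxel
topology tests cheap after warm-up.

Connectivity pairing is (26, 6): the object is 26-connected, the
background 6-connected — the standard pairing that avoids paradoxes of
digital Jordan curves.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)

# offsets of the 6 face neighbors within the 3x3x3 block
_FACE_IDX = [(0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)]
# 18-neighborhood: face + edge neighbors (corners excluded)
_N18_MASK = np.zeros((3, 3, 3), dtype=bool)
for _dz in range(3):
    for _dy in range(3):
        for _dx in range(3):
            if abs(_dz - 1) + abs(_dy - 1) + abs(_dx - 1) in (1, 2):
                _N18_MASK[_dz, _dy, _dx] = True


def encode(block: np.ndarray) -> int:
    """Pack a 3×3×3 boolean block into a 27-bit integer."""
    return int(np.packbits(block.astype(np.uint8).ravel(), bitorder="little")[:4].view(np.uint32)[0])


def _decode(code: int) -> np.ndarray:
    bits = np.array([(code >> i) & 1 for i in range(27)], dtype=bool)
    return bits.reshape(3, 3, 3)


@lru_cache(maxsize=1 << 20)
def object_components_26(code: int) -> int:
    """Number of 26-connected object components among the 26 neighbors.

    The center voxel is excluded before labeling.
    """
    block = _decode(code)
    block[1, 1, 1] = False
    if not block.any():
        return 0
    _, n = ndimage.label(block, structure=_STRUCT26)
    return int(n)


@lru_cache(maxsize=1 << 20)
def background_components_6(code: int) -> int:
    """Number of 6-connected background components in the 18-neighborhood
    that are 6-adjacent to the center voxel."""
    block = _decode(code)
    bg = (~block) & _N18_MASK
    if not bg.any():
        return 0
    labels, n = ndimage.label(bg, structure=_STRUCT6)
    face_labels = {labels[idx] for idx in _FACE_IDX if labels[idx] != 0}
    return len(face_labels)


@lru_cache(maxsize=1 << 20)
def neighbor_count(code: int) -> int:
    """Number of object voxels among the 26 neighbors."""
    return bin(code & ~(1 << 13)).count("1")


def is_simple(code: int) -> bool:
    """Topology-preserving deletability of the center voxel.

    A voxel is *simple* iff its removal changes neither object nor
    background topology locally: exactly one 26-object component among
    its neighbors and exactly one 6-background component adjacent to it.
    """
    return object_components_26(code) == 1 and background_components_6(code) == 1


def extract_block(mask: np.ndarray, z: int, y: int, x: int) -> np.ndarray:
    """3×3×3 neighborhood of (z, y, x), zero-padded at the array border."""
    block = np.zeros((3, 3, 3), dtype=bool)
    z0, z1 = max(z - 1, 0), min(z + 2, mask.shape[0])
    y0, y1 = max(y - 1, 0), min(y + 2, mask.shape[1])
    x0, x1 = max(x - 1, 0), min(x + 2, mask.shape[2])
    block[z0 - z + 1 : z1 - z + 1, y0 - y + 1 : y1 - y + 1, x0 - x + 1 : x1 - x + 1] = \
        mask[z0:z1, y0:y1, x0:x1]
    return block
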