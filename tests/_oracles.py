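"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain-python loops and
flood-fill, with no reliance on the package's own vectorised code paths.
"""

from __future__ import annotations

import numpy as np


def flood_fill_components(binary: np.ndarray) -> list[set[tuple[int, int, int]]]:
    """26-connected components of a boolean 3D grid via BFS flood fill."""
    shape = binary.shape
    seen = np.zeros(shape, dtype=bool)
    comps: list[set[tuple[int, int, int]]] = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for idx in zip(*np.nonzero(binary)):
        if seen[idx]:
            continue
        comp = set()
        stack = [idx]
        seen[idx] = True
        while stack:
            cur = stack.pop()
            comp.add(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= n < s for n, s in zip(nb, shape)):
                    if binary[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
        comps.append(comp)
    return comps


def brute_force_match(cand_labels: np.ndarray, ref_labels: np.ndarray,
                      class_code: int) -> dict:
    """Lesion matching by exhaustive voxel-overlap enumeration.

    Returns tp/fp/fn counts, detected-reference count, sensitivity and PPV
    computed straight from the definitions.
    """
    cand_comps = flood_fill_components(cand_labels == class_code)
    ref_comps = flood_fill_components(ref_labels == class_code)
    detected = sum(
        1 for rc in ref_comps if any(rc & cc for cc in cand_comps)
    )
    fn = len(ref_comps) - detected
    tp = sum(1 for cc in cand_comps if any(cc & rc for rc in ref_comps))
    fp = len(cand_comps) - tp
    n_ref = len(ref_comps)
    return {
        "tp": tp, "fp": fp, "fn": fn, "detected": detected, "n_ref": n_ref,
        "sensitivity": detected / n_ref if n_ref else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
    }


def mirror_index(i: int, n: int) -> int:
    """Reflect an out-of-range index about the array boundary without
    repeating the edge value (period 2n - 2)."""
    if n == 1:
        return 0
    period = 2 * n - 2
    i = i % period
    return i if i < n else period - i


def mirror_window(arr: np.ndarray, starts, size) -> np.ndarray:
    """Extract a window with mirror padding by explicit index reflection."""
    out = np.empty(size, dtype=arr.dtype)
    for ia in range(size[0]):
        for ib in range(size[1]):
            for ic in range(size[2]):
                src = (
                    mirror_index(starts[0] + ia, arr.shape[0]),
                    mirror_index(starts[1] + ib, arr.shape[1]),
                    mirror_index(starts[2] + ic, arr.shape[2]),
                )
                out[ia, ib, ic] = arr[src]
    return out


def random_lesion_labels(rng: np.random.Generator, shape=(6, 6, 6),
                         max_blobs: int = 3) -> np.ndarray:
    """Random small multi-class label map made of overlapping boxes."""
    labels = np.zeros(shape, dtype=np.int16)
    for _ in range(rng.integers(0, max_blobs + 1)):
        cls = int(rng.integers(1, 4))
        lo = [int(rng.integers(0, s - 1)) for s in shape]
        hi = [int(rng.integers(l + 1, min(l + 3, s) + 1)) for l, s in zip(lo, shape)]
        labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = cls
    return labels
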