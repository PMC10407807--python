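"""Independent brute-force oracles used by the tests.

These enumerate pixel pairs with explicit Python loops and stay
deliberately independent of the vectorized implementations they check.
"""

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_cooccurrence_counts(image, mask, distance=1, angles=(0, 45, 90, 135),
                              symmetric=True, levels=256):
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    h, w = image.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    for a in angles:
        dy, dx = OFFSETS[a][0] * distance, OFFSETS[a][1] * distance
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dy, c + dx
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    counts[image[r, c], image[r2, c2]] += 1
                    if symmetric:
                        counts[image[r2, c2], image[r, c]] += 1
    return counts


def brute_difference_counts(image, mask, distance=1, angles=(0, 45, 90, 135), levels=256):
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    h, w = image.shape
    counts = np.zeros(levels, dtype=np.int64)
    for a in angles:
        dy, dx = OFFSETS[a][0] * distance, OFFSETS[a][1] * distance
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dy, c + dx
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    counts[abs(int(image[r, c]) - int(image[r2, c2]))] += 1
    return counts
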