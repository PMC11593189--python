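"""Shared exhaustive-enumeration GLCM oracle, independent of the package code."""
import numpy as np


def glcm_enumeration_oracle(img, offset, levels, symmetric=True):
    di, dj = offset
    rows, cols = img.shape
    counts = np.zeros((levels, levels))
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + di, c + dj
            if 0 <= r2 < rows and 0 <= c2 < cols and img[r, c] >= 0 and img[r2, c2] >= 0:
                counts[img[r, c], img[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()
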