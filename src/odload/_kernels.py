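"""Optional numba-accelerated inner loops for the bit-packed engine.

Pure-numpy fallbacks keep the package fully functional without numba; the
compiled paths walk the bit matrix in 64-bit words and skip zero words,
which is where almost all time goes at mutation-selection balance (allele
frequencies are low, so the matrix is sparse in set bits).

Byte order: columns are packed MSB-first within each byte (matching
``np.packbits``/``np.unpackbits``); 64-bit words are read little-endian, so
byte ``k`` of word ``j`` is global byte ``8 j + k``.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def _as_words(H: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(H).view(np.uint64)


# ------------------------------------------------------------ numpy paths
def _score_pairs_numpy(
    g1: np.ndarray, g2: np.ndarray, lut_x: np.ndarray, lut_a: np.ndarray
) -> np.ndarray:
    nb = lut_x.shape[0]
    idx = np.arange(nb)[None, :]
    return lut_x[idx, g1 ^ g2].sum(axis=1, dtype=np.float64) + lut_a[
        idx, g1 & g2
    ].sum(axis=1, dtype=np.float64)


def _popcount_columns_numpy(H: np.ndarray) -> np.ndarray:
    return np.unpackbits(H, axis=1).sum(axis=0, dtype=np.int64)


def _gamete_batch_numpy(
    H: np.ndarray, parents: np.ndarray, masks: np.ndarray
) -> np.ndarray:
    h1 = H[2 * parents]
    h2 = H[2 * parents + 1]
    return (h1 & masks) | (h2 & ~masks)


if HAVE_NUMBA:

    @numba.njit(cache=True)
    def _score_pairs_nb(g1w, g2w, lut_x, lut_a):  # pragma: no cover - compiled
        M, nw = g1w.shape
        out = np.zeros(M, dtype=np.float64)
        for i in range(M):
            acc = 0.0
            for j in range(nw):
                a = g1w[i, j]
                b = g2w[i, j]
                if a | b:
                    x = a ^ b
                    d = a & b
                    for k in range(8):
                        xb = (x >> (8 * k)) & 0xFF
                        db = (d >> (8 * k)) & 0xFF
                        if xb | db:
                            acc += lut_x[8 * j + k, xb] + lut_a[8 * j + k, db]
            out[i] = acc
        return out

    @numba.njit(cache=True)
    def _popcount_words_nb(Hw):  # pragma: no cover - compiled
        nrow, nw = Hw.shape
        counts = np.zeros(nw * 64, dtype=np.int64)
        for i in range(nrow):
            for j in range(nw):
                w = Hw[i, j]
                if w:
                    for k in range(8):
                        b = (w >> (8 * k)) & 0xFF
                        if b:
                            base = (8 * j + k) * 8
                            for m in range(8):
                                if b & (0x80 >> m):
                                    counts[base + m] += 1
        return counts

    @numba.njit(cache=True)
    def _gamete_batch_nb(Hw, parents, masksw):  # pragma: no cover - compiled
        M, nw = masksw.shape
        out = np.empty((M, nw), dtype=np.uint64)
        for i in range(M):
            r1 = 2 * parents[i]
            r2 = r1 + 1
            for j in range(nw):
                m = masksw[i, j]
                out[i, j] = (Hw[r1, j] & m) | (Hw[r2, j] & ~m)
        return out

    def score_pairs(g1, g2, lut_x, lut_a):
        return _score_pairs_nb(_as_words(g1), _as_words(g2), lut_x, lut_a)

    def popcount_columns(H):
        return _popcount_words_nb(_as_words(H))[: H.shape[1] * 8]

    def gamete_batch(H, parents, masks):
        out = _gamete_batch_nb(
            _as_words(H), np.ascontiguousarray(parents), _as_words(masks)
        )
        return out.view(np.uint8)

else:
    score_pairs = _score_pairs_numpy
    popcount_columns = _popcount_columns_numpy
    gamete_batch = _gamete_batch_numpy
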