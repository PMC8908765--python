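"""Inner loops of online SOM training.

The sequential (per-frame) update is the performance-critical part of
the package, so it is compiled with numba when available.  A pure-numpy
fallback with identical per-frame sequencing is used otherwise; the two
backends agree to floating-point rounding (the fallback vectorizes the
per-neuron reductions, so bit-level reproducibility is guaranteed only
within a backend).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _train_epoch_numba(codebook, data, order, lrs, radii, map_dist):
    """One pass over ``data`` in ``order``; mutates codebook in place.

    Returns the mean pre-update BMU distance (quantization error of the
    epoch, measured as frames are presented).
    """
    n_neurons, n_feat = codebook.shape
    total = 0.0
    for s in range(order.shape[0]):
        i = order[s]
        best = 0
        bestd = np.inf
        for j in range(n_neurons):
            d = 0.0
            for f in range(n_feat):
                diff = data[i, f] - codebook[j, f]
                d += diff * diff
            if d < bestd:
                bestd = d
                best = j
        total += np.sqrt(bestd)
        lr = lrs[s]
        rad = radii[s]
        denom = 2.0 * rad * rad
        for j in range(n_neurons):
            md = map_dist[best, j]
            if md <= rad:
                h = lr * np.exp(-(md * md) / denom)
                for f in range(n_feat):
                    codebook[j, f] += h * (data[i, f] - codebook[j, f])
    return total / order.shape[0]


def _train_epoch_numpy(codebook, data, order, lrs, radii, map_dist):
    total = 0.0
    for s, i in enumerate(order):
        x = data[i]
        d2 = ((codebook - x) ** 2).sum(axis=1)
        best = int(np.argmin(d2))  # argmin takes the first minimum: lowest index
        total += np.sqrt(d2[best])
        rad = radii[s]
        md = map_dist[best]
        mask = md <= rad
        h = lrs[s] * np.exp(-(md[mask] ** 2) / (2.0 * rad * rad))
        codebook[mask] += h[:, None] * (x - codebook[mask])
    return total / len(order)


train_epoch = _train_epoch_numba if HAVE_NUMBA else _train_epoch_numpy
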