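"""Independent reference implementations used as test oracles.

Deliberately brute-force / textbook-style and kept separate from the
package code paths they check.
"""

import numpy as np


def numerical_gradient(model, x, r, d, h=1e-5):
    """Central-difference gradient of E = 1/2 sum D (r - p)^2 over all params."""
    from srmd.gwann import forward

    def loss():
        out = forward(model, x)[-1]
        return 0.5 * np.sum(d * (r[:, None] - out) ** 2)

    grads_w, grads_b = [], []
    for arr_list, grads in ((model.weights, grads_w), (model.biases, grads_b)):
        for arr in arr_list:
            g = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                old = arr[idx]
                arr[idx] = old + h
                e_plus = loss()
                arr[idx] = old - h
                e_minus = loss()
                arr[idx] = old
                g[idx] = (e_plus - e_minus) / (2 * h)
            grads.append(g)
    return grads_w, grads_b


class PlainANN:
    """Standard full-batch backpropagation with tanh layers; no geography."""

    def __init__(self, weights, biases):
        self.w = [w.copy() for w in weights]
        self.b = [b.copy() for b in biases]

    def epoch(self, x, r, eta):
        acts = [x]
        a = x
        for w, b in zip(self.w, self.b):
            a = np.tanh(a @ w + b)
            acts.append(a)
        err = float(0.5 * np.sum(np.ones_like(a) * (r[:, None] - a) ** 2) / x.shape[0])
        delta = (1.0 - a**2) * (np.ones_like(a) * (a - r[:, None]))
        deltas = [delta]
        for l in range(len(self.w) - 1, 0, -1):
            delta = (1.0 - acts[l] ** 2) * (deltas[0] @ self.w[l].T)
            deltas.insert(0, delta)
        lr = eta / x.shape[0]
        for l in range(len(self.w)):
            self.w[l] -= lr * (acts[l].T @ deltas[l])
            self.b[l] -= lr * deltas[l].sum(axis=0)
        return err


def brute_force_distance_km(grid, region_mask):
    """O(n^2) min centre-to-centre distance from every cell to the region."""
    rr, cc = np.nonzero(region_mask)
    out = np.zeros(grid.shape)
    for r in range(grid.shape[0]):
        for c in range(grid.shape[1]):
            d2 = (r - rr) ** 2 + (c - cc) ** 2
            out[r, c] = np.sqrt(d2.min()) * grid.cell_size_m / 1000.0
    return out


def brute_force_min_distances(srmd_boundary, mine_boundary, cell_km):
    """All-pairs minimum distances between two boundary pixel sets, km."""
    sb = np.argwhere(srmd_boundary)
    mb = np.argwhere(mine_boundary)
    out = []
    for r, c in sb:
        d2 = ((mb - (r, c)) ** 2).sum(axis=1)
        out.append(np.sqrt(d2.min()) * cell_km)
    return np.array(out)


def nearest_rank_percentile(samples, percent):
    """Sort-and-index percentile: the ceil(p n)-th ascending value."""
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    rank = max(1, int(np.ceil(percent / 100.0 * s.size)))
    return float(s[rank - 1])
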