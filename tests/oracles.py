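"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration, first-principles formulas) and shares no code with the
package implementation paths it checks.
"""

from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# Graph oracles (dense boolean adjacency, n small)
# ---------------------------------------------------------------------------

def floyd_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    d[adj.astype(bool)] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        out[v] = tri / (k * (k - 1) / 2)
    return out


def brute_path_length(adj: np.ndarray) -> float:
    d = floyd_distances(adj)
    vals = [d[i, j] for i in range(len(adj)) for j in range(len(adj))
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def brute_global_efficiency(adj: np.ndarray) -> float:
    d = floyd_distances(adj)
    n = len(adj)
    if n < 2:
        return 0.0
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
            for i, j in combinations(range(n), 2)]
    return float(np.mean(vals))


def _all_shortest_paths(adj, s, t, dist):
    """Enumerate every geodesic from s to t by DFS."""
    if s == t:
        return [[s]]
    paths = []
    for u in range(len(adj)):
        if adj[s, u] and dist[u, t] == dist[s, t] - 1:
            for rest in _all_shortest_paths(adj, u, t, dist):
                paths.append([s] + rest)
    return paths


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness by exhaustive geodesic enumeration."""
    n = len(adj)
    dist = floyd_distances(adj)
    btw = np.zeros(n)
    for s, t in combinations(range(n), 2):
        if not np.isfinite(dist[s, t]) or dist[s, t] == 0:
            continue
        paths = _all_shortest_paths(adj, s, t, dist)
        for path in paths:
            for v in path[1:-1]:
                btw[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return btw / norm if norm > 0 else btw


def brute_modularity(adj: np.ndarray, partition) -> float:
    """Q = sum_c (e_c/m - (d_c/2m)^2) evaluated directly."""
    m = adj.sum() / 2.0
    q = 0.0
    for comm in partition:
        comm = list(comm)
        e_c = sum(adj[i, j] for i, j in combinations(comm, 2))
        d_c = sum(adj[i].sum() for i in comm)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


# ---------------------------------------------------------------------------
# Spectral / connectivity oracles
# ---------------------------------------------------------------------------

def brute_wpli(data: np.ndarray, fs: float, band, window: float = 2.0,
               overlap: float = 0.5) -> np.ndarray:
    """wPLI from raw Hann-tapered segment FFTs, via the defining ratio
    with explicit loops (no shared code with the package)."""
    n_ch, n_samp = data.shape
    nper = int(round(window * fs))
    step = nper - int(round(nper * overlap))
    win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nper) / nper)  # periodic Hann
    starts = list(range(0, n_samp - nper + 1, step))
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    bins = [k for k, f in enumerate(freqs) if band[0] - 1e-9 <= f <= band[1] + 1e-9]
    ffts = [[np.fft.rfft(data[c, s:s + nper] * win) for c in range(n_ch)]
            for s in starts]
    out = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(n_ch):
            if i == j:
                continue
            vals = []
            for k in bins:
                ims = [np.imag(ffts[s][i][k] * np.conj(ffts[s][j][k]))
                       for s in range(len(starts))]
                num = abs(np.mean(ims))
                den = np.mean(np.abs(ims))
                vals.append(num / den if den > 0 else 0.0)
            out[i, j] = np.mean(vals)
    return out


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------

def brute_permutation_p(x, y) -> float:
    """Exact two-sided permutation p by full enumeration of label splits."""
    pooled = list(x) + list(y)
    nx = len(x)
    obs = abs(np.mean(pooled[:nx]) - np.mean(pooled[nx:]))
    count, total = 0, 0
    for idx in combinations(range(len(pooled)), nx):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(np.mean(a) - np.mean(b)) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def brute_split_plot_ss(data: np.ndarray, groups) -> dict:
    """Split-plot sums of squares from the textbook cell-mean formulas,
    computed with explicit loops."""
    data = np.asarray(data, dtype=float)
    groups = list(groups)
    n, k = data.shape
    levels = sorted(set(groups), key=str)
    grand = data.mean()

    ss_group = 0.0
    for g in levels:
        rows = [i for i in range(n) if groups[i] == g]
        ss_group += len(rows) * k * (data[rows].mean() - grand) ** 2

    ss_between_subj = 0.0
    for i in range(n):
        ss_between_subj += k * (data[i].mean() - grand) ** 2
    ss_err_between = ss_between_subj - ss_group

    ss_band = 0.0
    for b in range(k):
        ss_band += n * (data[:, b].mean() - grand) ** 2

    ss_inter = 0.0
    for g in levels:
        rows = [i for i in range(n) if groups[i] == g]
        gm = data[rows].mean()
        for b in range(k):
            cell = data[rows][:, b].mean()
            ss_inter += len(rows) * (cell - gm - data[:, b].mean() + grand) ** 2

    ss_within = 0.0
    for i in range(n):
        for b in range(k):
            ss_within += (data[i, b] - data[i].mean()) ** 2
    ss_err_within = ss_within - ss_band - ss_inter
    return {"group": ss_group, "err_between": ss_err_between,
            "band": ss_band, "interaction": ss_inter,
            "err_within": ss_err_within,
            "total": float(((data - grand) ** 2).sum())}
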