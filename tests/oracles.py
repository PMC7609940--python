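"""Independent brute-force oracles shared by the test modules.

These recompute statistics from first principles (own t formula, own
breadth-first clustering, exhaustive enumeration of sign assignments)
and never call the implementation under test.
"""

import itertools

import numpy as np


def oracle_t(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    sd = D.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = D.mean(axis=0) / (sd / np.sqrt(n))
    return np.nan_to_num(t)


def oracle_clusters(t_map: np.ndarray, t_crit: float) -> list[float]:
    """Signed t-sums of 4-connected supra-threshold clusters (BFS)."""
    visited = np.zeros(t_map.shape, bool)
    out = []
    for sign in (1, -1):
        supra = sign * t_map > t_crit
        for start in zip(*np.nonzero(supra & ~visited)):
            stack, total = [start], 0.0
            visited[start] = True
            while stack:
                i, j = stack.pop()
                total += t_map[i, j]
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = i + di, j + dj
                    if (0 <= ni < t_map.shape[0]
                            and 0 <= nj < t_map.shape[1]
                            and supra[ni, nj] and not visited[ni, nj]):
                        visited[ni, nj] = True
                        stack.append((ni, nj))
            out.append(total)
    return out


def oracle_exact_fwe(D: np.ndarray, t_crit: float) -> dict[float, float]:
    """Exact FWE p for each observed cluster, over all 2^n assignments."""
    n = D.shape[0]
    obs = oracle_clusters(oracle_t(D), t_crit)
    null = []
    for signs in itertools.product([1, -1], repeat=n):
        t = oracle_t(np.asarray(signs)[:, None, None] * D)
        sums = oracle_clusters(t, t_crit)
        null.append(max((abs(s) for s in sums), default=0.0))
    null = np.asarray(null)
    return {round(s, 10): float(np.mean(null >= abs(s))) for s in obs}
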