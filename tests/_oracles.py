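"""Independent straight-from-definition oracles used to cross-check the package.

These deliberately share no code with micronet: the PCIT oracle is a scalar
triple loop over unordered trios, the scan oracle a position-by-position
string comparison, and the enrichment oracle an exact combinatorial sum.
"""

import itertools
import math

import numpy as np


def pcit_oracle(R: np.ndarray) -> np.ndarray:
    """PCIT significance by literal enumeration of every unordered trio."""
    n = R.shape[0]
    knocked = np.zeros((n, n), dtype=bool)
    for x, y, z in itertools.combinations(range(n), 3):
        edges = [((x, y), z), ((x, z), y), ((y, z), x)]
        ratios = []
        for (a, b), c in edges:
            r_ab, r_ac, r_bc = R[a, b], R[a, c], R[b, c]
            den = math.sqrt(max((1 - r_ac**2) * (1 - r_bc**2), 0.0))
            if r_ab != 0 and den > 1e-12:
                partial = (r_ab - r_ac * r_bc) / den
                ratios.append(abs(partial / r_ab))
        if not ratios:
            continue  # degenerate trio: skipped, knocks nothing out
        eps = sum(ratios) / len(ratios)
        for (a, b), c in edges:
            if abs(R[a, b]) < eps * abs(R[a, c]) and abs(R[a, b]) < eps * abs(R[b, c]):
                knocked[a, b] = knocked[b, a] = True
    significant = ~knocked
    np.fill_diagonal(significant, False)
    return significant


def scan_oracle(utr: str, site: str) -> list[int]:
    """All overlapping exact occurrences by character-wise comparison."""
    return [i for i in range(len(utr) - len(site) + 1) if utr[i : i + len(site)] == site]


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for Hypergeometric(N, K, n) by enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    ) / total


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook covariance / (sigma_x sigma_y)."""
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def random_correlation(rng: np.random.Generator, n_nodes: int, n_obs: int = 12) -> np.ndarray:
    """A valid correlation matrix: empirical correlation of random data."""
    data = rng.normal(size=(n_nodes, n_obs))
    R = np.corrcoef(data)
    np.fill_diagonal(R, 1.0)
    return R
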