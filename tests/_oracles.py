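"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
explicit dynamic programming for local alignment, parent-chain walking
for hierarchy expansion, ancestor-set intersection for the LCA, mid-rank
Pearson arithmetic for Spearman, and an explicit hat-matrix eigenproblem
for CCA.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def sw_affine_score(a: str, b: str, gap_open: int = 11,
                    gap_extend: int = 1) -> float:
    """Smith-Waterman with affine gaps (gap of length L costs open + L*extend),
    full Gotoh dynamic programming, quadratic memory."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _B62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def expand_by_parent_walk(h, seeds: list[int]) -> set[str]:
    """Domain ids whose ancestor chain meets any seed (walks parents up)."""
    seeds = set(seeds)
    out = set()
    for node in h.nodes.values():
        if node.level != "domain":
            continue
        t = node.sunid
        while t is not None:
            if t in seeds:
                out.add(node.identifier)
                break
            t = h.nodes[t].parent_sunid
    return out


def lca_by_ancestor_sets(taxonomy, tax_ids: list[int]) -> int:
    """Deepest node in the intersection of full ancestor sets."""
    ancestor_sets = []
    for t in tax_ids:
        path = taxonomy.path_to_root(t)
        ancestor_sets.append(set(path))
    common = set.intersection(*ancestor_sets)
    return max(common, key=lambda t: len(taxonomy.path_to_root(t)))


def midrank(v: np.ndarray) -> np.ndarray:
    """Mid-ranks computed by explicit tie-group averaging."""
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), float)
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_midrank_pearson(x, y) -> float:
    rx, ry = midrank(np.asarray(x, float)), midrank(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def spearman_perm_p_enumerated(x, y) -> float:
    """Two-sided exact p by explicit enumeration of all orderings of y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    obs = abs(spearman_midrank_pearson(x, y))
    hits = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        r = abs(spearman_midrank_pearson(x, y[list(perm)]))
        hits += r >= obs - 1e-12
        total += 1
    return hits / total


def cca_one_constraint_eigenvalue(Y: np.ndarray, x: np.ndarray) -> float:
    """Largest eigenvalue of the constrained part via an explicit hat
    matrix and dense symmetric eigendecomposition."""
    Y = np.asarray(Y, float)
    total = Y.sum()
    P = Y / total
    r, c = P.sum(axis=1), P.sum(axis=0)
    Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    xc = x - np.dot(r, x)
    Xw = (np.sqrt(r) * xc)[:, None]
    hat = Xw @ np.linalg.inv(Xw.T @ Xw) @ Xw.T
    Qhat = hat @ Qbar
    vals = np.linalg.eigvalsh(Qhat @ Qhat.T)
    return float(vals[-1])


def chi_square_over_total(Y: np.ndarray) -> float:
    """Pearson chi-square statistic of the table divided by its grand total."""
    Y = np.asarray(Y, float)
    total = Y.sum()
    exp = np.outer(Y.sum(axis=1), Y.sum(axis=0)) / total
    return float(((Y - exp) ** 2 / exp).sum() / total)
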