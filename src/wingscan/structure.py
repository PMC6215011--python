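"""Population-structure diagnostics: GRM, NJ relatedness tree, PCA, clustering.

These operations establish (or refute) neutral differentiation in the sample.
For the sympatric morphotype design the expected outcome is *no* structure:
one BIC-optimal cluster, no principal component aligned with morph, and a
relatedness tree without morph-sorted clades — leaving locus-specific scans
as the only place a genetic signal can appear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .genotype import MISSING, GenotypeMatrix


@dataclass
class PcaResult:
    """Scores, eigenvalues and the loci used for a genotype PCA.

    ``eigenvalues`` is the full nonincreasing spectrum (singular values
    squared over ``n − 1``); ``scores`` holds the first ``k_max`` columns.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    loci_used: list[str]


def _freq_and_standardize(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled frequencies, polymorphic-locus mask, and the centered matrix
    with missing entries contributing zero."""
    p = gm.alt_freq()
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    calls = gm.calls.astype(float)
    called = gm.called_mask()
    z = np.where(called, calls - 2.0 * p, 0.0)
    return p, poly, z


def grm(gm: GenotypeMatrix) -> np.ndarray:
    """Allele-frequency-standardized (VanRaden-type) genomic relatedness.

    ``G = Z Zᵀ / (2 Σ_k p̂_k (1 − p̂_k))`` with ``Z`` the 2p̂-centered
    genotype matrix; missing genotypes are mean-imputed, i.e. contribute
    zero after centering.  Monomorphic loci are excluded.
    """
    if gm.n_individuals < 2:
        raise ValueError("GRM requires at least two individuals")
    if (~gm.called_mask()).all(axis=1).any():
        raise ValueError("GRM undefined for an individual with no called genotypes")
    p, poly, z = _freq_and_standardize(gm)
    if not poly.any():
        raise ValueError("no polymorphic loci")
    z = z[:, poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    g = (z @ z.T) / denom
    return (g + g.T) / 2.0


def grm_to_distance(g: np.ndarray) -> np.ndarray:
    """Squared-Euclidean distance induced by a relatedness matrix:
    ``d(x, y) = G_xx + G_yy − 2 G_xy`` (clipped at zero)."""
    d = np.diag(g)[:, None] + np.diag(g)[None, :] - 2.0 * g
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("label", "children")  # children: list[(child, branch_length)]

    def __init__(self, label: str | None = None):
        self.label = label
        self.children: list[tuple["_Node", float]] = []

    def newick(self) -> str:
        return self._fmt() + ";"

    def _fmt(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c._fmt()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(d: np.ndarray, labels: list[str], atol: float = 1e-8) -> str:
    """Saitou–Nei neighbor joining; returns a newick string.

    Uses the standard Q-criterion.  A negative branch length is clamped to
    zero with the deficit transferred to the sister branch, preserving the
    path length between the joined pair.  Exactly reproduces any additive
    distance matrix.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if d.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix and labels are inconsistent")
    if not np.allclose(d, d.T, atol=atol):
        raise ValueError("distance matrix is not symmetric within tolerance")
    d = (d + d.T) / 2.0

    nodes: list[_Node] = [_Node(str(l)) for l in labels]
    active = list(range(n))
    dm = d.copy()

    while len(active) > 3:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(q), q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        a, b = active[i_s], active[j_s]
        dab = sub[i_s, j_s]
        la = 0.5 * dab + (r[i_s] - r[j_s]) / (2.0 * (m - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        parent = _Node()
        parent.children = [(nodes[a], la), (nodes[b], lb)]
        # distances from the new node to the remaining taxa
        new_row = np.full(dm.shape[0] + 1, 0.0)
        for idx in active:
            if idx in (a, b):
                continue
            new_row[idx] = 0.5 * (dm[a, idx] + dm[b, idx] - dab)
        dm = np.pad(dm, ((0, 1), (0, 1)))
        dm[-1, : len(new_row) - 1] = new_row[:-1]
        dm[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [dm.shape[0] - 1]

    # final three-way join (closed form)
    a, b, c = active
    la = 0.5 * (dm[a, b] + dm[a, c] - dm[b, c])
    lb = 0.5 * (dm[a, b] + dm[b, c] - dm[a, c])
    lc = 0.5 * (dm[a, c] + dm[b, c] - dm[a, b])
    la, lb, lc = _clamp_triplet(la, lb, lc)
    root = _Node()
    root.children = [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    return root.newick()


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def _clamp_triplet(la: float, lb: float, lc: float) -> tuple[float, float, float]:
    vals = [la, lb, lc]
    for i in range(3):
        if vals[i] < 0:
            deficit = vals[i]
            vals[i] = 0.0
            # transfer to the largest sibling to preserve total length
            j = int(np.argmax(vals))
            vals[j] += deficit
    return tuple(max(v, 0.0) for v in vals)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# PCA and cluster-number selection
# ---------------------------------------------------------------------------


def pca(gm: GenotypeMatrix, k_max: int) -> PcaResult:
    """PCA of per-locus standardized genotypes.

    Standardization is ``(g − 2 p̂) / sqrt(2 p̂ (1 − p̂))`` with missing
    entries imputed to zero after centering; monomorphic loci are excluded.
    """
    if gm.n_individuals < 2:
        raise ValueError("PCA requires at least two individuals")
    p, poly, z = _freq_and_standardize(gm)
    if poly.sum() < 2:
        raise ValueError("PCA requires at least two polymorphic loci")
    if k_max > min(gm.n_individuals, int(poly.sum())):
        raise ValueError("k_max exceeds min(individuals, polymorphic loci)")
    scale = np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    x = z[:, poly] / scale
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (gm.n_individuals - 1)
    scores = u[:, :k_max] * s[:k_max]
    return PcaResult(
        scores=scores,
        eigenvalues=eig,
        loci_used=[lid for j, lid in enumerate(gm.locus_ids) if poly[j]],
    )


def choose_k_bic(result: PcaResult, k_max: int, seed: int = 0) -> int:
    """Select the number of clusters by k-means + BIC on PC scores.

    ``BIC(k) = n ln(WSS_k / n) + k ln n``; ties (within 1e-9) break toward
    smaller k.  k-means uses 25 restarts with a fixed seed.
    """
    x = np.asarray(result.scores, dtype=float)
    n = x.shape[0]
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    if k_max > n:
        raise ValueError("k_max cannot exceed the number of individuals")
    best_k, best_bic = 1, np.inf
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((x - x.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(x)
            wss = float(km.inertia_)
        if wss <= 0:
            bic = -np.inf
        else:
            bic = n * np.log(wss / n) + k * np.log(n)
        if bic < best_bic - 1e-9:
            best_k, best_bic = k, bic
    return best_k


def scree_k(eigenvalues: np.ndarray, tau: float = 0.1) -> int:
    """Automated Cattell elbow rule for the number of retained components.

    Returns the largest index ``i`` (1-based) such that
    ``λ_i − λ_{i+1} > tau · (λ_1 − λ_last)``; at least 1.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size < 2:
        raise ValueError("need at least two eigenvalues")
    if np.any(np.diff(eig) > 1e-12):
        raise ValueError("eigenvalues must be nonincreasing")
    drops = -np.diff(eig)
    cutoff = tau * (eig[0] - eig[-1])
    big = np.where(drops > cutoff)[0]
    return int(big[-1]) + 1 if big.size else 1
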