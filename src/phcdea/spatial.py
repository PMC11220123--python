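"""Spatial weights and global/local Moran's I with permutation inference.

Global Moran's I for values x over a weights matrix W is

    I = sum_ij w_ij (x_i - xbar)(x_j - xbar) / (S^2 * S0),

with S^2 = (1/n) sum_i (x_i - xbar)^2 and S0 = sum_ij w_ij — algebraically
the familiar (n / S0) normalized cross-product form.  Its expectation under
spatial randomness is -1/(n-1).  The local statistic

    I_i = (x_i - xbar) / S^2 * sum_j w_ij (x_j - xbar)

satisfies sum_i I_i = I * S0 exactly, and each unit is classified into a
high-high / high-low / low-high / low-low quadrant from the signs of its
centered value and centered spatial lag.  Inference is by full random
relabelling (global) or conditional relabelling holding x_i fixed (local),
plus the closed-form randomization-variance normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

QUADRANTS = ("high-high", "high-low", "low-high", "low-low")


@dataclass
class SpatialWeights:
    labels: list
    W: np.ndarray
    standardized: bool = False
    provenance: str = "custom"

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.shape != (len(self.labels), len(self.labels)):
            raise ValueError("weight matrix shape does not match labels")
        if np.any(W < 0):
            raise ValueError("negative spatial weights")
        if np.any(np.diag(W) != 0):
            raise ValueError("nonzero diagonal in weight matrix")
        self.W = W

    @property
    def n(self) -> int:
        return len(self.labels)

    def row_standardize(self) -> "SpatialWeights":
        rs = self.W.sum(axis=1)
        if np.any(rs == 0):
            iso = self.labels[int(np.argmin(rs))]
            raise ValueError(f"isolated unit {iso!r} cannot be row-standardized")
        return SpatialWeights(self.labels, self.W / rs[:, None], True,
                              self.provenance + "|row-standardized")

    def align(self, labels) -> "SpatialWeights":
        """Reorder rows/columns to a given label order."""
        idx = [self.labels.index(l) for l in labels]
        return SpatialWeights(list(labels), self.W[np.ix_(idx, idx)],
                              self.standardized, self.provenance)


def weights_from_edges(labels, edges, standardize: bool = True) -> SpatialWeights:
    """Binary contiguity weights from an undirected edge list.

    Duplicate edges collapse to a single link; an isolated unit raises
    (with the unit named) because a row-standardized matrix needs every
    row to have at least one neighbour.
    """
    labels = list(labels)
    index = {l: i for i, l in enumerate(labels)}
    W = np.zeros((len(labels), len(labels)))
    for a, b in edges:
        if a not in index or b not in index:
            raise ValueError(f"edge ({a!r}, {b!r}) references unknown unit")
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        W[index[a], index[b]] = W[index[b], index[a]] = 1.0
    w = SpatialWeights(labels, W, False, "contiguity")
    return w.row_standardize() if standardize else w


def read_gal(path, standardize: bool = True) -> SpatialWeights:
    """Read a GAL-style neighbour list.

    Format: a header line with the unit count, then per unit a line
    ``label n_neighbours`` followed by a line of neighbour labels.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    lines = [ln.split() for ln in tokens if ln.strip()]
    n = int(lines[0][-1])
    labels, edges = [], []
    i = 1
    while i < len(lines):
        label, deg = lines[i][0], int(lines[i][1])
        labels.append(label)
        if deg:
            edges += [(label, nb) for nb in lines[i + 1]]
            if len(lines[i + 1]) != deg:
                raise ValueError(f"unit {label!r}: expected {deg} neighbours")
            i += 2
        else:
            i += 1
    if len(labels) != n:
        raise ValueError(f"GAL header says {n} units, found {len(labels)}")
    return weights_from_edges(labels, edges, standardize)


def weights_knn(labels, coords, k: int = 5, standardize: bool = True) -> SpatialWeights:
    """k-nearest-neighbour weights from planar coordinates.

    Distance ties are broken by label order (stable argsort), so exactly k
    entries per row are nonzero.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(labels)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    W = np.zeros((n, n))
    for i in range(n):
        W[i, np.argsort(d[i], kind="stable")[:k]] = 1.0
    w = SpatialWeights(list(labels), W, False, f"knn:{k}")
    return w.row_standardize() if standardize else w


@dataclass
class MoranGlobal:
    I: float
    expected: float
    variance: float
    z: float
    p_norm: float
    p_perm: float | None = None
    n_perm: int = 0
    seed: int | None = None


@dataclass
class MoranLocal:
    unit: object
    I_i: float
    quadrant: str
    p_perm: float | None = None


def _check_x(x, n):
    x = np.asarray(x, dtype=float)
    if len(x) != n:
        raise ValueError("value vector length does not match weights")
    if not np.all(np.isfinite(x)):
        raise ValueError("NaN or infinite value in x")
    if np.ptp(x) == 0:
        raise ValueError("Moran's I undefined for a constant vector")
    if n < 3:
        raise ValueError("need at least 3 units")
    return x


def _moran_stat(z, W, S0):
    return float(len(z) * (z @ W @ z) / ((z @ z) * S0))


def global_moran(x, weights: SpatialWeights) -> MoranGlobal:
    """Global Moran's I with the randomization normal approximation."""
    W = weights.W
    n = weights.n
    x = _check_x(x, n)
    z = x - x.mean()
    S0 = W.sum()
    I = _moran_stat(z, W, S0)
    EI = -1.0 / (n - 1)
    # randomization (permutation) variance, closed form
    S1 = 0.5 * np.sum((W + W.T) ** 2)
    S2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    b2 = n * np.sum(z ** 4) / np.sum(z ** 2) ** 2
    num = (n * ((n ** 2 - 3 * n + 3) * S1 - n * S2 + 3 * S0 ** 2)
           - b2 * ((n ** 2 - n) * S1 - 2 * n * S2 + 6 * S0 ** 2))
    var = num / ((n - 1) * (n - 2) * (n - 3) * S0 ** 2) - EI ** 2
    zscore = (I - EI) / np.sqrt(var)
    p_norm = 2.0 * stats.norm.sf(abs(zscore))
    return MoranGlobal(I=I, expected=EI, variance=float(var), z=float(zscore),
                       p_norm=float(p_norm))


def moran_significance(x, weights: SpatialWeights, n_perm: int = 999,
                       seed: int | None = None, alternative: str = "two-sided") -> MoranGlobal:
    """Permutation p-value from full random relabellings, plus the normal one.

    p_perm = (1 + #{|I_perm| >= |I_obs|}) / (n_perm + 1) under the
    two-sided convention; 'greater' counts only I_perm >= I_obs.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    res = global_moran(x, weights)
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    z = x - x.mean()
    S0 = weights.W.sum()
    n = weights.n
    Z = rng.permuted(np.tile(z, (n_perm, 1)), axis=1)
    sims = n * np.einsum("bi,ij,bj->b", Z, weights.W, Z) / ((z @ z) * S0)
    if alternative == "two-sided":
        extreme = np.sum(np.abs(sims) >= abs(res.I))
    elif alternative == "greater":
        extreme = np.sum(sims >= res.I)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    res.p_perm = float((1 + extreme) / (n_perm + 1))
    res.n_perm = n_perm
    res.seed = seed
    return res


def local_moran(x, weights: SpatialWeights, n_perm: int = 0,
                seed: int | None = None) -> list[MoranLocal]:
    """Local Moran's I per unit with HH/HL/LH/LL quadrant labels.

    Uses the same S^2 = (1/n) sum z^2 scaling as the global statistic, so
    sum_i I_i = I_global * S0 holds exactly.  With ``n_perm > 0`` each unit
    gets a conditional-permutation p-value (x_i held fixed, the remaining
    values shuffled over the remaining units; two-sided).
    """
    W = weights.W
    n = weights.n
    x = _check_x(x, n)
    z = x - x.mean()
    s2 = np.sum(z ** 2) / n
    lag = W @ z
    I_i = z * lag / s2
    quad = np.where(z >= 0, np.where(lag >= 0, "high-high", "high-low"),
                    np.where(lag >= 0, "low-high", "low-low"))
    p = [None] * n
    if n_perm:
        rng = np.random.default_rng(seed)
        for i in range(n):
            others = np.delete(z, i)
            wi = np.delete(W[i], i)
            perms = rng.permuted(np.tile(others, (n_perm, 1)), axis=1)
            sims = z[i] * (perms @ wi) / s2
            p[i] = float((1 + np.sum(np.abs(sims) >= abs(I_i[i]))) / (n_perm + 1))
    return [MoranLocal(unit=weights.labels[i], I_i=float(I_i[i]),
                       quadrant=str(quad[i]), p_perm=p[i]) for i in range(n)]


def local_frame(locals_: list[MoranLocal]) -> pd.DataFrame:
    return pd.DataFrame([{"unit": l.unit, "I_i": l.I_i, "quadrant": l.quadrant,
                          "p_perm": l.p_perm} for l in locals_])
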