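"""Independent oracles: closed forms, vertex enumeration, quadrature,
double-loop summation.  Deliberately naive — these never share code with
the implementation paths they check."""

import itertools

import numpy as np
from scipy import integrate, stats


def crs_ratio_te(x, y, target):
    """1-input/1-output CRS efficiency: (y0/x0) / max_j (y_j/x_j)."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    r = y / x
    return r[target] / r.max()


def vertex_dea_single_input(x, Y, target, frontier):
    """Input-oriented score for 1 input, any outputs, by vertex enumeration.

    Minimizes (sum lam_j x_j) / x0 over {Y lam >= y0, lam >= 0}
    (plus sum lam = 1 under VRS) by enumerating basic solutions: supports S
    and active output sets T with the square system Y[T, S] lam_S = y0[T]
    (VRS adds the convexity row).
    """
    x = np.asarray(x, float).ravel()
    Y = np.atleast_2d(np.asarray(Y, float))
    n, s = Y.shape
    y0, x0 = Y[target], x[target]
    best = np.inf
    max_support = s + (1 if frontier == "vrs" else 0)
    for size in range(1, max_support + 1):
        for S in itertools.combinations(range(n), size):
            n_eq = size - 1 if frontier == "vrs" else size
            for T in itertools.combinations(range(s), n_eq):
                A = Y[np.ix_(S, T)].T if n_eq else np.empty((0, size))
                b = y0[list(T)]
                if frontier == "vrs":
                    A = np.vstack([A, np.ones(size)])
                    b = np.r_[b, 1.0]
                if A.shape[0] != size:
                    continue
                try:
                    lam = np.linalg.solve(A, b)
                except np.linalg.LinAlgError:
                    continue
                if np.any(lam < -1e-10):
                    continue
                full = np.zeros(n)
                full[list(S)] = np.clip(lam, 0, None)
                if np.any(Y.T @ full < y0 - 1e-9):
                    continue
                best = min(best, float(full @ x) / x0)
    return best


def composed_error_logpdf(eps, sigma_v, sigma_u):
    """Density of eps = v + u (v Gaussian, u half-normal) by quadrature."""
    def integrand(u):
        return (stats.norm.pdf(eps - u, scale=sigma_v)
                * 2 * stats.norm.pdf(u, scale=sigma_u))
    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return np.log(val)


def conditional_mean_u(eps, sigma_v, sigma_u):
    """E[u | v + u = eps] by quadrature."""
    def joint(u):
        return (stats.norm.pdf(eps - u, scale=sigma_v)
                * 2 * stats.norm.pdf(u, scale=sigma_u))
    num, _ = integrate.quad(lambda u: u * joint(u), 0, np.inf, limit=200)
    den, _ = integrate.quad(joint, 0, np.inf, limit=200)
    return num / den


def moran_double_loop(x, W):
    """Global Moran's I by explicit double summation."""
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    s2 = sum((xi - xbar) ** 2 for xi in x) / n
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += W[i, j]
    return num / (s2 * s0)
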