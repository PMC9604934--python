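"""Independent brute-force oracles for the geometric fits.

Each oracle minimises the same geometric objective numerically over an
explicit parameterisation (spherical angles for directions, raw center and
radius for spheres) with multiple restarts, sharing no code with the
package's eigen-decomposition / Levenberg-Marquardt implementations.
"""

import numpy as np
from scipy.optimize import minimize


def _dir_from_angles(theta: float, phi: float) -> np.ndarray:
    return np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def _multistart(objective, rng, n_starts=12):
    best = None
    for _ in range(n_starts):
        x0 = rng.uniform([0.0, -np.pi], [np.pi, np.pi])
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    return best


def brute_plane_normal(points, seed=0) -> np.ndarray:
    """Normal minimising summed squared orthogonal distances (offset solved
    analytically for each candidate normal)."""
    pts = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)

    def objective(x):
        n = _dir_from_angles(*x)
        proj = pts @ n
        return float(((proj - proj.mean()) ** 2).sum())

    best = _multistart(objective, rng)
    return _dir_from_angles(*best.x)


def brute_line_direction(points, seed=0) -> np.ndarray:
    """Direction minimising summed squared orthogonal distances about the
    centroid."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    rng = np.random.default_rng(seed)

    def objective(x):
        d = _dir_from_angles(*x)
        resid = centered - np.outer(centered @ d, d)
        return float((resid**2).sum())

    best = _multistart(objective, rng)
    return _dir_from_angles(*best.x)


def brute_sphere(points, seed=0):
    """(center, radius) minimising sum((|p - c| - r)^2) by direct numerical
    minimisation from several perturbed starts."""
    pts = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    centroid = pts.mean(axis=0)
    scale = float(np.linalg.norm(pts - centroid, axis=1).mean())

    def objective(x):
        c, r = x[:3], x[3]
        return float(((np.linalg.norm(pts - c, axis=1) - r) ** 2).sum())

    best = None
    for _ in range(8):
        x0 = np.append(centroid + rng.normal(0, 0.5 * scale, 3), scale * rng.uniform(0.5, 2.0))
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 8000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x[:3], float(abs(best.x[3]))


def anova_icc_a1(matrix) -> float:
    """ICC(2,1) by explicit scalar-loop ANOVA (no vectorised shortcuts)."""
    x = [[float(v) for v in row] for row in np.asarray(matrix, dtype=float)]
    n = len(x)
    k = len(x[0])
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sse = sum(
        (x[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
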