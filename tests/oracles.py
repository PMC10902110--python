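"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: dense
pseudoinverse linear algebra for the sparse circuit solver, explicit
enumeration for zonal statistics and neighbour counts, and closed-form
normal equations for the regression fits.
"""

import numpy as np


def dense_laplacian(graph) -> np.ndarray:
    n = graph.n_cells
    L = np.zeros((n, n))
    for a, b, g in zip(graph.edge_a, graph.edge_b, graph.conductance):
        L[a, b] -= g
        L[b, a] -= g
        L[a, a] += g
        L[b, b] += g
    return L


def dense_pair_potentials(graph, source, target) -> np.ndarray:
    """Potentials via the dense Laplacian pseudoinverse, grounded at target.

    The pseudoinverse is evaluated through rank-one deflation:
    (L + J/n)^-1 agrees with pinv(L) on zero-sum injections and is
    numerically far better conditioned than an SVD cutoff.
    """
    n = graph.n_cells
    L = dense_laplacian(graph)
    e = np.zeros(n)
    e[source], e[target] = 1.0, -1.0
    v = np.linalg.solve(L + np.ones((n, n)) / n, e)
    return v - v[target]


def dense_effective_resistance(graph, a, b) -> float:
    v = dense_pair_potentials(graph, a, b)
    return float(v[a] - v[b])


def dense_current_density(graph, source, target) -> np.ndarray:
    v = dense_pair_potentials(graph, source, target)
    n = graph.n_cells
    dens = np.zeros(n)
    for a, b, g in zip(graph.edge_a, graph.edge_b, graph.conductance):
        i = abs(g * (v[a] - v[b]))
        dens[a] += 0.5 * i
        dens[b] += 0.5 * i
    dens[source] = 1.0
    dens[target] = 1.0
    return dens


def brute_force_zonal(values, cell_size, xll, yll, x, y, radius):
    """Cell-by-cell enumeration of a circular zonal extraction."""
    nrows, ncols = values.shape
    out = []
    for r in range(nrows):
        for c in range(ncols):
            cx = xll + (c + 0.5) * cell_size
            cy = yll + (nrows - r - 0.5) * cell_size
            if (cx - x) ** 2 + (cy - y) ** 2 <= radius**2:
                out.append(values[r, c])
    return np.array(out)


def ols_normal_equations(x, y):
    """Closed-form simple OLS: slope, intercept, R^2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xd = x - x.mean()
    yd = y - y.mean()
    slope = (xd @ yd) / (xd @ xd)
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    r2 = 1.0 - (resid @ resid) / (yd @ yd)
    return slope, intercept, r2
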