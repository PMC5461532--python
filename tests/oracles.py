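"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: repeated edge expansion for ontology
closures, explicit dummy-coded least squares for ANOVA sums of squares.
They share no code with the package paths they check.
"""

import numpy as np


def brute_force_closure(edges, term):
    """Reflexive transitive closure by repeated expansion of (child,
    parent) edges until a fixed point."""
    closure = {term}
    while True:
        new = {p for (c, p) in edges if c in closure} - closure
        if not new:
            return closure
        closure |= new


def random_dag(rng, n_nodes, edge_prob=0.25):
    """Random labeled DAG: edges forward in a random node permutation."""
    labels = [f"N{i}" for i in rng.permutation(n_nodes)]
    edges = [
        (labels[i], labels[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < edge_prob
    ]
    return labels, edges


def _dummies(levels, values):
    levels = sorted(set(levels))
    return np.column_stack([(np.asarray(values) == lv).astype(float) for lv in levels])


def _rss(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def brute_force_type2(design):
    """Type II sums of squares from explicit nested least-squares fits.

    Returns (ss_gof, ss_expq, ss_interaction, ss_residual) computed as
    RSS differences between the four nested cell-mean models.
    """
    y = design["mean_retention"].to_numpy(dtype=float)
    a = design["GOf"].to_numpy()
    b = design["ExpQ"].to_numpy()
    ones = np.ones((len(y), 1))
    A = _dummies(a, a)[:, 1:]
    B = _dummies(b, b)[:, 1:]
    AB = np.column_stack([A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])])
    rss_b = _rss(y, np.hstack([ones, B]))
    rss_a = _rss(y, np.hstack([ones, A]))
    rss_ab = _rss(y, np.hstack([ones, A, B]))
    rss_full = _rss(y, np.hstack([ones, A, B, AB]))
    return (rss_b - rss_ab, rss_a - rss_ab, rss_ab - rss_full, rss_full)


def brute_force_f_stats(design):
    """(F_gof, F_expq, F_interaction) from the Type II sums of squares."""
    ss_a, ss_b, ss_ab, ss_res = brute_force_type2(design)
    k_a = len(set(design["GOf"])) - 1
    k_b = len(set(design["ExpQ"])) - 1
    df_res = len(design) - (k_a + 1) * (k_b + 1)
    ms_res = ss_res / df_res
    return ss_a / k_a / ms_res, ss_b / k_b / ms_res, ss_ab / (k_a * k_b) / ms_res
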