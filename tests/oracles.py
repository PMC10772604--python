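"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with naive loops and closed forms,
sharing no code path with the vectorized implementations they check.
"""

import numpy as np

from aerotraits.fitting import classify, f1_score
from aerotraits.model import TraitSet, metabolic_index


def brute_force_fit(dataset, a_grid, e_grid, dedt_grid, t_ref=15.0,
                    weighted=True):
    """Naive triple-loop argmax-F1 with the estimator's tie-break rule.

    Evaluates every grid point through classify()/f1_score(), then
    applies the documented plateau rule: the tie set is every point
    within eps (half a presence-weight unit) of the maximum; the winner
    is the point nearest the tie set's median (log A, E, dEdT in
    grid-step units), residual ties resolved by (lowest A, |E| nearest
    zero, lowest E, lowest dEdT).
    """
    a_grid = np.asarray(a_grid, float)
    e_grid = np.asarray(e_grid, float)
    dedt_grid = np.asarray(dedt_grid, float)
    w = dataset.weight if weighted else np.ones(len(dataset.T))
    scores = {}
    for i, a in enumerate(a_grid):
        for j, e in enumerate(e_grid):
            for k, d in enumerate(dedt_grid):
                traits = TraitSet("", A_eco=a, E_eco_ref=e, dEdT=d,
                                  T_ref=t_ref)
                phi = metabolic_index(dataset.pO2, dataset.T, traits)
                hab = phi >= 1.0
                tp = float(w[dataset.presence & hab].sum())
                fp = float(w[~dataset.presence & hab].sum())
                fn = float(w[dataset.presence & ~hab].sum())
                scores[(i, j, k)] = f1_score(tp, fp, fn) if tp > 0 else 0.0
    wp = float(w[dataset.presence].sum())
    eps = 0.5 / max(wp, 1.0)
    best = max(scores.values())
    cand = [ijk for ijk, s in scores.items() if s >= best - eps]
    la = np.log(a_grid)
    step_a = np.median(np.diff(la)) if a_grid.size > 1 else 1.0
    step_e = np.median(np.diff(e_grid)) if e_grid.size > 1 else 1.0
    step_d = np.median(np.diff(dedt_grid)) if dedt_grid.size > 1 else 1.0
    med_a = np.median([la[i] for i, _, _ in cand])
    med_e = np.median([e_grid[j] for _, j, _ in cand])
    med_d = np.median([dedt_grid[k] for _, _, k in cand])
    dist = {ijk: ((la[ijk[0]] - med_a) / step_a) ** 2
            + ((e_grid[ijk[1]] - med_e) / step_e) ** 2
            + ((dedt_grid[ijk[2]] - med_d) / step_d) ** 2 for ijk in cand}
    dmin = min(dist.values())
    final = [ijk for ijk in cand if dist[ijk] == dmin]
    final.sort(key=lambda ijk: (a_grid[ijk[0]], abs(e_grid[ijk[1]]),
                                e_grid[ijk[1]], dedt_grid[ijk[2]]))
    i, j, k = final[0]
    return (a_grid[i], e_grid[j], dedt_grid[k]), scores[(i, j, k)]


def habitat_volume_loop(env, a, e, dedt, phi_max, depth_band, t_ref=15.0):
    """Per-cell loop oracle for aerobic habitat volume."""
    traits = TraitSet("", A_eco=a, E_eco_ref=e, dEdT=dedt, T_ref=t_ref)
    total = 0.0
    T, pO2 = env.annual()
    for z in range(env.depth.size):
        if not (depth_band[0] <= env.depth[z] < depth_band[1]):
            continue
        for y in range(env.lat.size):
            for x in range(env.lon.size):
                phi = metabolic_index(pO2[z, y, x], T[z, y, x], traits)
                if 1.0 <= phi <= phi_max:
                    total += env.cell_volume[z, y, x]
    return total


def ks_statistic_enumerated(x, y):
    """sup |ECDF_x - ECDF_y| over every evaluation point."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


def pagel_lambda_grid(tree, tip_values, step=1e-4):
    """Dense lambda-grid maximum of the profile likelihood."""
    from aerotraits.phylo import _gauss_profile_loglik, phylo_covariance

    import pandas as pd
    values = pd.Series(tip_values, dtype=float)
    labels, C = phylo_covariance(tree, 1.0)
    order = [i for i, lab in enumerate(labels) if lab in values.index]
    C = C[np.ix_(order, order)]
    y = values.loc[[labels[i] for i in order]].to_numpy()
    diag = np.diag(C).copy()
    best_l, best_ll = 0.0, -np.inf
    for lam in np.arange(0.0, 1.0 + step / 2, step):
        V = lam * C
        np.fill_diagonal(V, diag)
        ll, _, _ = _gauss_profile_loglik(V, y)
        if ll > best_ll:
            best_l, best_ll = lam, ll
    return best_l, best_ll
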