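"""F1-maximizing diagnosis of active hypoxia traits.

A species' traits (A_eco, E_eco_ref, dEdT) are found by exhaustive grid
search maximizing the F1-score of the ``Phi >= 1`` habitability
classifier over its presence/background samples in T-pO2 space,
followed by one local refinement pass at higher resolution around the
coarse optimum.  Ties are broken deterministically: lowest A_eco, then
E_eco_ref nearest zero (then lowest), then lowest dEdT.

The search is vectorized: for each (E, dEdT) pair the per-sample
habitability threshold in A is ``g = f(E_eff, T)/pO2`` (a cell is
habitable at A >= g), so confusion counts across the whole A axis come
from one ``searchsorted``/``bincount`` pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .constants import CELSIUS_OFFSET, K_B, T_REF_DEFAULT
from .errors import InvalidInputError
from .model import TraitSet, metabolic_index
from .occupancy import OccupancyDataset

__all__ = ["SearchSpec", "ConfusionCounts", "FitResult", "f1_score",
           "classify", "fit_traits", "MetabolicIndexClassifier"]


def _default_a_grid():
    return np.geomspace(0.5, 100.0, 40)


def _default_e_grid():
    return np.linspace(-1.0, 2.0, 61)


def _default_dedt_grid():
    return np.linspace(0.0, 0.12, 13)


@dataclass(frozen=True)
class SearchSpec:
    """Trait-search grid; defaults span the diagnosed trait ranges.

    A_eco is log-spaced 0.5-100 atm^-1 (40 points), E_eco_ref runs
    -1..2 eV in 0.05 steps, dEdT 0..0.12 eV/degC in 0.01 steps; the
    refinement pass re-grids +-1 coarse step around the optimum at
    ``refine_factor`` times the resolution (1 disables refinement).
    """

    a_grid: np.ndarray = field(default_factory=_default_a_grid)
    e_grid: np.ndarray = field(default_factory=_default_e_grid)
    dedt_grid: np.ndarray = field(default_factory=_default_dedt_grid)
    t_ref: float = T_REF_DEFAULT
    refine_factor: int = 5

    def __post_init__(self):
        for name in ("a_grid", "e_grid", "dedt_grid"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size == 0 or np.any(np.diff(arr) <= 0):
                raise InvalidInputError(f"{name} must be ascending and non-empty")
        if self.a_grid[0] <= 0:
            raise InvalidInputError("a_grid must be positive")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: float
    fp: float
    fn: float
    tn: float


@dataclass
class FitResult:
    """Best-fit traits plus classifier skill and occupancy diagnostics."""

    species_id: str
    traits: TraitSet
    f1: float
    tp: float
    fp: float
    fn: float
    tn: float
    t_cold: float       # 5th percentile of inhabited T, degC
    t_warm: float       # 95th percentile of inhabited T, degC
    phi_max: float      # 95th percentile of Phi over presence samples
    n_presence_cells: int
    flag: str = "ok"
    presence_phi: np.ndarray = field(default=None, repr=False)


def f1_score(tp, fp, fn):
    """F1 = 2TP/(2TP + FP + FN); 0 when TP = 0 with errors present."""
    if tp < 0 or fp < 0 or fn < 0:
        raise InvalidInputError("confusion counts must be >= 0")
    if tp == 0:
        if fp == 0 and fn == 0:
            raise InvalidInputError("F1 undefined when all counts are zero")
        return 0.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def classify(dataset: OccupancyDataset, traits: TraitSet,
             weighted=False) -> ConfusionCounts:
    """Confusion counts of the ``Phi >= 1`` classifier on a dataset."""
    phi = metabolic_index(dataset.pO2, dataset.T, traits)
    habitable = phi >= 1.0
    w = dataset.weight if weighted else np.ones(len(dataset.T))
    pres = dataset.presence
    return ConfusionCounts(
        tp=float(w[pres & habitable].sum()),
        fp=float(w[~pres & habitable].sum()),
        fn=float(w[pres & ~habitable].sum()),
        tn=float(w[~pres & ~habitable].sum()),
    )


# ---------------------------------------------------------------------------
# Vectorized F1 surface
# ---------------------------------------------------------------------------

def _f1_surface(T, pO2, presence, weight, a_grid, e_grid, dedt_grid, t_ref):
    """F1 over the full (A, E, dEdT) grid; shape (nA, nE, nD).

    Uses f(E + dEdT*d, T) = exp(E*x) * exp(dEdT*d*x) with
    x = -(1/k_B)(1/T_K - 1/Tref_K) and d = T - t_ref, precomputing the
    two exponential banks once per axis.
    """
    x = -(1.0 / K_B) * (1.0 / (T + CELSIUS_OFFSET) - 1.0 / (t_ref + CELSIUS_OFFSET))
    d = T - t_ref
    with np.errstate(divide="ignore"):
        inv_p = np.where(pO2 > 0, 1.0 / pO2, np.inf)
    P = np.exp(np.outer(e_grid, x))          # (nE, n)
    Q = np.exp(np.outer(dedt_grid, d * x))   # (nD, n)
    nA = a_grid.size
    wp = np.where(presence, weight, 0.0)
    wb = np.where(presence, 0.0, weight)
    Wp = wp.sum()
    F1 = np.empty((nA, e_grid.size, dedt_grid.size))
    for ie in range(e_grid.size):
        for idd in range(dedt_grid.size):
            g = P[ie] * Q[idd] * inv_p
            idx = np.searchsorted(a_grid, g, side="left")
            tp = np.cumsum(np.bincount(idx, weights=wp, minlength=nA + 1))[:nA]
            fp = np.cumsum(np.bincount(idx, weights=wb, minlength=nA + 1))[:nA]
            denom = tp + fp + Wp  # == 2TP + FP + FN
            with np.errstate(invalid="ignore", divide="ignore"):
                F1[:, ie, idd] = np.where(tp > 0, 2.0 * tp / denom, 0.0)
    return F1


def _select_argmax(F1, a_grid, e_grid, dedt_grid, eps=0.0):
    """Deterministic plateau-centered argmax over the F1 surface.

    Near-maximal F1 values form plateaus: the binned data cannot
    distinguish curves that differ by less than about one reclassified
    sample, so ``eps`` (that one-sample F1 scale) widens the tie set
    accordingly.  The tie is resolved toward the plateau's median
    (log A, E, dEdT in grid-step units) — an unbiased central
    representative — with any residual tie broken by the fixed ordering
    (lowest A, then |E| nearest zero, then lowest dEdT).
    """
    m = F1.max()
    cand = np.argwhere(F1 >= m - eps)
    if len(cand) == 1:
        i, j, k = cand[0]
        return (int(i), int(j), int(k)), float(F1[i, j, k])
    la = np.log(a_grid)
    step_a = np.median(np.diff(la)) if a_grid.size > 1 else 1.0
    step_e = np.median(np.diff(e_grid)) if e_grid.size > 1 else 1.0
    step_d = np.median(np.diff(dedt_grid)) if dedt_grid.size > 1 else 1.0
    ca, ce, cd = la[cand[:, 0]], e_grid[cand[:, 1]], dedt_grid[cand[:, 2]]
    dist = (((ca - np.median(ca)) / step_a) ** 2
            + ((ce - np.median(ce)) / step_e) ** 2
            + ((cd - np.median(cd)) / step_d) ** 2)
    best = dist == dist.min()
    order = sorted(
        (tuple(c) for c in cand[best]),
        key=lambda c: (a_grid[c[0]], abs(e_grid[c[1]]), e_grid[c[1]],
                       dedt_grid[c[2]]),
    )
    i, j, k = order[0]
    return (int(i), int(j), int(k)), float(F1[i, j, k])


def _refined_axis(grid, i, factor, log=False, span=2):
    """Axis spanning +-span coarse steps around grid[i] at factor x density."""
    n = grid.size
    lo = grid[max(i - span, 0)]
    hi = grid[min(i + span, n - 1)]
    if lo == hi:
        return np.array([lo])
    npts = 2 * span * factor + 1
    if log:
        return np.geomspace(lo, hi, npts)
    return np.linspace(lo, hi, npts)


def _is_log_spaced(grid):
    if grid.size < 3 or np.any(grid <= 0):
        return False
    r = np.diff(np.log(grid))
    return np.allclose(r, r[0], rtol=1e-6)


class MetabolicIndexClassifier(ClassifierMixin, BaseEstimator):
    """Habitability classifier fitted by F1 grid search over traits.

    A scikit-learn-style estimator.  ``X`` is ``(n_samples, 2)`` with
    columns ``(T [degC], pO2 [atm])`` and ``y`` is 1 for presence cells
    and 0 for background cells.  Fitting selects the trait triple
    (A_eco, E_eco_ref, dEdT) whose ``Phi >= 1`` prediction maximizes the
    (optionally sample-weighted) F1-score, with deterministic
    tie-breaking, then refines locally.

    Parameters
    ----------
    a_grid, e_grid, dedt_grid : array-like, optional
        Search axes; defaults per :class:`SearchSpec`.
    t_ref : float
        Reference temperature, degC.
    refine_factor : int
        Local refinement density multiplier; 1 disables refinement.

    Attributes
    ----------
    traits_ : TraitSet
    f1_ : float
    confusion_ : ConfusionCounts
    """

    def __init__(self, a_grid=None, e_grid=None, dedt_grid=None,
                 t_ref=T_REF_DEFAULT, refine_factor=5):
        self.a_grid = a_grid
        self.e_grid = e_grid
        self.dedt_grid = dedt_grid
        self.t_ref = t_ref
        self.refine_factor = refine_factor

    def _spec(self):
        kw = {}
        if self.a_grid is not None:
            kw["a_grid"] = np.asarray(self.a_grid, dtype=float)
        if self.e_grid is not None:
            kw["e_grid"] = np.asarray(self.e_grid, dtype=float)
        if self.dedt_grid is not None:
            kw["dedt_grid"] = np.asarray(self.dedt_grid, dtype=float)
        return SearchSpec(t_ref=self.t_ref, refine_factor=self.refine_factor,
                          **kw)

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InvalidInputError("X must be (n_samples, 2): columns (T, pO2)")
        if len(y) != len(X):
            raise InvalidInputError("X and y length mismatch")
        pres = y.astype(bool)
        if not pres.any():
            raise InvalidInputError("no presence samples")
        if pres.all():
            raise InvalidInputError("no background samples; F1 fit is degenerate")
        w = (np.ones(len(y)) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        T, pO2 = X[:, 0], X[:, 1]
        spec = self._spec()

        # one-sample F1 scale: widens the argmax tie set to the plateau of
        # curves the quantized data cannot distinguish
        wp_total = float(np.where(pres, w, 0.0).sum())
        eps = 0.5 / max(wp_total, 1.0)
        F1 = _f1_surface(T, pO2, pres, w, spec.a_grid, spec.e_grid,
                         spec.dedt_grid, spec.t_ref)
        (i, j, k), best = _select_argmax(F1, spec.a_grid, spec.e_grid,
                                         spec.dedt_grid, eps=eps)
        a, e, dd = spec.a_grid[i], spec.e_grid[j], spec.dedt_grid[k]
        flags = []
        if i in (0, spec.a_grid.size - 1):
            flags.append("edge:A")
        if j in (0, spec.e_grid.size - 1):
            flags.append("edge:E")
        if k == spec.dedt_grid.size - 1:
            flags.append("edge:dEdT")

        if spec.refine_factor > 1:
            ra = _refined_axis(spec.a_grid, i, spec.refine_factor,
                               log=_is_log_spaced(spec.a_grid))
            re_ = _refined_axis(spec.e_grid, j, spec.refine_factor)
            rd = _refined_axis(spec.dedt_grid, k, spec.refine_factor)
            F1r = _f1_surface(T, pO2, pres, w, ra, re_, rd, spec.t_ref)
            (ri, rj, rk), bestr = _select_argmax(F1r, ra, re_, rd, eps=eps)
            if bestr >= best - eps:
                a, e, dd, best = ra[ri], re_[rj], rd[rk], bestr

        self.traits_ = TraitSet("", A_eco=float(a), E_eco_ref=float(e),
                                dEdT=float(dd), T_ref=spec.t_ref)
        # Confusion via the same A >= f/pO2 rule used in the surface, so
        # reported F1 is exactly the surface maximum.
        from .model import arrhenius_factor, effective_activation_energy
        f = arrhenius_factor(effective_activation_energy(self.traits_, T), T,
                             spec.t_ref)
        with np.errstate(divide="ignore"):
            g = np.where(pO2 > 0, np.asarray(f) / pO2, np.inf)
        habitable = self.traits_.A_eco >= g
        tp = float(w[pres & habitable].sum())
        fp = float(w[~pres & habitable].sum())
        fn = float(w[pres & ~habitable].sum())
        tn = float(w[~pres & ~habitable].sum())
        self.confusion_ = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        self.f1_ = float(best)
        if self.f1_ < 0.5:
            flags.append("low_skill")
        self.flags_ = flags
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return metabolic_index(X[:, 1], X[:, 0], self.traits_) - 1.0

    def predict(self, X):
        return (self.decision_function(X) >= 0.0).astype(int)

    def score(self, X, y, sample_weight=None):
        """F1-score of the fitted classifier on (X, y)."""
        pred = self.predict(X).astype(bool)
        pres = np.asarray(y).astype(bool)
        w = (np.ones(len(pres)) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        return f1_score(w[pres & pred].sum(), w[~pres & pred].sum(),
                        w[pres & ~pred].sum())


def fit_traits(dataset: OccupancyDataset, search_spec: SearchSpec | None = None,
               weighted=True) -> FitResult:
    """Diagnose (A_eco, E_eco_ref, dEdT) for one species' occupancy data.

    Thin wrapper over :class:`MetabolicIndexClassifier` that also
    reports the inhabited-temperature percentiles T_C/T_W (5th/95th,
    linear interpolation) and Phi_max (95th percentile of Phi over
    presence samples at the fitted traits).  ``weighted`` applies the
    dataset's sample weights (cell counts per state-space bin by
    default, cell volumes when the dataset was built volume-weighted),
    keeping the F1 a cell-level score.
    """
    spec = search_spec or SearchSpec()
    est = MetabolicIndexClassifier(
        a_grid=spec.a_grid, e_grid=spec.e_grid, dedt_grid=spec.dedt_grid,
        t_ref=spec.t_ref, refine_factor=spec.refine_factor,
    )
    X = np.column_stack([dataset.T, dataset.pO2])
    est.fit(X, dataset.presence,
            sample_weight=dataset.weight if weighted else None)
    traits = replace(est.traits_, species_id=dataset.species_id)
    pres_T = dataset.T[dataset.presence]
    pres_phi = metabolic_index(dataset.pO2[dataset.presence], pres_T, traits)
    c = est.confusion_
    return FitResult(
        species_id=dataset.species_id,
        traits=traits,
        f1=est.f1_,
        tp=c.tp, fp=c.fp, fn=c.fn, tn=c.tn,
        t_cold=float(np.percentile(pres_T, 5)),
        t_warm=float(np.percentile(pres_T, 95)),
        phi_max=float(np.percentile(pres_phi, 95)),
        n_presence_cells=dataset.n_presence_cells,
        flag=",".join(est.flags_) if est.flags_ else "ok",
        presence_phi=pres_phi,
    )
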