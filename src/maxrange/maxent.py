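"""Maximum-entropy presence-background model with L1-regularized features.

The model is the Gibbs density ``q(x) ∝ exp(βᵀf(x))`` over the background
cells (every cell of a species' native region), fitted by minimizing the
per-presence negative log-likelihood

    F(β) = −mean_presence βᵀf(x) + log Σ_background exp(βᵀf(x)) + Σ_j λ_j |β_j|

which is convex; we solve it with accelerated proximal gradient descent
(FISTA with adaptive restart and backtracking line search).  Per-feature
penalties follow the classic defaults of the reference implementation:
``λ_j = rm · β_default(kind, n) · s_j / √n`` with ``s_j`` the presence
standard deviation of feature j (floored) and ``rm`` a global
regularization multiplier.

Feature classes are the usual transformations of min/max-scaled variables:
linear (l), quadratic (q), product (p), hinge (h, forward and reverse
ramps) and threshold (t, step indicators), combined in the six canonical
sets l, lq, h, lqh, lqhp, lqhpt.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "FEATURE_COMBOS",
    "REG_MULTIPLIERS",
    "FeatureExpansion",
    "MaxentModel",
    "Prediction",
    "build_features",
    "fit_maxent",
    "predict_raw",
    "predict_cloglog",
    "permutation_importance",
    "aicc",
    "UNAVAILABLE",
]

FEATURE_COMBOS = ("l", "lq", "h", "lqh", "lqhp", "lqhpt")
REG_MULTIPLIERS = (1, 2, 3, 5, 10)

#: AICc (and similar) returned as None when the sample-size correction
#: denominator is non-positive or a presence has zero predicted density.
UNAVAILABLE = None

# Published default regularization tables, interpolated on presence count.
_BETA_TABLES = {
    "linear": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "product": ([0, 10, 17, 30, 100], [2.6, 1.6, 1.0, 0.8, 0.17]),
    "hinge": ([0, 100], [0.5, 0.5]),
    "threshold": ([0, 100], [2.0, 1.0]),
}

_SD_FLOOR = 1e-3  # keeps every penalty strictly positive


def beta_default(kind: str, n_presence: int) -> float:
    xs, ys = _BETA_TABLES[kind]
    return float(np.interp(n_presence, xs, ys))


@dataclass(frozen=True)
class FeatureDescriptor:
    kind: str  # linear | quadratic | product | hinge_fwd | hinge_rev | threshold
    variables: tuple[str, ...]
    knot: float | None = None

    @property
    def table_kind(self) -> str:
        if self.kind in ("hinge_fwd", "hinge_rev"):
            return "hinge"
        return self.kind


@dataclass
class FeatureExpansion:
    """Frozen feature construction: scaling bounds, knots and descriptors.

    Scaling bounds come from the training background; any later values
    are clamped to [0, 1] after scaling so prediction never extrapolates
    the ramps.
    """

    combo: str
    variables: tuple[str, ...]
    lo: np.ndarray  # per-variable background min
    hi: np.ndarray  # per-variable background max
    descriptors: list[FeatureDescriptor] = field(default_factory=list)
    n_knots: int = 50

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    def scale(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        Z = (np.asarray(X, dtype=float) - self.lo) / span
        return np.clip(Z, 0.0, 1.0)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """(n_cells, n_variables) raw values -> (n_cells, n_features) design."""
        Z = self.scale(X)
        col_of = {v: i for i, v in enumerate(self.variables)}
        out = np.empty((Z.shape[0], self.n_features), dtype=float)
        for j, d in enumerate(self.descriptors):
            if d.kind == "linear":
                out[:, j] = Z[:, col_of[d.variables[0]]]
            elif d.kind == "quadratic":
                out[:, j] = Z[:, col_of[d.variables[0]]] ** 2
            elif d.kind == "product":
                out[:, j] = Z[:, col_of[d.variables[0]]] * Z[:, col_of[d.variables[1]]]
            elif d.kind == "hinge_fwd":
                k = d.knot
                out[:, j] = np.maximum(0.0, (Z[:, col_of[d.variables[0]]] - k) / (1.0 - k))
            elif d.kind == "hinge_rev":
                k = d.knot
                out[:, j] = np.maximum(0.0, (k - Z[:, col_of[d.variables[0]]]) / k)
            elif d.kind == "threshold":
                out[:, j] = (Z[:, col_of[d.variables[0]]] >= d.knot).astype(float)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {d.kind!r}")
        return out


def build_features(env, native, variables, combo: str, n_knots: int = 50) -> FeatureExpansion:
    """Construct the feature expansion for a combo over the native background.

    Variables constant over the background carry no information and are
    dropped with a warning.  Knots for hinge and threshold features are
    evenly spaced on the scaled [0, 1] range.
    """
    import warnings

    if combo not in FEATURE_COMBOS:
        raise ValueError(f"combo must be one of {FEATURE_COMBOS}, got {combo!r}")
    variables = list(variables)
    if not variables:
        raise ValueError("empty variable list")
    missing = [v for v in variables if v not in env.layers]
    if missing:
        raise ValueError(f"variables not in environment: {missing}")
    rows, cols = native.cells()
    X = env.values_at(variables, rows, cols)
    lo = np.nanmin(X, axis=0)
    hi = np.nanmax(X, axis=0)
    keep = hi > lo
    if not keep.all():
        dropped = [v for v, k in zip(variables, keep) if not k]
        warnings.warn(f"dropping constant background variables: {dropped}", stacklevel=2)
        variables = [v for v, k in zip(variables, keep) if k]
        lo, hi = lo[keep], hi[keep]
        if not variables:
            raise ValueError("all variables constant over background")
    descriptors: list[FeatureDescriptor] = []
    if "l" in combo:
        descriptors += [FeatureDescriptor("linear", (v,)) for v in variables]
    if "q" in combo:
        descriptors += [FeatureDescriptor("quadratic", (v,)) for v in variables]
    if "h" in combo:
        fwd = np.linspace(0.0, 1.0, n_knots, endpoint=False)
        rev = fwd + 1.0 / n_knots
        for v in variables:
            descriptors += [FeatureDescriptor("hinge_fwd", (v,), float(k)) for k in fwd]
            descriptors += [FeatureDescriptor("hinge_rev", (v,), float(k)) for k in rev]
    if "p" in combo:
        descriptors += [FeatureDescriptor("product", (a, b)) for a, b in combinations(variables, 2)]
    if "t" in combo:
        knots = (np.arange(n_knots) + 0.5) / n_knots
        for v in variables:
            descriptors += [FeatureDescriptor("threshold", (v,), float(k)) for k in knots]
    return FeatureExpansion(
        combo=combo,
        variables=tuple(variables),
        lo=lo,
        hi=hi,
        descriptors=descriptors,
        n_knots=n_knots,
    )


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model.

    ``log_normalizer`` is log Σ_background exp(βᵀf) at the training
    background; ``entropy`` is the Shannon entropy of the normalized raw
    distribution there, which anchors the cloglog transform.
    """

    expansion: FeatureExpansion
    beta: np.ndarray
    rm: float
    log_normalizer: float
    entropy: float
    n_presence: int
    converged: bool = True
    objective: float = math.nan

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))

    def to_json(self) -> str:
        payload = {
            "combo": self.expansion.combo,
            "variables": list(self.expansion.variables),
            "lo": self.expansion.lo.tolist(),
            "hi": self.expansion.hi.tolist(),
            "n_knots": self.expansion.n_knots,
            "descriptors": [
                {"kind": d.kind, "variables": list(d.variables), "knot": d.knot}
                for d in self.expansion.descriptors
            ],
            "beta": self.beta.tolist(),
            "rm": self.rm,
            "log_normalizer": self.log_normalizer,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        d = json.loads(text)
        expansion = FeatureExpansion(
            combo=d["combo"],
            variables=tuple(d["variables"]),
            lo=np.array(d["lo"]),
            hi=np.array(d["hi"]),
            descriptors=[
                FeatureDescriptor(e["kind"], tuple(e["variables"]), e["knot"])
                for e in d["descriptors"]
            ],
            n_knots=d["n_knots"],
        )
        return cls(
            expansion=expansion,
            beta=np.array(d["beta"]),
            rm=d["rm"],
            log_normalizer=d["log_normalizer"],
            entropy=d["entropy"],
            n_presence=d["n_presence"],
        )


@dataclass
class Prediction:
    """Raw (relative occurrence rate) and cloglog (suitability index) maps."""

    raw: np.ndarray
    cloglog: np.ndarray


def _log_z(F_bg: np.ndarray, beta: np.ndarray) -> float:
    eta = F_bg @ beta
    m = eta.max()
    return float(m + np.log(np.exp(eta - m).sum()))


def penalties(
    expansion: FeatureExpansion, F_pres: np.ndarray, rm: float, n_presence: int
) -> np.ndarray:
    """Per-feature L1 penalties λ_j from the default regularization tables."""
    s = F_pres.std(axis=0, ddof=0)
    s = np.maximum(s, _SD_FLOOR)
    base = np.array(
        [beta_default(d.table_kind, n_presence) for d in expansion.descriptors]
    )
    return rm * base * s / math.sqrt(max(n_presence, 1))


def fit_maxent(
    expansion: FeatureExpansion,
    presence_features: np.ndarray,
    background_features: np.ndarray,
    rm: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    beta0: np.ndarray | None = None,
) -> MaxentModel:
    """Fit the L1-penalized maximum-entropy model.

    Parameters
    ----------
    presence_features, background_features:
        Design matrices from :meth:`FeatureExpansion.transform`; presence
        cells must be a subset of the background in spirit (background is
        every native cell), though only the matrices are required here.
    rm:
        Global regularization multiplier.
    beta0:
        Optional warm start (e.g. the neighbouring fold's solution).

    Raises
    ------
    RuntimeError
        If the objective has not converged within ``max_iter``.
    """
    F_pres = np.asarray(presence_features, dtype=float)
    F_bg = np.asarray(background_features, dtype=float)
    if F_pres.shape[0] < 1:
        raise ValueError("need at least one presence")
    if F_bg.shape[0] < 2:
        raise ValueError("need at least two background cells")
    n = F_pres.shape[0]
    lam = penalties(expansion, F_pres, rm, n)
    mean_pres = F_pres.mean(axis=0)
    n_feat = F_bg.shape[1]

    def smooth(beta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        eta = F_bg @ beta
        m = eta.max()
        w = np.exp(eta - m)
        z = w.sum()
        q = w / z
        value = float(-mean_pres @ beta + m + np.log(z))
        grad = F_bg.T @ q - mean_pres
        return value, grad, q

    def total(beta: np.ndarray, smooth_val: float) -> float:
        return smooth_val + float(lam @ np.abs(beta))

    beta = np.zeros(n_feat) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    y = beta.copy()
    t_mom = 1.0
    step = 1.0 / max(1.0, float((F_bg**2).sum(axis=1).max()))  # crude Lipschitz guess
    f_y, g_y, _ = smooth(y)
    obj = total(beta, smooth(beta)[0])
    converged = False
    for _ in range(max_iter):
        # backtracking proximal step from the momentum point y
        while True:
            cand = np.sign(y - step * g_y) * np.maximum(np.abs(y - step * g_y) - step * lam, 0.0)
            f_cand = smooth(cand)[0]
            diff = cand - y
            if f_cand <= f_y + g_y @ diff + (diff @ diff) / (2 * step) + 1e-12:
                break
            step *= 0.5
        new_obj = total(cand, f_cand)
        if new_obj > obj:  # adaptive restart: kill momentum
            y = beta.copy()
            t_mom = 1.0
            f_y, g_y, _ = smooth(y)
            cand2 = np.sign(y - step * g_y) * np.maximum(np.abs(y - step * g_y) - step * lam, 0.0)
            new_obj = total(cand2, smooth(cand2)[0])
            cand = cand2
        t_next = (1 + math.sqrt(1 + 4 * t_mom**2)) / 2
        y = cand + ((t_mom - 1) / t_next) * (cand - beta)
        beta = cand
        t_mom = t_next
        f_y, g_y, _ = smooth(y)
        if abs(obj - new_obj) <= tol * max(1.0, abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
        step *= 1.25  # allow the step to grow back after backtracking
    if not converged:
        raise RuntimeError(f"maxent fit did not converge; last objective {obj:.6g}")
    _, _, q = smooth(beta)
    log_z = _log_z(F_bg, beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-(q * np.where(q > 0, np.log(q), 0.0)).sum())
    return MaxentModel(
        expansion=expansion,
        beta=beta,
        rm=rm,
        log_normalizer=log_z,
        entropy=entropy,
        n_presence=n,
        converged=converged,
        objective=obj,
    )


def scores(model: MaxentModel, features: np.ndarray) -> np.ndarray:
    """Linear predictor βᵀf — a monotone stand-in for raw when ranking."""
    return np.asarray(features, dtype=float) @ model.beta


def predict_raw(model: MaxentModel, env, mask) -> np.ndarray:
    """Raw relative occurrence rate per cell of ``mask``.

    On the training extent the values sum to 1.  Returned as a vector
    aligned with ``mask.cells()`` row-major order.
    """
    missing = [v for v in model.expansion.variables if v not in env.layers]
    if missing:
        raise ValueError(f"variables missing from environment: {missing}")
    rows, cols = mask.cells()
    X = env.values_at(model.expansion.variables, rows, cols)
    F = model.expansion.transform(X)
    return raw_from_features(model, F)


def raw_from_features(model: MaxentModel, features: np.ndarray) -> np.ndarray:
    return np.exp(np.asarray(features, dtype=float) @ model.beta - model.log_normalizer)


def predict_cloglog(model: MaxentModel, raw: np.ndarray) -> np.ndarray:
    """Complementary log-log transform: 1 − exp(−e^H · raw).

    H is the entropy of the training-background raw distribution, frozen
    at fit time, so the transform is a fixed monotone map on any extent.
    """
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("raw values must be non-negative")
    return 1.0 - np.exp(-np.exp(model.entropy) * raw)


def predict(model: MaxentModel, env, mask) -> Prediction:
    raw = predict_raw(model, env, mask)
    return Prediction(raw=raw, cloglog=predict_cloglog(model, raw))


def permutation_importance(
    model: MaxentModel,
    presence_X: np.ndarray,
    background_X: np.ndarray,
    seed: int = 0,
) -> dict[str, float]:
    """Percent importance of each variable by training-AUC drop.

    Each variable's raw values are permuted jointly across the pooled
    presence + background rows, all its features recomputed, and the drop
    in training AUC (presence vs background ranking of βᵀf) measured
    without refitting.  Negative drops are floored at zero and the drops
    normalized to sum to 100 (uniform split if all are zero).
    """
    from .evaluation import roc_auc

    rng = np.random.default_rng(seed)
    n_pres = presence_X.shape[0]
    pooled = np.vstack([presence_X, background_X])
    F_pres = model.expansion.transform(presence_X)
    F_bg = model.expansion.transform(background_X)
    base_auc = roc_auc(scores(model, F_pres), scores(model, F_bg))
    drops = {}
    for i, var in enumerate(model.expansion.variables):
        perm = rng.permutation(pooled.shape[0])
        shuffled = pooled.copy()
        shuffled[:, i] = pooled[perm, i]
        F_all = model.expansion.transform(shuffled)
        auc = roc_auc(
            scores(model, F_all[:n_pres]), scores(model, F_all[n_pres:])
        )
        drops[var] = max(0.0, base_auc - auc)
    tot = sum(drops.values())
    if tot <= 0:
        k = len(drops)
        return {v: 100.0 / k for v in drops}
    return {v: 100.0 * d / tot for v, d in drops.items()}


def aicc(model: MaxentModel, presence_raw_unnormalized: np.ndarray, full_raw_sum: float):
    """Corrected Akaike information criterion of a fitted model.

    ``lnL = Σ_presences ln(raw_i / Σ_fullgrid raw)`` with raw standardized
    over the full native grid; ``K`` counts nonzero coefficients.
    Returns :data:`UNAVAILABLE` (None) when ``n − K − 1 <= 0`` or any
    presence has zero density.
    """
    n = model.n_presence
    k = model.n_nonzero
    if n - k - 1 <= 0:
        return UNAVAILABLE
    p = np.asarray(presence_raw_unnormalized, dtype=float) / full_raw_sum
    if (p <= 0).any():
        return UNAVAILABLE
    ln_l = float(np.log(p).sum())
    return 2 * k - 2 * ln_l + (2 * k * (k + 1)) / (n - k - 1)
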