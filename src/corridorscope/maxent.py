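"""Presence-only maximum-entropy habitat model.

The model is the Gibbs distribution q(cell) ~ exp(lambda . f(cell)) over a
background sample of valid cells, fit by maximizing the L1-regularized
presence log-likelihood

    L(lambda) = lambda . mean_presence(f) - log Z - sum_j beta_j |lambda_j|

with cyclic coordinate ascent (Newton steps with soft-thresholding and
backtracking, so the objective is non-decreasing).  At the optimum the KKT
conditions bound every feature expectation: |E_q[f_j] - E_presence[f_j]| <=
beta_j.  Feature classes are linear + quadratic terms of standardized
continuous covariates plus one indicator per category of categorical
covariates; per-update objective gains are attributed to the owning variable
to report percent contributions, and a jackknife refits with each variable
alone / withheld.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score

from corridorscope.ahp import R_MIN, invert_rescale
from corridorscope.pointset import PointSet
from corridorscope.raster import CovariateStack, GridSpec, RasterLayer

__all__ = [
    "FeatureMatrix",
    "MaxentModel",
    "build_features",
    "presence_rows",
    "fit_maxent",
    "predict",
    "split_points",
    "auc_presence_background",
    "variable_contributions",
    "jackknife",
    "suitability_to_resistance",
]

DEFAULT_BETA = 0.5
DEFAULT_BACKGROUND = 10_000
LOG_EPS = 1e-12


@dataclass
class FeatureMatrix:
    """Per-valid-cell feature vectors with provenance.

    Rows follow row-major order over the valid cells of the stack; ``cells``
    maps each row back to its (row, col) grid index.
    """

    X: np.ndarray
    names: tuple[str, ...]
    variables: tuple[str, ...]  # owning covariate role per feature
    cells: np.ndarray  # (n, 2) grid indices
    spec: GridSpec
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.names) or len(self.names) != len(self.variables):
            raise ValueError("feature metadata length mismatch")
        if self.X.shape[0] != len(self.cells):
            raise ValueError("row/cell count mismatch")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def row_lookup(self) -> np.ndarray:
        lut = np.full(self.spec.shape, -1, dtype=np.int64)
        lut[self.cells[:, 0], self.cells[:, 1]] = np.arange(self.n_cells)
        return lut

    def select_variables(self, keep: set[str]) -> "FeatureMatrix":
        idx = [i for i, v in enumerate(self.variables) if v in keep]
        if not idx:
            raise ValueError("no features left after selection")
        return FeatureMatrix(
            self.X[:, idx],
            tuple(self.names[i] for i in idx),
            tuple(self.variables[i] for i in idx),
            self.cells,
            self.spec,
            self.mask,
        )


def build_features(stack: CovariateStack, exclude: tuple[str, ...] = ("dist_wells",)) -> FeatureMatrix:
    """Deterministically ordered feature matrix over the stack's valid cells."""
    unknown = set(exclude) - set(stack.roles())
    if unknown:
        raise ValueError(f"cannot exclude unknown roles {sorted(unknown)}")
    mask = stack.shared_mask()
    if not mask.any():
        raise ValueError("no valid cells in stack")
    cells = np.argwhere(mask)
    cols: list[np.ndarray] = []
    names: list[str] = []
    variables: list[str] = []
    for role in stack.roles():
        if role in exclude:
            continue
        layer = stack[role]
        vals = layer.values[mask]
        if layer.kind == "continuous":
            sd = vals.std()
            if sd == 0:
                raise ValueError(f"zero variance covariate {role!r}")
            z = (vals - vals.mean()) / sd
            z2 = z**2
            z2sd = z2.std()
            if z2sd == 0:
                raise ValueError(f"zero variance covariate {role!r}")
            z2 = (z2 - z2.mean()) / z2sd
            cols.extend([z, z2])
            names.extend([f"{role}:linear", f"{role}:quadratic"])
            variables.extend([role, role])
        else:
            codes = np.unique(vals)
            if len(codes) < 2:
                raise ValueError(f"zero variance covariate {role!r}")
            for code in codes:
                cols.append((vals == code).astype(float))
                names.append(f"{role}:cat{int(code)}")
                variables.append(role)
    X = np.column_stack(cols)
    return FeatureMatrix(X, tuple(names), tuple(variables), cells, stack.spec, mask)


def presence_rows(features: FeatureMatrix, points: PointSet, dedupe: bool = True) -> np.ndarray:
    """Map presence points to feature rows (optionally one per cell)."""
    r, c = features.spec.index_of(points.x, points.y)
    lut = features.row_lookup()
    rows = lut[r, c]
    rows = rows[rows >= 0]
    if dedupe:
        rows = np.unique(rows)
    if len(rows) == 0:
        raise ValueError("no presence points fall on valid cells")
    return rows


@dataclass
class MaxentModel:
    lam: np.ndarray
    beta: np.ndarray
    feature_names: tuple[str, ...]
    variables: tuple[str, ...]
    background_rows: np.ndarray
    log_z: float
    entropy: float
    n_presence: int
    seed: int
    objective: float
    trace: list[tuple[int, float]] = field(default_factory=list)  # (feature index, objective gain)
    objective_path: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "lambda": {n: float(l) for n, l in zip(self.feature_names, self.lam)},
            "beta": {n: float(b) for n, b in zip(self.feature_names, self.beta)},
            "log_z": self.log_z,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "seed": self.seed,
            "objective": self.objective,
        }


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, diagnostics: dict):
        super().__init__(msg)
        self.diagnostics = diagnostics


def _objective(lam, fbar, scores, beta):
    return float(lam @ fbar - logsumexp(scores) - beta @ np.abs(lam))


def fit_maxent(
    features: FeatureMatrix,
    presence: np.ndarray,
    background: np.ndarray | None = None,
    beta: float | np.ndarray = DEFAULT_BETA,
    *,
    seed: int = 0,
    background_size: int = DEFAULT_BACKGROUND,
    min_presence: int = 20,
    beta_mode: str = "scaled",
    tol: float = 1e-8,
    max_sweeps: int = 5000,
) -> MaxentModel:
    """Fit the regularized maxent model by cyclic coordinate ascent.

    With ``beta_mode='scaled'`` (default) the per-feature bound is
    ``beta * sd_background(f_j) / sqrt(n_presence)`` — the conventional
    presence-only default, which shrinks the tolerance as presences grow.
    ``'absolute'`` uses ``beta`` for every feature as-is.
    """
    presence = np.asarray(presence, dtype=np.int64)
    if len(presence) < min_presence:
        raise ValueError(f"need at least {min_presence} presence cells (got {len(presence)})")
    if background is None:
        rng = np.random.default_rng(seed)
        n = features.n_cells
        if n > background_size:
            background = np.sort(rng.choice(n, size=background_size, replace=False))
        else:
            background = np.arange(n)
    background = np.asarray(background, dtype=np.int64)
    F = features.X[background]
    fbar = features.X[presence].mean(axis=0)
    k = features.n_features
    beta_vec = np.full(k, float(beta)) if np.isscalar(beta) else np.asarray(beta, dtype=float).copy()
    if beta_mode == "scaled":
        beta_vec = beta_vec * F.std(axis=0) / np.sqrt(len(presence))
    elif beta_mode != "absolute":
        raise ValueError(f"unknown beta_mode {beta_mode!r}")

    lam = np.zeros(k)
    scores = np.zeros(len(background))
    obj = _objective(lam, fbar, scores, beta_vec)
    trace: list[tuple[int, float]] = []
    path = [obj]
    converged = False
    F2 = F**2
    kkt = np.inf
    for step in range(max_sweeps * k):
        # greedy coordinate ascent: the step's gain is credited to the
        # updated feature, so attribution follows signal strength
        w = np.exp(scores - logsumexp(scores))
        e = w @ F
        var = np.maximum(w @ F2 - e**2, 0.0)
        g = fbar - e
        kkt = float(np.max(np.abs(g) - beta_vec))
        usable = var > 1e-12
        z = np.where(usable, lam + g / np.where(usable, var, 1.0), lam)
        lam_cand = np.sign(z) * np.maximum(np.abs(z) - beta_vec / np.where(usable, var, 1.0), 0.0)
        delta_all = np.where(usable, np.clip(lam_cand - lam, -10.0, 10.0), 0.0)
        est_gain = (
            g * delta_all
            - 0.5 * var * delta_all**2
            - beta_vec * (np.abs(lam + delta_all) - np.abs(lam))
        )
        j = int(np.argmax(est_gain))
        if est_gain[j] < tol and kkt < 1e-7:
            converged = True
            break
        delta = delta_all[j]
        if delta == 0.0:
            if kkt < 1e-7:
                converged = True
            break
        col = F[:, j]
        # backtrack so the objective never decreases
        for _ in range(30):
            cand_lam = lam[j] + delta
            cand_scores = scores + delta * col
            cand_obj = _objective(
                np.r_[lam[:j], cand_lam, lam[j + 1 :]], fbar, cand_scores, beta_vec
            )
            if cand_obj >= obj - 1e-12:
                break
            delta *= 0.5
        else:
            break
        gain = cand_obj - obj
        lam[j] = lam[j] + delta
        scores = cand_scores
        obj = cand_obj
        path.append(obj)
        if gain > 0:
            trace.append((j, gain))
    if not converged:
        raise ConvergenceError(
            "maxent fit did not converge",
            {"steps": len(path) - 1, "objective": obj, "kkt_violation": kkt},
        )
    log_z = float(logsumexp(scores))
    w = np.exp(scores - log_z)
    entropy = float(-(w * np.log(np.clip(w, LOG_EPS, None))).sum())
    return MaxentModel(
        lam,
        beta_vec,
        features.names,
        features.variables,
        background,
        log_z,
        entropy,
        len(presence),
        seed,
        obj,
        trace,
        path,
    )


def constraint_violation(model: MaxentModel, features: FeatureMatrix, presence: np.ndarray) -> float:
    """max_j(|E_q[f_j] - E_presence[f_j]| - beta_j); <= tol on a converged fit."""
    F = features.X[model.background_rows]
    scores = F @ model.lam
    w = np.exp(scores - logsumexp(scores))
    eq = w @ F
    fbar = features.X[presence].mean(axis=0)
    return float(np.max(np.abs(eq - fbar) - model.beta))


def predict(model: MaxentModel, features: FeatureMatrix, mode: str = "logistic") -> RasterLayer:
    """Model output as a raster: raw (sums to 1 over background), log, or
    logistic ``e^H q / (1 + e^H q)`` (0.5 for a no-information model)."""
    if tuple(features.names) != tuple(model.feature_names):
        raise ValueError("feature matrix does not match the model's features")
    if mode not in ("raw", "log", "logistic"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    scores = features.X @ model.lam
    log_raw = scores - model.log_z
    if mode == "raw":
        vals = np.exp(log_raw)
    elif mode == "log":
        vals = log_raw
    else:
        expo = model.entropy + log_raw
        vals = 1.0 / (1.0 + np.exp(-expo))
    out = np.zeros(features.spec.shape, dtype=float)
    out[features.cells[:, 0], features.cells[:, 1]] = vals
    return RasterLayer(features.spec, out, "continuous", features.mask.copy())


def split_points(points: PointSet, test_frac: float = 0.25, seed: int = 0) -> tuple[PointSet, PointSet]:
    """Seeded disjoint, exhaustive train/test split of presence points."""
    n = len(points)
    if n < 8:
        raise ValueError("need at least 8 points to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(n * test_frac))
    test_idx = np.sort(order[:n_test])
    train_idx = np.sort(order[n_test:])

    def subset(idx):
        return PointSet(
            points.x[idx],
            points.y[idx],
            ids=points.ids[idx] if points.ids is not None else None,
            t=points.t[idx] if points.t is not None else None,
        )

    return subset(train_idx), subset(test_idx)


def auc_presence_background(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(presence > background) + 0.5 P(tie)."""
    presence_scores = np.asarray(presence_scores, dtype=float)
    background_scores = np.asarray(background_scores, dtype=float)
    if len(presence_scores) == 0 or len(background_scores) == 0:
        raise ValueError("both score sets must be non-empty")
    labels = np.r_[np.ones(len(presence_scores)), np.zeros(len(background_scores))]
    return float(roc_auc_score(labels, np.r_[presence_scores, background_scores]))


def variable_contributions(model: MaxentModel) -> dict[str, float]:
    """Objective gain credited to each variable, normalized to percent."""
    if not model.trace:
        raise ValueError("fit trace is empty; cannot attribute contributions")
    gains: dict[str, float] = {v: 0.0 for v in dict.fromkeys(model.variables)}
    for j, gain in model.trace:
        gains[model.variables[j]] += gain
    total = sum(gains.values())
    if total <= 0:
        return {v: 0.0 for v in gains}
    return {v: 100.0 * g / total for v, g in gains.items()}


def jackknife(
    features: FeatureMatrix,
    presence: np.ndarray,
    background: np.ndarray,
    beta: float | np.ndarray = DEFAULT_BETA,
) -> dict[str, dict[str, float]]:
    """Per-variable explanatory power: regularized training gain over the
    null model with the variable alone, and with it withheld."""
    null_obj = -np.log(len(background))
    out: dict[str, dict[str, float]] = {}
    variables = list(dict.fromkeys(features.variables))
    full = fit_maxent(features, presence, background, beta)
    full_gain = full.objective - null_obj
    for var in variables:
        only = fit_maxent(features.select_variables({var}), presence, background, beta)
        others = set(variables) - {var}
        without = fit_maxent(features.select_variables(others), presence, background, beta)
        out[var] = {
            "only_gain": only.objective - null_obj,
            "without_gain": without.objective - null_obj,
            "full_gain": full_gain,
        }
    return out


def suitability_to_resistance(layer: RasterLayer, mode: str = "maxent") -> RasterLayer:
    """Invert a suitability surface into a [R_MIN, 1] cost/resistance surface.

    maxent mode log-transforms the (epsilon-floored) raw output and rescales
    before inverting; ahp mode inverts the [0,1] surface directly.
    """
    if mode == "ahp":
        return invert_rescale(layer)
    if mode != "maxent":
        raise ValueError(f"unknown mode {mode!r}")
    vals = np.log(np.clip(layer.values, LOG_EPS, None))
    valid = vals[layer.mask]
    if np.ptp(valid) == 0:
        raise ValueError("cannot rescale a constant layer")
    r = (vals - valid.min()) / (valid.max() - valid.min())
    cost = R_MIN + (1.0 - r) * (1.0 - R_MIN)
    cost[~layer.mask] = 0.0
    return layer.copy_with(cost)
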