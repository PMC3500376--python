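"""Expert-based habitat suitability via the Analytic Hierarchy Process.

Reciprocal pairwise-comparison matrices on a 1-9 judgment scale are reduced
to relative weights (principal eigenvector), screened with the standard
consistency ratio, aggregated across experts by element-wise geometric mean,
and applied as coefficients of a weighted linear combination over the
categorized covariate stack.  The resulting suitability surface lies in
[0, 1] and inverts to a cost surface on [R_MIN, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from corridorscope.raster import CovariateStack, RasterLayer, reclassify

__all__ = [
    "R_MIN",
    "CATEGORY_BINS",
    "CATEGORY_CODES",
    "PairwiseMatrix",
    "AHPWeights",
    "Survey",
    "principal_weights",
    "consistency_ratio",
    "aggregate_surveys",
    "weights_from_surveys",
    "categorize_stack",
    "weighted_suitability",
    "ahp_suitability",
    "invert_rescale",
    "save_surveys",
    "load_surveys",
]

#: floor of every rescaled cost/resistance surface, keeping graph edge
#: weights strictly positive (shared with the maxent inversion path)
R_MIN = 0.01

#: attribute bin edges turning continuous covariates into expert categories
#: (right-open bins: e.g. a distance of exactly 150 m falls in the 150-1000 class)
CATEGORY_BINS: dict[str, list[float]] = {
    "dist_wells": [150.0, 1000.0],
    "dist_water": [1000.0, 10000.0],
    "dist_roads": [300.0, 1000.0],
    "ndvi": [0.2, 0.3, 0.6],
}

#: category codes per variable after categorization
CATEGORY_CODES: dict[str, list[int]] = {
    "dist_wells": [0, 1, 2],
    "dist_water": [0, 1, 2],
    "dist_roads": [0, 1, 2],
    "ndvi": [0, 1, 2, 3],
    "fence": [0, 1],
    "landcover": [1, 2, 3, 4, 5, 6],
    "topo_position": [1, 2, 3, 4],
}

#: Saaty random consistency indices by matrix order
RANDOM_INDEX = {3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

SCALE_BOUND = 9.0


@dataclass
class PairwiseMatrix:
    """Reciprocal judgment matrix on the 1-9 scale."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        self.labels = tuple(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if np.any(self.values <= 0):
            raise ValueError("judgments must be positive")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("diagonal must be 1")
        if np.max(np.abs(self.values * self.values.T - 1.0)) > 1e-6:
            raise ValueError("matrix is not reciprocal")
        lo, hi = 1.0 / SCALE_BOUND - 1e-9, SCALE_BOUND + 1e-9
        if np.any(self.values < lo) or np.any(self.values > hi):
            raise ValueError(f"judgments outside the [1/{SCALE_BOUND:.0f}, {SCALE_BOUND:.0f}] scale")

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_upper(cls, labels: Sequence[str], upper: Sequence[Sequence[float]]) -> "PairwiseMatrix":
        """Build from row-wise upper-triangle judgments (a_ij for j > i)."""
        n = len(labels)
        vals = np.eye(n)
        if len(upper) != n - 1:
            raise ValueError("upper triangle must have n-1 rows")
        for i, row in enumerate(upper):
            if len(row) != n - 1 - i:
                raise ValueError(f"upper triangle row {i} has wrong length")
            for k, a in enumerate(row):
                j = i + 1 + k
                a = _parse_judgment(a)
                vals[i, j] = a
                vals[j, i] = 1.0 / a
        return cls(vals, tuple(labels))

    def upper(self) -> list[list[float]]:
        return [[float(self.values[i, j]) for j in range(i + 1, self.n)] for i in range(self.n - 1)]


def _parse_judgment(a) -> float:
    if isinstance(a, str):
        return float(Fraction(a))
    return float(a)


@dataclass
class Survey:
    """One expert's judgments for one season: a variable-level matrix plus
    one category-level matrix per variable."""

    expert: str
    season: str
    variables: PairwiseMatrix
    categories: dict[str, PairwiseMatrix]


@dataclass
class AHPWeights:
    """Variable weights and per-category scores derived from surveys."""

    variable_weights: dict[str, float]
    category_scores: dict[str, dict[int, float]]
    diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)
    n_experts: int = 1

    def __post_init__(self) -> None:
        total = sum(self.variable_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValueError(f"variable weights must sum to 1 (got {total})")
        for var, scores in self.category_scores.items():
            if any(s < 0 for s in scores.values()):
                raise ValueError(f"negative category score for {var}")
            best = max(scores.values())
            if not math.isclose(best, 1.0, abs_tol=1e-8):
                raise ValueError(f"best category of {var} must score 1 (got {best})")

    def contributions_percent(self) -> dict[str, float]:
        """Per-variable relative contribution, scaled to sum to 100."""
        return {v: 100.0 * w for v, w in self.variable_weights.items()}


def principal_weights(matrix: PairwiseMatrix, tol: float = 1e-10, max_iter: int = 10_000) -> tuple[np.ndarray, float]:
    """Normalized principal right eigenvector and eigenvalue, by power iteration."""
    a = matrix.values
    w = np.full(matrix.n, 1.0 / matrix.n)
    for _ in range(max_iter):
        aw = a @ w
        w_new = aw / aw.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    lam = float((a @ w).sum())  # Aw = lam*w and sum(w)=1
    return w, lam


def consistency_ratio(matrix: PairwiseMatrix) -> float:
    """Saaty consistency ratio CI/RI; values above 0.1 warrant a warning."""
    n = matrix.n
    if n not in RANDOM_INDEX:
        raise ValueError(f"no random index for matrix order {n}")
    _, lam = principal_weights(matrix)
    ci = (lam - n) / (n - 1)
    return ci / RANDOM_INDEX[n]


def aggregate_surveys(matrices: Sequence[PairwiseMatrix]) -> PairwiseMatrix:
    """Element-wise geometric mean of expert judgments (reciprocal by construction)."""
    if not matrices:
        raise ValueError("need at least one matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValueError("label mismatch across surveys")
    logs = np.mean([np.log(m.values) for m in matrices], axis=0)
    agg = np.exp(logs)
    # enforce exact reciprocity against floating-point asymmetry
    agg = np.sqrt(agg / agg.T)
    np.fill_diagonal(agg, 1.0)
    return PairwiseMatrix(agg, labels)


def weights_from_surveys(surveys: Sequence[Survey], cr_warn: float = 0.1) -> AHPWeights:
    """Aggregate expert surveys into variable weights and category scores.

    Surveys with a consistency ratio above ``cr_warn`` are flagged in the
    diagnostics but retained.
    """
    if not surveys:
        raise ValueError("no surveys given")
    var_agg = aggregate_surveys([s.variables for s in surveys])
    vw, lam = principal_weights(var_agg)
    diagnostics: dict[str, dict[str, float]] = {
        "variables": _matrix_diag(var_agg, lam),
    }
    weights = {label: float(w) for label, w in zip(var_agg.labels, vw)}
    category_scores: dict[str, dict[int, float]] = {}
    for var in surveys[0].categories:
        cat_agg = aggregate_surveys([s.categories[var] for s in surveys])
        cw, clam = principal_weights(cat_agg)
        diagnostics[var] = _matrix_diag(cat_agg, clam)
        cw = cw / cw.max()  # best category scores 1
        codes = CATEGORY_CODES.get(var)
        if codes is None or len(codes) != len(cat_agg.labels):
            codes = list(range(len(cat_agg.labels)))
        category_scores[var] = {int(code): float(s) for code, s in zip(codes, cw)}
    return AHPWeights(weights, category_scores, diagnostics, n_experts=len(surveys))


def _matrix_diag(matrix: PairwiseMatrix, lam: float) -> dict[str, float]:
    n = matrix.n
    ci = (lam - n) / (n - 1)
    cr = ci / RANDOM_INDEX[n] if n in RANDOM_INDEX else float("nan")
    return {"lambda_max": lam, "CI": ci, "CR": cr, "flagged": float(cr > 0.1)}


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def categorize_stack(stack: CovariateStack) -> dict[str, RasterLayer]:
    """Bin the continuous covariates into their expert attribute classes."""
    out: dict[str, RasterLayer] = {}
    for role in stack.roles():
        layer = stack[role]
        if role in CATEGORY_BINS:
            out[role] = reclassify(layer, CATEGORY_BINS[role])
        else:
            out[role] = layer
    return out


def weighted_suitability(
    stack: CovariateStack,
    variable_weights: Mapping[str, float],
    category_scores: Mapping[str, Mapping[int, float]],
) -> RasterLayer:
    """Weighted linear combination of per-category scores: the one scoring
    definition shared by the AHP engine and the synthetic truth model."""
    cats = categorize_stack(stack)
    spec = stack.spec
    total = np.zeros(spec.shape, dtype=float)
    mask = stack.shared_mask()
    for role, w in variable_weights.items():
        if role not in cats:
            raise ValueError(f"weight given for unknown variable {role!r}")
        scored = reclassify(cats[role], dict(category_scores[role]))
        total += w * scored.values
    total[~mask] = 0.0
    return RasterLayer(spec, total, "continuous", mask)


def ahp_suitability(stack: CovariateStack, weights: AHPWeights) -> RasterLayer:
    return weighted_suitability(stack, weights.variable_weights, weights.category_scores)


def invert_rescale(layer: RasterLayer, r_min: float = R_MIN) -> RasterLayer:
    """Cost surface = 1 - suitability, affinely rescaled onto [r_min, 1]."""
    vals = layer.values[layer.mask]
    if np.min(vals) < -1e-9 or np.max(vals) > 1 + 1e-9:
        raise ValueError("suitability must lie in [0, 1]")
    if np.ptp(vals) == 0:
        raise ValueError("cannot invert a constant layer")
    cost = r_min + (1.0 - layer.values) * (1.0 - r_min)
    cost[~layer.mask] = 0.0
    return layer.copy_with(cost)


# ---------------------------------------------------------------------------
# Survey serialization (structured text)
# ---------------------------------------------------------------------------

def save_surveys(surveys: Sequence[Survey], path: str | Path) -> Path:
    path = Path(path)
    docs = []
    for s in surveys:
        docs.append(
            {
                "expert": s.expert,
                "season": s.season,
                "variables": {"labels": list(s.variables.labels), "upper": s.variables.upper()},
                "categories": {
                    var: {"labels": list(m.labels), "upper": m.upper()} for var, m in s.categories.items()
                },
            }
        )
    path.write_text(yaml.safe_dump({"surveys": docs}, sort_keys=False))
    return path


def load_surveys(path: str | Path) -> list[Survey]:
    raw = yaml.safe_load(Path(path).read_text())
    surveys = []
    for doc in raw["surveys"]:
        variables = PairwiseMatrix.from_upper(doc["variables"]["labels"], doc["variables"]["upper"])
        categories = {
            var: PairwiseMatrix.from_upper(m["labels"], m["upper"]) for var, m in doc["categories"].items()
        }
        surveys.append(Survey(doc["expert"], doc["season"], variables, categories))
    return surveys
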