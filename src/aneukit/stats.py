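"""Rupture-status statistics.

Group comparison (two-tailed Mann-Whitney U), rank-correlation screening
(Spearman), threshold-sweep optimisation of WSS area indices, ROC
analysis, and polynomial logistic rupture models — including evaluation
of the two published three-parameter models (maxWSSG-NSI-AR and
AHG-NSI-AR) with their printed coefficients.

Conventions mirrored from the source procedure:

* predictors entering a logistic model are first normalised by their mean
  over *all* aneurysms ("starred" predictors);
* the optimal area-index threshold is the grid argument minimising the
  Mann-Whitney p-value of the area between groups, with no multiplicity
  correction (a Bonferroni-across-grid option exists but is off by
  default — the resulting type-I inflation is measured in the test suite,
  not hidden);
* the ROC operating point maximises Youden's J, ties resolved toward
  higher sensitivity; AUC is the pairwise concordance probability with
  ties counted 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import SeparationError
from .mesh import TriSurfaceMesh
from .metrics import MetricMap, area_index

__all__ = [
    "mann_whitney_u",
    "spearman",
    "significance_stars",
    "roc",
    "RocResult",
    "threshold_sweep",
    "ThresholdSweepResult",
    "normalize_predictors",
    "fit_logistic",
    "select_polynomial_order",
    "published_model",
    "LogisticModel",
    "PUBLISHED_MODELS",
    "group_comparison",
]


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (U of sample x, p).

    Exact enumeration when n_x + n_y ≤ 20 and the pooled data are tie-free,
    otherwise the tie-corrected normal approximation with continuity
    correction.  If every pooled value is identical the test is degenerate
    and p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; (ρ, p).

    p uses the t-approximation.  Constant input is an error (the
    correlation is undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need n ≥ 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def significance_stars(p: float) -> str:
    """'**' for p < 0.01, '*' for 0.01 ≤ p < 0.05, '' otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """AUC plus the Youden-optimal operating point."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    thresholds: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    fpr: np.ndarray = field(repr=False, default=None)


def roc(scores, labels) -> RocResult:
    """ROC analysis of a score against binary labels (1 = event).

    AUC is the pairwise concordance probability (ties ½), computed from
    average ranks.  Candidate operating thresholds are midpoints between
    consecutive distinct scores (positive when score ≥ threshold); the
    reported threshold maximises J = sensitivity + specificity − 1, ties
    resolved toward higher sensitivity.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    uniq = np.unique(scores)
    mid = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], mid, [uniq[-1] + 1.0]])
    pred = scores[None, :] >= cands[:, None]
    tp = (pred & (labels == 1)).sum(axis=1)
    fp = (pred & (labels == 0)).sum(axis=1)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.flatnonzero(np.isclose(j, best_j))
    best = tied[np.argmax(sens[tied])]
    return RocResult(
        auc=float(auc),
        threshold=float(cands[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        thresholds=cands,
        tpr=sens,
        fpr=1.0 - spec,
    )


# ---------------------------------------------------------------------------
# threshold sweep (area-index optimisation)
# ---------------------------------------------------------------------------

@dataclass
class ThresholdSweepResult:
    """p-value curves of an area-index threshold sweep."""

    metric: str
    direction: str
    grid: np.ndarray
    p_area: np.ndarray
    p_ratio: np.ndarray
    optimal_threshold: float
    min_p: float
    significant: bool  # any p_area < 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.grid, "p_area": self.p_area, "p_ratio": self.p_ratio}
        )


def threshold_sweep(
    meshes: TriSurfaceMesh | Sequence[TriSurfaceMesh],
    metric_values: Sequence[np.ndarray] | Sequence[MetricMap],
    labels: Sequence[int],
    direction: str,
    metric_name: str = "metric",
    grid: np.ndarray | None = None,
    n_grid: int = 200,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> ThresholdSweepResult:
    """Optimise an area-index threshold by minimising the between-group p.

    For every candidate threshold the per-aneurysm dome area (and area
    ratio) beyond the threshold is computed and compared between ruptured
    (label 1) and unruptured (label 0) groups with the two-tailed
    Mann-Whitney U test; the optimal threshold is the grid arg-min of the
    area p-curve (ties → smaller threshold).  ``meshes`` may be a single
    shared mesh or one per aneurysm.  The default grid is ``n_grid``
    uniform points between the pooled 1st and 99th percentiles.  Grid
    points where no aneurysm (or every aneurysm entirely) passes the
    threshold are degenerate and get p = 1.
    """
    labels = np.asarray(labels, int)
    values = [
        m.values if isinstance(m, MetricMap) else np.asarray(m, float)
        for m in metric_values
    ]
    if isinstance(meshes, TriSurfaceMesh):
        meshes = [meshes] * len(values)
    if len(meshes) != len(values) or len(values) != len(labels):
        raise ValueError("meshes, metric_values and labels must align")
    if grid is None:
        pooled = np.concatenate(values)
        lo, hi = np.percentile(pooled, [1.0, 99.0])
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0) and len(grid) > 1:
        raise ValueError("threshold grid must be strictly increasing")

    n = len(values)
    areas = np.empty((n, len(grid)))
    ratios = np.empty((n, len(grid)))
    for i, (mesh, vals) in enumerate(zip(meshes, values)):
        dome = mesh.dome_faces
        face_vals = vals[mesh.faces[dome]].mean(axis=1)
        fa = mesh.face_areas[dome]
        total = fa.sum()
        order = np.argsort(face_vals)
        sorted_vals = face_vals[order]
        csum = np.concatenate([[0.0], np.cumsum(fa[order])])
        if direction == "above":
            # area where value > t  (strict); snap empty sets to exact zero
            pos = np.searchsorted(sorted_vals, grid, side="right")
            areas[i] = np.where(pos == len(sorted_vals), 0.0, total - csum[pos])
        elif direction == "below":
            pos = np.searchsorted(sorted_vals, grid, side="left")
            areas[i] = csum[pos]
        else:
            raise ValueError("direction must be 'above' or 'below'")
        ratios[i] = areas[i] / total

    p_area = np.ones(len(grid))
    p_ratio = np.ones(len(grid))
    rup = labels == 1
    for j in range(len(grid)):
        col = areas[:, j]
        if np.all(col == col[0]):
            continue  # degenerate grid point: p = 1
        _, p_area[j] = mann_whitney_u(col[rup], col[~rup])
        _, p_ratio[j] = mann_whitney_u(ratios[rup, j], ratios[~rup, j])
    if np.all(p_area == 1.0):
        warnings.warn("every grid point degenerate (empty area index)", stacklevel=2)

    best = int(np.argmin(p_area))  # argmin takes the smallest-threshold tie
    crit = alpha / len(grid) if bonferroni else alpha
    return ThresholdSweepResult(
        metric=metric_name,
        direction=direction,
        grid=grid,
        p_area=p_area,
        p_ratio=p_ratio,
        optimal_threshold=float(grid[best]),
        min_p=float(p_area[best]),
        significant=bool(p_area.min() < crit),
    )


# ---------------------------------------------------------------------------
# logistic rupture models
# ---------------------------------------------------------------------------

def normalize_predictors(
    cohort: pd.DataFrame,
    names: Sequence[str],
    means: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Starred predictors x* = x / mean(x over all aneurysms).

    When ``means`` is given (e.g. stored from a training cohort) those are
    applied instead of the new data's own means.  Means must be positive.
    """
    out = {}
    used = {}
    for name in names:
        mu = float(cohort[name].mean()) if means is None else float(means[name])
        if mu <= 0:
            raise ValueError(f"{name}: normalisation mean must be positive")
        out[name + "*"] = cohort[name].to_numpy(float) / mu
        used[name] = mu
    return pd.DataFrame(out, index=cohort.index), used


def _design_matrix(
    starred: pd.DataFrame, orders: Mapping[str, int]
) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones(len(starred))], ["intercept"]
    for name, order in orders.items():
        x = starred[name + "*"].to_numpy(float)
        for k in range(1, order + 1):
            cols.append(x**k)
            names.append(f"{name}*^{k}" if k > 1 else f"{name}*")
    return np.column_stack(cols), names


class LogisticModel:
    """Polynomial logistic rupture-status model (sklearn-style).

    Predictors are normalised by their cohort means and expanded to the
    requested polynomial orders; the fit is unpenalised maximum likelihood
    (Newton).  Fitted attributes carry a trailing underscore; a model
    built from published coefficients has ``published=True``.
    """

    def __init__(self, predictors: Sequence[str], orders: Mapping[str, int] | int = 1):
        self.predictors = list(predictors)
        if isinstance(orders, int):
            orders = {p: orders for p in self.predictors}
        self.orders = {p: int(orders[p]) for p in self.predictors}
        if any(o < 1 for o in self.orders.values()):
            raise ValueError("polynomial orders must be ≥ 1")
        self.published = False

    # -- sklearn-compatible surface --------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"predictors": self.predictors, "orders": self.orders}

    def set_params(self, **params) -> "LogisticModel":
        for key, val in params.items():
            setattr(self, key, val)
        return self

    @property
    def n_terms(self) -> int:
        return sum(self.orders.values())

    def fit(self, cohort: pd.DataFrame, y=None, label: str = "ruptured") -> "LogisticModel":
        """Maximum-likelihood fit on a cohort table with a binary label."""
        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        yv = np.asarray(cohort[label] if y is None else y, int)
        n_events = int(yv.sum())
        epv = n_events / self.n_terms if self.n_terms else np.inf
        if epv < 5:
            warnings.warn(
                f"events per variable {epv:.1f} < 5: estimates may be unstable",
                stacklevel=2,
            )
        starred, means = normalize_predictors(cohort, self.predictors)
        design, names = _design_matrix(starred, self.orders)
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            try:
                res = sm.Logit(yv, design).fit(method="newton", disp=False, maxiter=100)
            except (PerfectSeparationError, RuntimeWarning, np.linalg.LinAlgError) as exc:
                raise SeparationError(
                    "logistic fit did not converge (complete or quasi-complete "
                    "separation)"
                ) from exc
        if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 1e4:
            raise SeparationError("logistic fit did not converge (diverging coefficients)")
        self.coef_ = np.asarray(res.params, float)
        self.term_names_ = names
        self.normalization_means_ = means
        self.converged_ = True
        self.llf_ = float(res.llf)
        return self

    def set_published(
        self, coef: Sequence[float], means: Mapping[str, float] | None = None
    ) -> "LogisticModel":
        """Install fixed (published) coefficients instead of fitting."""
        _, names = _design_matrix(
            pd.DataFrame({p + "*": [1.0] for p in self.predictors}), self.orders
        )
        coef = np.asarray(coef, float)
        if len(coef) != len(names):
            raise ValueError(f"expected {len(names)} coefficients, got {len(coef)}")
        self.coef_ = coef
        self.term_names_ = names
        self.normalization_means_ = dict(means or {p: 1.0 for p in self.predictors})
        self.converged_ = True
        self.published = True
        return self

    def _starred(self, cohort: pd.DataFrame) -> pd.DataFrame:
        pre_normalized = all(p + "*" in cohort.columns for p in self.predictors)
        if pre_normalized:
            return cohort
        starred, _ = normalize_predictors(
            cohort, self.predictors, means=self.normalization_means_
        )
        return starred

    def decision_function(self, cohort: pd.DataFrame) -> np.ndarray:
        """The linear predictor (log-odds of rupture)."""
        design, _ = _design_matrix(self._starred(cohort), self.orders)
        return design @ self.coef_

    def predict_odds(self, cohort: pd.DataFrame) -> np.ndarray:
        return np.exp(self.decision_function(cohort))

    def predict_proba(self, cohort: pd.DataFrame) -> np.ndarray:
        """Rupture probability p = odds/(1 + odds) ∈ (0, 1)."""
        from scipy.special import expit

        return expit(self.decision_function(cohort))

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(cohort) >= 0.5).astype(int)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Human-readable key-value model file."""
        with open(path, "w") as fh:
            fh.write("predictors: " + " ".join(self.predictors) + "\n")
            fh.write(
                "orders: " + " ".join(str(self.orders[p]) for p in self.predictors) + "\n"
            )
            fh.write("terms: " + " ".join(self.term_names_) + "\n")
            fh.write("coefficients: " + " ".join(f"{c:.17g}" for c in self.coef_) + "\n")
            fh.write(
                "normalization_means: "
                + " ".join(f"{self.normalization_means_[p]:.17g}" for p in self.predictors)
                + "\n"
            )
            fh.write(f"published: {int(self.published)}\n")

    @classmethod
    def load(cls, path) -> "LogisticModel":
        fields = {}
        with open(path) as fh:
            for line in fh:
                if ":" in line:
                    key, val = line.split(":", 1)
                    fields[key.strip()] = val.split()
        predictors = fields["predictors"]
        orders = {p: int(o) for p, o in zip(predictors, fields["orders"])}
        model = cls(predictors, orders)
        means = {
            p: float(v) for p, v in zip(predictors, fields["normalization_means"])
        }
        model.set_published([float(c) for c in fields["coefficients"]], means)
        model.published = bool(int(fields.get("published", ["0"])[0]))
        return model


def fit_logistic(
    cohort: pd.DataFrame,
    orders: Mapping[str, int],
    label: str = "ruptured",
) -> LogisticModel:
    """Fit a polynomial logistic rupture model on starred predictors."""
    return LogisticModel(list(orders), orders).fit(cohort, label=label)


def select_polynomial_order(
    cohort: pd.DataFrame,
    predictor: str,
    max_order: int = 5,
    label: str = "ruptured",
) -> int:
    """Single-predictor polynomial order maximising in-sample AUC.

    Fits orders 1..max_order and returns the arg-max of the apparent AUC
    (ties → lower order); non-convergent orders are skipped with a warning.
    """
    if max_order < 1:
        raise ValueError("max_order must be ≥ 1")
    y = np.asarray(cohort[label], int)
    best_order, best_auc = None, -np.inf
    for order in range(1, max_order + 1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_logistic(cohort, {predictor: order}, label=label)
        except SeparationError:
            warnings.warn(f"order {order} did not converge; skipped", stacklevel=2)
            continue
        auc = roc(model.predict_proba(cohort), y).auc
        if auc > best_auc + 1e-12:
            best_order, best_auc = order, auc
    if best_order is None:
        raise SeparationError("no polynomial order converged")
    return best_order


# ---------------------------------------------------------------------------
# published models
# ---------------------------------------------------------------------------

#: printed coefficients of the two published rupture models:
#: intercept, x, x², NSI, AR — on mean-normalised (starred) predictors
PUBLISHED_MODELS: dict[str, dict] = {
    "maxWSSG-NSI-AR": {
        "predictors": ["maxWSSG", "NSI", "AR"],
        "orders": {"maxWSSG": 2, "NSI": 1, "AR": 1},
        "coef": [-12.268, 2.638, -0.374, 8.131, 3.246],
    },
    "AHG-NSI-AR": {
        "predictors": ["AHG", "NSI", "AR"],
        "orders": {"AHG": 2, "NSI": 1, "AR": 1},
        "coef": [-14.027, 2.927, -0.854, 10.076, 3.524],
    },
}


def published_model(which: str) -> LogisticModel:
    """One of the two published polynomial logistic models.

    Inputs to ``predict_*`` must already be starred (mean-normalised), or a
    DataFrame with columns named e.g. ``maxWSSG*`` may be passed directly.
    """
    try:
        spec = PUBLISHED_MODELS[which]
    except KeyError:
        raise ValueError(
            f"unknown model {which!r}; choose from {sorted(PUBLISHED_MODELS)}"
        ) from None
    model = LogisticModel(spec["predictors"], spec["orders"])
    return model.set_published(spec["coef"])


# ---------------------------------------------------------------------------
# cohort-level convenience
# ---------------------------------------------------------------------------

def group_comparison(
    cohort: pd.DataFrame, label: str = "ruptured"
) -> pd.DataFrame:
    """Per-parameter group means ± SD and Mann-Whitney p, with stars.

    Reproduces the layout of a ruptured-vs-unruptured comparison table.
    """
    rows = []
    rup = cohort[cohort[label] == 1]
    unrup = cohort[cohort[label] == 0]
    for col in cohort.columns:
        if col == label:
            continue
        _, p = mann_whitney_u(rup[col], unrup[col])
        rows.append(
            {
                "parameter": col,
                "ruptured_mean": rup[col].mean(),
                "ruptured_sd": rup[col].std(ddof=1),
                "unruptured_mean": unrup[col].mean(),
                "unruptured_sd": unrup[col].std(ddof=1),
                "p_value": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows)
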