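"""VO₂ regression models: forward selection under 10-fold cross-validation,
evaluation metrics, per-task relative errors, and the published equations.

The modelling experiment mirrors a common protocol in energy-expenditure
work: windows (not participants) are randomly partitioned into k = 10
folds; within each fold's 90% training split a greedy forward selection
grows ordinary-least-squares models of 1..max_k predictors drawn from one
of three variable sets (all 55 features, the 32 linear ones, or the 23
nonlinear ones); held-out predictions are pooled across folds to give a
performance curve; the final model refits the modal 3-predictor set on all
data.  A ``group_by`` option folds by participant instead, since
window-level folding leaks within-participant correlation.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_INDEX, FEATURE_NAMES, FeatureVector, feature_class_map

log = logging.getLogger(__name__)

VARIABLE_SETS = ("all", "linear", "nonlinear")


class SingularityError(ValueError):
    """The design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"design matrix is rank deficient; offending columns: {self.columns}"
        )


@dataclass(frozen=True)
class LinearModel:
    """Affine VO₂ predictor: intercept + Σ coefficient × feature.

    ``terms`` is an ordered tuple of (canonical feature name, coefficient);
    all names must belong to the model's ``variable_set``.
    """

    intercept: float
    terms: tuple[tuple[str, float], ...]
    variable_set: str = "all"

    def __post_init__(self) -> None:
        if self.variable_set not in VARIABLE_SETS:
            raise ValueError(f"unknown variable_set {self.variable_set!r}")
        names = [n for n, _ in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate term names in model")
        cmap = feature_class_map()
        for n in names:
            if n not in FEATURE_INDEX:
                raise ValueError(f"unknown feature name {n!r}")
            if self.variable_set != "all" and cmap[n] != self.variable_set:
                raise ValueError(
                    f"feature {n!r} has class {cmap[n]!r}, not allowed in a "
                    f"{self.variable_set!r} model"
                )

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.terms)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "terms": [[n, c] for n, c in self.terms],
            "variable_set": self.variable_set,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(intercept=float(d["intercept"]),
                   terms=tuple((str(n), float(c)) for n, c in d["terms"]),
                   variable_set=str(d.get("variable_set", "all")))


def published_models() -> dict[str, LinearModel]:
    """The three published predictive equations, coefficients verbatim.

    All-variables and linear-variables models share the same three
    predictors (RV_75-25, Y_VAR, Y_SD) with marginally different printed
    coefficients; the nonlinear model uses RV_DYN, RV_ND1 and Y_DYN.
    VO₂ is in mL·kg⁻¹·min⁻¹.
    """
    return {
        "all": LinearModel(
            intercept=3.4921,
            terms=(("RV_75-25", 10.784), ("Y_VAR", -25.4524), ("Y_SD", 21.0447)),
            variable_set="all",
        ),
        "linear": LinearModel(
            intercept=3.4921,
            terms=(("RV_75-25", 10.7083), ("Y_VAR", -25.4524), ("Y_SD", 21.04487)),
            variable_set="linear",
        ),
        "nonlinear": LinearModel(
            intercept=-343.0891,
            terms=(("RV_DYN", 503.1303), ("RV_ND1", 1.6797), ("Y_DYN", -156.1103)),
            variable_set="nonlinear",
        ),
    }


def predict(model: LinearModel, fv) -> float | np.ndarray:
    """Evaluate a model on a FeatureVector, mapping, or feature table.

    Returns a float for a single vector, an ndarray for a table.  A missing
    feature raises ``KeyError`` naming it.
    """
    names = model.predictors
    if isinstance(fv, pd.DataFrame):
        for n in names:
            if n not in fv.columns:
                raise KeyError(f"feature {n!r} missing from table")
        out = np.full(len(fv), model.intercept, dtype=float)
        for n, c in model.terms:
            out += c * fv[n].to_numpy(float)
        return out
    values = fv.values if isinstance(fv, FeatureVector) else fv
    out = model.intercept
    for n, c in model.terms:
        if n not in values:
            raise KeyError(f"feature {n!r} missing from feature vector")
        out += c * float(values[n])
    return float(out)


# ---------------------------------------------------------------------------
# fitting


def _design(table: pd.DataFrame, names) -> np.ndarray:
    cols = [np.ones(len(table))]
    for n in names:
        if n not in table.columns:
            raise KeyError(f"feature {n!r} missing from table")
        cols.append(table[n].to_numpy(float))
    return np.column_stack(cols)


def _offending_columns(X: np.ndarray, names) -> list[str]:
    """Columns that do not increase the rank of the growing design matrix."""
    bad = []
    rank = 1  # intercept column
    for j, n in enumerate(names, start=1):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            bad.append(n)
        rank = r
    return bad


def fit_ols(table: pd.DataFrame, names, target: str = "vo2",
            variable_set: str = "all") -> LinearModel:
    """Ordinary least squares of ``target`` on the named features.

    Raises :class:`SingularityError` naming the offending columns when the
    design matrix (intercept + predictors) is rank deficient.
    """
    names = list(names)
    if len(table) < len(names) + 2:
        raise ValueError(
            f"need at least {len(names) + 2} rows to fit {len(names)} predictors"
        )
    X = _design(table, names)
    y = table[target].to_numpy(float)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularityError(_offending_columns(X, names) or names)
    return LinearModel(intercept=float(beta[0]),
                       terms=tuple(zip(names, map(float, beta[1:]))),
                       variable_set=variable_set)


def ols_standard_errors(table: pd.DataFrame, model: LinearModel,
                        target: str = "vo2") -> dict[str, float]:
    """Classical OLS standard errors of the intercept and coefficients."""
    names = list(model.predictors)
    X = _design(table, names)
    y = table[target].to_numpy(float)
    resid = y - predict(model, table)
    dof = len(y) - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough rows for standard errors")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return {"intercept": float(se[0]), **{n: float(s) for n, s in zip(names, se[1:])}}


def metrics(pred, obs) -> dict[str, float]:
    """Pearson correlation, mean squared error and mean absolute error.

    A constant input yields correlation 0 with a logged warning.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size != obs.size:
        raise ValueError("pred and obs must have equal lengths")
    if pred.size < 3:
        raise ValueError("metrics needs at least 3 pairs")
    err = pred - obs
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        log.warning("metrics: constant series, correlation reported as 0")
        r = 0.0
    else:
        r = float(np.clip(np.corrcoef(pred, obs)[0, 1], -1.0, 1.0))
    return {"correlation": r,
            "mse": float(np.mean(err**2)),
            "mae": float(np.mean(np.abs(err)))}


# ---------------------------------------------------------------------------
# cross-validated forward selection


def kfold_split(n_windows: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random fold assignment of ``n_windows`` items into ``k`` near-equal
    folds (sizes differ by at most 1); deterministic for a fixed seed."""
    if n_windows < k:
        raise ValueError(f"cannot split {n_windows} windows into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_windows)
    assignment = np.empty(n_windows, dtype=int)
    base, rem = divmod(n_windows, k)
    start = 0
    for f in range(k):
        size = base + (1 if f < rem else 0)
        assignment[perm[start:start + size]] = f
        start += size
    return assignment


def group_kfold_split(groups, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold assignment keeping all windows of one group (participant) in a
    single fold: groups are shuffled then dealt round-robin."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < k:
        raise ValueError(f"cannot split {uniq.size} groups into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq.size)
    fold_of = {uniq[g]: i % k for i, g in enumerate(order)}
    return np.array([fold_of[g] for g in groups], dtype=int)


def candidate_features(variable_set: str) -> list[str]:
    """The canonical-order candidate pool for a variable set."""
    if variable_set == "all":
        return list(FEATURE_NAMES)
    cmap = feature_class_map()
    return [n for n in FEATURE_NAMES if cmap[n] == variable_set]


def forward_select(table: pd.DataFrame, variable_set: str = "all",
                   max_k: int = 10, target: str = "vo2") -> list[str]:
    """Greedy forward selection: at each step add the candidate minimizing
    the training MSE of the refit OLS model.

    Ties are broken by canonical feature-name order (candidates are scanned
    in canonical order and only a strict improvement replaces the incumbent).
    Candidates whose addition makes the design singular are skipped.
    """
    cands = candidate_features(variable_set)
    if not cands:
        raise ValueError(f"empty candidate set for variable_set={variable_set!r}")
    y = table[target].to_numpy(float)
    selected: list[str] = []
    X_sel = np.ones((len(table), 1))
    for _ in range(min(max_k, len(cands))):
        best_name, best_mse, best_col = None, math.inf, None
        for name in cands:
            if name in selected:
                continue
            col = table[name].to_numpy(float)
            X = np.column_stack([X_sel, col])
            beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            if rank < X.shape[1]:
                continue
            resid = y - X @ beta
            mse = float(resid @ resid) / len(y)
            if mse < best_mse:
                best_name, best_mse, best_col = name, mse, col
        if best_name is None:
            break
        selected.append(best_name)
        X_sel = np.column_stack([X_sel, best_col])
    return selected


@dataclass
class CVExperiment:
    """Results of one cross-validated forward-selection experiment."""

    variable_set: str
    seed: int
    k: int
    max_k: int
    final_k: int
    fold_assignment: np.ndarray
    selections: list[list[str]]            # per fold, ordered selection
    curve: pd.DataFrame                    # columns: k, split, correlation, mse, mae
    fold_curve: pd.DataFrame               # per-fold training/validation metrics
    final_predictors: tuple[str, ...]
    final_model: LinearModel
    final_model_se: dict[str, float]
    validation: pd.DataFrame               # label, obs, pred at k = final_k

    def to_dict(self) -> dict:
        return {
            "variable_set": self.variable_set,
            "seed": self.seed,
            "k": self.k,
            "max_k": self.max_k,
            "final_k": self.final_k,
            "selections": self.selections,
            "curve": self.curve.to_dict(orient="records"),
            "final_predictors": list(self.final_predictors),
            "final_model": self.final_model.to_dict(),
            "final_model_se": self.final_model_se,
        }


def run_cv_experiment(table: pd.DataFrame, variable_set: str = "all",
                      k: int = 10, max_k: int = 10, final_k: int = 3,
                      seed: int = 0, target: str = "vo2",
                      group_by: str | None = None) -> CVExperiment:
    """Run the full k-fold forward-selection experiment on a feature table.

    Per fold, selection and fitting use the training 90% only; predictions
    on the held-out 10% are pooled across folds (training predictions
    likewise) to produce one metric triple per predictor count 1..max_k and
    split.  The final predictor set is the ``final_k``-predictor set chosen
    most frequently across folds (ties broken by canonical order); the
    final model is that set refit by OLS on all windows.
    """
    n = len(table)
    if group_by is None:
        folds = kfold_split(n, k=k, seed=seed)
    else:
        folds = group_kfold_split(table[group_by].to_numpy(), k=k, seed=seed)
    max_k = min(max_k, len(candidate_features(variable_set)))
    if not 1 <= final_k <= max_k:
        raise ValueError(f"final_k must be in 1..max_k={max_k}")

    pooled = {("training", kk): ([], []) for kk in range(1, max_k + 1)}
    pooled.update({("validation", kk): ([], []) for kk in range(1, max_k + 1)})
    selections: list[list[str]] = []
    fold_rows = []
    val_rows = []

    for f in range(k):
        tr = table.loc[folds != f]
        va = table.loc[folds == f]
        sel = forward_select(tr, variable_set=variable_set, max_k=max_k, target=target)
        selections.append(sel)
        for kk in range(1, len(sel) + 1):
            model = fit_ols(tr, sel[:kk], target=target, variable_set=variable_set)
            p_tr = predict(model, tr)
            p_va = predict(model, va)
            pooled[("training", kk)][0].append(p_tr)
            pooled[("training", kk)][1].append(tr[target].to_numpy(float))
            pooled[("validation", kk)][0].append(p_va)
            pooled[("validation", kk)][1].append(va[target].to_numpy(float))
            for split, p, o in (("training", p_tr, tr[target].to_numpy(float)),
                                ("validation", p_va, va[target].to_numpy(float))):
                m = metrics(p, o)
                fold_rows.append({"fold": f, "k": kk, "split": split, **m})
            if kk == final_k:
                val_rows.append(pd.DataFrame({
                    "label": va["label"].to_numpy(),
                    "obs": va[target].to_numpy(float),
                    "pred": p_va,
                }))

    curve_rows = []
    for (split, kk), (ps, os_) in sorted(pooled.items(), key=lambda t: (t[0][1], t[0][0])):
        if not ps:
            continue
        m = metrics(np.concatenate(ps), np.concatenate(os_))
        curve_rows.append({"k": kk, "split": split, **m})
    curve = pd.DataFrame(curve_rows)

    counts = Counter(frozenset(sel[:final_k]) for sel in selections
                     if len(sel) >= final_k)
    if not counts:
        raise ValueError("no fold produced a selection of the requested size")
    top = max(counts.values())
    tied = [s for s, c in counts.items() if c == top]
    final_set = min(tied, key=lambda s: tuple(sorted(FEATURE_INDEX[n] for n in s)))
    final_names = sorted(final_set, key=FEATURE_INDEX.__getitem__)
    final_model = fit_ols(table, final_names, target=target, variable_set=variable_set)
    final_se = ols_standard_errors(table, final_model, target=target)

    return CVExperiment(
        variable_set=variable_set, seed=seed, k=k, max_k=max_k, final_k=final_k,
        fold_assignment=folds, selections=selections, curve=curve,
        fold_curve=pd.DataFrame(fold_rows),
        final_predictors=tuple(final_names), final_model=final_model,
        final_model_se=final_se,
        validation=pd.concat(val_rows, ignore_index=True),
    )


def task_error_table(pred, obs, labels) -> pd.DataFrame:
    """Per-activity relative errors of pooled validation predictions.

    For each activity label: relative normalized MSE = 100 × MSE / mean(obs²)
    and relative MAE = 100 × MAE / mean(obs), in percent.  Activities with
    fewer than 2 windows are flagged and left uncomputed (NaN).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    labels = np.asarray(labels)
    if not (pred.size == obs.size == labels.size):
        raise ValueError("pred, obs and labels must be aligned")
    rows = []
    for lab in pd.unique(labels):
        m = labels == lab
        if m.sum() < 2:
            rows.append({"label": lab, "rel_mse_pct": np.nan,
                         "rel_mae_pct": np.nan, "n_windows": int(m.sum()),
                         "flagged": True})
            continue
        e = pred[m] - obs[m]
        rows.append({
            "label": lab,
            "rel_mse_pct": 100.0 * float(np.mean(e**2)) / float(np.mean(obs[m] ** 2)),
            "rel_mae_pct": 100.0 * float(np.mean(np.abs(e))) / float(np.mean(obs[m])),
            "n_windows": int(m.sum()),
            "flagged": False,
        })
    return pd.DataFrame(rows)
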