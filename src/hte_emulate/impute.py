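"""Iterative random-forest imputation of missing baseline covariates.

Missing cells are initialized with the column mean (continuous) or mode
(categorical/binary), then each incomplete variable is regressed on all
other variables with a random forest and its missing cells overwritten,
cycling in ascending order of missingness until the out-of-sample-style
difference statistic increases for both variable kinds (the classic
stopping rule for this family of imputers), at which point the previous
completed table is returned.

Treatment and outcome columns are legitimate predictors (the imputation
model is congenial with the outcome model that consumes the completed
table) but are themselves never imputed: missingness there is a contract
violation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .schema import NON_COVARIATE_COLS, CovariateSchema


@dataclass
class ImputationResult:
    completed: pd.DataFrame
    n_iterations: int
    convergence_trace: list[dict]


def _is_missing(col: pd.Series) -> np.ndarray:
    return col.isna().to_numpy()


def _mode_fill(col: pd.Series, levels: tuple[str, ...] | None):
    counts = col.value_counts(dropna=True)
    if counts.empty:
        raise ValueError(f"column {col.name!r} is entirely missing")
    top = counts.max()
    # lexicographically-first mode for determinism
    modes = sorted(str(v) for v, c in counts.items() if c == top)
    return modes[0]


def _encode_predictors(
    df: pd.DataFrame, schema: CovariateSchema, exclude: str
) -> np.ndarray:
    """One-hot encode the current completed table minus the target column."""
    parts = []
    for name in df.columns:
        if name == exclude:
            continue
        col = df[name]
        if name in schema and schema[name].kind == "categorical":
            for lev in schema[name].levels:
                parts.append((col.astype(str) == lev).to_numpy(dtype=float))
        else:
            parts.append(col.to_numpy(dtype=float))
    return np.column_stack(parts)


def rf_impute(
    table: pd.DataFrame,
    schema: CovariateSchema,
    max_iter: int = 10,
    trees: int = 100,
    seed: int = 0,
) -> ImputationResult:
    """Complete all missing covariate cells in ``table``.

    Only columns named in ``schema`` are imputed; identifier, treatment and
    outcome columns pass through (and participate as predictors where
    numeric).  Deterministic in ``seed``.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows to impute")
    cov_cols = [c for c in schema.names if c in table.columns]
    for c in NON_COVARIATE_COLS:
        if c in table.columns and table[c].isna().any():
            raise ValueError(f"column {c!r} has missing values; treatment/outcome are never imputed")

    masks = {c: _is_missing(table[c]) for c in cov_cols}
    n_missing = {c: int(m.sum()) for c, m in masks.items()}
    for c, m in masks.items():
        if m.all():
            raise ValueError(f"column {c!r} is entirely missing")
    if not any(m.any() for m in masks.values()):
        return ImputationResult(table.copy(), 1, [])
    has_complete_cov = any(n_missing[c] == 0 for c in cov_cols)
    has_complete_other = any(
        c in table.columns and not table[c].isna().any() for c in NON_COVARIATE_COLS
    )
    if not (has_complete_cov or has_complete_other):
        raise ValueError("need at least one fully observed column")

    rng = np.random.default_rng(seed)
    work = table.copy()
    # model columns: covariates + any complete numeric bookkeeping columns
    model_cols = list(cov_cols)
    for c in ("treatment", "y_uncontrolled"):
        if c in table.columns:
            model_cols.append(c)
    work_model = work[model_cols].copy()

    # initialization: mean / mode
    for c in cov_cols:
        m = masks[c]
        if not m.any():
            continue
        cov = schema[c]
        if cov.kind == "continuous":
            work_model.loc[m, c] = float(work_model[c].mean())
        else:
            fill = _mode_fill(table[c], cov.levels if cov.kind == "categorical" else None)
            if cov.kind == "binary":
                fill = float(fill)
            col = work_model[c]
            if isinstance(col.dtype, pd.CategoricalDtype):
                col = col.astype("object")
            col = col.copy()
            col[m] = fill
            work_model[c] = col

    visit = sorted((c for c in cov_cols if n_missing[c] > 0), key=lambda c: (n_missing[c], c))
    cont_cols = [c for c in visit if schema[c].kind == "continuous"]
    cat_cols = [c for c in visit if schema[c].kind != "continuous"]

    prev_completed = work_model.copy()
    trace: list[dict] = []
    prev_stat = {"continuous": np.inf, "categorical": np.inf}
    n_iterations = 0
    for it in range(1, max_iter + 1):
        n_iterations = it
        old = work_model.copy()
        for c in visit:
            m = masks[c]
            Xfull = _encode_predictors(work_model, schema, exclude=c)
            Xobs, Xmis = Xfull[~m], Xfull[m]
            cov = schema[c]
            fit_seed = int(rng.integers(0, 2**31 - 1))
            if cov.kind == "continuous":
                model = RandomForestRegressor(
                    n_estimators=trees, random_state=fit_seed, n_jobs=1, min_samples_leaf=5
                )
                yobs = work_model.loc[~m, c].to_numpy(dtype=float)
                model.fit(Xobs, yobs)
                work_model.loc[m, c] = model.predict(Xmis)
            else:
                yobs = work_model.loc[~m, c].astype(str).to_numpy()
                if len(np.unique(yobs)) == 1:
                    pred = np.repeat(yobs[0], int(m.sum()))
                else:
                    model = RandomForestClassifier(
                        n_estimators=trees, random_state=fit_seed, n_jobs=1, min_samples_leaf=5
                    )
                    model.fit(Xobs, yobs)
                    # majority vote with lexicographic tie-break
                    proba = model.predict_proba(Xmis)
                    order = np.argsort(model.classes_)  # classes_ already sorted; explicit
                    classes = model.classes_[order]
                    pred = classes[np.argmax(proba[:, order], axis=1)]
                if cov.kind == "binary":
                    work_model.loc[m, c] = pred.astype(float)
                else:
                    col = work_model[c]
                    if isinstance(col.dtype, pd.CategoricalDtype):
                        col = col.astype("object")
                    col = col.copy()
                    col[m] = pred
                    work_model[c] = col

        # difference statistics vs previous iteration, over imputed cells
        stat = {}
        if cont_cols:
            num = den = 0.0
            for c in cont_cols:
                m = masks[c]
                new = work_model.loc[m, c].to_numpy(dtype=float)
                prev = old.loc[m, c].to_numpy(dtype=float)
                num += float(np.sum((new - prev) ** 2))
                den += float(np.sum(new**2))
            stat["continuous"] = num / den if den > 0 else 0.0
        if cat_cols:
            changed = total = 0
            for c in cat_cols:
                m = masks[c]
                changed += int(np.sum(work_model.loc[m, c].astype(str).to_numpy() != old.loc[m, c].astype(str).to_numpy()))
                total += int(m.sum())
            stat["categorical"] = changed / total if total else 0.0
        trace.append({"iteration": it, **stat})

        kinds = [k for k in ("continuous", "categorical") if k in stat]
        increased = [stat[k] > prev_stat[k] for k in kinds]
        if kinds and all(increased):
            # divergence: return the previous completed table
            work_model = prev_completed
            break
        prev_completed = work_model.copy()
        prev_stat = {k: stat.get(k, np.inf) for k in ("continuous", "categorical")}
        if all(stat.get(k, 0.0) == 0.0 for k in kinds):
            break

    out = table.copy()
    for c in cov_cols:
        if schema[c].kind == "categorical":
            out[c] = pd.Categorical(
                work_model[c].astype(str), categories=list(schema[c].levels)
            )
        else:
            out[c] = work_model[c].to_numpy(dtype=float)
    # observed cells are bit-identical by construction (only masked cells
    # were ever written); assert the completion contract
    for c in cov_cols:
        if out[c].isna().any():
            raise AssertionError(f"column {c!r} still has missing values after imputation")
    return ImputationResult(out, n_iterations, trace)


def mean_impute(table: pd.DataFrame, schema: CovariateSchema) -> pd.DataFrame:
    """Column-mean / mode baseline imputer (benchmark comparator)."""
    out = table.copy()
    for c in schema.names:
        if c not in out.columns:
            continue
        m = _is_missing(out[c])
        if not m.any():
            continue
        cov = schema[c]
        if cov.kind == "continuous":
            out.loc[m, c] = float(out[c].mean())
        else:
            fill = _mode_fill(table[c], cov.levels if cov.kind == "categorical" else None)
            if cov.kind == "binary":
                out.loc[m, c] = float(fill)
            else:
                col = out[c].astype("object")
                col[m] = fill
                out[c] = pd.Categorical(col, categories=list(cov.levels))
    return out


def imputation_error(
    completed: pd.DataFrame,
    truth: pd.DataFrame,
    mask: pd.DataFrame,
    schema: CovariateSchema,
) -> tuple[float, float]:
    """(NRMSE over imputed continuous cells, proportion falsely classified).

    NRMSE is normalized by the variance of the true values of the imputed
    cells; PFC is the error rate over imputed binary/categorical cells.
    ``mask`` marks the cells that were imputed (True = was missing).
    """
    cont_err = []
    cont_truth = []
    cat_wrong = cat_total = 0
    any_cells = False
    for c in schema.names:
        if c not in completed.columns or c not in mask.columns:
            continue
        m = mask[c].to_numpy(dtype=bool)
        if not m.any():
            continue
        any_cells = True
        if schema[c].kind == "continuous":
            imp = completed.loc[m, c].to_numpy(dtype=float)
            tru = truth.loc[m, c].to_numpy(dtype=float)
            cont_err.append(imp - tru)
            cont_truth.append(tru)
        else:
            imp = completed.loc[m, c].astype(str).to_numpy()
            tru = truth.loc[m, c].astype(str).to_numpy()
            cat_wrong += int(np.sum(imp != tru))
            cat_total += int(m.sum())
    if not any_cells:
        raise ValueError("empty imputation mask")
    if cont_err:
        err = np.concatenate(cont_err)
        tru = np.concatenate(cont_truth)
        var = float(np.var(tru))
        nrmse = float(np.sqrt(np.mean(err**2) / var)) if var > 0 else float(np.sqrt(np.mean(err**2)))
    else:
        nrmse = 0.0
    pfc = cat_wrong / cat_total if cat_total else 0.0
    return nrmse, pfc
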