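"""G-formula effect estimation and trial-emulation diagnostics.

The causal contrast is estimated by outcome regression: the fitted ensemble
predicts each person's outcome with the treatment column set to 1 and to 0;
the per-person difference is the individual treatment effect (ITE, risk
difference for the binary endpoint, negative = benefit), its mean the ATE,
and the ratio of mean counterfactual risks the risk ratio.  Uncertainty
comes from a percentile bootstrap over persons.  The module also provides
the number needed to treat, the E-value for unmeasured confounding, a
cross-fitted propensity-overlap (positivity) diagnostic, and a
baseline-characteristics table with per-covariate tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .ensemble import EnsembleModel, _simplex_lstsq, cv_stack, predict_ensemble
from .schema import TREATMENT_COL, CovariateSchema

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# counterfactual predictions and ITE
# ---------------------------------------------------------------------------


@dataclass
class CounterfactualPredictions:
    p1: np.ndarray  # predicted outcome with treatment set to 1
    p0: np.ndarray  # predicted outcome with treatment set to 0
    outcome_kind: str  # "binary" | "continuous"

    def __post_init__(self) -> None:
        if len(self.p1) != len(self.p0):
            raise ValueError("p1 and p0 must be aligned")
        if self.outcome_kind == "binary" and (
            np.any((self.p1 <= 0) | (self.p1 >= 1)) or np.any((self.p0 <= 0) | (self.p0 >= 1))
        ):
            raise ValueError("binary counterfactual predictions must lie in (0, 1)")


@dataclass
class ITEVector:
    ite: np.ndarray

    @property
    def ate(self) -> float:
        return float(np.mean(self.ite))


def counterfactual_predict(model: EnsembleModel, X: pd.DataFrame) -> CounterfactualPredictions:
    """Predictions under both counterfactual treatment assignments.

    ``X`` may include or omit the treatment column; it is overwritten with
    1 (treated) and 0 (control) for the two passes.
    """
    X1 = X.copy()
    X1[TREATMENT_COL] = 1.0
    X1 = X1[model.feature_names]
    X0 = X1.copy()
    X0[TREATMENT_COL] = 0.0
    return CounterfactualPredictions(
        p1=predict_ensemble(model, X1),
        p0=predict_ensemble(model, X0),
        outcome_kind=model.loss,
    )


def compute_ite(cf: CounterfactualPredictions) -> ITEVector:
    """Per-person effect p1 - p0 (negative = benefit)."""
    return ITEVector(ite=cf.p1 - cf.p0)


# ---------------------------------------------------------------------------
# summary transforms
# ---------------------------------------------------------------------------


def nnt_from_rd(rd: float) -> float:
    """Number needed to treat: reciprocal of the absolute risk difference.

    Returned at full precision (NNT * |rd| == 1); display rounding to one
    decimal belongs to the formatting layer.
    """
    if rd == 0:
        raise ValueError("NNT undefined for a zero risk difference")
    return 1.0 / abs(rd)


def evalue_rr(rr: float) -> float:
    """E-value for a risk ratio (protective ratios are inverted first).

    E = rr* + sqrt(rr* (rr* - 1)) with rr* = max(rr, 1/rr): the minimum
    strength of association an unmeasured confounder would need with both
    treatment and outcome to explain away the observed ratio.
    """
    if rr <= 0 or not np.isfinite(rr):
        raise ValueError("risk ratio must be a positive finite number")
    rr_star = max(rr, 1.0 / rr)
    return float(rr_star + np.sqrt(rr_star * (rr_star - 1.0)))


# ---------------------------------------------------------------------------
# effect estimation with bootstrap
# ---------------------------------------------------------------------------


@dataclass
class EffectEstimate:
    scale: str  # "risk difference" | "risk ratio" | "mean difference"
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _resample_both_arms(rng, n, A, max_retry=100):
    for _ in range(max_retry):
        idx = rng.integers(0, n, size=n)
        if 0 < A[idx].sum() < n:
            return idx
        log.warning("bootstrap resample lost an arm; redrawing")
    raise RuntimeError("could not draw a bootstrap resample containing both arms")


def estimate_effects(
    X: pd.DataFrame,
    y: np.ndarray,
    library=None,
    V: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    fast_boot: bool = False,
    loss: str | None = None,
    model: EnsembleModel | None = None,
) -> dict[str, EffectEstimate]:
    """Point and percentile-bootstrap interval estimates of ATE (and RR for
    a binary outcome).

    The point estimates are plug-in: ATE = mean(p1 - p0) over the cohort,
    RR = mean(p1)/mean(p0).  Each bootstrap resample redraws persons with
    replacement (redrawn, up to 100 times, if an arm vanishes) and either
    refits the whole stack (default) or, with ``fast_boot``, refits only the
    simplex weights on the fixed fitted learners — a cheap approximation
    for large simulation batches.
    """
    y = np.asarray(y, dtype=float)
    A = X[TREATMENT_COL].to_numpy()
    if A.sum() == 0 or A.sum() == len(A):
        raise ValueError("both treatment arms must be present")
    if model is None:
        model = cv_stack(X, y, library=library, V=V, seed=seed, loss=loss)
    cf = counterfactual_predict(model, X)
    ite = compute_ite(cf)
    binary = model.binary

    ate_point = ite.ate
    rr_point = float(np.mean(cf.p1) / np.mean(cf.p0)) if binary else None

    rng = np.random.default_rng((seed, 17))
    n = len(y)
    ate_bs, rr_bs = [], []

    if fast_boot:
        ok = [k for k, w in enumerate(model.weights) if model.refit_learners[k] is not None]
        X1 = X.copy()
        X1[TREATMENT_COL] = 1.0
        X0 = X.copy()
        X0[TREATMENT_COL] = 0.0
        X1v = X1[model.feature_names].to_numpy(dtype=float)
        X0v = X0[model.feature_names].to_numpy(dtype=float)
        P1 = np.column_stack([model.refit_learners[k].predict(X1v) for k in ok])
        P0 = np.column_stack([model.refit_learners[k].predict(X0v) for k in ok])
        Z = model.oof_predictions[:, ok]
        for _ in range(n_boot):
            idx = _resample_both_arms(rng, n, A)
            w = _simplex_lstsq(Z[idx], y[idx])
            p1b = P1[idx] @ w
            p0b = P0[idx] @ w
            ate_bs.append(float(np.mean(p1b - p0b)))
            if binary:
                rr_bs.append(float(np.mean(p1b) / np.mean(p0b)))
    else:
        for b in range(n_boot):
            idx = _resample_both_arms(rng, n, A)
            Xb = X.iloc[idx].reset_index(drop=True)
            mb = cv_stack(
                Xb, y[idx], library=model.library, V=model.V, seed=seed + 1000 + b, loss=model.loss
            )
            cfb = counterfactual_predict(mb, Xb)
            ate_bs.append(float(np.mean(cfb.p1 - cfb.p0)))
            if binary:
                rr_bs.append(float(np.mean(cfb.p1) / np.mean(cfb.p0)))

    def _ci(samples):
        return (
            float(np.percentile(samples, 2.5)),
            float(np.percentile(samples, 97.5)),
        )

    out: dict[str, EffectEstimate] = {}
    lo, hi = _ci(ate_bs) if ate_bs else (ate_point, ate_point)
    out["ATE"] = EffectEstimate(
        scale="risk difference" if binary else "mean difference",
        point=ate_point,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        seed=seed,
    )
    if binary:
        lo, hi = _ci(rr_bs) if rr_bs else (rr_point, rr_point)
        out["RR"] = EffectEstimate(
            scale="risk ratio", point=rr_point, ci_low=lo, ci_high=hi, n_boot=n_boot, seed=seed
        )
    return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def propensity_overlap(
    X: pd.DataFrame, A: np.ndarray, V: int = 5, seed: int = 0
) -> dict:
    """Cross-fitted treatment-probability estimates and their per-arm spread.

    A positivity diagnostic: the report carries per-arm quantiles of the
    estimated probability of treatment, the interval where both arms have
    support, and a warning flag when the arms are perfectly separable in
    the estimated probabilities.
    """
    A = np.asarray(A, dtype=int)
    if A.sum() == 0 or A.sum() == len(A):
        raise ValueError("both treatment arms must be present")
    Xv = X.drop(columns=[TREATMENT_COL], errors="ignore").to_numpy(dtype=float)
    ps = np.empty(len(A))
    splitter = StratifiedKFold(n_splits=V, shuffle=True, random_state=seed)
    for train_idx, test_idx in splitter.split(Xv, A):
        mdl = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
        mdl.fit(Xv[train_idx], A[train_idx])
        ps[test_idx] = mdl.predict_proba(Xv[test_idx])[:, 1]

    qs = [0.0, 0.01, 0.25, 0.5, 0.75, 0.99, 1.0]

    def _summ(p):
        return {f"q{int(q * 100):02d}": float(np.quantile(p, q)) for q in qs}

    p_treated = ps[A == 1]
    p_control = ps[A == 0]
    lo = max(p_treated.min(), p_control.min())
    hi = min(p_treated.max(), p_control.max())
    separable = p_control.max() < p_treated.min() or p_treated.max() < p_control.min()
    return {
        "treated": _summ(p_treated),
        "control": _summ(p_control),
        "overlap_interval": [float(lo), float(min(hi, 1.0))] if hi >= lo else None,
        "separation_warning": bool(separable or hi < lo),
        "estimated_probabilities": ps,
    }


def _p_display(p: float) -> str:
    return "< 0.01" if p < 0.01 else f"{p:.2f}"


def baseline_table(
    table: pd.DataFrame, schema: CovariateSchema, treatment_col: str = TREATMENT_COL
) -> pd.DataFrame:
    """Baseline-characteristics summary by arm.

    Discrete covariates: per-level counts and column percentages with a
    chi-square test over observed levels and an explicit Missing row.
    Continuous covariates: mean (SD) per arm with a two-sample t test.
    P-values are floored at "< 0.01" in the display column, matching the
    usual table convention.
    """
    A = table[treatment_col].to_numpy(dtype=int)
    rows = []
    arm = {"control": A == 0, "treated": A == 1}
    if not (arm["control"].any() and arm["treated"].any()):
        raise ValueError("both treatment arms must be present")
    for cov in schema.entries:
        col = table[cov.name]
        if cov.kind == "continuous":
            x0 = col[arm["control"]].dropna().to_numpy(dtype=float)
            x1 = col[arm["treated"]].dropna().to_numpy(dtype=float)
            t, p = stats.ttest_ind(x0, x1, equal_var=False)
            rows.append(
                {
                    "covariate": cov.name,
                    "level": "mean (SD)",
                    "control": f"{x0.mean():.1f} ({x0.std(ddof=1):.1f})",
                    "treated": f"{x1.mean():.1f} ({x1.std(ddof=1):.1f})",
                    "control_mean": x0.mean(),
                    "control_sd": x0.std(ddof=1),
                    "treated_mean": x1.mean(),
                    "treated_sd": x1.std(ddof=1),
                    "p_value": float(p),
                    "p_display": _p_display(float(p)),
                }
            )
        else:
            levels = list(cov.levels) if cov.kind == "categorical" else [1.0, 0.0]
            label = {1.0: "yes", 0.0: "no"}
            counts = {}
            for a, m in arm.items():
                vals = col[m]
                counts[a] = {
                    lev: int((vals == lev).sum()) for lev in levels
                }
                counts[a]["__missing__"] = int(vals.isna().sum())
                counts[a]["__n__"] = int(m.sum())
            contingency = np.array(
                [[counts[a][lev] for lev in levels] for a in ("control", "treated")]
            )
            keep = contingency.sum(axis=0) > 0
            if keep.sum() >= 2 and contingency.sum(axis=1).min() > 0:
                _, p, _, _ = stats.chi2_contingency(contingency[:, keep])
            else:
                p = np.nan
            for lev in levels:
                rows.append(
                    {
                        "covariate": cov.name,
                        "level": label.get(lev, str(lev)),
                        "control": f"{counts['control'][lev]:,} ({100 * counts['control'][lev] / counts['control']['__n__']:.0f})",
                        "treated": f"{counts['treated'][lev]:,} ({100 * counts['treated'][lev] / counts['treated']['__n__']:.0f})",
                        "control_n": counts["control"][lev],
                        "treated_n": counts["treated"][lev],
                        "p_value": float(p) if lev == levels[0] else np.nan,
                        "p_display": _p_display(float(p)) if lev == levels[0] and np.isfinite(p) else "",
                    }
                )
            rows.append(
                {
                    "covariate": cov.name,
                    "level": "Missing",
                    "control": f"{counts['control']['__missing__']:,} ({100 * counts['control']['__missing__'] / counts['control']['__n__']:.0f})",
                    "treated": f"{counts['treated']['__missing__']:,} ({100 * counts['treated']['__missing__'] / counts['treated']['__n__']:.0f})",
                    "control_n": counts["control"]["__missing__"],
                    "treated_n": counts["treated"]["__missing__"],
                    "p_value": np.nan,
                    "p_display": "",
                }
            )
    return pd.DataFrame(rows)
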