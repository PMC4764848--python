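"""Comparator predictors: parental-trait regression and stepwise regression.

Both baselines predate the metabolite PLS approach.  The parental-trait
baseline correlates each sum/difference/ratio encoding of the parents'
own phenotypes with the hybrid trait and fits a one-variable line.  The
stepwise baseline is SPSS-style probability-of-F selection on the
metabolite features: forward entry at p <= 0.05, backward removal at
p >= 0.10, iterated to a fixed point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import encode_pair_features, expand_to_hybrids
from .panel import DiallelCross

logger = logging.getLogger("hybridmet")


def parental_trait_baseline(
    parent_traits: pd.DataFrame,
    hybrid_traits: pd.DataFrame,
    cross: DiallelCross,
    encoding: str = "sum",
) -> pd.DataFrame:
    """Correlate one parental-trait encoding with each hybrid trait.

    Returns a row per trait: (trait, r, p_value, slope, intercept, n);
    constant predictors are reported as undefined.
    """
    feats = encode_pair_features(parent_traits, cross, encodings=(encoding,))
    X, Y = expand_to_hybrids(feats, cross, hybrid_traits, mode="duplicate")
    rows = []
    for trait in Y.columns:
        x = X[f"{trait}__{encoding}"].to_numpy(dtype=float)
        y = Y[trait].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"trait": trait, "r": np.nan, "p_value": np.nan,
                         "slope": np.nan, "intercept": np.nan, "n": len(y),
                         "note": "undefined (constant input)"})
            continue
        r, p = stats.pearsonr(x, y)
        fit = stats.linregress(x, y)
        rows.append({"trait": trait, "r": r, "p_value": p, "slope": fit.slope,
                     "intercept": fit.intercept, "n": len(y), "note": ""})
    return pd.DataFrame(rows)


@dataclass
class StepwiseModel:
    """Result of probability-of-F stepwise selection."""

    selected: list[str]
    params: pd.Series
    intercept: float
    rsquared: float
    rsquared_adj: float
    history: pd.DataFrame = field(repr=False)

    def predict(self, exog: pd.DataFrame) -> pd.Series:
        X = exog[self.selected].to_numpy(dtype=float) if self.selected else np.zeros((len(exog), 0))
        return pd.Series(X @ self.params.to_numpy() + self.intercept, index=exog.index)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(((y - y.mean()) ** 2).sum())
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ coef
    return float(r @ r)


def _partial_f_p(rss_small: float, rss_big: float, df_big: int) -> float:
    """p-value of the 1-df partial F comparing nested OLS fits."""
    if df_big <= 0 or rss_big <= 0:
        return 0.0 if rss_big < rss_small else 1.0
    f = (rss_small - rss_big) / (rss_big / df_big)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, 1, df_big))


def stepwise_regression(
    design: pd.DataFrame,
    response,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseModel:
    """Forward-entry / backward-removal linear regression.

    Each round adds the candidate with the smallest partial-F p-value if
    it is <= ``p_enter`` (ties broken by lowest column index), then removes
    any included variable whose p-value is >= ``p_remove``.  Stops at a
    fixed point, or with a warning if a variable oscillates in and out
    twice (a known stepwise pathology).
    """
    if p_enter >= p_remove:
        raise ValueError("p_enter must be below p_remove")
    y = np.asarray(response, dtype=float).ravel()
    n = len(y)
    if n <= 2:
        raise ValueError("need more than 2 observations")
    cols = list(design.columns)
    Xall = design.to_numpy(dtype=float)

    ss_tot0 = float(((y - y.mean()) ** 2).sum())

    def _adj_r2(idxs: list[int]) -> float:
        rss = _ols_rss(Xall[:, idxs], y)
        r2 = 1.0 - rss / ss_tot0 if ss_tot0 > 0 else np.nan
        df = n - len(idxs) - 1
        return 1.0 - (1.0 - r2) * (n - 1) / df if df > 0 else np.nan

    included: list[int] = []
    history: list[dict] = []
    bounce_count: dict[int, int] = {}
    step = 0
    while True:
        changed = False
        # forward entry (skipped once the fit is numerically perfect)
        rss_cur = _ols_rss(Xall[:, included], y)
        best_j, best_p = None, None
        candidates = range(len(cols)) if rss_cur > 1e-12 * max(ss_tot0, 1e-300) else ()
        for j in candidates:
            if j in included:
                continue
            trial = included + [j]
            Xt = Xall[:, trial]
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), Xt])) < len(trial) + 1:
                warnings.warn(f"candidate {cols[j]!r} collinear with current model; skipped",
                              stacklevel=2)
                continue
            p = _partial_f_p(rss_cur, _ols_rss(Xt, y), n - len(trial) - 1)
            if best_p is None or p < best_p - 1e-15:
                best_j, best_p = j, p
        if best_j is not None and best_p <= p_enter:
            included.append(best_j)
            step += 1
            history.append({"step": step, "action": "enter", "variable": cols[best_j],
                            "p_value": best_p, "adjusted_r2": _adj_r2(included)})
            changed = True
        # backward removal
        while len(included) > 0:
            rss_full = _ols_rss(Xall[:, included], y)
            df = n - len(included) - 1
            worst_j, worst_p = None, None
            for j in included:
                rest = [i for i in included if i != j]
                p = _partial_f_p(_ols_rss(Xall[:, rest], y), rss_full, df)
                if worst_p is None or p > worst_p + 1e-15:
                    worst_j, worst_p = j, p
            if worst_p is not None and worst_p >= p_remove:
                included.remove(worst_j)
                step += 1
                history.append({"step": step, "action": "remove", "variable": cols[worst_j],
                                "p_value": worst_p, "adjusted_r2": _adj_r2(included)})
                changed = True
                if history and len(history) >= 2 and history[-2]["action"] == "enter" \
                        and history[-2]["variable"] == cols[worst_j]:
                    bounce_count[worst_j] = bounce_count.get(worst_j, 0) + 1
                    if bounce_count[worst_j] >= 2:
                        warnings.warn("stepwise oscillation detected; stopping", stacklevel=2)
                        changed = False
                        break
            else:
                break
        if not changed:
            break

    sel = [cols[j] for j in included]
    X = Xall[:, included]
    if included:
        A = np.column_stack([np.ones(n), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        intercept, betas = float(coef[0]), coef[1:]
        resid = y - A @ coef
    else:
        intercept, betas = float(y.mean()), np.array([])
        resid = y - intercept
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
    df = n - len(included) - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / df if df > 0 else np.nan
    hist_df = pd.DataFrame(history,
                           columns=["step", "action", "variable", "p_value", "adjusted_r2"])
    logger.info("stepwise: %d variable(s) selected, adj R2 = %s", len(sel),
                f"{adj:.3f}" if np.isfinite(adj) else "nan")
    return StepwiseModel(selected=sel, params=pd.Series(betas, index=sel),
                         intercept=intercept, rsquared=r2, rsquared_adj=adj,
                         history=hist_df)
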