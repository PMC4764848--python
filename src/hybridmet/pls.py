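"""Single-response partial least squares regression with VIP selection.

PLS1 projects a (possibly p >> n, collinear) predictor matrix onto latent
factors that maximize covariance with the response.  The fit is the
classical NIPALS sequence on autoscaled data: for each factor a, the
weight vector w_a is proportional to X_{a-1}^T y_{a-1}, the score is
t_a = X_{a-1} w_a, and X and y are deflated by their projections on t_a.
Scores are mutually orthogonal by construction; with k = rank(X) factors
the fit coincides with least squares.

The latent number is chosen where the training adjusted R^2,
1 - (1 - R^2)(n - 1)/(n - k - 1), peaks (smallest k on ties).  Variable
importance in the projection (VIP) of Factor 1,

    VIP_j = sqrt(p) * |w_j1| / ||w_1||,

has mean square 1 over variables, so 1 is the conventional retention
threshold; filtering keeps VIP >= threshold and refits.  A cumulative
(all-factor, variance-weighted) VIP is available as an alternative mode.

Interface follows the Model/Results convention: ``PLS1(endog, exog)``
builds the model, ``.fit()`` returns a :class:`PLS1Results`.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger("hybridmet")

_EPS = 1e-12


class PLS1:
    """Single-response PLS regression model.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response vector.
    exog : DataFrame or array-like, shape (n, p)
        Predictor matrix; column names are taken from the DataFrame.
    scale : bool
        Autoscale predictors and response to unit variance before fitting
        (coefficients are always reported on the original scale).
    """

    def __init__(self, endog, exog, var_names=None, scale: bool = True):
        if isinstance(exog, pd.DataFrame):
            if var_names is None:
                var_names = [str(c) for c in exog.columns]
            self.row_index = exog.index
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            self.row_index = pd.RangeIndex(X.shape[0])
        y = np.asarray(endog, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError(f"shape mismatch: exog {X.shape}, endog {y.shape}")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in model data")
        if np.std(y) == 0:
            raise ValueError("constant response: nothing to model")
        if var_names is None:
            var_names = [f"x{j}" for j in range(X.shape[1])]

        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance predictor column(s)",
                stacklevel=2,
            )
        self.X = X[:, keep]
        self.y = y
        self.var_names = [v for v, k in zip(var_names, keep) if k]
        self.scale = scale
        self.n, self.p = self.X.shape
        if self.p == 0:
            raise ValueError("no usable predictor columns")

        self._x_mean = self.X.mean(axis=0)
        self._y_mean = self.y.mean()
        if scale:
            self._x_sd = self.X.std(axis=0, ddof=1)
            self._y_sd = self.y.std(ddof=1)
        else:
            self._x_sd = np.ones(self.p)
            self._y_sd = 1.0

    @property
    def k_cap(self) -> int:
        """Largest admissible latent count, min(n - 1, p)."""
        return min(self.n - 1, self.p)

    # -- fitting ---------------------------------------------------------

    def _nipals(self, k_max: int):
        """Run NIPALS for up to k_max factors; stops when X or y deflates out."""
        Xs = (self.X - self._x_mean) / self._x_sd
        ys = (self.y - self._y_mean) / self._y_sd
        y_ref = float(ys @ ys)
        W = np.zeros((self.p, k_max))
        T = np.zeros((self.n, k_max))
        P = np.zeros((self.p, k_max))
        q = np.zeros(k_max)
        k_used = 0
        for a in range(k_max):
            w = Xs.T @ ys
            nw = np.linalg.norm(w)
            if nw < _EPS * max(1.0, np.sqrt(y_ref)):
                break
            w /= nw
            t = Xs @ w
            tt = float(t @ t)
            if tt < _EPS:
                break
            p_load = Xs.T @ t / tt
            q_a = float(ys @ t) / tt
            Xs -= np.outer(t, p_load)
            ys = ys - q_a * t
            W[:, a], T[:, a], P[:, a], q[a] = w, t, p_load, q_a
            k_used += 1
            if float(ys @ ys) < _EPS * max(1.0, y_ref):
                break
        return W[:, :k_used], T[:, :k_used], P[:, :k_used], q[:k_used]

    def fit(self, n_factors: int | None = None, max_factors: int | None = None) -> "PLS1Results":
        """Fit the model.

        With ``n_factors`` given, fit exactly that many latent factors.
        Otherwise scan k = 1..``max_factors`` (default min(n-1, p)) and keep
        the smallest k maximizing the training adjusted R^2.
        """
        cap = self.k_cap
        if n_factors is not None:
            if not (1 <= n_factors <= cap):
                raise ValueError(f"n_factors must be in [1, {cap}], got {n_factors}")
            k_max = n_factors
        else:
            k_max = cap if max_factors is None else min(max_factors, cap)
        W, T, P, q = self._nipals(k_max)
        k_avail = W.shape[1]
        if k_avail == 0:
            raise ValueError("no latent factor could be extracted (response orthogonal to X?)")

        # cumulative standardized fitted values: factor a adds q_a * t_a
        ys = (self.y - self._y_mean) / self._y_sd
        ss_tot = float(ys @ ys)
        contrib = T * q  # (n, k)
        cum_fit = np.cumsum(contrib, axis=1)
        resid2 = ((ys[:, None] - cum_fit) ** 2).sum(axis=0)
        r2 = 1.0 - resid2 / ss_tot
        ks = np.arange(1, k_avail + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = self.n - ks - 1
            adj = np.where(denom > 0, 1.0 - (1.0 - r2) * (self.n - 1) / denom, np.nan)
        table = pd.DataFrame({"k": ks, "r2": r2, "adj_r2": adj})

        if n_factors is not None:
            if k_avail < n_factors:
                warnings.warn(
                    f"only {k_avail} factors extractable (requested {n_factors})",
                    stacklevel=2,
                )
            k_star = k_avail
        else:
            valid = table.dropna(subset=["adj_r2"])
            if valid.empty:
                k_star = 1
                warnings.warn("adjusted R^2 undefined for every k; defaulting to k=1", stacklevel=2)
            else:
                best = valid["adj_r2"].max()
                k_star = int(valid.loc[valid["adj_r2"] >= best - 1e-15, "k"].iloc[0])
        return PLS1Results(self, W[:, :k_star], T[:, :k_star], P[:, :k_star], q[:k_star], table)


class PLS1Results:
    """Fitted PLS1 model: latent structure, coefficients, VIP, diagnostics."""

    def __init__(self, model: PLS1, W, T, P, q, selection_table: pd.DataFrame):
        self.model = model
        self.x_weights = W
        self.x_scores = T
        self.x_loadings = P
        self.y_loadings = q
        self.selection_table = selection_table
        self.n_factors = W.shape[1]

        # coefficients on the standardized then original predictor scale
        M = P.T @ W  # upper triangular with unit diagonal in exact arithmetic
        beta_std = W @ np.linalg.solve(M, q)
        self.params = pd.Series(
            model._y_sd * beta_std / model._x_sd, index=model.var_names, name="coef"
        )
        self.intercept = float(model._y_mean - model._x_mean @ self.params.to_numpy())
        self.fittedvalues = pd.Series(
            model.X @ self.params.to_numpy() + self.intercept,
            index=model.row_index, name="fitted",
        )
        resid = model.y - self.fittedvalues.to_numpy()
        ss_tot = float(((model.y - model.y.mean()) ** 2).sum())
        self.rsquared = 1.0 - float(resid @ resid) / ss_tot
        dof = model.n - self.n_factors - 1
        self.rsquared_adj = (
            1.0 - (1.0 - self.rsquared) * (model.n - 1) / dof if dof > 0 else np.nan
        )

    # -- variable importance --------------------------------------------

    @property
    def vip(self) -> pd.Series:
        """Factor-1 VIP: sqrt(p) |w_j1| / ||w_1||; mean square is 1."""
        w1 = self.x_weights[:, 0]
        nw = np.linalg.norm(w1)
        if nw < _EPS:
            raise ValueError("zero Factor-1 weight vector")
        return pd.Series(
            np.sqrt(self.model.p) * np.abs(w1) / nw, index=self.model.var_names, name="vip"
        )

    @property
    def vip_cumulative(self) -> pd.Series:
        """Variance-weighted VIP over all fitted factors."""
        ssy = self.y_loadings**2 * (self.x_scores**2).sum(axis=0)  # per-factor explained SS
        wnorm2 = (self.x_weights**2).sum(axis=0)
        wnorm2[wnorm2 < _EPS] = 1.0
        contrib = (self.x_weights**2 / wnorm2) @ ssy
        v = np.sqrt(self.model.p * contrib / ssy.sum())
        return pd.Series(v, index=self.model.var_names, name="vip_cumulative")

    # -- prediction ------------------------------------------------------

    def predict(self, exog) -> pd.Series:
        """Evaluate intercept + X @ coefficients on new feature rows.

        A DataFrame is aligned by column name and must cover every model
        variable; extra columns are ignored.
        """
        if isinstance(exog, pd.DataFrame):
            missing = [v for v in self.model.var_names if v not in exog.columns]
            if missing:
                raise KeyError(f"missing predictor column(s): {missing[:5]}")
            X = exog[self.model.var_names].to_numpy(dtype=float)
            idx = exog.index
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != self.model.p:
                raise ValueError(f"expected {self.model.p} columns, got {X.shape[1]}")
            idx = pd.RangeIndex(X.shape[0])
        return pd.Series(X @ self.params.to_numpy() + self.intercept, index=idx, name="predicted")

    # -- filtering -------------------------------------------------------

    def filter_vip(
        self, threshold: float = 1.0, mode: str = "factor1", max_factors: int | None = None
    ) -> "PLS1Results":
        """Drop variables with VIP below ``threshold`` and refit.

        Retention is VIP >= threshold.  The latent number of the reduced
        model is re-selected by adjusted R^2.
        """
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        v = self.vip if mode == "factor1" else self.vip_cumulative
        keep = v[v >= threshold].index.tolist()
        if not keep:
            raise ValueError(
                f"no variable reaches VIP >= {threshold}; lower the threshold"
            )
        sub = PLS1(
            self.model.y,
            pd.DataFrame(
                self.model.X[:, [self.model.var_names.index(c) for c in keep]],
                index=self.model.row_index, columns=keep,
            ),
            scale=self.model.scale,
        )
        logger.info("VIP filter (%s, >= %g): retained %d of %d variables",
                    mode, threshold, len(keep), self.model.p)
        return sub.fit(max_factors=max_factors)

    # -- diagnostics -----------------------------------------------------

    def score_orthogonality(self) -> float:
        """Largest |cos| between distinct score vectors (0 when orthogonal)."""
        T = self.x_scores
        norms = np.linalg.norm(T, axis=0)
        G = (T.T @ T) / np.outer(norms, norms)
        np.fill_diagonal(G, 0.0)
        return float(np.abs(G).max()) if self.n_factors > 1 else 0.0

    def loo_q2(self) -> float:
        """Leave-one-out Q^2 at the fitted latent number (diagnostic only)."""
        press = 0.0
        y = self.model.y
        for i in range(self.model.n):
            mask = np.ones(self.model.n, dtype=bool)
            mask[i] = False
            sub = PLS1(y[mask], self.model.X[mask], var_names=self.model.var_names,
                       scale=self.model.scale)
            k = min(self.n_factors, sub.k_cap)
            res = sub.fit(n_factors=k)
            pred = float(self.model.X[i] @ res.params.to_numpy() + res.intercept)
            press += (y[i] - pred) ** 2
        ss = float(((y - y.mean()) ** 2).sum())
        return 1.0 - press / ss

    def variance_explained(self) -> pd.DataFrame:
        """Per-factor proportion of X and y variance explained."""
        Xs = (self.model.X - self.model._x_mean) / self.model._x_sd
        ssx_tot = float((Xs**2).sum())
        tt = (self.x_scores**2).sum(axis=0)
        ssx = (self.x_loadings**2).sum(axis=0) * tt
        ys = (self.model.y - self.model._y_mean) / self.model._y_sd
        ssy_tot = float(ys @ ys)
        ssy = self.y_loadings**2 * tt
        return pd.DataFrame(
            {
                "factor": np.arange(1, self.n_factors + 1),
                "x_variance": ssx / ssx_tot,
                "y_variance": ssy / ssy_tot,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Machine-readable per-variable table: weight, VIP, coefficient."""
        return pd.DataFrame(
            {
                "variable": self.model.var_names,
                "weight_factor1": self.x_weights[:, 0],
                "vip": self.vip.to_numpy(),
                "coefficient": self.params.to_numpy(),
            }
        )

    def equation(self) -> str:
        """Plain-text prediction equation on the original predictor scale."""
        terms = [f"{self.intercept:+.6g}"]
        terms += [f"{c:+.6g}*[{v}]" for v, c in self.params.items()]
        return "y = " + " ".join(terms)

    def summary(self) -> str:
        lines = [
            "PLS1 regression results",
            "=" * 46,
            f"n observations      {self.model.n:>10d}",
            f"n predictors        {self.model.p:>10d}",
            f"latent factors      {self.n_factors:>10d}",
            f"R-squared           {self.rsquared:>10.4f}",
            f"adj. R-squared      {self.rsquared_adj:>10.4f}",
            f"score orthogonality {self.score_orthogonality():>10.2e}",
            "=" * 46,
        ]
        return "\n".join(lines)


# -- functional conveniences mirroring the pipeline vocabulary -----------

def fit_pls(design, response, k: int, scale: bool = True) -> PLS1Results:
    """Fit a PLS1 model with exactly ``k`` latent factors."""
    return PLS1(response, design, scale=scale).fit(n_factors=k)


def select_latent_number(design, response, k_max: int | None = None, scale: bool = True):
    """Adjusted-R^2 latent selection; returns (results, selection table)."""
    res = PLS1(response, design, scale=scale).fit(max_factors=k_max)
    return res, res.selection_table


def vip_factor1(results: PLS1Results) -> pd.Series:
    return results.vip


def filter_and_refit(
    design, response, threshold: float = 1.0, k_max: int | None = None, scale: bool = True
) -> tuple[PLS1Results, int]:
    """Full-model fit, VIP >= threshold filter, refit; returns (refit, n kept)."""
    full = PLS1(response, design, scale=scale).fit(max_factors=k_max)
    refit = full.filter_vip(threshold=threshold, max_factors=k_max)
    return refit, refit.model.p
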