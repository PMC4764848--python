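"""Predictive-ability computation and stratified evaluation.

Predictive ability is the Pearson correlation (with its two-tailed
t-test p-value) between predicted and observed hybrid values.  It is
reported for the whole population and stratified by subgroup (i / j / ij)
and by the two reciprocal sets (one ordered hybrid of each pair per set;
set A holds the canonical orientation).  A metabolite-trait correlation
screen (with Benjamini-Hochberg adjusted p-values reported alongside the
raw ones) supports rough single-analyte interpretation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel import DiallelCross
from .preprocess import MetaboliteMatrix

logger = logging.getLogger("hybridmet")


def predictive_ability(observed, predicted) -> tuple[float, float, int]:
    """Pearson r of predicted vs observed with 2-tailed p; returns (r, p, n)."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must align")
    n = len(obs)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(obs) == 0 or np.std(pred) == 0:
        return (np.nan, np.nan, n)
    r, p = stats.pearsonr(obs, pred)
    return (float(r), float(p), n)


@dataclass
class PredictionReport:
    """Per-hybrid predictions plus stratified predictive abilities."""

    predictions: pd.DataFrame  # hybrid, trait, observed, predicted, subgroup, reciprocal_set
    abilities: pd.DataFrame    # trait, stratum, r, p_value, n

    def ability(self, trait: str, stratum: str = "whole") -> float:
        sel = self.abilities[(self.abilities["trait"] == trait)
                             & (self.abilities["stratum"] == stratum)]
        return float(sel["r"].iloc[0]) if len(sel) else np.nan


def stratified_evaluation(
    observed: pd.DataFrame,
    predicted: pd.DataFrame,
    cross: DiallelCross,
) -> PredictionReport:
    """Evaluate predictions per trait for the whole population and strata.

    ``observed`` and ``predicted`` are indexed by hybrid id with one
    column per trait/response.  Strata: subgroups i/j/ij and reciprocal
    sets A (canonical orientation) / B.  Strata with fewer than 3 hybrids
    are skipped with a warning.
    """
    hids = cross.hybrid_ids
    sub = pd.Series(cross.subgroup, index=hids)
    rec = pd.Series(["A" if cross.is_canonical(k) else "B" for k in range(len(cross))],
                    index=hids)
    pred_rows = []
    ab_rows = []
    for col in observed.columns:
        obs = observed.loc[hids, col]
        pred = predicted.loc[hids, col]
        for h in hids:
            pred_rows.append({"hybrid": h, "trait": col, "observed": obs[h],
                              "predicted": pred[h], "subgroup": sub[h],
                              "reciprocal_set": rec[h]})
        strata: list[tuple[str, pd.Index]] = [("whole", pd.Index(hids))]
        strata += [(g, sub.index[sub == g]) for g in ("i", "j", "ij")]
        strata += [(f"reciprocal_{s}", rec.index[rec == s]) for s in ("A", "B")]
        for name, idx in strata:
            if len(idx) == 0:
                continue
            if len(idx) < 3:
                warnings.warn(f"stratum {name!r} has n={len(idx)} < 3; skipped", stacklevel=2)
                continue
            r, p, n = predictive_ability(obs.loc[idx], pred.loc[idx])
            ab_rows.append({"trait": col, "stratum": name, "r": r, "p_value": p, "n": n})
    report = PredictionReport(
        predictions=pd.DataFrame(pred_rows),
        abilities=pd.DataFrame(ab_rows),
    )
    logger.info("evaluated %d responses over %d hybrids and %d strata",
                observed.shape[1], len(hids),
                report.abilities["stratum"].nunique())
    return report


def metabolite_trait_correlation(
    matrix: MetaboliteMatrix | pd.DataFrame,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r and 2-tailed p per (analyte, trait), plus BH-adjusted p.

    The adjustment is reported for transparency only; no pipeline step
    gates on it.  Constant analytes are flagged undefined.
    """
    df = matrix.values if isinstance(matrix, MetaboliteMatrix) else matrix
    common = df.index.intersection(traits.index)
    if len(common) < 3:
        raise ValueError("need at least 3 aligned rows")
    X = df.loc[common]
    rows = []
    for trait in traits.columns:
        y = traits.loc[common, trait].to_numpy(dtype=float)
        for analyte in X.columns:
            x = X[analyte].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"analyte": analyte, "trait": trait, "r": np.nan,
                             "p_value": np.nan, "note": "undefined (constant)"})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"analyte": analyte, "trait": trait, "r": r, "p_value": p, "note": ""})
    out = pd.DataFrame(rows)
    out["p_bh"] = np.nan
    ok = out["p_value"].notna()
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    return out
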