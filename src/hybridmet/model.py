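"""Study-level model: the full metabolite-based hybrid prediction workflow.

:class:`MetabolicPredictionModel` binds a parental metabolite matrix, the
diallel cross and the trait tables; :meth:`fit` runs, per response (trait
per se, LPH/MPH/BPH relative heterosis and SCA for each trait), the PLS
regression with adjusted-R^2 latent selection, Factor-1 VIP filtering with
refit, and in-sample prediction; the results object carries the fitted
per-response models, a model-summary table, the heterosis table and the
stratified predictive-ability report.
"""

from __future__ import annotations

import logging

import pandas as pd

from .config import PipelineConfig
from .diallel import heterosis_table, response_names
from .encoding import encode_pair_features, expand_to_hybrids
from .evaluate import PredictionReport, stratified_evaluation
from .io import read_panel, read_trait_table, write_report
from .panel import DiallelCross
from .pls import PLS1, PLS1Results
from .preprocess import MetaboliteMatrix, preprocess_pipeline

logger = logging.getLogger("hybridmet")


class MetabolicPredictionModel:
    """Predict hybrid performance from parental metabolite profiles.

    Parameters
    ----------
    mean_matrix : MetaboliteMatrix (stage='mean')
        Replicate-averaged relative metabolite levels of the parents.
    hybrid_traits, parent_traits : DataFrame
        Trait tables indexed by hybrid / parent id.
    cross : DiallelCross
    config : PipelineConfig, optional
    """

    def __init__(
        self,
        mean_matrix: MetaboliteMatrix,
        hybrid_traits: pd.DataFrame,
        parent_traits: pd.DataFrame,
        cross: DiallelCross,
        config: PipelineConfig | None = None,
    ):
        self.mean_matrix = mean_matrix
        self.hybrid_traits = hybrid_traits
        self.parent_traits = parent_traits
        self.cross = cross
        self.config = config or PipelineConfig()

    @classmethod
    def from_study(cls, study, config: PipelineConfig | None = None):
        """Build from a :class:`~hybridmet.simulate.SyntheticStudy`."""
        return cls(study.mean, study.hybrid_traits, study.parent_traits,
                   study.cross, config=config)

    @classmethod
    def from_csv(
        cls,
        metabolite_csv,
        metadata_csv,
        parent_trait_csv,
        hybrid_trait_csv,
        config: PipelineConfig | None = None,
    ):
        """Build from the four interchange CSVs (raw peak areas are
        preprocessed on the way in)."""
        from .diallel import enumerate_diallel

        panel, raw, parent_traits = read_panel(metabolite_csv, metadata_csv, parent_trait_csv)
        mean, _ = preprocess_pipeline(raw)
        hybrid_traits = read_trait_table(hybrid_trait_csv, name="hybrid trait table")
        cross = enumerate_diallel(panel)
        return cls(mean, hybrid_traits, parent_traits, cross, config=config)

    # -----------------------------------------------------------------

    def fit(self, responses: list[str] | None = None) -> "MetabolicPredictionResults":
        """Fit one PLS model per response and evaluate predictions.

        ``responses`` defaults to all 15 standard columns.
        """
        het = heterosis_table(self.hybrid_traits, self.parent_traits, self.cross,
                              hd_sign_flip=self.config.hd_sign_flip)
        feats = encode_pair_features(self.mean_matrix, self.cross,
                                     encodings=self.config.encodings)
        X, Y = expand_to_hybrids(feats, self.cross, het.hybrid_values,
                                 mode=self.config.reciprocal_mode)
        if responses is None:
            responses = [c for c in response_names() if c in Y.columns]

        full: dict[str, PLS1Results] = {}
        refit: dict[str, PLS1Results] = {}
        preds = pd.DataFrame(index=Y.index)
        for resp in responses:
            logger.info("fitting PLS for response %s", resp)
            res = PLS1(Y[resp], X).fit(max_factors=self.config.latent_cap)
            filt = res.filter_vip(threshold=self.config.vip_threshold,
                                  max_factors=self.config.latent_cap)
            full[resp] = res
            refit[resp] = filt
            # predict on the unique pair rows and expand, so reciprocal
            # hybrids receive bit-identical predictions in duplicate mode
            pair_pred = filt.predict(feats.values)
            if self.config.reciprocal_mode == "duplicate":
                preds[resp] = pair_pred.loc[self.cross.pair_keys].set_axis(X.index)
            else:
                preds[resp] = pair_pred

        if self.config.reciprocal_mode == "duplicate":
            report = stratified_evaluation(Y[responses], preds, self.cross)
        else:
            report = None  # pair-averaged rows have no per-hybrid strata
        return MetabolicPredictionResults(self, feats, X, Y, het, full, refit, preds, report)


class MetabolicPredictionResults:
    """Fitted workflow: per-response PLS models, predictions, reports."""

    def __init__(self, model, features, X, Y, het, full, refit, predictions, report):
        self.model = model
        self.features = features
        self.design = X
        self.responses = Y
        self.heterosis = het
        self.full_models = full
        self.refit_models = refit
        self.predictions = predictions
        self.report: PredictionReport | None = report

    def summary_table(self) -> pd.DataFrame:
        """Per-response fit summary: latent numbers, R^2, retained counts."""
        rows = []
        for resp, res in self.full_models.items():
            filt = self.refit_models[resp]
            rows.append(
                {
                    "trait": resp,
                    "latent_number_full": res.n_factors,
                    "r2_full": res.rsquared,
                    "n_variables": res.model.p,
                    "n_retained": filt.model.p,
                    "latent_number_refit": filt.n_factors,
                    "r2_refit": filt.rsquared,
                }
            )
        return pd.DataFrame(rows)

    def ability_table(self) -> pd.DataFrame:
        """Predictive ability per response and stratum (whole, i, j, ij, A/B)."""
        if self.report is None:
            raise ValueError("stratified evaluation unavailable in average mode")
        return self.report.abilities

    def summary(self) -> str:
        st = self.summary_table()
        lines = ["Metabolic hybrid-prediction results",
                 "=" * 72,
                 f"hybrids: {len(self.model.cross)}   pairs: {self.features.values.shape[0]}   "
                 f"features: {self.features.n_features}",
                 "-" * 72]
        for _, r in st.iterrows():
            lines.append(
                f"{r['trait']:>10s}  k={int(r['latent_number_full']):>3d} "
                f"R2={r['r2_full']:.3f}  kept={int(r['n_retained']):>4d} "
                f"k'={int(r['latent_number_refit']):>3d} R2'={r['r2_refit']:.3f}"
            )
        if self.report is not None:
            lines.append("-" * 72)
            whole = self.report.abilities.query("stratum == 'whole'")
            for _, r in whole.iterrows():
                lines.append(f"{r['trait']:>10s}  predictive ability r = {r['r']:.3f}"
                             f"  (n={int(r['n'])})")
        lines.append("=" * 72)
        return "\n".join(lines)

    def write(self, out_dir) -> pd.DataFrame:
        """Write heterosis, model summary, predictions and ability CSVs."""
        tables = {
            "heterosis": self.heterosis.hybrid_values.reset_index(),
            "gca": self.heterosis.gca.reset_index(),
            "model_summary": self.summary_table(),
            "predictions": (self.report.predictions if self.report is not None
                            else self.predictions.reset_index()),
        }
        if self.report is not None:
            tables["predictive_ability"] = self.report.abilities
        return write_report(tables, out_dir)

    def plot_predictions(self, response: str, ax=None):
        """Diagnostic scatter of predicted vs observed for one response."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        obs = self.responses[response]
        pred = self.predictions[response]
        ax.scatter(obs, pred, s=12, alpha=0.6)
        lo = min(obs.min(), pred.min())
        hi = max(obs.max(), pred.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel(f"observed {response}")
        ax.set_ylabel(f"predicted {response}")
        return ax
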