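"""Synthetic diallel studies with known ground truth.

The generator emulates the study design every stage of the pipeline is
built for: a panel of inbred parents split into two subspecies groups
(default 9 indica + 9 japonica), a complete diallel without selfs (306
ordered hybrids at n = 18), GC-MS peak areas for ~525 positive-valued
analytes measured in replicate with a ribitol internal standard, and
three agronomic traits.

Hybrid traits follow a sparse linear model on the canonical parental
ratio features plus an additive combining-ability structure:

    P_fm = mu + signal_fm + gca_f + gca_m + sca_{fm} + rec_{fm} + eps

where signal is sum(beta_k * ratio_k) over ``n_causal`` analytes.  Betas
are drawn +-Uniform[1, 2] times a per-trait scale on the unit-variance
ratio scale (each causal analyte contributes a comparable share of the
signal regardless of its abundance spread); the signal is centered
across hybrids.
gca/sca are Gaussian with spreads expressed relative to the signal sd,
rec is an optional reciprocal (cytoplasm) effect, and eps is residual
noise.  By default eps is calibrated so the ratio-feature signal explains
``target_r2`` (0.9) of the hybrid trait variance.  All randomness flows
from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diallel import enumerate_diallel
from .encoding import encode_pair_features
from .panel import TRAITS, DiallelCross, Panel, ParentLine, pair_key
from .preprocess import MetaboliteMatrix, preprocess_pipeline

logger = logging.getLogger("hybridmet")

# trait baselines (hybrid population mean) and causal-coefficient scales,
# in trait units: grams/plant, cm, days
TRAIT_MEAN = {"YPP": 40.0, "MSPH": 110.0, "HD": 100.0}
COEF_SCALE = {"YPP": 1.0, "MSPH": 3.0, "HD": 2.0}


@dataclass
class SyntheticStudySpec:
    """Parameters of a synthetic diallel study.

    sd parameters for trait structure (``gca_sd``, ``sca_sd``,
    ``reciprocal_effect_sd``) are fractions of the causal-signal sd;
    ``noise_sd`` of None calibrates residual noise so that the ratio
    signal explains ``target_r2`` of the total hybrid trait variance.
    """

    n_parents: int = 18
    n_analytes: int = 525
    n_replicates: int = 3
    n_causal: int = 10
    coefficient_scale: dict[str, float] = field(default_factory=lambda: dict(COEF_SCALE))
    noise_sd: float | dict[str, float] | None = None
    target_r2: float = 0.9
    gca_sd: float = 0.2
    sca_sd: float = 0.1
    reciprocal_effect_sd: float = 0.0
    group_shift_sd: float = 1.0
    group_shift_frac: float = 0.3
    biological_sd: float = 1.2
    replicate_sd: float = 0.1
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_analytes:
            raise ValueError("n_causal exceeds n_analytes")
        for name in ("gca_sd", "sca_sd", "reciprocal_effect_sd", "group_shift_sd",
                     "biological_sd", "replicate_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.target_r2 <= 1):
            raise ValueError("target_r2 must be in (0, 1]")
        if not (0 <= self.group_shift_frac <= 1):
            raise ValueError("group_shift_frac must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually used, for recovery tests."""

    causal: dict[str, list[str]]          # trait -> causal analyte names
    beta: dict[str, pd.Series]            # trait -> coefficients on ratio features
    gca: pd.DataFrame                     # parent x trait
    sca: dict[str, pd.Series]             # trait -> per-pair SCA
    noise_sd: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for trait, b in self.beta.items():
            for analyte, coef in b.items():
                rows.append({"trait": trait, "analyte": analyte, "coefficient": coef})
        return pd.DataFrame(rows, columns=["trait", "analyte", "coefficient"])


@dataclass
class SyntheticStudy:
    """A complete generated study, ready for every pipeline stage."""

    spec: SyntheticStudySpec
    panel: Panel
    raw: MetaboliteMatrix
    mean: MetaboliteMatrix
    log2: MetaboliteMatrix
    cross: DiallelCross
    parent_traits: pd.DataFrame
    hybrid_traits: pd.DataFrame
    truth: GroundTruth


def generate_parents(
    spec: SyntheticStudySpec, rng: np.random.Generator | None = None
) -> tuple[Panel, MetaboliteMatrix]:
    """Parental panel plus raw replicate-level peak areas.

    Analyte abundances are log-normal with per-analyte group-level mean
    shifts (so clustering and PCA separate the two subspecies groups);
    replicate noise is multiplicative; ribitol areas are positive and
    vary slightly between runs.
    """
    if rng is None:
        rng = np.random.default_rng(spec.random_seed)
    n = spec.n_parents
    n_ind = (n + 1) // 2
    lines = []
    for i in range(n):
        if i < n_ind:
            lines.append(ParentLine(id=f"IND{i+1:02d}", group="indica",
                                    f_i=float(rng.uniform(0.39, 1.0))))
        else:
            lines.append(ParentLine(id=f"JAP{i-n_ind+1:02d}", group="japonica",
                                    f_i=float(rng.uniform(0.0, 0.33))))
    panel = Panel(lines)

    k = spec.n_analytes
    base = rng.uniform(np.log(1e4), np.log(1e6), size=k)       # analyte-level abundance
    # a fraction of analytes carries an indica-vs-japonica offset; the rest
    # are group-neutral (real metabolomes mix both kinds)
    shift = rng.normal(0.0, spec.group_shift_sd, size=k)
    shift[rng.random(k) >= spec.group_shift_frac] = 0.0
    is_indica = np.array([p.group == "indica" for p in panel], dtype=float)
    log_level = (
        base[None, :]
        + np.outer(is_indica, shift)
        + rng.normal(0.0, spec.biological_sd, size=(n, k))
    )

    rep_rows = []
    index = []
    std_areas = []
    for pi, p in enumerate(panel):
        for r in range(1, spec.n_replicates + 1):
            ribitol = float(np.exp(rng.normal(np.log(2e5), 0.05)))
            noise = rng.normal(0.0, spec.replicate_sd, size=k)
            rep_rows.append(np.exp(log_level[pi] + noise) * ribitol)
            index.append((p.id, r))
            std_areas.append(ribitol)
    names = [f"m{j+1:03d}" for j in range(k)]
    idx = pd.MultiIndex.from_tuples(index, names=["parent_id", "replicate"])
    values = pd.DataFrame(np.array(rep_rows), index=idx, columns=names)
    raw = MetaboliteMatrix(values=values, stage="raw",
                           internal_standard=pd.Series(std_areas, index=idx))
    logger.info("generated %d parents x %d analytes x %d replicates",
                n, k, spec.n_replicates)
    return panel, raw


def generate_hybrids(
    spec: SyntheticStudySpec,
    panel: Panel,
    mean_matrix: MetaboliteMatrix,
    cross: DiallelCross,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Hybrid and parental trait tables plus the ground-truth record."""
    if rng is None:
        rng = np.random.default_rng(spec.random_seed + 1)
    feats = encode_pair_features(mean_matrix, cross, encodings=("ratio",))
    ratio = feats.values  # pair_key x analyte__ratio
    analytes = mean_matrix.analyte_names
    hids = cross.hybrid_ids
    keys = cross.pair_keys

    hybrid = pd.DataFrame(index=pd.Index(hids, name="id"), columns=list(TRAITS), dtype=float)
    parent = pd.DataFrame(index=pd.Index(panel.ids, name="id"), columns=list(TRAITS), dtype=float)
    causal: dict[str, list[str]] = {}
    beta: dict[str, pd.Series] = {}
    gca_tab = pd.DataFrame(index=panel.ids, columns=list(TRAITS), dtype=float)
    sca_tab: dict[str, pd.Series] = {}
    noise_used: dict[str, float] = {}

    # Causal analytes are drawn from the half of the panel least
    # differentiated between the two subspecies groups (so the trait signal
    # does not simply recapitulate population structure) and subject to
    # mutual near-orthogonality of their ratio features: with 18 parents
    # the 525 ratio features are strongly collinear, and a sparse ground
    # truth is only identifiable when its members carry distinguishable
    # signal directions.
    is_ind = np.array([panel.group_of(p) == "indica" for p in panel.ids])
    logm = np.log(mean_matrix.values.to_numpy())
    contrast = np.abs(logm[is_ind].mean(axis=0) - logm[~is_ind].mean(axis=0))
    low_contrast = np.argsort(contrast)[: max(spec.n_analytes // 2, spec.n_causal)]
    Z = ratio.to_numpy()
    Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0, ddof=1) > 0, Z.std(axis=0, ddof=1), 1.0)
    n_rows = Z.shape[0]

    def _pick_causal(max_corr: float = 0.10) -> list[int]:
        order = [low_contrast[t] for t in rng.permutation(len(low_contrast))]
        chosen: list[int] = []
        for j in order:
            if all(abs(Z[:, j] @ Z[:, c]) / (n_rows - 1) <= max_corr for c in chosen):
                chosen.append(j)
            if len(chosen) == spec.n_causal:
                return chosen
        # fall back: fill with the least-collinear remaining candidates
        rest = [j for j in order if j not in chosen]
        rest.sort(key=lambda j: max(abs(Z[:, j] @ Z[:, c]) / (n_rows - 1) for c in chosen))
        return chosen + rest[: spec.n_causal - len(chosen)]

    for trait in TRAITS:
        scale = spec.coefficient_scale.get(trait, 1.0)
        picked = sorted(_pick_causal()) if spec.n_causal else []
        names = [analytes[j] for j in picked]
        b = rng.uniform(1.0, 2.0, size=len(picked)) * rng.choice([-1.0, 1.0], size=len(picked))
        b = b * scale
        causal[trait] = names
        feat_names = [f"{a}__ratio" for a in names]
        if picked:
            # express coefficients on the unit-variance ratio scale so every
            # causal analyte carries a comparable share of the signal
            sd_feat = ratio[feat_names].std(ddof=1).to_numpy()
            b = b / np.where(sd_feat > 0, sd_feat, 1.0)
        beta[trait] = pd.Series(b, index=feat_names)

        if picked:
            sig_pair = ratio[beta[trait].index].to_numpy() @ b
        else:
            sig_pair = np.zeros(ratio.shape[0])
        sig_by_key = pd.Series(sig_pair, index=ratio.index)
        signal = sig_by_key.loc[keys].to_numpy()
        signal = signal - signal.mean()
        sd_sig = float(signal.std())
        ref = sd_sig if sd_sig > 0 else scale  # fallback scale when beta is empty/zero

        gca = rng.normal(0.0, spec.gca_sd * ref, size=len(panel))
        gca_tab[trait] = gca
        sca_by_key = pd.Series(
            rng.normal(0.0, spec.sca_sd * ref, size=len(ratio)), index=ratio.index
        )
        sca_tab[trait] = sca_by_key
        rec = rng.normal(0.0, spec.reciprocal_effect_sd * ref, size=len(hids))

        if spec.noise_sd is None:
            var_budget = sd_sig**2 * (1.0 - spec.target_r2) / spec.target_r2
            var_struct = 2 * (spec.gca_sd * ref) ** 2 + (spec.sca_sd * ref) ** 2
            eps_sd = float(np.sqrt(max(var_budget - var_struct, 0.0)))
        elif isinstance(spec.noise_sd, dict):
            eps_sd = float(spec.noise_sd.get(trait, 0.0))
        else:
            eps_sd = float(spec.noise_sd)
        noise_used[trait] = eps_sd
        eps = rng.normal(0.0, eps_sd, size=len(hids)) if eps_sd > 0 else np.zeros(len(hids))

        g_idx = {p: i for i, p in enumerate(panel.ids)}
        gf = np.array([gca[g_idx[f]] for f, _ in cross.hybrids])
        gm = np.array([gca[g_idx[m]] for _, m in cross.hybrids])
        sca_h = sca_by_key.loc[keys].to_numpy()
        hybrid[trait] = TRAIT_MEAN[trait] + signal + gf + gm + sca_h + rec + eps

        # parents sit a little below the hybrid mean with comparable spread
        parent[trait] = 0.85 * TRAIT_MEAN[trait] + rng.normal(0.0, ref, size=len(panel))

    truth = GroundTruth(causal=causal, beta=beta, gca=gca_tab, sca=sca_tab,
                        noise_sd=noise_used)
    logger.info("generated traits for %d hybrids (noise sd: %s)",
                len(hids), {t: round(s, 3) for t, s in noise_used.items()})
    return hybrid, parent, truth


def generate_study(spec: SyntheticStudySpec | None = None) -> SyntheticStudy:
    """Generate a full study: parents, metabolites, diallel, traits, truth."""
    if spec is None:
        spec = SyntheticStudySpec()
    rng = np.random.default_rng(spec.random_seed)
    panel, raw = generate_parents(spec, rng)
    mean, log2 = preprocess_pipeline(raw)
    cross = enumerate_diallel(panel)
    hybrid, parent, truth = generate_hybrids(spec, panel, mean, cross, rng)
    return SyntheticStudy(spec=spec, panel=panel, raw=raw, mean=mean, log2=log2,
                          cross=cross, parent_traits=parent, hybrid_traits=hybrid,
                          truth=truth)
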