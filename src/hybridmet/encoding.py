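"""Parental pair-feature encodings: sum, difference and ratio.

For a pair of parents with values a1 (first parent in canonical panel
order) and a2, the encodings per analyte are

    sum        = (a1 + a2) * 0.5
    difference = a1 - a2
    ratio      = a1 / a2

Reciprocal hybrids share a single feature row: one row is built per
unordered parent pair and expanded to the ordered hybrid list only when
aligning with responses.  Canonicalizing on panel order makes the matrix
independent of hybrid input order; the orientation convention is arbitrary
but fixed (reciprocal evaluation shows it is inconsequential).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import DiallelCross, SchemaError
from .preprocess import MetaboliteMatrix

logger = logging.getLogger("hybridmet")

ENCODINGS = ("sum", "difference", "ratio")


@dataclass
class FeatureMatrix:
    """Pair-level predictor matrix.

    ``values``: one row per pair_key, columns ``<analyte>__<encoding>``.
    ``row_expansion``: pair_key -> ordered hybrid ids sharing that row.
    """

    values: pd.DataFrame
    encodings: tuple[str, ...]
    source_stage: str
    row_expansion: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _parent_values(parent_matrix, pid: str) -> np.ndarray:
    df = parent_matrix.values if isinstance(parent_matrix, MetaboliteMatrix) else parent_matrix
    if pid not in df.index:
        raise SchemaError(f"parent {pid!r} missing from parent value table")
    return df.loc[pid].to_numpy(dtype=float)


def encode_pair_features(
    parent_matrix: MetaboliteMatrix | pd.DataFrame,
    cross: DiallelCross,
    encodings: tuple[str, ...] = ("ratio",),
) -> FeatureMatrix:
    """Build the pair-level feature matrix from parental values.

    ``parent_matrix`` is either a stage=mean metabolite matrix (the default
    pipeline input) or a parental trait table; columns become analytes.
    Ratio encoding requires strictly positive second-parent values.
    """
    bad = [e for e in encodings if e not in ENCODINGS]
    if bad:
        raise ValueError(f"unknown encoding(s) {bad}; choose from {ENCODINGS}")
    df = parent_matrix.values if isinstance(parent_matrix, MetaboliteMatrix) else parent_matrix
    stage = parent_matrix.stage if isinstance(parent_matrix, MetaboliteMatrix) else "trait"
    cols = list(df.columns)

    expansion: dict[str, list[str]] = {}
    pair_parents: dict[str, tuple[str, str]] = {}
    for k, (f, m) in enumerate(cross.hybrids):
        key = cross.pair_keys[k]
        expansion.setdefault(key, []).append(cross.hybrid_ids[k])
        if key not in pair_parents:
            a, b = (f, m) if cross.panel.rank(f) < cross.panel.rank(m) else (m, f)
            pair_parents[key] = (a, b)

    rows = {}
    for key, (a, b) in pair_parents.items():
        a1 = _parent_values(parent_matrix, a)
        a2 = _parent_values(parent_matrix, b)
        parts = []
        for enc in encodings:
            if enc == "sum":
                parts.append((a1 + a2) * 0.5)
            elif enc == "difference":
                parts.append(a1 - a2)
            else:
                if np.any(a2 <= 0):
                    j = int(np.argmax(a2 <= 0))
                    raise ZeroDivisionError(
                        f"nonpositive denominator for pair {key!r}, analyte {cols[j]!r}"
                    )
                parts.append(a1 / a2)
        rows[key] = np.concatenate(parts)

    colnames = [f"{c}__{enc}" for enc in encodings for c in cols]
    values = pd.DataFrame.from_dict(rows, orient="index", columns=colnames)
    values.index.name = "pair_key"
    logger.info(
        "encoded %d pairs x %d features (%s on stage=%s)",
        values.shape[0], values.shape[1], "+".join(encodings), stage,
    )
    return FeatureMatrix(values=values, encodings=tuple(encodings), source_stage=stage,
                         row_expansion=expansion)


def expand_to_hybrids(
    features: FeatureMatrix,
    cross: DiallelCross,
    responses: pd.DataFrame,
    mode: str = "duplicate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align pair features with per-hybrid responses.

    mode="duplicate": one design row per ordered hybrid; reciprocals get
    identical predictor rows but keep their own response values.
    mode="average": one row per pair; reciprocal responses are averaged.

    Returns ``(X, Y)`` with matching indexes (hybrid ids or pair keys).
    """
    if mode not in ("duplicate", "average"):
        raise ValueError(f"mode must be 'duplicate' or 'average', got {mode!r}")
    orphans = [k for k in cross.pair_keys if k not in features.values.index]
    if orphans:
        raise SchemaError(f"pair key(s) absent from feature matrix: {sorted(set(orphans))[:5]}")
    missing = [h for h in cross.hybrid_ids if h not in responses.index]
    if missing:
        raise SchemaError(f"hybrid(s) absent from response table: {missing[:5]}")

    if mode == "duplicate":
        X = features.values.loc[cross.pair_keys].set_axis(cross.hybrid_ids, axis=0)
        Y = responses.loc[cross.hybrid_ids]
    else:
        keys = features.values.index
        X = features.values
        grouped = responses.loc[cross.hybrid_ids].copy()
        grouped["pair_key"] = cross.pair_keys
        Y = grouped.groupby("pair_key", sort=False).mean().loc[keys]
    X.index.name = "row_id"
    Y.index.name = "row_id"
    logger.info("expanded to %d design rows (mode=%s) from %d pairs",
                X.shape[0], mode, features.values.shape[0])
    return X, Y
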