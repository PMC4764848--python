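"""GC-MS peak-area preprocessing.

Raw peak areas become analysis-ready parental metabolite levels in three
steps: (1) divide every analyte area by the ribitol internal-standard area
of its own replicate run (*relative levels*), (2) average replicates per
parent on that relative scale, (3) log2-transform for the statistical
analyses (distance, clustering, PCA).  Steps 2 and 3 do not commute
(arithmetic vs geometric mean); the pipeline order is mean-then-log.
Duplicate annotations are disambiguated with ``-1``, ``-2``, ... suffixes
assigned in retention-time order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("hybridmet")

STAGES = ("raw", "relative", "mean", "log2")


class NormalizationError(ValueError):
    pass


@dataclass
class MetaboliteMatrix:
    """Parents-by-analytes matrix with provenance of its normalization stage.

    Before replicate averaging (``stage`` in {"raw", "relative"}) the frame
    has one row per (parent, replicate), carried in a two-level index;
    afterwards one row per parent.  ``internal_standard`` holds the per-
    replicate ribitol areas while they are still relevant.
    """

    values: pd.DataFrame
    stage: str
    internal_standard: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.isna().any().any():
            raise NormalizationError("metabolite matrix contains missing cells")
        names = list(self.values.columns)
        if len(names) != len(set(names)):
            raise ValueError("analyte names are not unique")
        if self.stage in ("relative", "mean") and (self.values.to_numpy() <= 0).any():
            raise NormalizationError(f"stage={self.stage} requires strictly positive values")

    @property
    def analyte_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def parent_ids(self) -> list[str]:
        idx = self.values.index
        if isinstance(idx, pd.MultiIndex):
            return list(dict.fromkeys(idx.get_level_values(0)))
        return list(idx)

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]


def relative_levels(raw: MetaboliteMatrix) -> MetaboliteMatrix:
    """Normalize each replicate's analyte areas by its internal-standard area.

    Scale-equivariant: multiplying all areas of a replicate (analytes and
    ribitol alike) by c > 0 leaves the output unchanged.
    """
    if raw.stage != "raw":
        raise ValueError(f"expected stage='raw', got {raw.stage!r}")
    if raw.internal_standard is None:
        raise NormalizationError("raw matrix lacks internal-standard areas")
    std = raw.internal_standard.reindex(raw.values.index)
    bad = std.index[~(std > 0)].tolist()
    if bad:
        raise NormalizationError(f"nonpositive internal-standard area for replicate(s) {bad[:5]}")
    rel = raw.values.div(std, axis=0)
    logger.info("relative levels: %d replicate rows x %d analytes", *rel.shape)
    return MetaboliteMatrix(values=rel, stage="relative")


def replicate_means(relative: MetaboliteMatrix) -> MetaboliteMatrix:
    """Average replicates per parent on the relative scale (arithmetic mean)."""
    if relative.stage != "relative":
        raise ValueError(f"expected stage='relative', got {relative.stage!r}")
    idx = relative.values.index
    if not isinstance(idx, pd.MultiIndex):
        raise ValueError("replicate averaging needs a (parent, replicate) index")
    mean = relative.values.groupby(level=0, sort=False).mean()
    logger.info("replicate means: %d parents x %d analytes", *mean.shape)
    return MetaboliteMatrix(values=mean, stage="mean")


def log2_transform(mean: MetaboliteMatrix) -> MetaboliteMatrix:
    """Elementwise log2; requires strictly positive input."""
    if mean.stage != "mean":
        raise ValueError(f"expected stage='mean', got {mean.stage!r}")
    arr = mean.values.to_numpy(dtype=float)
    if (arr <= 0).any():
        r, c = np.argwhere(arr <= 0)[0]
        raise NormalizationError(
            f"nonpositive value at parent {mean.values.index[r]!r}, analyte {mean.values.columns[c]!r}"
        )
    out = pd.DataFrame(np.log2(arr), index=mean.values.index, columns=mean.values.columns)
    return MetaboliteMatrix(values=out, stage="log2")


def disambiguate_annotations(
    names: list[str], retention_times: list[float] | None = None
) -> list[str]:
    """Suffix duplicated annotations ``-1``, ``-2``, ... in retention-time order.

    Analytes sharing an annotation (same compound name matched at different
    retention times) are renamed; the earliest-eluting gets ``-1``.  Ties in
    retention time fall back to original column order with a warning.
    Unique annotations pass through unchanged.
    """
    n = len(names)
    if retention_times is not None and len(retention_times) != n:
        raise ValueError("retention_times length mismatch")
    out = list(names)
    groups: dict[str, list[int]] = {}
    for i, nm in enumerate(names):
        groups.setdefault(nm, []).append(i)
    for nm, idxs in groups.items():
        if len(idxs) == 1:
            continue
        if retention_times is None:
            raise ValueError(f"duplicated annotation {nm!r} but no retention times given")
        rts = [retention_times[i] for i in idxs]
        if len(set(rts)) < len(rts):
            warnings.warn(
                f"tied retention times for annotation {nm!r}; breaking tie by column order",
                stacklevel=2,
            )
        order = sorted(idxs, key=lambda i: (retention_times[i], i))
        for rank, i in enumerate(order, start=1):
            out[i] = f"{nm}-{rank}"
    return out


def preprocess_pipeline(raw: MetaboliteMatrix) -> tuple[MetaboliteMatrix, MetaboliteMatrix]:
    """Run the full chain; returns (stage=mean, stage=log2) matrices.

    The mean-stage matrix feeds the pair-feature encodings; the log2 matrix
    feeds distance, clustering and PCA.
    """
    rel = relative_levels(raw)
    mean = replicate_means(rel)
    return mean, log2_transform(mean)
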