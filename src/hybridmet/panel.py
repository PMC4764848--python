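"""Core domain types: parental lines, the diallel cross set, trait tables.

A *complete diallel* crosses every ordered pair of distinct parents, so a
panel of n inbred lines yields n(n-1) hybrids; the two orders of a pair
(reciprocal hybrids) differ only in which parent donated the cytoplasm.
Hybrids are labelled by subgroup: ``i`` (both parents indica), ``j`` (both
japonica) or ``ij`` (inter-subspecific).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("hybridmet")

TRAITS = ("YPP", "MSPH", "HD")

GROUPS = ("indica", "japonica")


class SchemaError(ValueError):
    """An input table violates the documented schema or an invariant."""


@dataclass(frozen=True)
class ParentLine:
    """One parental inbred line.

    Parameters
    ----------
    id : str
        Short unique identifier within a panel.
    group : str
        Subspecies label, ``"indica"`` or ``"japonica"``.
    f_i : float, optional
        Indica-content fraction in [0, 1] (from marker genotyping; an
        input here, never computed).
    origin : str, optional
        Free-text provenance.
    """

    id: str
    group: str
    f_i: float | None = None
    origin: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(f"parent {self.id!r}: group must be one of {GROUPS}, got {self.group!r}")
        if self.f_i is not None and not (0.0 <= self.f_i <= 1.0):
            raise SchemaError(f"parent {self.id!r}: f_i={self.f_i} outside [0, 1]")


class Panel:
    """An ordered collection of :class:`ParentLine` with unique ids."""

    def __init__(self, lines: Iterable[ParentLine]):
        self.lines: list[ParentLine] = list(lines)
        ids = [p.id for p in self.lines]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicated parent id(s): {sorted(dupes)}")
        self._index = {p.id: k for k, p in enumerate(self.lines)}

    def __len__(self) -> int:
        return len(self.lines)

    def __iter__(self):
        return iter(self.lines)

    def __getitem__(self, pid: str) -> ParentLine:
        return self.lines[self._index[pid]]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.lines]

    def rank(self, pid: str) -> int:
        """Position of a parent in panel order (canonicalization key)."""
        return self._index[pid]

    def group_of(self, pid: str) -> str:
        return self[pid].group

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parent_id": self.ids,
                "group": [p.group for p in self.lines],
                "f_i": [p.f_i for p in self.lines],
                "origin": [p.origin for p in self.lines],
            }
        )


def hybrid_id(female: str, male: str) -> str:
    """``FEMALE/MALE`` notation, e.g. ``"YB/Balilla"``."""
    return f"{female}/{male}"


def pair_key(a: str, b: str) -> str:
    """Unordered pair identifier shared by reciprocal hybrids."""
    lo, hi = sorted((a, b))
    return f"{lo}|{hi}"


@dataclass
class DiallelCross:
    """The ordered hybrid set of a diallel mating design.

    Attributes
    ----------
    hybrids : list of (female_id, male_id)
        Ordered crosses, female first.
    subgroup : list of str
        ``"i"``, ``"j"`` or ``"ij"`` per hybrid.
    pair_keys : list of str
        Unordered-pair identifier; reciprocals share one key.
    panel : Panel
        The parental panel (defines canonical parent order).
    """

    hybrids: list[tuple[str, str]]
    subgroup: list[str]
    pair_keys: list[str]
    panel: Panel = field(repr=False)

    def __post_init__(self) -> None:
        for f, m in self.hybrids:
            if f == m:
                raise SchemaError(f"selfed cross {f}/{m} not allowed")

    def __len__(self) -> int:
        return len(self.hybrids)

    @property
    def hybrid_ids(self) -> list[str]:
        return [hybrid_id(f, m) for f, m in self.hybrids]

    @property
    def unique_pair_keys(self) -> list[str]:
        seen: dict[str, None] = {}
        for k in self.pair_keys:
            seen.setdefault(k)
        return list(seen)

    def is_canonical(self, idx: int) -> bool:
        """True when the female is the first parent of the pair in panel order."""
        f, m = self.hybrids[idx]
        return self.panel.rank(f) < self.panel.rank(m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hybrid": self.hybrid_ids,
                "female": [f for f, _ in self.hybrids],
                "male": [m for _, m in self.hybrids],
                "subgroup": self.subgroup,
                "pair_key": self.pair_keys,
            }
        )


def _subgroup_label(ga: str, gb: str) -> str:
    if ga == gb == "indica":
        return "i"
    if ga == gb == "japonica":
        return "j"
    return "ij"


def enumerate_diallel(
    panel: Panel,
    include_selfs: bool = False,
    include_reciprocals: bool = True,
) -> DiallelCross:
    """Enumerate the diallel hybrid set over a parental panel.

    With reciprocals and without selfs (the default, a *complete diallel
    without selfs*) n parents give n(n-1) ordered hybrids.

    Parameters
    ----------
    panel : Panel
        At least two parents.
    include_selfs : bool
        Include P x P crosses (excluded in the default design).
    include_reciprocals : bool
        If False, only the canonical orientation of each pair is kept.
    """
    if len(panel) < 2:
        raise SchemaError("a diallel needs at least 2 parents")
    ids = panel.ids
    hybrids: list[tuple[str, str]] = []
    for f in ids:
        for m in ids:
            if f == m and not include_selfs:
                continue
            if not include_reciprocals and panel.rank(f) > panel.rank(m):
                continue
            hybrids.append((f, m))
    subgroup = [_subgroup_label(panel.group_of(f), panel.group_of(m)) for f, m in hybrids]
    keys = [pair_key(f, m) for f, m in hybrids]
    cross = DiallelCross(hybrids=hybrids, subgroup=subgroup, pair_keys=keys, panel=panel)
    logger.info(
        "enumerated diallel: %d parents -> %d hybrids (selfs=%s, reciprocals=%s)",
        len(panel), len(cross), include_selfs, include_reciprocals,
    )
    return cross


def validate_trait_table(df: pd.DataFrame, name: str = "trait table") -> pd.DataFrame:
    """Check the trait-table contract: finite values, YPP >= 0, MSPH > 0, HD > 0.

    Expects the index to carry line/hybrid ids and columns to include the
    three standard traits.
    """
    missing = [t for t in TRAITS if t not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing trait column(s) {missing}")
    vals = df[list(TRAITS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = df.index[~np.isfinite(vals).all(axis=1)].tolist()
        raise SchemaError(f"{name}: non-finite values in rows {bad[:5]}")
    if (df["YPP"] < 0).any():
        raise SchemaError(f"{name}: negative YPP values")
    if (df["MSPH"] <= 0).any() or (df["HD"] <= 0).any():
        raise SchemaError(f"{name}: MSPH and HD must be positive")
    if df.index.duplicated().any():
        raise SchemaError(f"{name}: duplicated id(s) {df.index[df.index.duplicated()].tolist()}")
    return df
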