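"""Heterosis and combining-ability statistics for a diallel cross.

Relative heterosis compares an F1 hybrid to its two parents:

    LPH = (F1 - P_low)  / P_low      (low-parent heterosis)
    MPH = (F1 - P_mean) / P_mean     (mid-parent heterosis)
    BPH = (F1 - P_high) / P_high     (better-parent heterosis)

For heading date, earlier heading is agronomically favorable, so the
computed values are negated (positive heterosis = earlier heading) when
``hd_sign_flip`` is on.

Combining abilities follow Griffing's decomposition of the hybrid table:
GCA_i = P_i. - P.. (a parent's average deviation, the conventional report
scale), where P_i. averages every hybrid having parent i in either role
and P.. is the grand hybrid mean.  SCA is the residual of the additive
least-squares fit to the no-self diallel,

    SCA_ij = P_ij - P.. - g_i - g_j,   g_i = (n-1)/(n-2) * (P_i. - P..),

whose (n-1)/(n-2) factor corrects for the missing diagonal: with it, on a
complete diallel the GCAs sum to zero and each parent's SCAs sum to zero
exactly, and a purely additive table has all-zero SCA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import (TRAITS, DiallelCross, SchemaError, enumerate_diallel,  # noqa: F401
                    hybrid_id)

logger = logging.getLogger("hybridmet")

HETEROSIS_KINDS = ("LPH", "MPH", "BPH")


@dataclass
class HeterosisTable:
    """Per-hybrid heterosis/SCA and per-parent GCA values.

    ``hybrid_values`` is indexed by hybrid id with columns
    ``<KIND>-<trait>`` (e.g. ``"MPH-YPP"``, ``"SCA-HD"``); ``gca`` is
    indexed by parent id with one column per trait.
    """

    hybrid_values: pd.DataFrame
    gca: pd.DataFrame

    def response(self, name: str) -> pd.Series:
        """One response column, e.g. ``"LPH-YPP"`` or ``"SCA-MSPH"``."""
        return self.hybrid_values[name]


def relative_heterosis(
    hybrid_traits: pd.DataFrame,
    parent_traits: pd.DataFrame,
    cross: DiallelCross,
    hd_sign_flip: bool = True,
) -> pd.DataFrame:
    """LPH/MPH/BPH per hybrid and trait; columns ``<KIND>-<trait>``."""
    rows = []
    for k, (f, m) in enumerate(cross.hybrids):
        hid = hybrid_id(f, m)
        if hid not in hybrid_traits.index:
            raise SchemaError(f"hybrid {hid!r} missing from hybrid trait table")
        for p in (f, m):
            if p not in parent_traits.index:
                raise SchemaError(f"parent {p!r} missing from parent trait table")
        rec: dict[str, float] = {"hybrid": hid}
        for trait in TRAITS:
            f1 = float(hybrid_traits.at[hid, trait])
            pa = float(parent_traits.at[f, trait])
            pb = float(parent_traits.at[m, trait])
            if pa <= 0 or pb <= 0 or (pa + pb) == 0:
                raise ZeroDivisionError(f"nonpositive parental {trait} for hybrid {hid!r}")
            p_low, p_high = min(pa, pb), max(pa, pb)
            p_mean = 0.5 * (pa + pb)
            lph = (f1 - p_low) / p_low
            mph = (f1 - p_mean) / p_mean
            bph = (f1 - p_high) / p_high
            if hd_sign_flip and trait == "HD":
                lph, mph, bph = -lph, -mph, -bph
            rec[f"LPH-{trait}"] = lph
            rec[f"MPH-{trait}"] = mph
            rec[f"BPH-{trait}"] = bph
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("hybrid")
    return out


def combining_ability(
    hybrid_traits: pd.DataFrame,
    cross: DiallelCross,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GCA per parent and SCA per ordered hybrid, per trait.

    Returns ``(sca, gca)``: sca indexed by hybrid id with columns
    ``SCA-<trait>``, gca indexed by parent id with trait columns.
    P_i. averages hybrids with parent i as female or male.
    """
    parents = cross.panel.ids
    n = len(parents)
    expected = n * (n - 1)
    if len(cross) != expected:
        warnings.warn(
            f"incomplete diallel ({len(cross)} of {expected} ordered hybrids); "
            "combining abilities computed from available cells",
            stacklevel=2,
        )
    hids = cross.hybrid_ids
    missing = [h for h in hids if h not in hybrid_traits.index]
    if missing:
        raise SchemaError(f"hybrid(s) missing from trait table: {missing[:5]}")

    gca = pd.DataFrame(index=pd.Index(parents, name="parent_id"), columns=list(TRAITS), dtype=float)
    sca = pd.DataFrame(index=pd.Index(hids, name="hybrid"), dtype=float)
    membership = {p: [] for p in parents}
    for k, (f, m) in enumerate(cross.hybrids):
        membership[f].append(k)
        membership[m].append(k)
    for p, ks in membership.items():
        if not ks:
            raise SchemaError(f"parent {p!r} appears in no hybrid")

    # least-squares effects for the diallel without selfs; the factor
    # corrects for the absent diagonal so per-parent SCA sums vanish
    factor = (n - 1) / (n - 2) if n > 2 else 1.0
    for trait in TRAITS:
        vals = hybrid_traits.loc[hids, trait].to_numpy(dtype=float)
        grand = vals.mean()
        p_dot = {p: vals[ks].mean() for p, ks in membership.items()}
        gca[trait] = [p_dot[p] - grand for p in parents]
        g_eff = {p: factor * (p_dot[p] - grand) for p in parents}
        sca[f"SCA-{trait}"] = [
            vals[k] - grand - g_eff[f] - g_eff[m] for k, (f, m) in enumerate(cross.hybrids)
        ]
    logger.info("combining ability: %d parents, %d hybrids, traits %s", n, len(cross), list(TRAITS))
    return sca, gca


def heterosis_table(
    hybrid_traits: pd.DataFrame,
    parent_traits: pd.DataFrame,
    cross: DiallelCross,
    hd_sign_flip: bool = True,
) -> HeterosisTable:
    """All per-hybrid responses: trait per se, LPH/MPH/BPH, and SCA.

    The returned ``hybrid_values`` holds 15 response columns for the three
    standard traits: ``<trait>`` (F1 value per se), ``LPH-<trait>``,
    ``MPH-<trait>``, ``BPH-<trait>`` and ``SCA-<trait>``.
    """
    het = relative_heterosis(hybrid_traits, parent_traits, cross, hd_sign_flip=hd_sign_flip)
    sca, gca = combining_ability(hybrid_traits, cross)
    perse = hybrid_traits.loc[cross.hybrid_ids, list(TRAITS)]
    values = pd.concat([perse, het, sca], axis=1)
    return HeterosisTable(hybrid_values=values, gca=gca)


def response_names() -> list[str]:
    """The 15 standard response columns in reporting order."""
    names = list(TRAITS)
    for kind in ("LPH", "MPH", "BPH", "SCA"):
        names += [f"{kind}-{t}" for t in TRAITS]
    return names
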