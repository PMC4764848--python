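"""Diallel enumeration, heterosis formulas, combining abilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridmet import (
    Panel,
    ParentLine,
    SchemaError,
    combining_ability,
    enumerate_diallel,
    relative_heterosis,
)
from hybridmet.panel import TRAITS


def make_panel(n_ind, n_jap):
    lines = [ParentLine(f"I{i}", "indica") for i in range(n_ind)]
    lines += [ParentLine(f"J{i}", "japonica") for i in range(n_jap)]
    return Panel(lines)


def trait_frame(ids, value_map):
    """All three trait columns share the same per-id value."""
    return pd.DataFrame({t: [value_map[i] for i in ids] for t in TRAITS},
                        index=pd.Index(ids, name="id"))


class TestEnumeration:
    def test_complete_diallel_counts(self):
        cross = enumerate_diallel(make_panel(9, 9))
        assert len(cross) == 306
        counts = pd.Series(cross.subgroup).value_counts()
        assert counts["i"] == 72 and counts["j"] == 72 and counts["ij"] == 162
        # every hybrid's reciprocal is present under the same pair key
        seen = dict(zip(cross.hybrids, cross.pair_keys))
        for (f, m), key in seen.items():
            assert seen[(m, f)] == key
        assert len(set(cross.pair_keys)) == 153

    def test_three_parents(self):
        assert len(enumerate_diallel(make_panel(2, 1))) == 6

    def test_too_few_parents(self):
        with pytest.raises(SchemaError):
            enumerate_diallel(make_panel(1, 0))

    def test_no_reciprocals_halves_the_set(self):
        cross = enumerate_diallel(make_panel(2, 2), include_reciprocals=False)
        assert len(cross) == 6


class TestRelativeHeterosis:
    @pytest.fixture
    def pair_setup(self):
        panel = make_panel(2, 0)
        cross = enumerate_diallel(panel)
        return panel, cross

    def test_printed_formulas(self, pair_setup):
        _, cross = pair_setup
        parents = trait_frame(["I0", "I1"], {"I0": 8.0, "I1": 10.0})
        hybrids = trait_frame(cross.hybrid_ids, dict.fromkeys(cross.hybrid_ids, 9.0))
        het = relative_heterosis(hybrids, parents, cross, hd_sign_flip=False)
        row = het.loc["I0/I1"]
        assert row["LPH-YPP"] == pytest.approx(0.125)
        assert row["MPH-YPP"] == pytest.approx(0.0)
        assert row["BPH-YPP"] == pytest.approx(-0.1)

    def test_no_heterosis_when_equal(self, pair_setup):
        _, cross = pair_setup
        parents = trait_frame(["I0", "I1"], {"I0": 9.0, "I1": 9.0})
        hybrids = trait_frame(cross.hybrid_ids, dict.fromkeys(cross.hybrid_ids, 9.0))
        het = relative_heterosis(hybrids, parents, cross, hd_sign_flip=False)
        assert np.allclose(het.to_numpy(), 0.0)

    def test_hd_sign_flip(self, pair_setup):
        """Earlier heading counts as positive heterosis for HD only."""
        _, cross = pair_setup
        parents = trait_frame(["I0", "I1"], {"I0": 85.0, "I1": 95.0})
        hybrids = trait_frame(cross.hybrid_ids, dict.fromkeys(cross.hybrid_ids, 80.0))
        het = relative_heterosis(hybrids, parents, cross, hd_sign_flip=True)
        assert het.loc["I0/I1", "MPH-HD"] == pytest.approx(1.0 / 9.0)
        assert het.loc["I0/I1", "MPH-YPP"] == pytest.approx(-1.0 / 9.0)

    @settings(deadline=None, max_examples=40)
    @given(f1=st.floats(1.0, 100.0), pa=st.floats(1.0, 100.0), pb=st.floats(1.0, 100.0))
    def test_mph_between_lph_and_bph(self, f1, pa, pb):
        panel = make_panel(2, 0)
        cross = enumerate_diallel(panel)
        parents = trait_frame(["I0", "I1"], {"I0": pa, "I1": pb})
        hybrids = trait_frame(cross.hybrid_ids, dict.fromkeys(cross.hybrid_ids, f1))
        het = relative_heterosis(hybrids, parents, cross, hd_sign_flip=False)
        lph, mph, bph = (het.loc["I0/I1", f"{k}-YPP"] for k in ("LPH", "MPH", "BPH"))
        assert bph - 1e-12 <= mph <= lph + 1e-12


class TestCombiningAbility:
    def test_constant_table_gives_zero(self):
        cross = enumerate_diallel(make_panel(4, 0))
        hybrids = trait_frame(cross.hybrid_ids, dict.fromkeys(cross.hybrid_ids, 7.0))
        sca, gca = combining_ability(hybrids, cross)
        assert np.allclose(gca.to_numpy(), 0.0)
        assert np.allclose(sca.to_numpy(), 0.0)

    def test_additive_table_has_zero_sca(self):
        """P_ij = g_i + g_j leaves no cross-specific deviation."""
        g = {"I0": 1.0, "I1": 2.0, "I2": 3.0, "I3": 4.0}
        cross = enumerate_diallel(make_panel(4, 0))
        vals = {h: g[f] + g[m] for h, (f, m) in zip(cross.hybrid_ids, cross.hybrids)}
        sca, gca = combining_ability(trait_frame(cross.hybrid_ids, vals), cross)
        assert np.allclose(sca.to_numpy(), 0.0, atol=1e-12)

    def test_three_parent_hand_computation(self):
        """P..=20, P_1.=15, P_2.=20, P_3.=25 -> GCA = (-5, 0, +5)."""
        cross = enumerate_diallel(make_panel(3, 0))
        val = {"I0|I1": 10.0, "I0|I2": 20.0, "I1|I2": 30.0}
        vals = {h: val[k] for h, k in zip(cross.hybrid_ids, cross.pair_keys)}
        _, gca = combining_ability(trait_frame(cross.hybrid_ids, vals), cross)
        np.testing.assert_allclose(gca["YPP"].to_numpy(), [-5.0, 0.0, 5.0])

    @settings(deadline=None, max_examples=25)
    @given(n=st.integers(3, 7), seed=st.integers(0, 10_000))
    def test_zero_sum_invariants(self, n, seed):
        """Sum GCA = 0; per-parent sum of SCA = 0 on complete diallels."""
        rng = np.random.default_rng(seed)
        cross = enumerate_diallel(make_panel(n, 0))
        vals = dict(zip(cross.hybrid_ids, rng.uniform(1, 100, size=len(cross))))
        sca, gca = combining_ability(trait_frame(cross.hybrid_ids, vals), cross)
        scale = np.abs(gca["YPP"]).max() + 1.0
        assert abs(gca["YPP"].sum()) / scale < 1e-10
        df = sca.copy()
        df["f"] = [f for f, _ in cross.hybrids]
        df["m"] = [m for _, m in cross.hybrids]
        for p in cross.panel.ids:
            total = df.loc[(df["f"] == p) | (df["m"] == p), "SCA-YPP"].sum()
            assert abs(total) / scale < 1e-10

    def test_reciprocal_symmetric_table_gives_symmetric_sca(self):
        rng = np.random.default_rng(5)
        cross = enumerate_diallel(make_panel(4, 0))
        by_key = {k: rng.uniform(10, 50) for k in set(cross.pair_keys)}
        vals = {h: by_key[k] for h, k in zip(cross.hybrid_ids, cross.pair_keys)}
        sca, _ = combining_ability(trait_frame(cross.hybrid_ids, vals), cross)
        for (f, m) in cross.hybrids:
            assert sca.loc[f"{f}/{m}", "SCA-YPP"] == pytest.approx(
                sca.loc[f"{m}/{f}", "SCA-YPP"], abs=1e-12)

    def test_incomplete_diallel_warns(self):
        cross = enumerate_diallel(make_panel(3, 0))
        cross.hybrids, cross.subgroup, cross.pair_keys = (
            cross.hybrids[:-1], cross.subgroup[:-1], cross.pair_keys[:-1])
        vals = dict.fromkeys([f"{f}/{m}" for f, m in cross.hybrids], 5.0)
        with pytest.warns(UserWarning, match="incomplete"):
            combining_ability(trait_frame(list(vals), vals), cross)
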