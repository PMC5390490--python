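"""Grassi-Magnani-style decomposition: weights, identities, accuracy."""

import numpy as np
import pytest

from photolim import (
    ReferenceState,
    for_species,
    forward_gross_assimilation,
    limitation_weights,
    partition_limitations,
    partition_limitations_c4,
)
from photolim.limitations import bootstrap_partition


@pytest.fixture
def consts():
    return for_species("rice")


def ref_state(consts, gs=0.25, gm=0.25, vcmax=80.0, ca=400.0):
    ag, c = forward_gross_assimilation(gs, gm, vcmax, ca, consts)
    return ReferenceState(AG=ag, gs_co2=gs, gm=gm, Vcmax=vcmax, C=c)


class TestWeights:
    def test_weights_sum_to_one(self, consts):
        w = limitation_weights(ref_state(consts), consts)
        assert w.l_s + w.l_mc + w.l_b == pytest.approx(1.0, abs=1e-12)
        assert all(0 <= v <= 1 for v in (w.l_s, w.l_mc, w.l_b))

    def test_equal_conductances_share_equally(self, consts):
        w = limitation_weights(ref_state(consts, gs=0.2, gm=0.2), consts)
        assert w.l_s == pytest.approx(w.l_mc, rel=1e-12)

    def test_substitution_example(self, consts):
        # gs = gm = 0.25, dAdC forced to 0.25 via Vcmax choice is awkward;
        # check the algebra directly instead: g_tot = 0.125 and equal
        # slope means l_b = g_tot/(g_tot+dAdC)
        ref = ReferenceState(AG=20.0, gs_co2=0.25, gm=0.25, Vcmax=80.0, C=250.0)
        w = limitation_weights(ref, consts)
        assert w.g_tot == pytest.approx(0.125, rel=1e-12)
        expected_lb = w.g_tot / (w.g_tot + w.dAdC)
        assert w.l_b == pytest.approx(expected_lb, rel=1e-12)

    def test_flat_demand_curve_puts_all_weight_on_biochemistry(self, consts):
        ref = ReferenceState(AG=20.0, gs_co2=0.25, gm=0.25, Vcmax=1e-6, C=250.0)
        w = limitation_weights(ref, consts)
        assert w.l_b == pytest.approx(1.0, abs=1e-6)


class TestPartition:
    def test_unstressed_leaf_has_no_limitation(self, consts):
        ref = ref_state(consts)
        w = limitation_weights(ref, consts)
        res = partition_limitations(ref, ref, w)
        assert res.SL == res.MCL == res.BL == 0.0

    def test_single_factor_stomatal_closure(self, consts):
        ref = ref_state(consts)
        w = limitation_weights(ref, consts)
        stressed = ReferenceState(
            AG=ref.AG * 0.9, gs_co2=ref.gs_co2 / 2, gm=ref.gm,
            Vcmax=ref.Vcmax, C=ref.C,
        )
        res = partition_limitations(ref, stressed, w)
        assert res.MCL == 0.0 and res.BL == 0.0
        assert res.SL == pytest.approx(w.l_s * np.log(2.0), rel=1e-12)

    def test_dl_is_sl_plus_mcl_always(self, consts):
        rng = np.random.default_rng(2)
        ref = ref_state(consts)
        w = limitation_weights(ref, consts)
        for _ in range(50):
            f = rng.uniform(0.4, 1.0, size=3)
            ag, c = forward_gross_assimilation(
                ref.gs_co2 * f[0], ref.gm * f[1], ref.Vcmax * f[2], 400.0, consts
            )
            stressed = ReferenceState(
                AG=ag, gs_co2=ref.gs_co2 * f[0], gm=ref.gm * f[1],
                Vcmax=ref.Vcmax * f[2], C=c,
            )
            res = partition_limitations(ref, stressed, w)
            assert res.DL == res.SL + res.MCL  # exact by construction
            assert res.SL >= 0 and res.MCL >= 0 and res.BL >= 0

    @pytest.mark.parametrize("factor", ["gs", "gm", "vcmax"])
    def test_first_order_accuracy_single_factor(self, consts, factor):
        """For a 10% single-factor perturbation the predicted components
        match the forward model's relative AG decline within 3%."""
        ref = ref_state(consts)
        w = limitation_weights(ref, consts)
        mult = {"gs": 1.0, "gm": 1.0, "vcmax": 1.0}
        mult[factor] = 0.9
        ag, c = forward_gross_assimilation(
            ref.gs_co2 * mult["gs"], ref.gm * mult["gm"],
            ref.Vcmax * mult["vcmax"], 400.0, consts,
        )
        stressed = ReferenceState(
            AG=ag, gs_co2=ref.gs_co2 * mult["gs"], gm=ref.gm * mult["gm"],
            Vcmax=ref.Vcmax * mult["vcmax"], C=c,
        )
        w_str = limitation_weights(stressed, consts)
        res = partition_limitations(ref, stressed, w, stressed_weights=w_str)
        # decline measured on the decomposition's own (log) scale
        actual = np.log(ref.AG / ag)
        assert res.total == pytest.approx(actual, rel=0.03)
        # midpoint weights still form an exact partition of unity
        half = 0.5
        assert (
            half * (w.l_s + w_str.l_s)
            + half * (w.l_mc + w_str.l_mc)
            + half * (w.l_b + w_str.l_b)
        ) == pytest.approx(1.0, abs=1e-12)

    def test_combined_stress_within_10_percent(self, consts):
        """gs -30%, gm -20%, Vcmax -40% predicted vs forward decline."""
        ref = ref_state(consts)
        w = limitation_weights(ref, consts)
        ag, c = forward_gross_assimilation(
            ref.gs_co2 * 0.7, ref.gm * 0.8, ref.Vcmax * 0.6, 400.0, consts
        )
        stressed = ReferenceState(
            AG=ag, gs_co2=ref.gs_co2 * 0.7, gm=ref.gm * 0.8,
            Vcmax=ref.Vcmax * 0.6, C=c,
        )
        w_str = limitation_weights(stressed, consts)
        res = partition_limitations(ref, stressed, w, stressed_weights=w_str)
        actual_log_decline = np.log(ref.AG / ag)
        assert res.total == pytest.approx(actual_log_decline, rel=0.10)

    def test_improved_driver_clipped_with_warning(self, consts):
        ref = ref_state(consts)
        w = limitation_weights(ref, consts)
        stressed = ReferenceState(
            AG=ref.AG, gs_co2=ref.gs_co2 * 1.2, gm=ref.gm,
            Vcmax=ref.Vcmax * 0.8, C=ref.C,
        )
        with pytest.warns(UserWarning, match="negative stomatal"):
            res = partition_limitations(ref, stressed, w)
        assert res.SL == 0.0
        assert res.BL > 0


class TestC4Partition:
    def test_identity_and_single_factor(self):
        consts = for_species("maize")
        # bundle-sheath operating point: high Cs flattens the slope
        ref = ReferenceState(AG=22.0, gs_co2=0.12, gm=consts.gm_c4,
                             Vcmax=28.0, C=5000.0)
        w = limitation_weights(ref, consts)
        same = partition_limitations_c4(ref, ref, w)
        assert same.SL == same.MCL == same.BL == 0.0
        stressed = ReferenceState(AG=15.0, gs_co2=0.12, gm=consts.gm_c4,
                                  Vcmax=28.0 * 0.6, C=5000.0)
        res = partition_limitations_c4(ref, stressed, w)
        assert res.DL == 0.0
        assert res.BL == pytest.approx(w.l_b * np.log(1 / 0.6), rel=1e-12)
        # CO2-saturated bundle sheath: biochemistry dominates the weights
        assert w.l_b > 0.9


def test_bootstrap_partition_reports_uncertainty(consts, rng):
    import pandas as pd

    ref = ref_state(consts)
    def reps(state, f, n=5):
        rows = []
        for _ in range(n):
            e = rng.lognormal(0, 0.05, size=4)
            gs, gm, vc = state.gs_co2 * f[0] * e[0], state.gm * f[1] * e[1], \
                state.Vcmax * f[2] * e[2]
            ag, c = forward_gross_assimilation(gs, gm, vc, 400.0, consts)
            rows.append({"AG": ag, "gs_co2": gs, "gm": gm, "Vcmax": vc, "C": c})
        return pd.DataFrame(rows)

    out = bootstrap_partition(
        reps(ref, (1, 1, 1)), reps(ref, (0.5, 0.8, 0.7)), consts,
        n_boot=200, rng=rng,
    )
    res = out["result"]
    assert res.SL > 0 and res.BL > 0
    assert out["SL_se"] > 0 and out["BL_se"] > 0
    assert out["n_boot_ok"] == 200
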