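"""Synthetic factorial experiments: determinism, invariants, recovery."""

import numpy as np
import pandas as pd
import pytest

from photolim import (
    Species,
    ValidationError,
    default_study_config,
    for_species,
    generate_experiment,
)
from photolim.c3 import RD_FRACTION, variable_j_result
from photolim.c4 import estimate_cs
from photolim.fluorescence import electron_transport, phi_psii


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = default_study_config()
        a = generate_experiment(cfg, seed=9)
        b = generate_experiment(cfg, seed=9)
        assert a.leaf_records == b.leaf_records
        assert a.biochem_records == b.biochem_records
        assert a.aci_curves == b.aci_curves
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)

    def test_different_seed_differs(self):
        cfg = default_study_config()
        a = generate_experiment(cfg, seed=9)
        b = generate_experiment(cfg, seed=10)
        assert a.leaf_records != b.leaf_records


class TestDesignInvariants:
    def test_wd_reduces_gs_by_at_least_40_percent(self, default_experiment):
        gt = default_experiment.ground_truth
        means = gt.groupby(["species", "treatment"])["gs"].mean()
        for sp in ("rice", "wheat", "maize"):
            assert means[sp, "WD"] <= 0.60 * means[sp, "control"]
            assert means[sp, "HT-WD"] <= 0.60 * means[sp, "HT"]

    def test_weak_wd_config_rejected(self):
        cfg = default_study_config()
        bad_mult = {
            k: dict(v) for k, v in cfg.multipliers.items()
        }
        bad_mult["WD"] = dict(bad_mult["WD"])
        bad_mult["WD"]["gs"] = {sp: 0.8 for sp in cfg.baselines}
        with pytest.raises(ValidationError, match="stomatal-closure"):
            type(cfg)(
                baselines=cfg.baselines, multipliers=bad_mult,
                cv=dict(cfg.cv), replicates=cfg.replicates,
            )

    def test_factorial_structure_complete(self, default_experiment):
        gt = default_experiment.ground_truth
        counts = gt.groupby(["species", "treatment"]).size()
        assert len(counts) == 12
        assert (counts == 5).all()

    def test_ht_depresses_activation_state(self, default_experiment):
        """HT halves the activation-state mean; at n=5 and 5% CV the
        sample means sit well within 3 sigma of that."""
        gt = default_experiment.ground_truth
        means = gt.groupby(["species", "treatment"])["activation_state"].mean()
        for sp in ("rice", "wheat", "maize"):
            ratio = means[sp, "HT"] / means[sp, "control"]
            se = 0.05 * np.sqrt(2.0 / 5.0)  # CV of a ratio of two n=5 means
            assert ratio == pytest.approx(0.5, abs=3 * se * 0.5 + 0.02)

    def test_control_means_match_printed_values(self):
        cfg = default_study_config()
        assert cfg.baselines[Species.RICE].rubisco_amount == 0.49
        assert cfg.baselines[Species.WHEAT].rubisco_amount == 0.34
        assert cfg.baselines[Species.MAIZE].rubisco_amount == 0.15
        assert cfg.baselines[Species.MAIZE].total_activity == 0.13
        assert cfg.baselines[Species.RICE].activation_state == (
            pytest.approx(0.31 / 0.36)
        )


class TestSelfConsistency:
    def test_noiseless_recovery_to_numerical_precision(self, noiseless_experiment):
        """With zero noise the inverse pipeline reproduces the generating
        gm (C3) and Cs (maize) from the emitted observables."""
        gt = noiseless_experiment.ground_truth.set_index(
            ["species", "treatment", "replicate_id"]
        )
        for rec in noiseless_experiment.leaf_records:
            key = (rec.treatment.species.value, rec.treatment.label,
                   rec.replicate_id)
            truth = gt.loc[key]
            consts = for_species(rec.treatment.species)
            j = electron_transport(
                phi_psii(rec.Fs, rec.Fm_prime), rec.PPFD, rec.alpha, rec.beta
            )
            assert j == pytest.approx(truth["J"], rel=1e-9)
            if rec.treatment.is_c4:
                res = estimate_cs(rec.AN, rec.Ci, rec.Rdark, consts)
                assert res.Cs == pytest.approx(truth["Cs"], rel=1e-6)
            else:
                res = variable_j_result(rec.AN, rec.Ci, rec.Rdark, j, consts)
                assert res.feasible
                assert res.gm == pytest.approx(truth["gm"], rel=1e-6)
                assert res.Cc == pytest.approx(truth["Cc"], rel=1e-6)

    def test_noisy_recovery_tracks_cv(self, default_experiment):
        """With multiplicative noise the recovered gm still matches the
        per-replicate truth (inversion is exact per leaf)."""
        gt = default_experiment.ground_truth.set_index(
            ["species", "treatment", "replicate_id"]
        )
        consts = for_species("rice")
        c3 = [r for r in default_experiment.leaf_records
              if r.treatment.species is Species.RICE]
        for rec in c3:
            truth = gt.loc[("rice", rec.treatment.label, rec.replicate_id)]
            j = electron_transport(
                phi_psii(rec.Fs, rec.Fm_prime), rec.PPFD, rec.alpha, rec.beta
            )
            res = variable_j_result(rec.AN, rec.Ci, rec.Rdark, j, consts)
            assert res.gm == pytest.approx(truth["gm"], rel=1e-6)

    def test_biochem_consistent_with_gas_exchange_vcmax(self, default_experiment):
        """The generated biochemistry reproduces the Vcmax that drove the
        leaf's gas exchange."""
        from photolim.biochem import (
            VcmaxInput, activation_state, rubisco_area_density,
            vcmax_biochemical,
        )
        gt = default_experiment.ground_truth
        bio = {(b.treatment.species.value, b.treatment.label, b.replicate_id): b
               for b in default_experiment.biochem_records}
        for _, row in gt.iterrows():
            b = bio[(row["species"], row["treatment"], row["replicate_id"])]
            consts = for_species(row["species"])
            act = activation_state(b.initial_activity, b.total_activity)
            vc = vcmax_biochemical(
                VcmaxInput(
                    rubisco_area_density(b.rubisco_amount, row["tsp_per_area"]),
                    act, consts.kcat,
                )
            )
            assert vc == pytest.approx(row["Vcmax"], rel=1e-9)
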