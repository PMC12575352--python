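import numpy as np
import pytest

import opbpk


class TestBuildModel:
    def test_per_kg_dose_resolution(self, rat_bhtf_model):
        assert rat_bhtf_model.regimen.amount_ug == pytest.approx(1.75)

    def test_absolute_dose_in_internal_units(self, human_fentanyl_model):
        assert human_fentanyl_model.dose_pg == pytest.approx(1e8)

    def test_missing_tissue_rejected(self, human_phys, fentanyl_human, kp_human_qsar):
        broken = dict(kp_human_qsar.kp)
        broken.pop("skin")
        with pytest.raises(opbpk.IncompleteKpSetError):
            opbpk.KpSet("fentanyl", "human", "table", broken)

    def test_species_mismatch_rejected(self, rat_phys, fentanyl_human, kp_human_qsar):
        with pytest.raises(opbpk.SpeciesMismatchError):
            opbpk.build_model(
                rat_phys, fentanyl_human, kp_human_qsar, opbpk.DoseRegimen(amount_ug=1.0)
            )

    def test_dose_validation(self):
        with pytest.raises(opbpk.DomainError):
            opbpk.DoseRegimen(amount_ug=-1.0)
        with pytest.raises(opbpk.DomainError):
            opbpk.DoseRegimen(route="iv_infusion", amount_ug=1.0, infusion_duration_h=0.0)


class TestConservationAndEquilibrium:
    def test_mass_conserved_without_clearance(
        self, human_phys, make_compound, uniform_kp
    ):
        c = make_compound(clsys=0.0, rbp=1.0)
        m = opbpk.build_model(
            human_phys, c, uniform_kp(3.0), opbpk.DoseRegimen(amount_ug=100.0)
        )
        sim = opbpk.simulate(m, 24.0, 241)
        total = sim.total_amount_pg()
        # after the input is complete, everything stays in the body
        after = sim.time_h > sim.metadata["input_duration_h"]
        assert np.all(np.abs(total[after] - sim.dose_pg) / sim.dose_pg < 1e-3)
        assert sim.metadata["mass_balance_error"] < 1e-3

    def test_tissues_reach_partition_equilibrium(
        self, human_phys, make_compound, kp_human_qsar
    ):
        c = make_compound(clsys=0.0, fup=0.255, rbp=1.01, name="fentanyl")
        m = opbpk.build_model(
            human_phys, c, kp_human_qsar, opbpk.DoseRegimen(amount_ug=100.0)
        )
        sim = opbpk.simulate(m, 400.0, 401)
        c_blood = sim.conc["venous_blood"][-1]
        for t in opbpk.TISSUES:
            ratio = sim.conc[t][-1] / c_blood
            assert ratio == pytest.approx(kp_human_qsar[t], rel=5e-3), t

    def test_eliminated_plus_remaining_equals_dose(self, human_fentanyl_sim):
        sim = human_fentanyl_sim
        assert sim.metadata["mass_balance_error"] < 1e-3


class TestExposureIdentities:
    def test_auc_equals_dose_over_clearance(self, human_fentanyl_sim):
        res = opbpk.nca_iv(
            opbpk.ConcProfile(human_fentanyl_sim.time_h, human_fentanyl_sim.plasma),
            dose_ug=100.0,
        )
        expected = 1e8 / (62.66 * 1000)  # pg·h/mL
        assert res.auc_0_inf == pytest.approx(expected, rel=0.01)

    def test_dose_linearity_exact(self, human_phys, fentanyl_human, kp_human_qsar):
        sims = []
        for dose in (100.0, 200.0):
            m = opbpk.build_model(
                human_phys, fentanyl_human, kp_human_qsar,
                opbpk.DoseRegimen(amount_ug=dose),
            )
            sims.append(opbpk.simulate(m, 12.0, 121))
        a, b = sims
        mask = a.plasma > a.plasma.max() * 1e-9
        assert np.allclose(b.plasma[mask] / a.plasma[mask], 2.0, rtol=1e-6)

    def test_nca_vss_matches_algebraic(
        self, human_fentanyl_sim, kp_human_qsar, human_phys, fentanyl_human
    ):
        res = opbpk.nca_iv(
            opbpk.ConcProfile(human_fentanyl_sim.time_h, human_fentanyl_sim.plasma),
            dose_ug=100.0,
        )
        v_alg = opbpk.vss_algebraic(kp_human_qsar, human_phys, fentanyl_human.rbp)
        assert res.vss_L == pytest.approx(v_alg, rel=0.02)

    def test_terminal_decline_grid_invariant(self, human_fentanyl_model):
        halves = []
        for n in (721, 1441):
            sim = opbpk.simulate(human_fentanyl_model, 72.0, n)
            res = opbpk.nca_iv(opbpk.ConcProfile(sim.time_h, sim.plasma), 100.0)
            halves.append(res.t_half_h)
        assert halves[0] == pytest.approx(halves[1], rel=0.01)


class TestVssAlgebraic:
    def test_unit_kp_gives_total_volume(self, human_phys, uniform_kp):
        v = opbpk.vss_algebraic(uniform_kp(1.0), human_phys, 1.0)
        assert v == pytest.approx(human_phys.total_volume_L, rel=1e-12)

    def test_linearity_in_kp(self, human_phys, uniform_kp):
        v1 = opbpk.vss_algebraic(uniform_kp(1.0), human_phys, 1.0)
        v2 = opbpk.vss_algebraic(uniform_kp(2.0), human_phys, 1.0)
        blood = human_phys.blood_volume_L
        assert v2 - blood == pytest.approx(2 * (v1 - blood), rel=1e-12)


class TestOneCompartmentLimit:
    def test_matches_closed_form_after_distribution_transient(
        self, human_phys, make_compound, uniform_kp
    ):
        """With all Kp = 1 and rbp = 1 the body is one well-mixed volume.

        The closed form holds when elimination is slow against every
        tissue's perfusion turnover (the instantaneous-mixing regime), so
        the test clearance keeps CL/V well below min_i Q_i/(V_i Kp_i).
        """
        cl = 1.0
        c = make_compound(clsys=cl, rbp=1.0)
        m = opbpk.build_model(
            human_phys, c, uniform_kp(1.0), opbpk.DoseRegimen(amount_ug=100.0)
        )
        sim = opbpk.simulate(m, 24.0, 241)
        v = human_phys.total_volume_L
        pred = (1e8 / (v * 1000)) * np.exp(-cl * sim.time_h / v)
        late = sim.time_h > 2.0
        assert np.allclose(sim.plasma[late], pred[late], rtol=0.02)


class TestHepaticClearanceMode:
    def test_hepatic_site_also_eliminates_the_dose(
        self, human_phys, fentanyl_human, kp_human_qsar
    ):
        m = opbpk.build_model(
            human_phys, fentanyl_human, kp_human_qsar,
            opbpk.DoseRegimen(amount_ug=100.0), clearance_site="hepatic",
        )
        sim = opbpk.simulate(m, 72.0, 721)
        assert sim.metadata["mass_balance_error"] < 1e-3
        assert sim.eliminated_pg[-1] > 0.9 * sim.dose_pg

    def test_extraction_is_flow_capped(self, human_phys, make_compound, uniform_kp):
        # intrinsic clearance far above liver flow must not break the model
        c = make_compound(clsys=500.0, rbp=1.0)
        m = opbpk.build_model(
            human_phys, c, uniform_kp(1.0), opbpk.DoseRegimen(amount_ug=10.0),
            clearance_site="hepatic",
        )
        sim = opbpk.simulate(m, 6.0, 121)
        assert np.all(sim.plasma >= 0)


def test_profile_roundtrip_via_long_csv(tmp_path, human_fentanyl_model):
    sim = opbpk.simulate(human_fentanyl_model, 6.0, 61)
    path = tmp_path / "profile.csv"
    sim.to_frame().to_csv(path, index=False)
    prof = opbpk.read_profile_csv(path, "plasma")
    assert np.allclose(prof.conc_pg_per_mL, sim.plasma)
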