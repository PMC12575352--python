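import numpy as np
import pytest

import opbpk

ACETYLFENTANYL_ROW = {  # printed analog-table values used as test inputs
    "clsys_L_per_h": 62.66,
    "vss_L": 250.140,
    "t_half_h": 2.766,
    "auc_0_t": 1567.0,
    "auc_0_inf": 1595.9,
}


@pytest.fixture(scope="session")
def human_phys():
    return opbpk.get_physiology("human", 70.0)


@pytest.fixture(scope="session")
def rat_phys():
    return opbpk.get_physiology("rat", 0.25)


@pytest.fixture(scope="session")
def fentanyl_human():
    return opbpk.load_compound("fentanyl_human")


@pytest.fixture(scope="session")
def kp_human_qsar():
    return opbpk.load_kp_table("fentanyl_human_qsar")


@pytest.fixture(scope="session")
def kp_rat_report():
    return opbpk.load_kp_table("fentanyl_rat_report")


@pytest.fixture(scope="session")
def kp_human_extrapolated():
    return opbpk.load_kp_table("fentanyl_human_extrapolated")


@pytest.fixture(scope="session")
def human_fentanyl_model(human_phys, fentanyl_human, kp_human_qsar):
    return opbpk.build_model(
        human_phys, fentanyl_human, kp_human_qsar, opbpk.DoseRegimen(amount_ug=100.0)
    )


@pytest.fixture(scope="session")
def human_fentanyl_sim(human_fentanyl_model):
    """Long, transient-resolving human fentanyl run reused across tests."""
    return opbpk.simulate(human_fentanyl_model, 72.0, 1441, dense_early=True)


@pytest.fixture(scope="session")
def rat_bhtf_model(rat_phys):
    comp = opbpk.load_compound("beta_hydroxythiofentanyl_rat")
    kp = opbpk.load_kp_table("beta_hydroxythiofentanyl_rat_qsar")
    return opbpk.build_model(rat_phys, comp, kp, opbpk.DoseRegimen(per_kg_ug=7.0))


@pytest.fixture
def make_compound():
    def _make(species="human", clsys=0.0, logp=4.0, pka=9.0, fup=0.2, rbp=1.0, name="x"):
        return opbpk.CompoundProperties(
            name=name,
            logP=logp,
            pka_list=((pka, "base"),) if pka is not None else (),
            fup=fup,
            rbp=rbp,
            clsys_L_per_h=clsys,
            species=species,
        )

    return _make


@pytest.fixture
def uniform_kp():
    def _make(value=1.0, species="human", compound="x", source="table"):
        return opbpk.KpSet(
            compound=compound,
            species=species,
            source=source,
            kp={t: value for t in opbpk.TISSUES},
        )

    return _make


@pytest.fixture
def mono_exp_profile():
    """Densely sampled mono-exponential: C = 100·exp(-0.5 t), dose-free."""
    t = np.linspace(0.0, 20.0, 401)
    return opbpk.ConcProfile(t, 100.0 * np.exp(-0.5 * t))
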