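"""Synthetic compound panels and noisy "observed" PK studies.

The generator emulates the study designs the pipeline is meant to analyse:

* analog parameter panels spanning the fentanyl-class property ranges
  (logP ~1.4-4.5, fup ~5-35%, Rbp ~0.8-1.1, basic pKa ~7.5-9.5);
* a sparse IV-bolus rat sampling schedule (8 samples over 0-240 min);
* multiplicative lognormal assay noise on plasma concentrations
  (median-1 multipliers with configurable CV), mimicking LC-MS/MS error.

Only assay noise is modelled — no inter-subject physiological variability —
so recovered parameters scatter around a single truth. Everything is
seeded and regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .kp_models import CompoundProperties
from .nca import ConcProfile, NCAResult, nca_iv
from .pbpk_core import ModelSpec, SimulationResult, simulate

#: the sparse rat sampling schedule: 0, 15, 45, 60, 90, 120, 180, 240 min
RAT_SCHEDULE_H = (0.0, 0.25, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0)

#: default property ranges for generated analog panels
DEFAULT_RANGES = {
    "logP": (1.4, 4.5),
    "fup": (0.05, 0.35),  # log-uniform
    "rbp": (0.8, 1.1),
    "pka_base": (7.5, 9.5),
    "sw_mg_per_mL": (0.1, 5.0),  # log-uniform, metadata only
}

#: shared systemic clearance applied to generated human analog panels (L/h),
#: the batch-design convention of reusing one well-measured reference value
DEFAULT_PANEL_CLSYS = 62.66


def gen_compound_panel(
    n: int,
    seed: int,
    ranges: dict | None = None,
    *,
    species: str = "human",
    clsys_L_per_h: float = DEFAULT_PANEL_CLSYS,
) -> list[CompoundProperties]:
    """Reproducible panel of synthetic fentanyl-class analog parameter sets.

    logP, Rbp and base pKa are uniform on their ranges; fup and water
    solubility log-uniform. All rows validate as :class:`CompoundProperties`.
    """
    if n < 1:
        raise DomainError("panel size must be >= 1")
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    for key, (lo, hi) in r.items():
        if not (lo < hi) or (key == "fup" and not (0 < lo and hi <= 1)):
            raise DomainError(f"invalid range for {key}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n):
        logp = rng.uniform(*r["logP"])
        fup = float(np.exp(rng.uniform(np.log(r["fup"][0]), np.log(r["fup"][1]))))
        rbp = rng.uniform(*r["rbp"])
        pka = rng.uniform(*r["pka_base"])
        sw = float(np.exp(rng.uniform(*np.log(r["sw_mg_per_mL"]))))
        panel.append(
            CompoundProperties(
                name=f"analog_{i + 1:03d}",
                logP=float(logp),
                pka_list=((float(pka), "base"),),
                fup=fup,
                rbp=float(rbp),
                sw_mg_per_mL=sw,
                clsys_L_per_h=clsys_L_per_h,
                species=species,
            )
        )
    return panel


def panel_to_frame(panel: list[CompoundProperties]) -> pd.DataFrame:
    rows = []
    for c in panel:
        rows.append(
            {
                "name": c.name,
                "logP": c.logP,
                "pka_base": c.strongest_base_pka,
                "fup": c.fup,
                "rbp": c.rbp,
                "sw_mg_per_mL": c.sw_mg_per_mL,
                "clsys_L_per_h": c.clsys_L_per_h,
                "species": c.species,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SyntheticStudy:
    """A simulated 'observed' study bundled with its generating truth."""

    truth_model: ModelSpec
    truth_sim: SimulationResult
    truth_nca: NCAResult
    schedule_h: tuple
    noise_cv: float
    n_subjects: int
    seed: int
    lloq_pg_per_mL: float
    observed: list[ConcProfile] = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "compound": self.truth_model.compound.name,
            "species": self.truth_model.physiology.species,
            "dose_ug": self.truth_model.regimen.amount_ug,
            "schedule_h": list(self.schedule_h),
            "noise_cv": self.noise_cv,
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "lloq_pg_per_mL": self.lloq_pg_per_mL,
            "truth": self.truth_nca.to_dict(),
        }


def gen_observed_study(
    model: ModelSpec,
    schedule_h=RAT_SCHEDULE_H,
    noise_cv: float = 0.15,
    n_subjects: int = 1,
    seed: int = 0,
    *,
    lloq_pg_per_mL: float = 0.0,
    sim: SimulationResult | None = None,
    t0_draw_h: float = 1.0 / 60.0,
) -> SyntheticStudy:
    """Noise-free simulation sampled at ``schedule_h`` times multiplicative noise.

    Noise multipliers are lognormal with median 1 and coefficient of
    variation ``noise_cv`` (sigma² = ln(1 + CV²)), independent across time
    points and subjects; ``noise_cv = 0`` reproduces the simulation exactly.
    Values below the LLOQ are dropped, not zeroed. The noise-free truth
    (simulation + NCA) is retained alongside the observations.

    A nominal time-zero entry in the schedule is a *post-dosing* draw (the
    bioanalytical convention for bolus studies), not a pre-dose blank: it is
    sampled at ``t0_draw_h`` (default 1 min), the earliest time a real draw
    can reflect a circulatory-mixed concentration rather than the transient
    venous spike of an ideal bolus.
    """
    if noise_cv < 0:
        raise DomainError("noise CV must be non-negative")
    schedule = np.asarray(schedule_h, dtype=float)
    if sim is None:
        t_end = float(schedule[-1])
        sim = simulate(
            model,
            t_end_h=t_end,
            n_points=max(int(t_end * 240) + 1, 241),
            dense_early=True,
        )
    if schedule[-1] > sim.time_h[-1] + 1e-9:
        raise DomainError("schedule extends beyond the simulated span")

    draw_times = np.where(schedule <= 0, t0_draw_h, schedule)
    truth_on_schedule = np.interp(draw_times, sim.time_h, sim.plasma)
    dose_ug = model.regimen.amount_ug
    truth_nca = nca_iv(
        ConcProfile(sim.time_h, sim.plasma, dose_ug, "truth"), dose_ug
    )

    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    observed = []
    for subj in range(n_subjects):
        mult = np.exp(rng.normal(0.0, sigma, size=schedule.size)) if sigma > 0 else 1.0
        c = truth_on_schedule * mult
        keep = c >= lloq_pg_per_mL if lloq_pg_per_mL > 0 else np.ones_like(c, bool)
        keep |= truth_on_schedule == 0  # keep structural pre-dose zeros
        observed.append(
            ConcProfile(schedule[keep], c[keep], dose_ug, f"subject_{subj + 1:03d}")
        )

    return SyntheticStudy(
        truth_model=model,
        truth_sim=sim,
        truth_nca=truth_nca,
        schedule_h=tuple(schedule),
        noise_cv=noise_cv,
        n_subjects=n_subjects,
        seed=seed,
        lloq_pg_per_mL=lloq_pg_per_mL,
        observed=observed,
    )


def study_to_frame(study: SyntheticStudy) -> pd.DataFrame:
    """Observed profiles in the long profile-CSV dialect."""
    rows = []
    for prof in study.observed:
        rows.append(
            pd.DataFrame(
                {
                    "time_h": prof.time_h,
                    "compartment": prof.label,
                    "conc_pg_per_mL": prof.conc_pg_per_mL,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
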