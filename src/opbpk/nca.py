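"""Non-compartmental analysis of concentration-time profiles.

Implements the standard IV-dose NCA parameter set: trapezoidal AUC
(linear or linear-up/log-down), terminal slope by best-adjusted-R²
log-linear regression over contiguous tail windows, tail extrapolation
(AUC and AUMC), clearance, mean residence time and steady-state volume of
distribution, plus tissue-distribution summaries (per-tissue Cmax and
brain/plasma exposure ratios) from simulated profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, EstimationError
from .pbpk_core import SimulationResult, UG_TO_PG
from .physiology import TISSUES

#: minimum number of terminal points for a log-linear slope fit
MIN_LAMBDA_Z_POINTS = 3

#: extrapolated AUC fraction above which the result is flagged
TAIL_WARN_FRACTION = 0.20


@dataclass(frozen=True)
class ConcProfile:
    """A single concentration-time profile (h, pg/mL)."""

    time_h: np.ndarray
    conc_pg_per_mL: np.ndarray
    dose_ug: float | None = None
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.time_h, dtype=float)
        c = np.asarray(self.conc_pg_per_mL, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise DomainError("time and concentration must be 1-D and same length")
        if t.size and t[0] < 0:
            raise DomainError("time must start at or after 0")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DomainError("time grid must be strictly increasing")
        if np.any(c < 0):
            raise DomainError("concentrations must be non-negative")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "conc_pg_per_mL", c)

    def __len__(self) -> int:
        return self.time_h.size

    def dropna_zero_tail(self) -> "ConcProfile":
        """Trim trailing zeros (below-LOQ tail) which break log-down AUC."""
        c = self.conc_pg_per_mL
        nz = np.nonzero(c)[0]
        if nz.size == 0:
            return self
        end = nz[-1] + 1
        return ConcProfile(self.time_h[:end], c[:end], self.dose_ug, self.label)


@dataclass
class NCAResult:
    """Derived PK parameters for one profile (paper-convention units)."""

    auc_0_t: float  # pg·h/mL
    auc_0_inf: float  # pg·h/mL
    aumc_0_inf: float  # pg·h²/mL
    cl_L_per_h: float | None
    vss_L: float | None
    t_half_h: float
    cmax: float  # pg/mL
    tmax_h: float
    lambda_z: float  # 1/h
    lambda_z_n_points: int
    lambda_z_adj_r2: float
    mrt_h: float
    extrapolated_fraction: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "auc_0_t", "auc_0_inf", "aumc_0_inf", "cl_L_per_h", "vss_L",
            "t_half_h", "cmax", "tmax_h", "lambda_z", "lambda_z_n_points",
            "lambda_z_adj_r2", "mrt_h", "extrapolated_fraction",
        )}
        d["flags"] = ";".join(self.flags)
        return d


# ---------------------------------------------------------------------------
# AUC / AUMC quadrature
# ---------------------------------------------------------------------------

def _interval_areas(t, c, method: str):
    """Per-interval (AUC, AUMC) using linear or linear-up/log-down rules."""
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    t1, t2 = t[:-1], t[1:]
    lin_auc = 0.5 * (c1 + c2) * dt
    lin_aumc = 0.5 * (c1 * t1 + c2 * t2) * dt
    if method == "linear":
        return lin_auc, lin_aumc
    if method != "linear_up_log_down":
        raise DomainError(f"unknown AUC method {method!r}")
    down = (c2 < c1) & (c2 > 0)
    k = np.ones_like(dt)
    k[down] = np.log(c1[down] / c2[down]) / dt[down]
    log_auc = np.where(down, (c1 - c2) / k, lin_auc)
    # ∫ t·C dt over a log-linear segment
    log_aumc = np.where(
        down,
        (c1 * t1 - c2 * t2) / k + (c1 - c2) / k**2,
        lin_aumc,
    )
    return log_auc, log_aumc


def auc_trapezoid(profile: ConcProfile, method: str = "linear_up_log_down") -> float:
    """AUC over the observed span (AUC0-t), pg·h/mL."""
    if len(profile) < 2:
        raise EstimationError("need at least 2 points for an AUC")
    auc, _ = _interval_areas(profile.time_h, profile.conc_pg_per_mL, method)
    return float(np.sum(auc))


# ---------------------------------------------------------------------------
# Terminal slope
# ---------------------------------------------------------------------------

def lambda_z(
    profile: ConcProfile,
    min_points: int = MIN_LAMBDA_Z_POINTS,
) -> tuple[float, int, float]:
    """Terminal log-linear rate constant (1/h).

    Fits ln(C) vs t over every contiguous terminal window of >= ``min_points``
    positive concentrations strictly after Tmax, and keeps the window with
    the highest adjusted R² (ties go to the window with more points —
    the WinNonlin-style "best fit" rule). Returns (lambda_z, n_points,
    adjusted R²); raises :class:`EstimationError` when no window yields a
    negative slope.
    """
    t, c = profile.time_h, profile.conc_pg_per_mL
    pos = c > 0
    if pos.sum() < min_points:
        raise EstimationError("need >= 3 positive concentrations for lambda_z")
    i_max = int(np.argmax(c))
    best = None  # (adj_r2, n, slope)
    n_all = len(t)
    for start in range(i_max + 1, n_all - min_points + 1):
        sel = slice(start, n_all)
        if not np.all(pos[sel]):
            continue
        ts, ys = t[sel], np.log(c[sel])
        m = ts.size
        slope, intercept = np.polyfit(ts, ys, 1)
        ss_tot = float(np.sum((ys - ys.mean()) ** 2))
        if ss_tot <= 1e-20 or slope >= -1e-10:  # flat tail: no decline to fit
            continue
        resid = ys - (slope * ts + intercept)
        ss_res = float(resid @ resid)
        r2 = 1 - ss_res / ss_tot
        adj = 1 - (1 - r2) * (m - 1) / (m - 2) if m > 2 else r2
        key = (round(adj, 4), m)
        if best is None or key > best[0]:
            best = (key, m, slope, adj)
    if best is None:
        raise EstimationError("no acceptable terminal log-linear fit (flat or rising tail)")
    _, n, slope, adj = best
    return -slope, n, adj


# ---------------------------------------------------------------------------
# Complete IV NCA
# ---------------------------------------------------------------------------

def _back_extrapolate_c0(t, c) -> float:
    """Log-linear back-extrapolation of C(0) from the first two positive points."""
    pos = np.nonzero(c > 0)[0]
    if pos.size < 2:
        return c[pos[0]] if pos.size else 0.0
    i, j = pos[0], pos[1]
    if c[j] >= c[i]:  # rising start (infusion-like); do not extrapolate upward
        return c[i]
    k = math.log(c[i] / c[j]) / (t[j] - t[i])
    return float(c[i] * math.exp(k * t[i]))


def nca_iv(
    profile: ConcProfile,
    dose_ug: float | None = None,
    *,
    infusion_duration_h: float = 0.0,
    method: str = "linear_up_log_down",
    back_extrapolate: bool = True,
) -> NCAResult:
    """Full non-compartmental analysis of an IV profile.

    For bolus data the time-zero concentration is back-extrapolated
    log-linearly from the first two positive points (replacing a missing or
    zero C(0)). The extrapolated tail is C_last/λz (AUC) and
    C_last·t_last/λz + C_last/λz² (AUMC); CL = Dose/AUC0-inf,
    MRT = AUMC/AUC − τ/2 for a τ-infusion, Vss = CL·MRT. An extrapolated
    AUC fraction above 20% is flagged, not hidden.
    """
    dose_ug = dose_ug if dose_ug is not None else profile.dose_ug
    profile = profile.dropna_zero_tail()
    t = profile.time_h.copy()
    c = profile.conc_pg_per_mL.copy()
    flags: list[str] = []

    if back_extrapolate and infusion_duration_h == 0:
        c0 = _back_extrapolate_c0(t, c)
        if t[0] > 0:
            t = np.insert(t, 0, 0.0)
            c = np.insert(c, 0, c0)
        elif c[0] == 0:
            c[0] = c0
    work = ConcProfile(t, c, dose_ug, profile.label)

    auc_t, aumc_t = _interval_areas(t, c, method)
    auc_0_t = float(np.sum(auc_t))
    aumc_0_t = float(np.sum(aumc_t))

    lz, n_lz, adj = lambda_z(work)
    c_last = c[-1]
    t_last = t[-1]
    auc_tail = c_last / lz
    aumc_tail = c_last * t_last / lz + c_last / lz**2
    auc_inf = auc_0_t + auc_tail
    aumc_inf = aumc_0_t + aumc_tail
    frac = auc_tail / auc_inf
    if frac > TAIL_WARN_FRACTION:
        flags.append(f"extrapolated_tail_{frac:.0%}")

    cmax = float(np.max(c))
    tmax = float(t[int(np.argmax(c))])
    t_half = math.log(2) / lz
    mrt = aumc_inf / auc_inf - infusion_duration_h / 2.0

    cl = vss = None
    if dose_ug is not None:
        dose_pg = dose_ug * UG_TO_PG
        cl = dose_pg / (auc_inf * 1000.0)  # pg / (pg·h/mL · mL/L) -> L/h
        vss = cl * mrt

    return NCAResult(
        auc_0_t=auc_0_t,
        auc_0_inf=auc_inf,
        aumc_0_inf=aumc_inf,
        cl_L_per_h=cl,
        vss_L=vss,
        t_half_h=t_half,
        cmax=cmax,
        tmax_h=tmax,
        lambda_z=lz,
        lambda_z_n_points=n_lz,
        lambda_z_adj_r2=adj,
        mrt_h=mrt,
        extrapolated_fraction=frac,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Tissue distribution summaries
# ---------------------------------------------------------------------------

def tissue_ratios(sim: SimulationResult, method: str = "linear_up_log_down") -> pd.DataFrame:
    """Per-tissue Cmax and exposure ratios against plasma.

    Returns one row per tissue with Cmax (pg/mL), Tmax, Cmax/plasma-Cmax and
    AUC0-t(tissue)/AUC0-t(plasma) on the simulated span. The brain row
    carries the brain/plasma penetration ratio on both bases (Cmax basis is
    the conventional default; the AUC basis is co-reported).
    """
    if sim.plasma is None or not np.any(sim.plasma > 0):
        raise DomainError("simulation lacks a plasma series")
    t = sim.time_h
    plasma_profile = ConcProfile(t, sim.plasma)
    auc_plasma = auc_trapezoid(plasma_profile, method)
    cmax_plasma = float(np.max(sim.plasma))
    rows = []
    for tissue in TISSUES:
        c = sim.conc[tissue]
        auc = auc_trapezoid(ConcProfile(t, c), method)
        cmax = float(np.max(c))
        rows.append(
            {
                "tissue": tissue,
                "cmax_pg_per_mL": cmax,
                "tmax_h": float(t[int(np.argmax(c))]),
                "cmax_ratio_vs_plasma": cmax / cmax_plasma,
                "auc_ratio_vs_plasma": auc / auc_plasma,
            }
        )
    return pd.DataFrame(rows)


def brain_plasma_ratio(sim: SimulationResult, basis: str = "cmax") -> float:
    """Brain/plasma exposure ratio, ``basis`` in {"cmax", "auc"}."""
    table = tissue_ratios(sim).set_index("tissue")
    col = {"cmax": "cmax_ratio_vs_plasma", "auc": "auc_ratio_vs_plasma"}
    if basis not in col:
        raise DomainError("basis must be 'cmax' or 'auc'")
    return float(table.loc["brain", col[basis]])
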