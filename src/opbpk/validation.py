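"""Predicted-versus-observed scoring with fold-error criteria.

The conventional PBPK acceptance band is the 2-fold window: a prediction p
against an observation o passes when max(p/o, o/p) <= 2. Reports carry both
this symmetric fold error and the directional ratio p/o as publications
print it, plus helpers for the unit conversions that typically precede the
comparison (min to h, per-kg volumes and doses to absolute).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, UnitError
from .nca import ConcProfile, NCAResult, nca_iv

#: literature-comparison band used for close fentanyl congeners
DEFAULT_RANGE = (1.3, 1.7)


@dataclass(frozen=True)
class FoldErrorReport:
    parameter: str
    predicted: float
    observed: float

    @property
    def ratio_as_printed(self) -> float:
        """Directional predicted/observed ratio, as papers print it."""
        return self.predicted / self.observed

    @property
    def fold_error(self) -> float:
        """Symmetric fold error max(p/o, o/p) >= 1."""
        r = self.ratio_as_printed
        return max(r, 1.0 / r)

    @property
    def within_2fold(self) -> bool:
        return self.within_fold(2.0)

    def within_fold(self, k: float) -> bool:
        """Closed-interval k-fold test (a fold error of exactly k passes)."""
        return self.fold_error <= k

    def within_range(self, lo: float, hi: float) -> bool:
        """Closed-interval band on the symmetric fold error."""
        return lo <= self.fold_error <= hi

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "predicted": self.predicted,
            "observed": self.observed,
            "ratio_as_printed": round(self.ratio_as_printed, 2),
            "fold_error": self.fold_error,
            "within_2fold": self.within_2fold,
        }


def fold_error(predicted: float, observed: float, parameter: str = "") -> FoldErrorReport:
    """Score one predicted/observed pair; both values must be positive."""
    if not (predicted > 0 and observed > 0):
        raise DomainError("fold error needs positive predicted and observed values")
    return FoldErrorReport(parameter=parameter, predicted=float(predicted), observed=float(observed))


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

_SIMPLE = {
    ("min", "h"): 1 / 60.0,
    ("h", "min"): 60.0,
    ("pg_h_per_mL", "ng_h_per_mL"): 1e-3,
    ("ng_h_per_mL", "pg_h_per_mL"): 1e3,
    ("mg", "ug"): 1e3,
    ("ug", "mg"): 1e-3,
    ("ug", "pg"): 1e6,
    ("pg", "ug"): 1e-6,
    ("mg", "pg"): 1e9,
    ("pg", "mg"): 1e-9,
}

_PER_KG = {
    ("L_per_kg", "L"),
    ("ug_per_kg", "ug"),
    ("mg_per_kg", "mg"),
}


def convert_units(
    value: float,
    from_unit: str,
    to_unit: str,
    *,
    body_weight_kg: float | None = None,
) -> float:
    """Exact arithmetic conversion between the supported unit pairs.

    Per-kg units (L/kg, µg/kg, mg/kg) require ``body_weight_kg``; e.g.
    1.7 L/kg at 70 kg -> 119 L, 7 µg/kg at 0.25 kg -> 1.75 µg.
    """
    pair = (from_unit, to_unit)
    if from_unit == to_unit:
        return float(value)
    if pair in _SIMPLE:
        return float(value) * _SIMPLE[pair]
    if pair in _PER_KG or (to_unit, from_unit) in _PER_KG:
        if body_weight_kg is None:
            raise UnitError(f"{from_unit} -> {to_unit} needs a body weight")
        if body_weight_kg <= 0:
            raise DomainError("body weight must be positive")
        if pair in _PER_KG:
            return float(value) * body_weight_kg
        return float(value) / body_weight_kg
    raise UnitError(f"unsupported unit conversion {from_unit!r} -> {to_unit!r}")


# ---------------------------------------------------------------------------
# Profile comparison
# ---------------------------------------------------------------------------

def compare_profiles(
    predicted: ConcProfile,
    observed: ConcProfile,
    *,
    dose_ug: float | None = None,
    infusion_duration_h: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, FoldErrorReport]]:
    """Overlay a prediction on observations and fold-score the NCA pair.

    The overlay interpolates the predicted profile (log-linearly where it
    declines) at the observed sampling times. Fold-error reports cover
    AUC0-t, AUC0-inf, CL, Vss and T1/2 from independent NCA runs on the two
    profiles; AUC0-t for the prediction is computed over the observed span
    so exposures are compared like for like.
    """
    t_obs = observed.time_h
    lo = max(predicted.time_h[0], t_obs[0])
    hi = min(predicted.time_h[-1], t_obs[-1])
    if hi <= lo:
        raise DomainError("predicted and observed spans do not overlap")

    pred_at_obs = _log_interp(predicted.time_h, predicted.conc_pg_per_mL, t_obs)
    overlay = pd.DataFrame(
        {
            "time_h": t_obs,
            "observed_pg_per_mL": observed.conc_pg_per_mL,
            "predicted_pg_per_mL": pred_at_obs,
        }
    )

    dose = dose_ug if dose_ug is not None else (observed.dose_ug or predicted.dose_ug)
    # prediction restricted to the observed window for a like-for-like AUC0-t
    mask = (predicted.time_h >= lo) & (predicted.time_h <= hi)
    pred_window = ConcProfile(
        predicted.time_h[mask], predicted.conc_pg_per_mL[mask], dose, predicted.label
    )
    nca_pred = nca_iv(pred_window, dose, infusion_duration_h=infusion_duration_h)
    nca_obs = nca_iv(observed, dose, infusion_duration_h=infusion_duration_h)

    reports = {}
    for name in ("auc_0_t", "auc_0_inf", "cl_L_per_h", "vss_L", "t_half_h"):
        p, o = getattr(nca_pred, name), getattr(nca_obs, name)
        if p is None or o is None or not (p > 0 and o > 0):
            continue
        reports[name] = fold_error(p, o, parameter=name)
    return overlay, reports


def _log_interp(t_src, c_src, t_new):
    """Interpolate a concentration series, log-scale where positive."""
    c_src = np.asarray(c_src, dtype=float)
    pos = c_src > 0
    out = np.interp(t_new, t_src, c_src)
    if pos.sum() >= 2:
        logc = np.interp(t_new, t_src[pos], np.log(c_src[pos]))
        inside = (t_new >= t_src[pos][0]) & (t_new <= t_src[pos][-1])
        out = np.where(inside, np.exp(logc), out)
    return out


def nca_fold_errors(
    predicted: NCAResult, observed: NCAResult
) -> dict[str, FoldErrorReport]:
    """Fold-score two already-computed NCA results parameter-by-parameter."""
    reports = {}
    for name in ("auc_0_t", "auc_0_inf", "cl_L_per_h", "vss_L", "t_half_h", "cmax"):
        p, o = getattr(predicted, name), getattr(observed, name)
        if p is None or o is None or not (p > 0 and o > 0):
            continue
        reports[name] = fold_error(p, o, parameter=name)
    return reports
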