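"""Tissue/blood partition coefficient (Kp) sets from three sources.

1. ``load_kp_table`` — packaged literature/report fixtures or user CSVs.
2. ``predict_kp_composition`` — a tissue-composition predictor in the
   Rodgers–Rowland family: tissue affinity is built up from fractional
   water, neutral lipid, neutral phospholipid and (for ionized bases)
   acidic-phospholipid content, with ionization at physiological pH.
3. ``extrapolate_kp`` — rat-to-human scaling of a rat Kp set by the ratio of
   unbound plasma fractions and blood:plasma ratios,

       Kp_human = (fup_human / fup_rat) * (BP_rat / BP_human) * Kp_rat.

All Kp values here are tissue:blood ratios (tissue concentration over whole
blood concentration at distribution equilibrium).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import DomainError, IncompleteKpSetError
from .physiology import TISSUES, canonical_tissue_name

BLOOD_PH = 7.4
INTRACELLULAR_PH = 7.0
BLOOD_CELL_PH = 7.22
HEMATOCRIT = {"rat": 0.46, "human": 0.45}

#: base pKa at or above this value triggers the acidic-phospholipid
#: (moderate-to-strong base) equations rather than the protein-binding ones.
STRONG_BASE_PKA = 7.0

KP_SOURCES = ("table", "composition_qsar", "extrapolated")

_FIXTURE_IDS = (
    "beta_hydroxythiofentanyl_rat_qsar",
    "fentanyl_rat_report",
    "fentanyl_rat_qsar",
    "fentanyl_human_extrapolated",
    "fentanyl_human_qsar",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundProperties:
    """Per-compound physicochemistry and binding parameters.

    ``fup`` is a fraction in (0, 1]; ``rbp`` the blood:plasma concentration
    ratio; ``clsys_L_per_h`` the plasma-referenced systemic clearance.
    ``sw_mg_per_mL`` (water solubility) and ``peff_1e4_cm_per_s`` (jejunal
    permeability) are metadata, unused for IV disposition.
    """

    name: str
    logP: float
    pka_list: tuple = ()  # ((value, "acid"|"base"), ...)
    fup: float = 1.0
    rbp: float = 1.0
    sw_mg_per_mL: float | None = None
    peff_1e4_cm_per_s: float | None = None
    clsys_L_per_h: float = 0.0
    species: str = "human"

    def __post_init__(self):
        if not 0 < self.fup <= 1:
            raise DomainError(f"fup must be in (0, 1], got {self.fup}")
        if self.rbp <= 0:
            raise DomainError(f"rbp must be positive, got {self.rbp}")
        if self.clsys_L_per_h < 0:
            raise DomainError("clearance must be non-negative")
        for pka, kind in self.pka_list:
            if kind not in ("acid", "base"):
                raise DomainError(f"pKa type must be 'acid' or 'base', got {kind!r}")

    @property
    def strongest_base_pka(self) -> float | None:
        vals = [v for v, k in self.pka_list if k == "base"]
        return max(vals) if vals else None


def _coerce_fup(value: float) -> float:
    """Accept percent-scale fup inputs (> 1) with an explicit conversion."""
    value = float(value)
    if value > 1:
        warnings.warn(
            f"fup = {value} looks percent-scaled; converting to fraction {value / 100}",
            stacklevel=3,
        )
        value /= 100.0
    return value


def compound_from_dict(d: dict) -> CompoundProperties:
    """Build :class:`CompoundProperties` from a plain dict (JSON schema).

    Percent-scale ``fup`` values (e.g. ``32.25`` or ``"32.25%"``) are
    converted to fractions with a warning, preventing silent 100x errors.
    """
    d = dict(d)
    d.pop("_note", None)
    fup = d.get("fup", 1.0)
    if isinstance(fup, str):
        fup = fup.rstrip("% ")
    d["fup"] = _coerce_fup(float(fup))
    d["pka_list"] = tuple((float(v), str(k)) for v, k in d.get("pka_list", ()))
    return CompoundProperties(**d)


def load_compound(path_or_fixture: str | Path) -> CompoundProperties:
    """Load a compound JSON file, or a bundled fixture by stem name."""
    p = Path(path_or_fixture)
    if p.suffix == ".json" and p.exists():
        return compound_from_dict(json.loads(p.read_text()))
    res = resources.files("opbpk.data.compounds").joinpath(f"{path_or_fixture}.json")
    if res.is_file():
        return compound_from_dict(json.loads(res.read_text()))
    raise FileNotFoundError(f"no compound file or fixture named {path_or_fixture!r}")


@dataclass(frozen=True)
class KpSet:
    """Tissue -> Kp (tissue:blood) map for one compound and species."""

    compound: str
    species: str
    source: str
    kp: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.source not in KP_SOURCES:
            raise DomainError(f"source must be one of {KP_SOURCES}")
        extra = set(self.kp) - set(TISSUES)
        missing = set(TISSUES) - set(self.kp)
        if missing or extra:
            raise IncompleteKpSetError(missing, extra)
        for t, v in self.kp.items():
            if not v > 0:
                raise DomainError(f"Kp[{t}] must be positive, got {v}")

    def __getitem__(self, tissue: str) -> float:
        return self.kp[canonical_tissue_name(tissue)]

    def scaled(self, factor: float, *, source: str | None = None) -> "KpSet":
        return KpSet(
            compound=self.compound,
            species=self.species,
            source=source or self.source,
            kp={t: v * factor for t, v in self.kp.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tissue": list(TISSUES), "kp": [self.kp[t] for t in TISSUES]}
        )


# ---------------------------------------------------------------------------
# Source 1: tables / fixtures
# ---------------------------------------------------------------------------

def kp_fixture_ids() -> tuple:
    return _FIXTURE_IDS


def load_kp_table(
    path_or_fixture: str | Path,
    *,
    compound: str | None = None,
    species: str | None = None,
    source: str = "table",
) -> KpSet:
    """Read a Kp CSV (columns ``tissue,kp``) or a bundled fixture by id.

    Fixture ids (``kp_fixture_ids()``) encode compound and species in the
    name; for user files these can be supplied explicitly. Tissue labels are
    matched case/space-insensitively onto the 13 canonical names; unknown or
    missing tissues raise :class:`IncompleteKpSetError`.
    """
    p = Path(path_or_fixture)
    if str(path_or_fixture) in _FIXTURE_IDS:
        fid = str(path_or_fixture)
        src = resources.files("opbpk.data.kp").joinpath(f"{fid}.csv")
        parts = fid.rsplit("_", 2)  # <compound>_<species>_<provenance>
        compound = compound or parts[0]
        species = species or parts[1]
        with resources.as_file(src) as f:
            df = pd.read_csv(f, comment="#")
    elif p.exists():
        df = pd.read_csv(p, comment="#")
    else:
        raise FileNotFoundError(f"no Kp file or fixture named {path_or_fixture!r}")

    kp: dict[str, float] = {}
    unknown = []
    for row in df.itertuples(index=False):
        try:
            name = canonical_tissue_name(row.tissue)
        except KeyError:
            unknown.append(str(row.tissue))
            continue
        v = float(row.kp)
        if not v > 0:
            raise DomainError(f"Kp[{name}] must be positive, got {v}")
        kp[name] = v
    missing = set(TISSUES) - set(kp)
    if missing or unknown:
        raise IncompleteKpSetError(missing, unknown)
    return KpSet(
        compound=compound or p.stem,
        species=species or "unknown",
        source=source,
        kp=kp,
    )


# ---------------------------------------------------------------------------
# Source 2: interspecies extrapolation
# ---------------------------------------------------------------------------

def extrapolate_kp(
    kp_rat: KpSet,
    fup_rat: float,
    fup_human: float,
    bp_rat: float,
    bp_human: float,
) -> KpSet:
    """Scale a rat Kp set to human by unbound-fraction and blood:plasma ratios.

    Applies Kp_human = (fup_human/fup_rat) * (BP_rat/BP_human) * Kp_rat
    tissue-wise; exactly linear, so reciprocal scalars invert it to machine
    precision.
    """
    if kp_rat.species != "rat":
        raise DomainError("extrapolation expects a rat Kp set")
    for label, v in (
        ("fup_rat", fup_rat),
        ("fup_human", fup_human),
        ("bp_rat", bp_rat),
        ("bp_human", bp_human),
    ):
        if not v > 0:
            raise DomainError(f"{label} must be positive, got {v}")
    s = (fup_human / fup_rat) * (bp_rat / bp_human)
    out = kp_rat.scaled(s, source="extrapolated")
    return KpSet(compound=out.compound, species="human", source="extrapolated", kp=out.kp)


# ---------------------------------------------------------------------------
# Source 3: tissue-composition predictor
# ---------------------------------------------------------------------------

def _load_composition(path=None) -> pd.DataFrame:
    src = path or resources.files("opbpk.data").joinpath("tissue_composition.csv")
    df = pd.read_csv(src, comment="#").set_index("tissue")
    return df


def _ionization_term(pka_list, ph: float) -> float:
    """Sum of ionized-over-neutral abundance terms at the given pH.

    Monoprotic base contributes 10^(pKa-pH); acid 10^(pH-pKa); diprotic
    bases add the doubly charged term. Neutral compounds contribute 0.
    """
    bases = sorted((v for v, k in pka_list if k == "base"), reverse=True)
    acids = sorted(v for v, k in pka_list if k == "acid")
    z = 0.0
    if bases:
        z += 10.0 ** (bases[0] - ph)
        if len(bases) > 1:
            z += 10.0 ** (bases[0] + bases[1] - 2 * ph)
    if acids:
        z += 10.0 ** (ph - acids[0])
        if len(acids) > 1:
            z += 10.0 ** (2 * ph - acids[0] - acids[1])
    return z


def predict_kp_composition(
    compound: CompoundProperties,
    species: str | None = None,
    *,
    blood_ph: float = BLOOD_PH,
    composition_table=None,
) -> KpSet:
    """Predict tissue:blood Kp for all 13 tissues from tissue composition.

    Partitioning of the unbound drug into tissue water, neutral lipid and
    neutral phospholipid is computed from logP and ionization; for
    moderate-to-strong bases (base pKa >= 7) the affinity of the cation for
    acidic phospholipids is calibrated from blood-cell partitioning (via
    ``rbp``, ``fup`` and hematocrit). For neutrals, acids and weak bases a
    tissue-to-plasma binding-protein ratio carries the protein-bound term.
    Adipose (and the adipose-like yellow marrow) neutral lipid uses a
    vegetable-oil:water partition surrogate rather than octanol:water.

    Returns a :class:`KpSet` labeled ``composition_qsar``. This predictor is
    a published tissue-composition method, not a reimplementation of any
    commercial QSAR engine; bundled fixture tables remain the canonical
    route for reproducing literature outputs.
    """
    species = (species or compound.species).lower()
    hct = HEMATOCRIT.get(species, 0.45)
    comp = _load_composition(composition_table)
    P = 10.0 ** compound.logP
    # vegetable-oil surrogate for neutral lipid in adipose-like tissues
    P_vo = 10.0 ** (1.115 * compound.logP - 1.35)
    fup, rbp = compound.fup, compound.rbp

    z_p = _ionization_term(compound.pka_list, blood_ph)
    z_iw = _ionization_term(compound.pka_list, INTRACELLULAR_PH)
    z_bc = _ionization_term(compound.pka_list, BLOOD_CELL_PH)

    base_pka = compound.strongest_base_pka
    strong_base = base_pka is not None and base_pka >= STRONG_BASE_PKA

    plasma = comp.loc["plasma"]
    bc = comp.loc["blood_cells"]

    def lipid_term(row, P_nl):
        return (P_nl * row.f_nl + (0.3 * P + 0.7) * row.f_np) / (1 + z_p)

    ka_ap = 0.0
    if strong_base:
        kpu_bc = (rbp - (1 - hct)) / (hct * fup)
        if kpu_bc <= 0:
            raise DomainError(
                "blood-cell partitioning (rbp - (1 - hct)) must be positive "
                "for the strong-base composition equations"
            )
        resid = (
            kpu_bc
            - (1 + z_bc) / (1 + z_p) * bc.f_iw
            - lipid_term(bc, P)
        )
        # negative residual => blood-cell binding fully explained by lipids;
        # no acidic-phospholipid affinity left to attribute
        ka_ap = max(resid, 0.0) * (1 + z_p) / (bc.ap_mg_per_g * z_bc) if z_bc > 0 else 0.0

    # plasma-protein bound term shared by the neutral/acid/weak-base class
    protein_resid = 1 / fup - 1 - (P * plasma.f_nl + (0.3 * P + 0.7) * plasma.f_np)

    kp: dict[str, float] = {}
    adipose_like = ("adipose", "yellow_marrow")
    for t in TISSUES:
        row = comp.loc[t]
        P_nl = P_vo if t in adipose_like else P
        kpu = (
            row.f_ew
            + (1 + z_iw) / (1 + z_p) * row.f_iw
            + lipid_term(row, P_nl)
        )
        if strong_base:
            kpu += ka_ap * row.ap_mg_per_g * z_iw / (1 + z_p)
        else:
            kpu += max(protein_resid, 0.0) * row.pr_ratio
        # tissue:plasma = Kpu * fup; tissue:blood divides by rbp
        kp[t] = max(kpu * fup / rbp, 1e-6)

    return KpSet(
        compound=compound.name,
        species=species,
        source="composition_qsar",
        kp=kp,
    )
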