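"""Whole-body reference physiology: compartment volumes and perfusion flows.

The body is represented by 13 perfused tissue compartments (lung, adipose,
muscle, liver, spleen, heart, brain, kidney, skin, reproductive organs, red
marrow, yellow marrow, rest of body) plus arterial and venous blood pools.
The lung sits in series with the heart and receives the entire cardiac
output; every other tissue is perfused in parallel from the arterial pool,
except the spleen, whose venous outflow drains through the liver (standard
splanchnic routing). ``rest_of_body`` closes both the volume and the flow
balance, so the venous return always equals the cardiac output.

Reference tables (one CSV per species) are package data and can be replaced
by user files with the same columns; see :func:`load_physiology_csv`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import DomainError, UnsupportedSpeciesError

#: Canonical tissue compartments, in the order used throughout the package.
TISSUES = (
    "lung",
    "adipose",
    "muscle",
    "liver",
    "spleen",
    "heart",
    "brain",
    "kidney",
    "skin",
    "reproductive_organs",
    "red_marrow",
    "yellow_marrow",
    "rest_of_body",
)

#: Blood pools (not perfused tissues).
BLOOD_COMPARTMENTS = ("arterial_blood", "venous_blood")

ALL_COMPARTMENTS = TISSUES + BLOOD_COMPARTMENTS

#: Body weight of the reference animal behind each bundled physiology table (kg).
REFERENCE_BODY_WEIGHT_KG = {"rat": 0.25, "human": 70.0}

#: Assumed whole-body density used for the volume mass-balance bound (kg/L).
BODY_DENSITY_KG_PER_L = 1.0

#: Relative tolerance on the venous-return flow closure.
FLOW_CLOSURE_RTOL = 0.01


def canonical_tissue_name(name: str) -> str:
    """Map a tissue label onto the canonical snake_case name.

    Case- and whitespace-insensitive ("Reproductive organs" -> =
    ``reproductive_organs``). Raises :class:`KeyError` for unknown labels.
    """
    key = "_".join(str(name).strip().lower().replace("-", " ").split())
    if key in ALL_COMPARTMENTS:
        return key
    raise KeyError(f"unknown compartment name: {name!r}")


@dataclass(frozen=True)
class Compartment:
    name: str
    volume_L: float
    flow_L_per_h: float


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Compartment volumes (L) and perfusion flows (L/h) for one body size."""

    species: str
    body_weight_kg: float
    cardiac_output_L_per_h: float
    compartments: dict[str, Compartment] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- accessors ---------------------------------------------------------
    def volume(self, name: str) -> float:
        return self.compartments[canonical_tissue_name(name)].volume_L

    def flow(self, name: str) -> float:
        return self.compartments[canonical_tissue_name(name)].flow_L_per_h

    @property
    def total_volume_L(self) -> float:
        return sum(c.volume_L for c in self.compartments.values())

    @property
    def blood_volume_L(self) -> float:
        return sum(self.compartments[b].volume_L for b in BLOOD_COMPARTMENTS)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.body_weight_kg <= 0:
            raise DomainError("body weight must be positive")
        missing = set(ALL_COMPARTMENTS) - set(self.compartments)
        if missing:
            raise DomainError(f"physiology missing compartments: {sorted(missing)}")
        for c in self.compartments.values():
            if c.volume_L <= 0:
                raise DomainError(f"non-positive volume for {c.name}")
            if c.name in TISSUES and c.flow_L_per_h <= 0:
                raise DomainError(f"non-positive flow for {c.name}")
        co = self.cardiac_output_L_per_h
        if co <= 0:
            raise DomainError("cardiac output must be positive")
        if not math.isclose(self.flow("lung"), co, rel_tol=1e-9):
            raise DomainError("lung blood flow must equal cardiac output")
        non_lung = sum(self.flow(t) for t in TISSUES if t != "lung")
        if not math.isclose(non_lung, co, rel_tol=FLOW_CLOSURE_RTOL):
            raise DomainError(
                f"venous return {non_lung:.4g} L/h does not close to cardiac "
                f"output {co:.4g} L/h within {FLOW_CLOSURE_RTOL:.0%}"
            )
        bound = self.body_weight_kg / BODY_DENSITY_KG_PER_L
        if self.total_volume_L > bound * (1 + 1e-9):
            raise DomainError(
                f"total compartment volume {self.total_volume_L:.4g} L exceeds "
                f"body volume bound {bound:.4g} L"
            )

    # -- scaling -----------------------------------------------------------
    def rescaled(self, body_weight_kg: float, exponent: float = 1.0) -> "SpeciesPhysiology":
        """Rescale to a new body weight: volumes ∝ BW, flows ∝ BW^exponent.

        The default exponent 1 gives plain linear scaling (so the algebraic
        steady-state distribution volume scales exactly with body weight);
        0.75 gives the conventional allometric perfusion scaling. Volumes
        always scale linearly so the whole-body mass balance is preserved.
        """
        if body_weight_kg <= 0:
            raise DomainError("body weight must be positive")
        k_v = body_weight_kg / self.body_weight_kg
        k_q = k_v**exponent
        comps = {
            n: Compartment(n, c.volume_L * k_v, c.flow_L_per_h * k_q)
            for n, c in self.compartments.items()
        }
        return replace(
            self,
            body_weight_kg=body_weight_kg,
            cardiac_output_L_per_h=self.cardiac_output_L_per_h * k_q,
            compartments=comps,
        )


def load_physiology_csv(path, species: str, body_weight_kg: float) -> SpeciesPhysiology:
    """Read a physiology table (columns compartment,volume_L,flow_L_per_h)."""
    df = pd.read_csv(path, comment="#")
    comps = {}
    for row in df.itertuples(index=False):
        name = canonical_tissue_name(row.compartment)
        comps[name] = Compartment(name, float(row.volume_L), float(row.flow_L_per_h))
    co = comps["lung"].flow_L_per_h
    return SpeciesPhysiology(
        species=species,
        body_weight_kg=body_weight_kg,
        cardiac_output_L_per_h=co,
        compartments=comps,
    )


def _reference_csv(species: str):
    return resources.files("opbpk.data").joinpath(f"physiology_{species}.csv")


def get_physiology(
    species: str,
    body_weight_kg: float | None = None,
    *,
    exponent: float = 1.0,
    table: str | Path | None = None,
) -> SpeciesPhysiology:
    """Reference physiology for a species, rescaled to ``body_weight_kg``.

    Parameters
    ----------
    species : {"rat", "human"}
    body_weight_kg : float, optional
        Defaults to the reference animal (0.25 kg rat, 70 kg human).
    exponent : float
        Allometric exponent for the rescale; 1.0 = linear.
    table : path, optional
        Substitute a user physiology CSV for the bundled reference table.
    """
    species = str(species).lower()
    if species not in REFERENCE_BODY_WEIGHT_KG:
        raise UnsupportedSpeciesError(species)
    if body_weight_kg is None:
        body_weight_kg = REFERENCE_BODY_WEIGHT_KG[species]
    if body_weight_kg <= 0:
        raise DomainError("body weight must be positive")
    src = table if table is not None else _reference_csv(species)
    ref = load_physiology_csv(src, species, REFERENCE_BODY_WEIGHT_KG[species])
    if body_weight_kg == ref.body_weight_kg:
        return ref
    return ref.rescaled(body_weight_kg, exponent=exponent)
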