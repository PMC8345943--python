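"""Physical parameters of the base pendulums and of the external drive.

All quantities are SI internally: moments of inertia in kg·m², backbone
radii in m, torsional constants in J, pair stiffnesses in N/m, dissipation
coefficients in J·s.  The built-in default table converts the published
scaled columns (×10⁻⁴⁴ kg·m², Å, ×10⁻¹⁸ J, ×10⁻² N/m, ×10⁻³⁴ J·s) once at
construction so that no scaling factors survive into the dynamics code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

PAIR_AT = "AT"
PAIR_GC = "GC"


def pair_type(base: str) -> str:
    """Which Watson–Crick pair ('AT' or 'GC') a chain-1 base belongs to."""
    if base in "AT":
        return PAIR_AT
    if base in "GC":
        return PAIR_GC
    raise ValueError(f"invalid base symbol {base!r}")


@dataclass(frozen=True)
class BaseParams:
    """Constants of one base type.

    I     moment of inertia about the backbone, kg·m²
    R     distance from the base's center of mass to the backbone, m
    K     torsional constant of the adjoining backbone segment, J
    beta  viscous dissipation coefficient of rotation in the solvent, J·s
          (beta = 0 selects the conservative, undamped limit)
    """

    I: float
    R: float
    K: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("I", "R", "K"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if self.beta < 0.0:
            raise ValueError("beta must be non-negative")


@dataclass(frozen=True)
class ForceSpec:
    """Uniform external drive F0·cos(omega·t) applied to every pendulum.

    F0 is the torque amplitude in J; omega the angular frequency in s⁻¹.
    omega = 0 gives a constant force switched on at t = 0.
    """

    F0: float = 0.0
    omega: float = 0.0

    def __post_init__(self) -> None:
        if self.F0 < 0.0:
            raise ValueError("F0 must be non-negative")
        if self.omega < 0.0:
            raise ValueError("omega must be non-negative")


@dataclass(frozen=True)
class ParamTable:
    """Per-base mechanical constants plus per-pair hydrogen-bond stiffness.

    ``bases`` maps each of A, C, G, T to its :class:`BaseParams`; ``k12``
    maps the pair type ('AT' / 'GC') to the elastic constant of the
    inter-chain bond in N/m.  k12 is a property of the pair and is seen with
    the same value from either chain.
    """

    bases: dict
    k12: dict

    def __post_init__(self) -> None:
        missing = {"A", "C", "G", "T"} - set(self.bases)
        if missing:
            raise ValueError(f"parameter table incomplete: missing bases {sorted(missing)}")
        if set(self.k12) != {PAIR_AT, PAIR_GC}:
            raise ValueError("k12 must be given for exactly the 'AT' and 'GC' pair types")
        for p, v in self.k12.items():
            if v <= 0.0:
                raise ValueError(f"k12[{p}] must be strictly positive")

    def __getitem__(self, base: str) -> BaseParams:
        return self.bases[base]

    def k12_for(self, base: str) -> float:
        return self.k12[pair_type(base)]

    def with_beta_scale(self, scale: float) -> "ParamTable":
        """A copy with every dissipation coefficient multiplied by ``scale``.

        ``scale=0`` turns off damping everywhere (conservative dynamics).
        """
        bases = {
            b: dataclasses.replace(p, beta=p.beta * scale) for b, p in self.bases.items()
        }
        return ParamTable(bases=bases, k12=dict(self.k12))

    def to_yaml(self, path) -> None:
        doc = {
            "units": {
                "I": "kg*m^2",
                "R": "m",
                "K": "J",
                "beta": "J*s",
                "k12": "N/m",
            },
            "bases": {
                b: {"I": p.I, "R": p.R, "K": p.K, "beta": p.beta}
                for b, p in sorted(self.bases.items())
            },
            "k12": dict(self.k12),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "ParamTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        bases = {
            b: BaseParams(I=v["I"], R=v["R"], K=v["K"], beta=v["beta"])
            for b, v in doc["bases"].items()
        }
        return cls(bases=bases, k12={k: float(v) for k, v in doc["k12"].items()})

    @classmethod
    def default(cls) -> "ParamTable":
        """The published coefficient table, already in SI."""
        return cls(
            bases={
                "A": BaseParams(I=7.61e-44, R=5.80e-10, K=2.35e-18, beta=4.25e-34),
                "T": BaseParams(I=4.86e-44, R=4.80e-10, K=1.61e-18, beta=2.91e-34),
                "G": BaseParams(I=8.22e-44, R=5.70e-10, K=2.27e-18, beta=4.10e-34),
                "C": BaseParams(I=4.11e-44, R=4.70e-10, K=1.54e-18, beta=2.79e-34),
            },
            k12={PAIR_AT: 6.20e-2, PAIR_GC: 9.60e-2},
        )
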