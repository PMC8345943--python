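"""Equations of motion of the two coupled pendulum chains.

Each base pair i carries two pendulums: base i of chain 1 (rest angle 0) and
its complementary base on chain 2 (rest angle π).  Newton's equations for
the rotation angles φ₁ᵢ, φ₂ᵢ contain three torques per pendulum:

* torsional coupling along the backbone, Kⱼᵢ[φⱼ,ᵢ₋₁ − 2φⱼᵢ + φⱼ,ᵢ₊₁] for
  interior sites, degenerating to a single-neighbour term at the free ends;
* the elastic pair interaction through the hydrogen bond, built from
  k₁₂ᵢR₁ᵢ(R₁ᵢ+R₂ᵢ)·sin φ and k₁₂ᵢR₁ᵢR₂ᵢ·sin(φ₁ᵢ−φ₂ᵢ) terms;
* the external influence Fⱼᵢ(t) = −βⱼᵢ·dφⱼᵢ/dt + F₀·cos ωt.

Two sign conventions for the chain-2 pair torque are shipped.  The
``as_printed`` variant keeps the sign structure of the source equations
(+k₁₂R₁(R₁+R₂)·sin φ₂ − k₁₂R₁R₂·sin(φ₁−φ₂)), under which the rest state
(0, π) is a stable equilibrium of a homoduplex but is *not* the gradient of
any potential.  The ``potential_consistent`` variant replaces it by the
negative gradient of the elastic pair energy, which makes the β=0, F₀=0
dynamics exactly conservative and therefore testable against an energy
functional, at the price of turning (0, π) into a saddle.

Numerically the chain-2 pair torques are evaluated through ψ₂ = φ₂ − π
using the exact identities sin φ₂ = −sin ψ₂ and
sin(φ₁−φ₂) = −sin(φ₁−ψ₂), so that at the equilibrium state the right-hand
side is exactly zero in floating point (π − π = 0 and sin 0 = 0), not
merely zero to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ForceSpec, ParamTable, pair_type
from .sequence_io import NucleotideSequence

AS_PRINTED = "as_printed"
POTENTIAL_CONSISTENT = "potential_consistent"
VARIANTS = (AS_PRINTED, POTENTIAL_CONSISTENT)


@dataclass
class State:
    """Angles (rad) and angular velocities (rad/s) of all 2n pendulums at time t."""

    t: float
    phi1: np.ndarray
    phi2: np.ndarray
    v1: np.ndarray
    v2: np.ndarray

    def copy(self) -> "State":
        return State(
            self.t, self.phi1.copy(), self.phi2.copy(), self.v1.copy(), self.v2.copy()
        )

    @property
    def n(self) -> int:
        return self.phi1.shape[0]

    def to_flat(self) -> np.ndarray:
        """Pack as [φ₁, φ₂, v₁, v₂] for generic ODE machinery."""
        return np.concatenate([self.phi1, self.phi2, self.v1, self.v2])

    @classmethod
    def from_flat(cls, t: float, y: np.ndarray) -> "State":
        n = y.shape[0] // 4
        return cls(t, y[:n].copy(), y[n : 2 * n].copy(), y[2 * n : 3 * n].copy(), y[3 * n :].copy())

    def validate(self, n: int) -> None:
        for name in ("phi1", "phi2", "v1", "v2"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"state array {name} has shape {arr.shape}, expected ({n},)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"state array {name} contains non-finite entries")


@dataclass(frozen=True)
class StateDerivative:
    """Time derivative of a :class:`State`: dφ/dt and dv/dt arrays."""

    dphi1: np.ndarray
    dphi2: np.ndarray
    dv1: np.ndarray
    dv2: np.ndarray


@dataclass(frozen=True)
class DuplexSystem:
    """A fully parameterized duplex: sequences, coefficient arrays, drive.

    The per-index arrays are filled from the parameter table by base
    identity: entry i of the chain-1 arrays belongs to chain1[i], entry i of
    the chain-2 arrays to its complement.  k12 depends only on whether pair
    i is A·T or G·C.
    """

    chain1: NucleotideSequence
    chain2: NucleotideSequence
    I1: np.ndarray
    I2: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    K1: np.ndarray
    K2: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    k12: np.ndarray
    force: ForceSpec
    variant: str = AS_PRINTED
    # precomputed pair-torque coefficients (derived, not independent inputs)
    c_on1: np.ndarray = field(default=None, repr=False)
    c_on2: np.ndarray = field(default=None, repr=False)
    c_cross: np.ndarray = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.chain1)

    def is_homopolymer(self) -> bool:
        return len(set(self.chain1.symbols)) == 1


def build_system(
    seq: NucleotideSequence,
    params: ParamTable | None = None,
    force: ForceSpec | None = None,
    variant: str = AS_PRINTED,
) -> DuplexSystem:
    """Assemble the mechanical system for a chain-1 sequence.

    Chain 2 is the base-wise complement; every coefficient array is filled
    per base identity of the respective chain, so e.g. an A at chain-1
    position i gives I1[i] = I(A), a T across the pair with I2[i] = I(T),
    and k12[i] = k12(A·T).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown rhs variant {variant!r}; choose from {VARIANTS}")
    params = params if params is not None else ParamTable.default()
    force = force if force is not None else ForceSpec()
    chain2 = seq.complement()

    def gather(attr: str, chain: NucleotideSequence) -> np.ndarray:
        return np.array([getattr(params[b], attr) for b in chain], dtype=float)

    k12 = np.array([params.k12[pair_type(b)] for b in seq], dtype=float)
    R1 = gather("R", seq)
    R2 = gather("R", chain2)
    sys = DuplexSystem(
        chain1=seq,
        chain2=chain2,
        I1=gather("I", seq),
        I2=gather("I", chain2),
        R1=R1,
        R2=R2,
        K1=gather("K", seq),
        K2=gather("K", chain2),
        beta1=gather("beta", seq),
        beta2=gather("beta", chain2),
        k12=k12,
        force=force,
        variant=variant,
        c_on1=k12 * R1 * (R1 + R2),
        c_on2=k12 * R2 * (R1 + R2),
        c_cross=k12 * R1 * R2,
    )
    return sys


def external_torque(t: float, v, beta, force: ForceSpec):
    """External influence F(t) = −β·v + F₀·cos(ωt) on one or many pendulums.

    With ω = 0 the drive reduces to the constant torque F₀ switched on at
    t = 0.  Accepts scalars or arrays for v and beta.
    """
    return -beta * v + force.F0 * np.cos(force.omega * t)


def equilibrium_state(n: int) -> State:
    """The rest state at t = 0: φ₁ᵢ = 0, φ₂ᵢ = π, all velocities zero."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return State(
        t=0.0,
        phi1=np.zeros(n),
        phi2=np.full(n, np.pi),
        v1=np.zeros(n),
        v2=np.zeros(n),
    )


def _free_end_laplacian(K: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Kᵢ·[φᵢ₋₁ − 2φᵢ + φᵢ₊₁] with single-neighbour ends; zero for n = 1."""
    out = np.empty_like(phi)
    if phi.shape[0] == 1:
        out[0] = 0.0
        return out
    out[1:-1] = phi[:-2] - 2.0 * phi[1:-1] + phi[2:]
    out[0] = phi[1] - phi[0]
    out[-1] = phi[-2] - phi[-1]
    out *= K
    return out


def rhs(state: State, system: DuplexSystem) -> StateDerivative:
    """Right-hand side of the 4n-dimensional first-order system."""
    state.validate(system.n)
    phi1, phi2, v1, v2 = state.phi1, state.phi2, state.v1, state.v2
    psi2 = phi2 - np.pi
    sin1 = np.sin(phi1)
    sin_psi2 = np.sin(psi2)
    # sin(φ₁ − φ₂) = −sin(φ₁ − ψ₂), exactly
    sin_diff = np.sin(phi1 - psi2)
    drive = system.force.F0 * np.cos(system.force.omega * state.t)

    a1 = _free_end_laplacian(system.K1, phi1)
    a1 -= system.c_on1 * sin1
    a1 += system.c_cross * sin_diff  # −c_cross·sin(φ₁−φ₂)
    a1 += -system.beta1 * v1 + drive
    a1 /= system.I1

    a2 = _free_end_laplacian(system.K2, phi2)
    if system.variant == AS_PRINTED:
        # +c_on1·sin φ₂ − c_cross·sin(φ₁−φ₂)
        a2 += -system.c_on1 * sin_psi2 + system.c_cross * sin_diff
    else:
        # −c_on2·sin φ₂ + c_cross·sin(φ₁−φ₂): negative pair-energy gradient
        a2 += system.c_on2 * sin_psi2 - system.c_cross * sin_diff
    a2 += -system.beta2 * v2 + drive
    a2 /= system.I2

    return StateDerivative(dphi1=v1.copy(), dphi2=v2.copy(), dv1=a1, dv2=a2)


def rhs_flat(t: float, y: np.ndarray, system: DuplexSystem) -> np.ndarray:
    """Flat-vector form of :func:`rhs` for scipy's ODE solvers."""
    n = system.n
    state = State(t, y[:n], y[n : 2 * n], y[2 * n : 3 * n], y[3 * n :])
    d = rhs(state, system)
    return np.concatenate([d.dphi1, d.dphi2, d.dv1, d.dv2])


def total_energy(state: State, system: DuplexSystem) -> float:
    """Total mechanical energy (J) of the conservative homoduplex variant.

    E = kinetic + torsional spring energy of both backbones + elastic pair
    energy; the pair energy per site is

        k₁₂[R₁(R₁+R₂)(1−cos φ₁) + R₂(R₁+R₂)(1−cos φ₂) + R₁R₂(1−cos(φ₁−φ₂))].

    Only defined for ``potential_consistent`` systems on homopolymer
    sequences: with site-varying K the torsional force term is not the
    gradient of a symmetric spring energy, and the printed chain-2 torque is
    not the gradient of anything, so an energy for those cases would be
    meaningless.
    """
    if system.variant != POTENTIAL_CONSISTENT:
        raise ValueError("total_energy is defined only for the potential_consistent variant")
    if not system.is_homopolymer():
        raise ValueError("total_energy is defined only for homopolymer sequences")
    state.validate(system.n)
    kin = 0.5 * np.sum(system.I1 * state.v1**2 + system.I2 * state.v2**2)
    K1 = system.K1[0]
    K2 = system.K2[0]
    tor = 0.5 * K1 * np.sum(np.diff(state.phi1) ** 2) + 0.5 * K2 * np.sum(
        np.diff(state.phi2) ** 2
    )
    psi2 = state.phi2 - np.pi
    # 1 − cos φ₂ = 1 + cos ψ₂ ; 1 − cos(φ₁−φ₂) = 1 + cos(φ₁−ψ₂)
    pair = np.sum(
        system.c_on1 * (1.0 - np.cos(state.phi1))
        + system.c_on2 * (1.0 + np.cos(psi2))
        + system.c_cross * (1.0 + np.cos(state.phi1 - psi2))
    )
    return float(kin + tor + pair)
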