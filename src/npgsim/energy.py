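"""Integrin reaction energetics on nanoporous gold (NPG) substrates.

Three reversible reactions drive focal-adhesion formation in the model:
activation of a single integrin (inside-out signalling, substrate
independent), binding of an active integrin to an ECM ligand, and
association between neighbouring bound integrins.  Each reaction is
characterised by a forward rate and an energy in kT units; the reverse
rate follows from the equilibrium ratio

    k_a+ / k_a- = exp(-E_a)        (activation)
    k_b+ / k_b- = exp(+E_b)        (binding)
    k_c+ / k_c- = exp(+E_c)        (association)

The substrate enters through the pore-size and gold-concentration
dependence of the binding and association energies:

    E_b = alpha * c * B / r_p + A * c
    E_c = beta  * c * r_p / r_max + C      (or a constant 6.2 kT)

with A = 3.5 kT, B = -12 kT nm, C = 5.2 kT, r_max = 150 nm.  Binding is
*weakened* by small pores (B < 0) and association is weakened as well
(r_p/r_max < 1), so both energies increase monotonically with pore size.
Flat gold behaves like the r_p -> infinity limit for binding and like the
r_p = r_max substrate for association.

All energies are in kT; temperature never appears separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "EnergyParams",
    "FLAT_GOLD",
    "SCENARIOS",
    "scenario_params",
    "activation_ratio",
    "binding_energy",
    "association_energy",
    "reverse_rate",
    "step_probability",
    "pair_step_probabilities",
]

#: Sentinel pore size for the flat-gold control substrate.  Binding sees the
#: r_p -> infinity limit (the B/r_p term vanishes); association is evaluated
#: at r_p = r_max, the pore size whose clustering matches flat gold.
FLAT_GOLD: float = math.inf


@dataclass(frozen=True)
class EnergyParams:
    """All constants of the three-reaction energy model.

    Energies are in kT, rates in 1/s, lengths in nm.  Defaults are the
    model's published operating point.
    """

    E_a: float = 3.0          # activation energy, kT
    A: float = 3.5            # binding offset coefficient, kT
    B: float = -12.0          # binding pore-size coefficient, kT nm
    C: float = 5.2            # association offset, kT
    r_max: float = 150.0      # pore size matching flat gold, nm
    alpha: float = 1.0        # intensity of the NPG effect on binding
    beta: float = 1.0         # intensity of the NPG effect on association
    k_a_plus: float = 10.0    # activation forward rate, 1/s
    k_b_plus: float = 10.0    # binding forward rate, 1/s
    k_c_plus: float = 1.0     # association forward rate, 1/s
    dt: float = 0.010         # Monte Carlo step interval, s
    constant_Ec: bool = False # freeze E_c at 6.2 kT (pore-independent association)

    def __post_init__(self) -> None:
        for name in ("k_a_plus", "k_b_plus", "k_c_plus", "dt", "r_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


#: E_c value used when association is pore-size independent.  Equals the
#: non-constant form at r_p = r_max, c = 1, beta = 1.
E_C_CONSTANT: float = 6.2

#: Scenario presets for the four simulated conditions: pore-size-dependent
#: binding with constant association (fig5b), both energies pore-dependent
#: at normal (fig5c), weak (fig5d) and strong (fig5e) substrate coupling.
SCENARIOS: dict[str, dict[str, float | bool]] = {
    "fig5b": {"alpha": 1.0, "beta": 1.0, "constant_Ec": True},
    "fig5c": {"alpha": 1.0, "beta": 1.0, "constant_Ec": False},
    "fig5d": {"alpha": 0.5, "beta": 0.5, "constant_Ec": False},
    "fig5e": {"alpha": 2.5, "beta": 2.0, "constant_Ec": False},
}


def scenario_params(name: str, base: EnergyParams | None = None) -> EnergyParams:
    """Return :class:`EnergyParams` for a named scenario preset."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    return replace(base or EnergyParams(), **SCENARIOS[name])


def activation_ratio(params: EnergyParams) -> float:
    """Equilibrium ratio k_a+/k_a- = exp(-E_a) of integrin activation."""
    return math.exp(-params.E_a)


def _check_pore_size(r_p: float) -> None:
    if not (r_p > 0):
        raise ValueError(f"pore size r_p must be positive (or FLAT_GOLD), got {r_p}")


def binding_energy(r_p: float, c: float, params: EnergyParams) -> float:
    """Integrin--ECM binding energy E_b = alpha*c*B/r_p + A*c, in kT.

    ``r_p`` is the substrate pore size in nm, or :data:`FLAT_GOLD` for the
    flat control (the 1/r_p term vanishes).  ``c`` is the local gold
    concentration in [0, 1]; both terms scale with c, so E_b = 0 over a pore.
    """
    _check_pore_size(r_p)
    if math.isinf(r_p):
        return params.A * c
    return params.alpha * c * params.B / r_p + params.A * c


def association_energy(
    r_p: float, c: float, params: EnergyParams, constant_mode: bool | None = None
) -> float:
    """Integrin--integrin association energy E_c, in kT.

    In constant mode the association is substrate independent and E_c is
    6.2 kT regardless of the inputs.  Otherwise E_c = beta*c*r_p/r_max + C,
    with flat gold mapped to the r_p = r_max value.
    """
    _check_pore_size(r_p)
    if constant_mode is None:
        constant_mode = params.constant_Ec
    if constant_mode:
        return E_C_CONSTANT
    if math.isinf(r_p):
        r_p = params.r_max
    return params.beta * c * r_p / params.r_max + params.C


Direction = Literal["favors_forward", "favors_reverse"]


def reverse_rate(k_plus: float, energy_kT: float, direction: Direction) -> float:
    """Reverse rate making the stated forward/reverse ratio hold.

    ``favors_reverse`` is the activation convention k+/k- = exp(-E), giving
    k- = k+ * exp(+E); ``favors_forward`` is the binding/association
    convention k+/k- = exp(+E), giving k- = k+ * exp(-E).
    """
    if k_plus <= 0:
        raise ValueError(f"forward rate must be positive, got {k_plus}")
    if direction == "favors_reverse":
        return k_plus * math.exp(energy_kT)
    if direction == "favors_forward":
        return k_plus * math.exp(-energy_kT)
    raise ValueError(f"unknown direction {direction!r}")


def step_probability(k: float, dt: float) -> float:
    """Probability 1 - exp(-k*dt) that a Poisson channel of rate k fires
    at least once within one step of length dt.  Always < 1, and ~ k*dt
    for small k*dt.
    """
    if k < 0:
        raise ValueError(f"rate must be non-negative, got {k}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return -math.expm1(-k * dt)


def pair_step_probabilities(k_fwd: float, k_rev: float, dt: float) -> tuple[float, float]:
    """Exact per-step transition probabilities of a reversible rate pair.

    For a two-state continuous-time channel with rates (k_fwd, k_rev), the
    probability of observing a forward (reverse) switch over an interval dt
    is k_fwd/(k_fwd+k_rev) * (1 - exp(-(k_fwd+k_rev)*dt)) (respectively with
    k_rev in the numerator).  The engine uses this mapping because it keeps
    the stationary ratio of every reaction pair equal to k_fwd/k_rev exactly
    at any finite dt — the naive per-channel form 1 - exp(-k*dt) distorts the
    equilibrium whenever k*dt is not small (here k_a- * dt ~ 2) — while both
    reduce to k*dt as dt -> 0.
    """
    if k_fwd < 0 or k_rev < 0:
        raise ValueError("rates must be non-negative")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    total = k_fwd + k_rev
    if total == 0.0:
        return 0.0, 0.0
    g = -math.expm1(-total * dt)
    p_fwd = g * k_fwd / total
    # complement within the switching mass g, so p_fwd + p_rev <= 1 holds
    # exactly in floating point (the engine's channel-sum guard relies on it)
    return p_fwd, g - p_fwd
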