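"""Temperature-dependent Metabolic Index model and trait algebra.

The central quantity is the Metabolic Index ``Phi``, the ratio of
organismal O2 supply to the O2 demand of an ecologically active
population.  A species with active hypoxia tolerance ``A_eco`` (1/atm)
and temperature sensitivity ``E_eco`` (eV) is metabolically viable where

    Phi(pO2, T) = A_eco * pO2 / f(E_eco(T), T) >= 1,

with the Arrhenius factor

    f(E, T) = exp(-E/k_B * (1/T_K - 1/Tref_K)).

``Phi`` here is normalized to the *active* threshold: ``Phi = 1``
exactly at the minimum viable partial pressure ``pO2_act``.  In terms of
the resting-state index this is Phi/Phi_crit; biogeographic fitting can
only constrain the product A_o/Phi_crit, never the factors separately.

The effective activation energy is allowed to vary linearly with
temperature, ``E_eco(T) = E_eco_ref + dEdT * (T - T_ref)``, a one-extra-
parameter summary of the multi-step nature of physiological O2 supply
(diffusion dominating in warm water, ventilation/circulation in cold).

Temperatures are in degrees Celsius everywhere in the public API and are
converted to Kelvin only inside :func:`arrhenius_factor`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import CELSIUS_OFFSET, K_B, T_REF_DEFAULT
from .errors import InvalidInputError, InvalidTraitError

__all__ = [
    "TraitSet",
    "RestingTraits",
    "arrhenius_factor",
    "effective_activation_energy",
    "po2_act",
    "metabolic_index",
    "compose_e_eco",
    "aeco_from_components",
]


def _check_finite(name, value):
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")
    return arr


@dataclass(frozen=True)
class TraitSet:
    """A species' diagnosed active hypoxia traits.

    Parameters
    ----------
    species_id : str
        Identifier used to join against occurrence and lab tables.
    A_eco : float
        Active hypoxia tolerance, 1/atm; strictly positive.  The
        reciprocal ``1/A_eco`` is the minimum viable pO2 at ``T_ref``.
    E_eco_ref : float
        Temperature sensitivity of active hypoxia tolerance at
        ``T_ref``, eV.
    dEdT : float
        Slope of the effective activation energy with temperature,
        eV/degC.  Diagnosed means are positive; negative values are
        rejected unless ``allow_negative_dedt`` is set.
    T_ref : float
        Reference temperature, degC (default 15).
    """

    species_id: str
    A_eco: float
    E_eco_ref: float
    dEdT: float = 0.0
    T_ref: float = T_REF_DEFAULT
    allow_negative_dedt: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        for name in ("A_eco", "E_eco_ref", "dEdT", "T_ref"):
            _check_finite(name, getattr(self, name))
        if self.A_eco <= 0:
            raise InvalidTraitError(f"A_eco must be > 0, got {self.A_eco}")
        if self.dEdT < 0 and not self.allow_negative_dedt:
            raise InvalidTraitError(
                f"dEdT must be >= 0 (got {self.dEdT}); pass "
                "allow_negative_dedt=True to relax"
            )


@dataclass(frozen=True)
class RestingTraits:
    """Laboratory (resting-state) traits; all fields optional.

    ``A_o = 1/V_h`` is resting hypoxia tolerance; ``Phi_crit`` the ratio
    of sustained to resting metabolic rate (between 1 and the factorial
    aerobic scope FAS = MMR:RMR); ``E_o = E_d - E_s`` its temperature
    sensitivity split into demand and supply activation energies;
    ``E_phicrit`` the temperature sensitivity of Phi_crit; ``alpha_S``
    and ``alpha_D`` the O2 supply efficacy and resting demand
    coefficients with ``A_o = alpha_S/alpha_D``.
    """

    species_id: str
    A_o: float | None = None
    V_h: float | None = None
    E_o: float | None = None
    Phi_crit: float | None = None
    FAS: float | None = None
    E_d: float | None = None
    E_s: float | None = None
    E_phicrit: float | None = None
    alpha_S: float | None = None
    alpha_D: float | None = None

    def __post_init__(self):
        if self.A_o is not None and self.V_h is not None:
            if not np.isclose(self.A_o * self.V_h, 1.0, rtol=1e-6):
                raise InvalidTraitError(
                    f"A_o * V_h must equal 1 (got {self.A_o * self.V_h})"
                )
        if self.Phi_crit is not None:
            if self.Phi_crit < 1:
                raise InvalidTraitError(f"Phi_crit must be >= 1, got {self.Phi_crit}")
            if self.FAS is not None and self.Phi_crit > self.FAS:
                raise InvalidTraitError(
                    f"Phi_crit ({self.Phi_crit}) exceeds FAS ({self.FAS})"
                )


def _maybe_scalar(out, *inputs):
    if all(np.ndim(x) == 0 for x in inputs):
        return float(out)
    return out


def arrhenius_factor(E, T, T_ref=T_REF_DEFAULT):
    """Arrhenius temperature factor ``f(E, T)``.

    ``f = exp(-E/k_B * (1/T_K - 1/Tref_K))`` with temperatures converted
    to Kelvin internally.  Strictly increasing in ``T`` iff ``E > 0``,
    and identically 1 at ``T = T_ref`` or ``E = 0``.

    Parameters are broadcast; scalars in, scalar out.
    """
    E = _check_finite("E", E)
    T = _check_finite("T", T)
    T_ref = _check_finite("T_ref", T_ref)
    if np.any(T <= -CELSIUS_OFFSET) or np.any(T_ref <= -CELSIUS_OFFSET):
        raise InvalidInputError("temperatures must exceed absolute zero (-273.15 C)")
    t_k = T + CELSIUS_OFFSET
    tref_k = T_ref + CELSIUS_OFFSET
    out = np.exp(-E / K_B * (1.0 / t_k - 1.0 / tref_k))
    return _maybe_scalar(out, E, T, T_ref)


def effective_activation_energy(traits: TraitSet, T):
    """Linear-in-T effective activation energy, eV.

    ``E_eco(T) = E_eco_ref + dEdT * (T - T_ref)``.
    """
    T = _check_finite("T", T)
    out = traits.E_eco_ref + traits.dEdT * (T - traits.T_ref)
    return _maybe_scalar(out, T)


def po2_act(traits: TraitSet, T):
    """Minimum viable O2 partial pressure for an active population, atm.

    ``pO2_act(T) = f(E_eco(T), T) / A_eco``; always positive.
    """
    if traits.A_eco <= 0:
        raise InvalidTraitError(f"A_eco must be > 0, got {traits.A_eco}")
    f = arrhenius_factor(effective_activation_energy(traits, T), T, traits.T_ref)
    out = np.asarray(f, dtype=float) / traits.A_eco
    return _maybe_scalar(out, T)


def metabolic_index(pO2, T, traits: TraitSet):
    """Metabolic Index ``Phi``, normalized to the active threshold.

    ``Phi = A_eco * pO2 / f(E_eco(T), T)``, so that ``Phi >= 1`` exactly
    where ``pO2 >= pO2_act(T)``.
    """
    pO2 = _check_finite("pO2", pO2)
    if np.any(pO2 < 0):
        raise InvalidInputError("pO2 must be >= 0")
    f = arrhenius_factor(effective_activation_energy(traits, T), T, traits.T_ref)
    out = traits.A_eco * pO2 / np.asarray(f, dtype=float)
    return _maybe_scalar(out, pO2, T)


def compose_e_eco(E_d, E_s, E_phicrit):
    """Compose the active temperature sensitivity from its parts, eV.

    ``E_eco = E_o + E_phicrit = E_d - E_s + E_phicrit``: metabolic
    demand minus physiological O2 supply, plus the temperature
    sensitivity of the sustained:resting metabolic-rate ratio.
    """
    E_d = _check_finite("E_d", E_d)
    E_s = _check_finite("E_s", E_s)
    E_phicrit = _check_finite("E_phicrit", E_phicrit)
    out = E_d - E_s + E_phicrit
    return _maybe_scalar(out, E_d, E_s, E_phicrit)


def aeco_from_components(
    Phi_crit,
    *,
    A_o=None,
    V_h=None,
    alpha_S=None,
    alpha_D=None,
    strict_phicrit=False,
):
    """Active hypoxia tolerance from resting-state components, 1/atm.

    Exactly one of the resting parameterizations must be supplied:
    ``A_o`` (giving ``A_o / Phi_crit``), ``V_h`` (``1/(V_h*Phi_crit)``),
    or the pair ``(alpha_S, alpha_D)`` (``alpha_S/(alpha_D*Phi_crit)``).
    The three forms agree when ``A_o = 1/V_h = alpha_S/alpha_D``.

    ``Phi_crit < 1`` warns by default (an active population cannot spend
    less than resting); set ``strict_phicrit=True`` to raise instead.
    """
    Phi_crit = float(_check_finite("Phi_crit", Phi_crit))
    if Phi_crit < 1:
        msg = f"Phi_crit < 1 is unphysical (got {Phi_crit})"
        if strict_phicrit:
            raise InvalidTraitError(msg)
        warnings.warn(msg, stacklevel=2)
    sources = {"A_o": A_o, "V_h": V_h, "alpha": alpha_S if alpha_S is not None else alpha_D}
    supplied = [k for k, v in sources.items() if v is not None]
    if len(supplied) != 1:
        raise InvalidInputError(
            "supply exactly one of A_o, V_h or (alpha_S, alpha_D); "
            f"got {supplied or 'none'}"
        )
    if Phi_crit == 0:
        raise InvalidInputError("Phi_crit must be nonzero")
    if A_o is not None:
        return float(_check_finite("A_o", A_o)) / Phi_crit
    if V_h is not None:
        V_h = float(_check_finite("V_h", V_h))
        if V_h == 0:
            raise InvalidInputError("V_h must be nonzero")
        return 1.0 / (V_h * Phi_crit)
    if alpha_S is None or alpha_D is None:
        raise InvalidInputError("alpha_S and alpha_D must be supplied together")
    alpha_S = float(_check_finite("alpha_S", alpha_S))
    alpha_D = float(_check_finite("alpha_D", alpha_D))
    if alpha_D == 0:
        raise InvalidInputError("alpha_D must be nonzero")
    return alpha_S / (alpha_D * Phi_crit)
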