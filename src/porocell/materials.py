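"""Poroelastic material parameters for cell compartments.

The cytoplasm is treated as a biphasic (poroelastic) medium: a drained
elastic skeleton of Young's modulus ``E`` [Pa] and Poisson ratio ``nu``,
permeated by an incompressible interstitial fluid that flows down pore
pressure gradients with hydraulic permeability ``k`` [um^2/(Pa s)]
(Darcy's law, v = -k grad p).  Pressure equilibration is diffusive with
the consolidation (poroelastic diffusion) constant

    D = k * M_oed,    M_oed = E (1 - nu) / ((1 + nu)(1 - 2 nu)),

the oedometric (confined-compression) modulus of the drained skeleton.
Exactly one of ``D`` or ``k`` is given; the other is derived through this
mapping.  Internal units throughout the package: um, s, Pa, nN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MaterialRegion",
    "oedometric_modulus",
    "d_from_k",
    "k_from_d",
    "k_si_to_internal",
    "k_internal_to_si",
]

#: 1 m^2/(Pa s) expressed in um^2/(Pa s): 1 m^2 = 1e12 um^2.
_M2_TO_UM2 = 1.0e12


def oedometric_modulus(E: float, nu: float) -> float:
    """Confined-compression (oedometric) modulus of the drained skeleton [Pa]."""
    return E * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))


def d_from_k(k: float, E: float, nu: float) -> float:
    """Poroelastic diffusion constant D [um^2/s] from permeability k [um^2/(Pa s)]."""
    return k * oedometric_modulus(E, nu)


def k_from_d(D: float, E: float, nu: float) -> float:
    """Hydraulic permeability k [um^2/(Pa s)] from diffusion constant D [um^2/s]."""
    return D / oedometric_modulus(E, nu)


def k_si_to_internal(k_si: float) -> float:
    """Convert permeability from m^2/(Pa s) to um^2/(Pa s).

    Example: 1.25e-13 m^2/(Pa s) -> 0.125 um^2/(Pa s).
    """
    return k_si * _M2_TO_UM2


def k_internal_to_si(k: float) -> float:
    """Convert permeability from um^2/(Pa s) to m^2/(Pa s)."""
    return k / _M2_TO_UM2


@dataclass
class MaterialRegion:
    """Drained elastic and transport parameters of one labelled subdomain.

    Parameters
    ----------
    label:
        Subdomain name, ``"cytoplasm"`` or ``"cortex"``.
    E:
        Drained Young's modulus [Pa], > 0.
    nu:
        Drained Poisson ratio, in (0, 0.5).
    D:
        Poroelastic diffusion constant [um^2/s].  Give exactly one of
        ``D`` and ``k``; the other is derived.
    k:
        Hydraulic permeability [um^2/(Pa s)].
    """

    label: str
    E: float
    nu: float = 0.3
    D: float | None = None
    k: float | None = None
    #: Lame parameters of the drained skeleton, derived.
    lam: float = field(init=False, repr=False)
    mu: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.label not in ("cytoplasm", "cortex"):
            raise ValueError(f"unknown region label {self.label!r}")
        if not self.E > 0:
            raise ValueError("E must be positive")
        if not 0.0 < self.nu < 0.5:
            raise ValueError("nu must lie in (0, 0.5)")
        if (self.D is None) == (self.k is None):
            raise ValueError("give exactly one of D and k")
        if self.D is None:
            if not self.k > 0:
                raise ValueError("k must be positive")
            self.D = d_from_k(self.k, self.E, self.nu)
        else:
            if not self.D > 0:
                raise ValueError("D must be positive")
            self.k = k_from_d(self.D, self.E, self.nu)
        self.lam = self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))
        self.mu = self.E / (2.0 * (1.0 + self.nu))
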