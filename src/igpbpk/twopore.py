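"""Two-pore transcapillary transport.

Capillary walls are modelled as parallel populations of small and large
cylindrical pores.  A solute of Stokes–Einstein radius :math:`a_e` interacts
with a pore of radius :math:`r` through the ratio :math:`\\lambda = a_e/r`:

* equilibrium partition coefficient :math:`\\Phi = (1-\\lambda)^2`,
* diffusive hindrance (Renkin) :math:`H_D = 1 - 2.104\\lambda + 2.09\\lambda^3
  - 0.95\\lambda^5`,
* convective hindrance :math:`1-\\sigma = \\Phi(2-\\Phi)(1-\\lambda^2/3)`,

all clipped to their physical ranges, with complete exclusion
(:math:`\\Phi=0,\\ \\sigma=1`) for :math:`\\lambda \\ge 1`.  Solute flux through
each pore class follows the Patlak convection–diffusion expression; the net
transcapillary fluid flow equals the lymph flow and is split between the pore
classes by their fractional hydraulic conductances plus an isogravimetric
recirculation flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .physiology import TissuePhysiology

#: default Stokes–Einstein size law a_e = C * MW**B (nm, MW in g/mol)
STOKES_C = 0.0483
STOKES_B = 0.386

#: Peclet number below which the series expansion of the Patlak flux is used
PECLET_SERIES_THRESHOLD = 1e-4

# Stokes–Einstein free diffusivity at 37 C
_KB = 1.380649e-23  # J/K
_T = 310.15  # K
_ETA = 6.913e-4  # Pa s, water at 37 C


def stokes_radius(mw: float, c: float = STOKES_C, b: float = STOKES_B) -> float:
    """Stokes–Einstein radius (nm) from molecular weight via a power law."""
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw!r}")
    return c * mw ** b


def free_diffusivity(a_e: float) -> float:
    """Free aqueous diffusivity at 37 C (cm^2/h) for radius ``a_e`` (nm)."""
    if a_e <= 0:
        raise ValueError("solute radius must be positive")
    d_m2_s = _KB * _T / (6.0 * math.pi * _ETA * a_e * 1e-9)
    return d_m2_s * 1e4 * 3600.0  # m^2/s -> cm^2/h


def hindrance(a_e: float, r_pore: float) -> tuple[float, float, float]:
    """Partitioning and hindrance factors for a solute in a cylindrical pore.

    Returns ``(phi, sigma, diffusive_hindrance)`` where ``phi`` is the
    equilibrium partition coefficient, ``sigma`` the osmotic reflection
    coefficient and ``diffusive_hindrance`` the product ``phi * H_D`` entering
    the permeability–surface-area product.  A solute larger than the pore
    (``lambda >= 1``) is fully excluded.
    """
    if a_e <= 0 or r_pore <= 0:
        raise ValueError("a_e and r_pore must be positive")
    lam = a_e / r_pore
    if lam >= 1.0:
        return 0.0, 1.0, 0.0
    phi = (1.0 - lam) ** 2
    renkin = 1.0 - 2.104 * lam + 2.09 * lam ** 3 - 0.95 * lam ** 5
    h_diff = phi * max(renkin, 0.0)
    w = phi * (2.0 - phi) * (1.0 - lam * lam / 3.0)
    sigma = min(max(1.0 - w, 0.0), 1.0)
    return phi, sigma, h_diff


def pore_fluid_flows(lymph_flow: float, alpha_large: float, alpha_small: float,
                     j_iso: float) -> tuple[float, float]:
    """Split the net transcapillary fluid flow between the pore classes.

    ``jv_large = alpha_large * L + j_iso`` and ``jv_small = alpha_small * L -
    j_iso`` so the two flows sum exactly to the lymph flow; the isogravimetric
    flow ``j_iso`` recirculates fluid through the large pores even at zero net
    filtration.
    """
    if lymph_flow <= 0:
        raise ValueError("lymph_flow must be positive")
    if abs(alpha_large + alpha_small - 1.0) > 1e-12:
        raise ValueError("alpha_large + alpha_small must equal 1")
    jv_large = alpha_large * lymph_flow + j_iso
    # algebraically alpha_small*L - j_iso; this form conserves bit-exactly
    jv_small = lymph_flow - jv_large
    if jv_small < 0:
        raise ValueError(
            f"j_iso={j_iso:.6g} exceeds the small-pore share of lymph flow "
            f"({alpha_small * lymph_flow:.6g} L/h); reduce j_iso for this tissue")
    return jv_large, jv_small


def patlak_coefficients(jv: float, sigma: float, ps: float) -> tuple[float, float]:
    """Linear flux coefficients (a, b) with flux = a*c_vasc - b*c_int.

    Derived from the Patlak expression; ``b = a - jv*(1-sigma)`` holds exactly.
    For Peclet numbers below :data:`PECLET_SERIES_THRESHOLD` a series expansion
    is used to avoid 0/0; the two branches agree to better than 1e-9 relative.
    """
    jvs = jv * (1.0 - sigma)
    if ps <= 0.0:
        # no diffusive pathway: pure convection (or no pathway at all)
        return jvs, 0.0
    pe = jvs / ps
    if pe < PECLET_SERIES_THRESHOLD:
        a = ps * (1.0 + pe / 2.0 + pe * pe / 12.0)
    else:
        a = jvs / (-math.expm1(-pe))
    return a, a - jvs


def transcapillary_flux(c_vasc: float, c_int: float, jv: float, sigma: float,
                        ps: float) -> float:
    """Patlak convection–diffusion solute flux through one pore class (umol/h).

    Positive flux is vascular -> interstitial.  Concentrations in uM, flows in
    L/h.
    """
    if c_vasc < 0 or c_int < 0:
        raise ValueError("concentrations must be non-negative")
    if jv < 0 or ps < 0:
        raise ValueError("jv and ps must be non-negative")
    a, b = patlak_coefficients(jv, sigma, ps)
    return a * c_vasc - b * c_int


@dataclass(frozen=True)
class PoreTransport:
    """Resolved two-pore parameters of one tissue for one solute."""

    tissue_id: str
    a_e: float  # nm
    lambda_small: float
    lambda_large: float
    phi_small: float
    phi_large: float
    sigma_small: float
    sigma_large: float
    ps_small: float  # L/h
    ps_large: float  # L/h
    jv_small: float  # L/h
    jv_large: float  # L/h

    @property
    def peclet_small(self) -> float:
        return (self.jv_small * (1 - self.sigma_small) / self.ps_small
                if self.ps_small > 0 else math.inf)

    @property
    def peclet_large(self) -> float:
        return (self.jv_large * (1 - self.sigma_large) / self.ps_large
                if self.ps_large > 0 else math.inf)

    @property
    def flux_coefficients(self) -> tuple[float, float]:
        """Summed linear coefficients (a, b) over both pore classes."""
        a_s, b_s = patlak_coefficients(self.jv_small, self.sigma_small, self.ps_small)
        a_l, b_l = patlak_coefficients(self.jv_large, self.sigma_large, self.ps_large)
        return a_s + a_l, b_s + b_l


def tissue_pore_transport(tissue: TissuePhysiology, mw: float) -> PoreTransport:
    """Resolve the two-pore exchange parameters of one tissue for a solute."""
    a_e = stokes_radius(mw)
    d_free = free_diffusivity(a_e)
    phi_s, sig_s, hd_s = hindrance(a_e, tissue.r_small)
    phi_l, sig_l, hd_l = hindrance(a_e, tissue.r_large)
    # PS (L/h) = (A0/dx)[cm] * D[cm^2/h] * phi * H_D / 1000 [cm^3 -> L]
    ps_s = tissue.aol_small * d_free * hd_s / 1000.0
    ps_l = tissue.aol_large * d_free * hd_l / 1000.0
    jv_l, jv_s = pore_fluid_flows(tissue.lymph_flow, tissue.alpha_large,
                                  tissue.alpha_small, tissue.j_iso)
    return PoreTransport(
        tissue_id=tissue.tissue_id, a_e=a_e,
        lambda_small=a_e / tissue.r_small, lambda_large=a_e / tissue.r_large,
        phi_small=phi_s, phi_large=phi_l,
        sigma_small=sig_s, sigma_large=sig_l,
        ps_small=ps_s, ps_large=ps_l,
        jv_small=jv_s, jv_large=jv_l,
    )


def pore_report(phys, mw: float):
    """Per-tissue diagnostic table of sigma/PS/Peclet for a solute of ``mw``.

    Returns a pandas DataFrame (one row per perfused tissue).
    """
    import pandas as pd

    from .physiology import PERFUSED_TISSUES

    rows = []
    for tid in PERFUSED_TISSUES:
        pt = tissue_pore_transport(phys.tissues[tid], mw)
        rows.append({
            "tissue": tid, "a_e_nm": pt.a_e,
            "sigma_small": pt.sigma_small, "sigma_large": pt.sigma_large,
            "ps_small_L_per_h": pt.ps_small, "ps_large_L_per_h": pt.ps_large,
            "jv_small_L_per_h": pt.jv_small, "jv_large_L_per_h": pt.jv_large,
            "peclet_small": pt.peclet_small, "peclet_large": pt.peclet_large,
        })
    return pd.DataFrame(rows)


def size_law_factor(mw_ratio: float) -> float:
    """Multiplier on a_e when MW is multiplied by ``mw_ratio``."""
    return mw_ratio ** STOKES_B


__all__ = [
    "stokes_radius", "free_diffusivity", "hindrance", "pore_fluid_flows",
    "transcapillary_flux", "patlak_coefficients", "tissue_pore_transport",
    "PoreTransport", "pore_report", "PECLET_SERIES_THRESHOLD",
]
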