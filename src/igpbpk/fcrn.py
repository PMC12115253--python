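"""Endosomal FcRn sub-model.

Drug enters the endothelial endosome of each tissue by fluid-phase
macropinocytosis from the vascular and interstitial sides, binds FcRn at
endosomal pH 6.0 in 1:1 quasi-equilibrium, and leaves either as bound complex
(exocytosed back to the vascular space or transcytosed to the interstitium) or
as unbound drug degraded in the lysosome.  Binding is resolved algebraically at
each instant from the mass-action quadratic; receptor occupancy by endogenous
IgG is not modelled (the exogenous dose operates in the non-competitive,
non-saturating regime).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .physiology import TissuePhysiology

#: fluid-phase pinocytosis rate constant, identical for all tissues (1/h)
DEFAULT_K_PINO = 0.0298


@dataclass
class FcRnParameters:
    """Rate constants of the endosomal pathway.

    ``k_pino`` (1/h) is the pinocytotic uptake rate referenced to the
    endosomal volume.  ``k_rec`` (1/h) moves bound complex out of the
    endosome, a fraction ``fr_vascular`` to the vascular space and the rest to
    the interstitium.  ``k_deg`` (1/h) degrades unbound endosomal drug;
    per-tissue degradation is weighted so the whole-body catabolic clearance
    distributes across tissues by the configured catabolism weights.
    ``uptake_split_vascular`` is the fraction of pinocytotic uptake drawn from
    the vascular (luminal) side.
    """

    k_pino: float = DEFAULT_K_PINO
    k_rec: float = 0.1
    k_deg: float = 1.0
    fr_vascular: float = 0.7
    uptake_split_vascular: float = 0.5

    def validate(self) -> None:
        if self.k_pino <= 0:
            raise ValueError("k_pino must be positive")
        if self.k_rec < 0 or self.k_deg < 0:
            raise ValueError("k_rec and k_deg must be non-negative")
        for name in ("fr_vascular", "uptake_split_vascular"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


def fcrn_equilibrium(c_total: float, fcrn_total: float, kd: float,
                     ) -> tuple[float, float]:
    """1:1 quasi-equilibrium bound/free split of endosomal drug.

    Solves ``cb^2 - (ct + ft + kd) cb + ct ft = 0`` for the physical root with
    the numerically stable quadratic form (small root via the product of the
    roots), so no cancellation occurs when ``kd`` is tiny or the species are
    strongly unbalanced.  Returns ``(c_bound, c_free)`` in the units of the
    inputs.
    """
    if c_total < 0 or fcrn_total < 0 or kd < 0:
        raise ValueError("c_total, fcrn_total and kd must be non-negative")
    if c_total == 0.0 or fcrn_total == 0.0:
        return 0.0, c_total
    s = c_total + fcrn_total + kd
    disc = math.sqrt(s * s - 4.0 * c_total * fcrn_total)
    cb = 2.0 * c_total * fcrn_total / (s + disc)
    cb = min(cb, c_total, fcrn_total)
    return cb, c_total - cb


@dataclass(frozen=True)
class EndosomalRates:
    """Instantaneous endosomal rates of one tissue (umol/h)."""

    uptake_from_vascular: float
    uptake_from_interstitial: float
    recycle_to_vascular: float
    transcytose_to_interstitial: float
    catabolism: float

    @property
    def net_endosomal_gain(self) -> float:
        return (self.uptake_from_vascular + self.uptake_from_interstitial
                - self.recycle_to_vascular - self.transcytose_to_interstitial
                - self.catabolism)


def endosomal_rates(c_total: float, fcrn_total: float, kd: float,
                    params: FcRnParameters, tissue: TissuePhysiology,
                    c_vasc: float, c_int: float,
                    catabolism_weight_scaled: float | None = None,
                    ) -> EndosomalRates:
    """Evaluate all endosomal pathway rates for one tissue.

    ``catabolism_weight_scaled`` defaults to the tissue's raw catabolism
    weight; the engine passes the volume-renormalised weight
    ``w_t * (sum V_e) / V_e_t`` so that at uniform endosomal exposure the
    whole-body catabolic clearance splits across tissues exactly by the
    configured weights.
    """
    params.validate()
    ve = tissue.v_endosomal
    cb, cf = fcrn_equilibrium(c_total, fcrn_total, kd)
    s = params.uptake_split_vascular
    w = (tissue.catabolism_weight if catabolism_weight_scaled is None
         else catabolism_weight_scaled)
    return EndosomalRates(
        uptake_from_vascular=params.k_pino * ve * s * c_vasc,
        uptake_from_interstitial=params.k_pino * ve * (1.0 - s) * c_int,
        recycle_to_vascular=params.k_rec * params.fr_vascular * cb * ve,
        transcytose_to_interstitial=params.k_rec * (1.0 - params.fr_vascular) * cb * ve,
        catabolism=params.k_deg * w * cf * ve,
    )


__all__ = ["FcRnParameters", "fcrn_equilibrium", "endosomal_rates",
           "EndosomalRates", "DEFAULT_K_PINO"]
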