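"""Species physiology tables for the whole-body PBPK model.

The model uses a fixed 15-compartment topology: 12 perfused tissues, each split
into vascular, endothelial-endosomal, interstitial and (inert) intracellular
sub-spaces, plus a central lymph node compartment and the venous and arterial
plasma pools.  Default parameter tables for the cynomolgus monkey (4 kg) and an
adult human (70 kg) ship as editable YAML files under ``igpbpk/data``; every
value can be overridden at load time via flat ``tissue.parameter`` paths.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, fields

import yaml

#: the 13 tissue identifiers (lymph node is carried in the table but wired as a
#: single well-stirred compartment by the engine)
TISSUE_IDS = (
    "lung", "adipose", "bone", "brain", "heart", "kidney", "muscle",
    "skin", "gut", "pancreas", "spleen", "liver", "lymph_node",
)

#: tissues that participate in perfusion/exchange (all but the lymph node)
PERFUSED_TISSUES = TISSUE_IDS[:-1]

SPECIES = ("monkey", "human")


class PhysiologyError(ValueError):
    """Raised when a physiology table violates a structural invariant."""


@dataclass
class TissuePhysiology:
    """Per-tissue volumes, flows and two-pore constants.

    Volumes in L, flows in L/h, pore radii in nm.  ``fcrn_fraction`` and
    ``catabolism_weight`` are dimensionless shares of the whole-body FcRn pool
    and of the endothelial catabolic clearance; each sums to 1 across tissues.
    ``aol_small``/``aol_large`` are the pore area-to-length densities (cm) from
    which permeability–surface-area products are computed.
    """

    tissue_id: str
    total_volume: float
    v_vascular: float
    v_interstitial: float
    v_endosomal: float
    v_intracellular: float
    plasma_flow: float
    lymph_flow: float
    fcrn_fraction: float
    catabolism_weight: float
    alpha_large: float
    alpha_small: float
    r_small: float
    r_large: float
    j_iso: float
    aol_small: float = 0.0
    aol_large: float = 0.0

    def validate(self) -> None:
        t = self.tissue_id
        if t not in TISSUE_IDS:
            raise PhysiologyError(f"unknown tissue id {t!r}")
        vols = (self.total_volume, self.v_vascular, self.v_interstitial,
                self.v_endosomal, self.v_intracellular)
        if any(v <= 0 for v in vols[:4]) or vols[4] < 0:
            raise PhysiologyError(f"{t}: all volumes must be positive")
        subtotal = sum(vols[1:])
        if subtotal > self.total_volume * (1 + 1e-9):
            raise PhysiologyError(
                f"{t}: sub-space volumes exceed total_volume "
                f"({subtotal:.6g} > {self.total_volume:.6g})")
        if not (0 < self.lymph_flow < self.plasma_flow):
            raise PhysiologyError(
                f"{t}: requires 0 < lymph_flow < plasma_flow "
                f"(got {self.lymph_flow:.6g}, {self.plasma_flow:.6g})")
        if abs(self.alpha_large + self.alpha_small - 1.0) > 1e-12:
            raise PhysiologyError(f"{t}: alpha_large + alpha_small must equal 1")
        if not (0 < self.r_small < self.r_large):
            raise PhysiologyError(f"{t}: requires 0 < r_small < r_large")
        if not (0 <= self.fcrn_fraction <= 1 and 0 <= self.catabolism_weight <= 1):
            raise PhysiologyError(f"{t}: fractional shares must lie in [0, 1]")
        if self.j_iso < 0:
            raise PhysiologyError(f"{t}: j_iso must be non-negative")
        if self.alpha_small * self.lymph_flow - self.j_iso < 0:
            raise PhysiologyError(
                f"{t}: j_iso too large — small-pore flow would be negative")


@dataclass
class SpeciesPhysiology:
    """Whole-body physiology for one species."""

    species: str
    body_weight: float  # kg
    tissues: dict[str, TissuePhysiology]
    v_venous: float  # L plasma
    v_arterial: float  # L plasma
    gfr: float  # L/h
    total_fcrn: float  # uM, referenced to total endosomal volume
    demographics: dict = field(default_factory=dict)

    @property
    def total_endosomal_volume(self) -> float:
        """Summed endosomal volume of the perfused tissues (L)."""
        return sum(self.tissues[t].v_endosomal for t in PERFUSED_TISSUES)

    @property
    def total_plasma_volume(self) -> float:
        """Venous + arterial + tissue vascular plasma (L)."""
        return (self.v_venous + self.v_arterial
                + sum(self.tissues[t].v_vascular for t in PERFUSED_TISSUES))

    def validate(self) -> None:
        if self.species not in SPECIES:
            raise PhysiologyError(f"unknown species {self.species!r}")
        missing = set(TISSUE_IDS) - set(self.tissues)
        extra = set(self.tissues) - set(TISSUE_IDS)
        if missing or extra:
            raise PhysiologyError(
                f"tissue set must be exactly the 13 ids; missing={sorted(missing)} "
                f"extra={sorted(extra)}")
        for tp in self.tissues.values():
            tp.validate()
        for name, total in (
            ("fcrn_fraction", sum(t.fcrn_fraction for t in self.tissues.values())),
            ("catabolism_weight",
             sum(t.catabolism_weight for t in self.tissues.values())),
        ):
            if abs(total - 1.0) > 1e-9:
                raise PhysiologyError(f"sum of {name} over tissues is {total!r}, not 1")
        if self.body_weight <= 0 or self.v_venous <= 0 or self.v_arterial <= 0:
            raise PhysiologyError("body weight and blood-pool volumes must be positive")
        if self.gfr < 0 or self.total_fcrn < 0:
            raise PhysiologyError("gfr and total_fcrn must be non-negative")


def _read_default_table(species: str) -> dict:
    ref = importlib.resources.files("igpbpk.data").joinpath(f"{species}.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def load_physiology(species: str, overrides: dict[str, float] | None = None,
                    ) -> SpeciesPhysiology:
    """Load the shipped physiology table for ``species``, applying overrides.

    Parameters
    ----------
    species:
        ``"monkey"`` or ``"human"``.
    overrides:
        Flat mapping of parameter paths to values.  Top-level scalars use the
        bare name (``"body_weight"``), tissue parameters use dotted paths
        (``"muscle.plasma_flow"``).  The lung plasma flow is derived from the
        other tissues (full cardiac output in series) and cannot be overridden.

    Returns
    -------
    SpeciesPhysiology
        A validated physiology; all invariants are enforced, and the applied
        overrides are recorded in ``demographics["overrides"]``.
    """
    if species not in SPECIES:
        raise PhysiologyError(f"unknown species {species!r}; expected one of {SPECIES}")
    raw = copy.deepcopy(_read_default_table(species))
    applied = {}
    tissue_fields = {f.name for f in fields(TissuePhysiology)} - {"tissue_id"}
    for path, value in (overrides or {}).items():
        if "." in path:
            tissue, param = path.split(".", 1)
            if tissue == "lung" and param == "plasma_flow":
                raise PhysiologyError(
                    "lung.plasma_flow is derived from the other tissue flows "
                    "and cannot be overridden")
            if tissue not in raw["tissues"] or param not in tissue_fields:
                raise PhysiologyError(f"unknown override path {path!r}")
            raw["tissues"][tissue][param] = float(value)
        else:
            if path not in ("body_weight", "v_venous", "v_arterial", "gfr",
                            "total_fcrn"):
                raise PhysiologyError(f"unknown override path {path!r}")
            raw[path] = float(value)
        applied[path] = float(value)

    # the lung receives the full cardiac plasma output in series; derive it so
    # the fluid circuit (including lymph return) balances exactly
    q_nonlung = sum(t["plasma_flow"] for name, t in raw["tissues"].items()
                    if name not in ("lung", "lymph_node"))
    raw["tissues"]["lung"]["plasma_flow"] = (
        q_nonlung + raw["tissues"]["lung"]["lymph_flow"])

    tissues = {
        name: TissuePhysiology(tissue_id=name, **params)
        for name, params in raw["tissues"].items()
    }
    phys = SpeciesPhysiology(
        species=raw["species"],
        body_weight=raw["body_weight"],
        tissues=tissues,
        v_venous=raw["v_venous"],
        v_arterial=raw["v_arterial"],
        gfr=raw["gfr"],
        total_fcrn=raw["total_fcrn"],
        demographics={"overrides": applied},
    )
    phys.validate()
    return phys


def scale_monkey_fcrn(human: SpeciesPhysiology, monkey: SpeciesPhysiology) -> float:
    """Monkey whole-body FcRn concentration from human per-gram abundance.

    Human tissue FcRn abundance per gram tissue (tissue mass taken as
    ``total_volume`` at unit density) is applied to the monkey tissue masses;
    the summed amount is referenced to the monkey total endosomal volume.

    Returns the monkey ``total_fcrn`` in uM.
    """
    human_amount = human.total_fcrn * human.total_endosomal_volume  # umol-equivalent
    total = 0.0
    for tid in PERFUSED_TISSUES:
        ht = human.tissues.get(tid)
        mt = monkey.tissues.get(tid)
        if ht is None or mt is None:
            raise PhysiologyError(f"tissue {tid!r} missing from one species table")
        per_gram = human_amount * ht.fcrn_fraction / ht.total_volume
        total += per_gram * mt.total_volume
    return total / monkey.total_endosomal_volume


def tissue_fcrn_concentration(phys: SpeciesPhysiology, tissue_id: str) -> float:
    """Endosomal FcRn concentration (uM) in one tissue.

    The whole-body FcRn amount (``total_fcrn`` x total endosomal volume) is
    distributed across tissues by ``fcrn_fraction`` and referenced to each
    tissue's own endosomal volume.
    """
    tp = phys.tissues[tissue_id]
    amount = phys.total_fcrn * phys.total_endosomal_volume * tp.fcrn_fraction
    return amount / tp.v_endosomal
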