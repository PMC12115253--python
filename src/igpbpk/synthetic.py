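"""Synthetic case-study generator.

Real case-study PK for biologics is typically proprietary, so complete case
bundles — a virtual drug, dosing designs, and noisy "observed" monkey and
human profiles with known ground truth — are generated from the simulator
itself.  Observed concentrations carry multiplicative log-normal residual
noise (``exp(N(0, sigma^2))`` with ``sigma = sqrt(ln(1 + cv^2))``) and
optional LLOQ censoring.  The true parameter values are sealed in a separate
ground-truth record that the analysis path never reads.

The generator encodes the study conditions directly: the true human
additional clearance is a configured fraction of the drug's total clearance
(resolved by the same fixed-point used for the IgG default), while the true
monkey additional clearance is, by default, drawn near the monkey IgG default
(monkey disposition of IgG-like drugs is well approximated by the IgG value).
The ``allometric_consistent`` mode instead derives the monkey value from the
human truth through the body-weight power law, making the allometric human
scenario exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import (REFERENCE_IGG, DEFAULT_ALLOMETRIC_EXPONENT, IgGReference,
                        TranslationContext, cladd_for_fraction,
                        reference_igg_metrics)
from .engine import DoseRegimen, DrugProperties, build_model, simulate
from .fcrn import FcRnParameters
from .io import (ObservedPK, drug_from_dict, drug_to_dict, read_observed_pk,
                 read_yaml, regimen_from_dict, regimen_to_dict,
                 write_observed_pk, write_yaml)
from .physiology import SpeciesPhysiology

GENERATOR_VERSION = "1"

#: default sampling schedules (h): dense early, sparse late
MONKEY_SCHEDULE = (0.5, 1, 2, 6, 12, 24, 48, 96, 168, 336, 504, 672)
HUMAN_SCHEDULE = (0.5, 1, 2, 6, 12, 24, 48, 96, 168, 336, 504, 672, 840, 1008)

_TRUTH_RTOL = 1e-8


@dataclass
class SyntheticCaseConfig:
    """Study conditions for one synthetic case."""

    seed: int
    case_id: str = "case"
    modality: str = "mAb"
    mw_range: tuple[float, float] = (145_000.0, 155_000.0)
    kd_range: tuple[float, float] = (0.2, 2.0)  # uM, log-uniform
    cladd_fraction_range: tuple[float, float] = (0.2, 0.6)
    monkey_data: bool = True
    monkey_cladd_mode: str = "igg_like"  # or "allometric_consistent"
    allometric_exponent: float = DEFAULT_ALLOMETRIC_EXPONENT
    noise_cv: float = 0.15
    monkey_schedule: tuple[float, ...] = MONKEY_SCHEDULE
    human_schedule: tuple[float, ...] = HUMAN_SCHEDULE
    lloq: float | None = None  # mg/L
    dose_levels_mg_per_kg: tuple[float, ...] = (3.0, 10.0, 30.0)
    infusion_duration: float = 1.0  # h

    def validate(self) -> None:
        for name in ("mw_range", "kd_range", "cladd_fraction_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be positive and ordered")
        if self.cladd_fraction_range[1] >= 1.0:
            raise ValueError("cl_add fraction must be < 1 (it is a share of total)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.monkey_cladd_mode not in ("igg_like", "allometric_consistent"):
            raise ValueError(f"unknown monkey_cladd_mode {self.monkey_cladd_mode!r}")
        if self.modality not in ("mAb", "ADC", "BiTCE"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class CaseStudy:
    """One generated case bundle.

    ``drug`` is the public description (``cl_add`` unset — the quantity the
    workflow predicts or fits); the true values live only in ``ground_truth``.
    """

    case_id: str
    drug: DrugProperties
    monkey_regimens: dict[str, DoseRegimen]
    human_regimens: dict[str, DoseRegimen]
    observed_monkey: ObservedPK | None
    observed_human: ObservedPK
    manifest: dict
    ground_truth: dict = field(repr=False, default_factory=dict)


def lognormal_sigma(cv: float) -> float:
    """Log-space SD giving a multiplicative residual CV of ``cv``."""
    return math.sqrt(math.log(1.0 + cv * cv))


def _noisy_observed(phys: SpeciesPhysiology, drug: DrugProperties,
                    fcrn: FcRnParameters, regimens: dict[str, DoseRegimen],
                    schedule, cv: float, lloq: float | None,
                    rng: np.random.Generator) -> ObservedPK:
    sigma = lognormal_sigma(cv)
    frames = []
    times = np.asarray(schedule, dtype=float)
    for dose_id, regimen in regimens.items():
        model = build_model(phys, drug, fcrn)
        res = simulate(model, regimen, t_end=float(times[-1]) * 1.02,
                       t_eval=times, rtol=_TRUTH_RTOL)
        truth = np.interp(times, res.t, res.plasma_conc_mg_per_L)
        noise = rng.normal(0.0, sigma, size=times.size) if sigma > 0 else 0.0
        obs = truth * np.exp(noise)
        censored = np.zeros(times.size, dtype=bool)
        if lloq is not None:
            censored = obs < lloq
        frames.append(pd.DataFrame({
            "time_h": times, "conc_mg_per_L": obs, "dose_id": dose_id,
            "censored": censored}))
    table = ObservedPK(data=pd.concat(frames, ignore_index=True), lloq=lloq)
    table.validate()
    return table


def make_case(config: SyntheticCaseConfig, ctx: TranslationContext) -> CaseStudy:
    """Generate one complete synthetic case study with sealed ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    mw = float(rng.uniform(*config.mw_range))
    kd = float(math.exp(rng.uniform(math.log(config.kd_range[0]),
                                    math.log(config.kd_range[1]))))
    kwargs = {}
    if config.modality == "BiTCE":
        kwargs["cl_renal"] = 0.02 * ctx.phys_human.gfr
    elif config.modality == "ADC":
        kwargs["k_deconj"] = float(rng.uniform(0.002, 0.008))
    base_drug = DrugProperties(name=config.case_id, modality=config.modality,
                               mw=mw, kd_human_fcrn=kd, **kwargs)
    base_drug.validate()

    fraction = float(rng.uniform(*config.cladd_fraction_range))
    cl_human_true, _ = cladd_for_fraction(ctx.phys_human, ctx.fcrn_human,
                                          fraction, drug=base_drug)
    if config.monkey_cladd_mode == "igg_like":
        cl_monkey_true = ctx.cl_add_igg_monkey * float(rng.uniform(0.8, 1.25))
    else:
        ratio = (ctx.phys_monkey.body_weight / ctx.phys_human.body_weight)
        cl_monkey_true = cl_human_true * ratio ** config.allometric_exponent

    route = "sc" if config.modality == "BiTCE" else "iv_infusion"
    regimens = {}
    for level in config.dose_levels_mg_per_kg:
        reg = DoseRegimen(route=route, dose_mg_per_kg=float(level),
                          infusion_duration=config.infusion_duration,
                          ka=0.015, f_sc=0.7)
        reg.validate()
        regimens[f"{level:g}mgkg"] = reg

    drug_h = replace(base_drug, cl_add=cl_human_true)
    observed_human = _noisy_observed(ctx.phys_human, drug_h, ctx.fcrn_human,
                                     regimens, config.human_schedule,
                                     config.noise_cv, config.lloq, rng)
    observed_monkey = None
    if config.monkey_data:
        drug_m = replace(base_drug, cl_add=cl_monkey_true)
        observed_monkey = _noisy_observed(ctx.phys_monkey, drug_m,
                                          ctx.fcrn_monkey, regimens,
                                          config.monkey_schedule,
                                          config.noise_cv, config.lloq, rng)

    manifest = {
        "case_id": config.case_id, "seed": config.seed,
        "generator_version": GENERATOR_VERSION,
        "modality": config.modality, "noise_cv": config.noise_cv,
        "lloq": config.lloq, "monkey_data": config.monkey_data,
        "monkey_cladd_mode": config.monkey_cladd_mode,
        "allometric_exponent": config.allometric_exponent,
        "dose_levels_mg_per_kg": list(config.dose_levels_mg_per_kg),
    }
    ground_truth = {
        "cl_add_human": cl_human_true, "cl_add_monkey": cl_monkey_true,
        "cladd_fraction_human": fraction, "mw": mw, "kd_human_fcrn": kd,
    }
    return CaseStudy(case_id=config.case_id, drug=base_drug,
                     monkey_regimens=regimens, human_regimens=regimens,
                     observed_monkey=observed_monkey,
                     observed_human=observed_human, manifest=manifest,
                     ground_truth=ground_truth)


def make_reference_igg(species: str, phys: SpeciesPhysiology,
                       k_rec: float = 0.12, k_deg: float = 10.0,
                       base: FcRnParameters | None = None,
                       t_ref: float | None = None,
                       ) -> tuple[DrugProperties, IgGReference, FcRnParameters]:
    """Self-consistent reference-IgG targets from a stated parameter pair.

    Simulates the standard reference study under the stated ``(k_rec, k_deg)``
    and returns the reference drug, an :class:`IgGReference` whose targets are
    exactly the simulated half-life and reference-time concentration, and the
    generating parameters — enabling closed-loop calibration tests.
    Deterministic: same inputs give bit-identical targets.
    """
    params = replace(base or FcRnParameters(), k_rec=k_rec, k_deg=k_deg)
    if t_ref is None:
        t_ref = 504.0 if species == "human" else 240.0
    t_end = 3000.0 if species == "human" else 2000.0
    t_half, conc = reference_igg_metrics(phys, params, t_ref, t_end)
    ref = IgGReference(species=species, target_t_half=t_half,
                       target_plasma_conc=conc, t_ref=t_ref,
                       source_note=f"synthetic, generated by k_rec={k_rec}, "
                                   f"k_deg={k_deg}")
    ref.validate()
    return replace(REFERENCE_IGG), ref, params


# ---------------------------------------------------------------- bundle I/O

def write_case(case: CaseStudy, directory: str | Path) -> None:
    """Write a case bundle; ground truth is sealed in its own subdirectory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_yaml(drug_to_dict(case.drug), d / "drug.yaml")
    write_yaml({k: regimen_to_dict(r) for k, r in case.human_regimens.items()},
               d / "regimens_human.yaml")
    write_yaml({k: regimen_to_dict(r) for k, r in case.monkey_regimens.items()},
               d / "regimens_monkey.yaml")
    write_observed_pk(case.observed_human, d / "observed_human.csv")
    if case.observed_monkey is not None:
        write_observed_pk(case.observed_monkey, d / "observed_monkey.csv")
    write_yaml(case.manifest, d / "manifest.yaml")
    write_yaml(case.ground_truth, d / "ground_truth" / "truth.yaml")


def read_case(directory: str | Path) -> CaseStudy:
    """Load a case bundle.  The sealed ground-truth directory is not read."""
    d = Path(directory)
    manifest = read_yaml(d / "manifest.yaml")
    drug = drug_from_dict(read_yaml(d / "drug.yaml"))
    human_reg = {k: regimen_from_dict(v)
                 for k, v in read_yaml(d / "regimens_human.yaml").items()}
    monkey_reg = {k: regimen_from_dict(v)
                  for k, v in read_yaml(d / "regimens_monkey.yaml").items()}
    observed_human = read_observed_pk(d / "observed_human.csv")
    observed_human.lloq = manifest.get("lloq")
    observed_monkey = None
    if (d / "observed_monkey.csv").exists():
        observed_monkey = read_observed_pk(d / "observed_monkey.csv")
        observed_monkey.lloq = manifest.get("lloq")
    return CaseStudy(case_id=manifest["case_id"], drug=drug,
                     monkey_regimens=monkey_reg, human_regimens=human_reg,
                     observed_monkey=observed_monkey,
                     observed_human=observed_human, manifest=manifest,
                     ground_truth={})


__all__ = [
    "SyntheticCaseConfig", "CaseStudy", "make_case", "make_reference_igg",
    "lognormal_sigma", "write_case", "read_case", "MONKEY_SCHEDULE",
    "HUMAN_SCHEDULE", "GENERATOR_VERSION",
]
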