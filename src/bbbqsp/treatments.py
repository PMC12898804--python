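"""Pharmacodynamics of NX210c and effect handles for standard-of-care drugs.

NX210c concentration couples to barrier repair through a sigmoidal Emax law;
the repair input feeds :func:`bbbqsp.bbb.step_bbb` (set-point raise + damage
clearance).  An in vitro mode reproduces the BMEC-monolayer experiment
design: a constant bath concentration held for 4 h to 5 days, reported as
fold-changes of claudin-5, TEER and dextran permeability versus vehicle.

The five RRMS standard-of-care drugs are represented by their mechanism of
action as named multipliers on immune/BBB parameters, active over scheduled
windows (their own plasma kinetics are not modelled):

* interferon beta-1a  - reduced dendritic-cell activation / Th1 priming
* teriflunomide       - reduced activated-lymphocyte proliferation
* natalizumab         - blocked CNS transmigration (alpha4-integrin)
* ocrelizumab         - B-cell depletion (persists across 6-month dosing)
* cladribine          - T/B lymphodepletion with slow reconstitution

Effect magnitudes are free parameters calibrated so the simulated 2-year
relapse counts in the highly active population reproduce the known efficacy
hierarchy (ocrelizumab ~ natalizumab < cladribine < teriflunomide ~
interferon beta-1a < untreated).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .pk import Compound, DoseRegimen, PKParams, simulate_pk

MINUTES_PER_DAY = 1440.0
DAYS_PER_WEEK = 7.0
DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class PDParams:
    """NX210c concentration-effect parameters.

    ``ec50_mg_per_l`` and ``hill`` shape the sigmoid; ``emax_repair`` is the
    maximal repair input per day at saturating concentration.  The molecular
    weight converts the in vitro micromolar bath concentrations to mg/L
    (SCO-spondin-derived 12-mer, ~1.2 kDa).  The in vitro gain/saturation
    constants scale cumulative repair into reported fold-changes.
    """

    ec50_mg_per_l: float = 15.0
    emax_repair: float = 1.0
    hill: float = 1.5
    mw_g_per_mol: float = 1204.0
    invitro_claudin5_gain: float = 0.25
    invitro_saturation: float = 2.0
    invitro_teer_exponent: float = 1.3335  # matches the barrier TEER coupling

    def validate(self) -> "PDParams":
        if self.ec50_mg_per_l <= 0:
            raise ValidationError("ec50 must be > 0")
        if self.emax_repair < 0:
            raise ValidationError("emax_repair must be >= 0")
        if self.hill < 1:
            raise ValidationError("hill must be >= 1")
        if self.mw_g_per_mol <= 0:
            raise ValidationError("molecular weight must be > 0")
        return self


def nx210c_effect(concentration: float, params: PDParams) -> float:
    """Barrier-repair input (per day) at an NX210c concentration (mg/L)."""
    params.validate()
    if not math.isfinite(concentration):
        raise ValidationError("concentration must be finite")
    if concentration < 0:
        raise ValidationError(f"concentration must be >= 0, got {concentration}")
    if concentration == 0.0:
        return 0.0
    c_h = concentration**params.hill
    return params.emax_repair * c_h / (params.ec50_mg_per_l**params.hill + c_h)


def daily_repair_series(
    regimen: DoseRegimen,
    pk_params: PKParams,
    pd_params: PDParams,
    horizon_days: int,
) -> np.ndarray:
    """Mean repair input for each simulation day of an NX210c regimen.

    The within-day concentration profile after a single infusion is computed
    once on a 1-minute grid (the profile decays to nothing well within a
    day, and infusions are never closer than 48 h), its effect integral is
    averaged over the day, and that per-infusion daily value is placed on
    every infusion day of the regimen.
    """
    pd_params.validate()
    if horizon_days <= 0:
        raise ValidationError("horizon_days must be > 0")
    if regimen.compound is not Compound.NX210c and regimen.compound is not Compound.NX210:
        raise ValidationError("unsupported compound")
    single = DoseRegimen.single_dose(
        regimen.compound, regimen.dose_mg_per_kg, regimen.infusion_duration_min
    )
    grid = np.arange(0.0, MINUTES_PER_DAY + 1.0, 1.0)
    conc = simulate_pk(single, pk_params, grid).conc_nx210c
    effects = np.array([nx210c_effect(c, pd_params) for c in conc])
    daily_effect = float(np.trapezoid(effects, grid) / MINUTES_PER_DAY)

    out = np.zeros(horizon_days)
    for day in regimen.infusion_days():
        idx = int(day)
        if 0 <= idx < horizon_days:
            out[idx] += daily_effect
    return out


def simulate_invitro(
    concentration_um: float, duration_h: float, params: PDParams
) -> dict[str, float]:
    """BMEC-monolayer exposure: fold-changes versus vehicle.

    A constant bath concentration (``concentration_um``, micromolar) is held
    for ``duration_h`` hours (supported window 4 h to 5 days, mirroring the
    experiment design; PK is bypassed).  Cumulative repair saturably raises
    claudin-5; TEER follows the same tight-junction coupling as the in vivo
    barrier and permeability is its inverse.
    """
    params.validate()
    if not 4.0 <= duration_h <= 120.0:
        raise ValidationError(
            f"duration must lie in [4, 120] hours, got {duration_h}"
        )
    if concentration_um < 0:
        raise ValidationError("concentration must be >= 0")
    conc_mg_l = concentration_um * params.mw_g_per_mol / 1000.0
    repair = nx210c_effect(conc_mg_l, params) * duration_h / 24.0
    claudin5 = 1.0 + params.invitro_claudin5_gain * repair / (
        1.0 + repair / params.invitro_saturation
    )
    teer = claudin5**params.invitro_teer_exponent
    return {
        "claudin5_foldchange": claudin5,
        "teer_foldchange": teer,
        "permeability_foldchange": 1.0 / teer,
    }


class Drug(str, enum.Enum):
    INTERFERON_B1A = "interferon_b1a"
    TERIFLUNOMIDE = "teriflunomide"
    NATALIZUMAB = "natalizumab"
    OCRELIZUMAB = "ocrelizumab"
    CLADRIBINE = "cladribine"
    NX210C = "nx210c"


@dataclass(frozen=True)
class TreatmentEffect:
    """Named multipliers a treatment applies while active.

    Suppressive multipliers live in [0, 1] (1 = no effect); ``bbb_repair_input``
    is the additive NX210c repair rate.  ``compose`` merges simultaneous
    treatments: multiplicative on the suppressive handles, complementary on
    the infiltration block, additive on repair — each handle is owned by a
    distinct mechanism, so composition never double-counts.
    """

    drug: Drug | None = None
    dc_activation_mult: float = 1.0
    lymphocyte_prolif_mult: float = 1.0
    infiltration_block: float = 0.0
    bcell_depletion_frac: float = 0.0
    lymphodepletion_frac: float = 0.0
    bbb_repair_input: float = 0.0

    def validate(self) -> "TreatmentEffect":
        for name in ("dc_activation_mult", "lymphocyte_prolif_mult"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("infiltration_block", "bcell_depletion_frac", "lymphodepletion_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.bbb_repair_input < 0:
            raise ValidationError("bbb_repair_input must be >= 0")
        return self

    @property
    def is_identity(self) -> bool:
        return (
            self.dc_activation_mult == 1.0
            and self.lymphocyte_prolif_mult == 1.0
            and self.infiltration_block == 0.0
            and self.bcell_depletion_frac == 0.0
            and self.lymphodepletion_frac == 0.0
            and self.bbb_repair_input == 0.0
        )


IDENTITY_EFFECT = TreatmentEffect()


def compose_effects(effects: list[TreatmentEffect]) -> TreatmentEffect:
    dc = 1.0
    prolif = 1.0
    passthrough = 1.0
    bdep = 0.0
    ldep = 0.0
    repair = 0.0
    for e in effects:
        e.validate()
        dc *= e.dc_activation_mult
        prolif *= e.lymphocyte_prolif_mult
        passthrough *= 1.0 - e.infiltration_block
        bdep = max(bdep, e.bcell_depletion_frac)
        ldep = max(ldep, e.lymphodepletion_frac)
        repair += e.bbb_repair_input
    return TreatmentEffect(
        dc_activation_mult=dc,
        lymphocyte_prolif_mult=prolif,
        infiltration_block=1.0 - passthrough,
        bcell_depletion_frac=bdep,
        lymphodepletion_frac=ldep,
        bbb_repair_input=repair,
    )


@dataclass(frozen=True)
class SoCRegimen:
    """Registered dosing schedule and effect magnitudes for one SoC drug.

    ``dose_days`` are relative to therapy start; ``persistence_days`` is how
    long one dose's effect lasts (covering the inter-dose interval for the
    depleting antibodies, whose biology outlives exposure).
    """

    drug: Drug
    dose_description: str
    dose_days: tuple[float, ...]
    persistence_days: float
    effect: TreatmentEffect

    def effect_at(self, t_days: float) -> TreatmentEffect:
        for d in self.dose_days:
            if d <= t_days < d + self.persistence_days:
                return self.effect
        return IDENTITY_EFFECT


def _soc_regimens(horizon_days: float = 3653.0) -> dict[Drug, SoCRegimen]:
    """Build the registered schedules out to ``horizon_days``.

    Magnitudes below are the calibrated mechanism strengths (see
    docs/methods.md for the hierarchy calibration).
    """
    regs: dict[Drug, SoCRegimen] = {}

    # interferon beta-1a: 22 mcg SC three times per week, continuous therapy
    ifn_days = tuple(
        w * DAYS_PER_WEEK + d
        for w in range(int(horizon_days / DAYS_PER_WEEK) + 1)
        for d in (0.0, 2.0, 4.0)
    )
    regs[Drug.INTERFERON_B1A] = SoCRegimen(
        drug=Drug.INTERFERON_B1A,
        dose_description="22 mcg SC three times weekly",
        dose_days=ifn_days,
        persistence_days=3.0,
        effect=TreatmentEffect(drug=Drug.INTERFERON_B1A, dc_activation_mult=0.55),
    )

    # teriflunomide: 14 mg oral daily
    teri_days = tuple(float(d) for d in range(int(horizon_days) + 1))
    regs[Drug.TERIFLUNOMIDE] = SoCRegimen(
        drug=Drug.TERIFLUNOMIDE,
        dose_description="14 mg oral once daily",
        dose_days=teri_days,
        persistence_days=1.5,
        effect=TreatmentEffect(drug=Drug.TERIFLUNOMIDE, lymphocyte_prolif_mult=0.70),
    )

    # natalizumab: 300 mg IV every 4 weeks; receptor saturation covers the interval
    nat_days = tuple(28.0 * i for i in range(int(horizon_days / 28.0) + 1))
    regs[Drug.NATALIZUMAB] = SoCRegimen(
        drug=Drug.NATALIZUMAB,
        dose_description="300 mg IV every 4 weeks",
        dose_days=nat_days,
        persistence_days=30.0,
        effect=TreatmentEffect(drug=Drug.NATALIZUMAB, infiltration_block=0.90),
    )

    # ocrelizumab: 600 mg IV every 6 months; depletion persists across the interval
    ocr_days = tuple(
        DAYS_PER_MONTH * 6.0 * i for i in range(int(horizon_days / (DAYS_PER_MONTH * 6.0)) + 1)
    )
    regs[Drug.OCRELIZUMAB] = SoCRegimen(
        drug=Drug.OCRELIZUMAB,
        dose_description="600 mg IV every 6 months",
        dose_days=ocr_days,
        persistence_days=DAYS_PER_MONTH * 6.0 + 14.0,
        effect=TreatmentEffect(drug=Drug.OCRELIZUMAB, bcell_depletion_frac=0.95),
    )

    # cladribine: 3.5 mg/kg oral over 2 years, first 5 days of months 1, 2, 13, 14;
    # lymphodepletion reconstitutes slowly, carrying the effect between courses
    clad_days = tuple(
        DAYS_PER_MONTH * m + d for m in (0.0, 1.0, 12.0, 13.0) for d in range(5)
    )
    regs[Drug.CLADRIBINE] = SoCRegimen(
        drug=Drug.CLADRIBINE,
        dose_description="3.5 mg/kg oral, first 5 days of months 1, 2, 13, 14",
        dose_days=clad_days,
        persistence_days=DAYS_PER_MONTH * 12.0,
        effect=TreatmentEffect(drug=Drug.CLADRIBINE, lymphodepletion_frac=0.55),
    )
    return regs


_SOC_CACHE: dict[Drug, SoCRegimen] = _soc_regimens()


def get_soc_regimen(drug: Drug | str) -> SoCRegimen:
    try:
        drug = Drug(drug)
    except ValueError:
        raise ValidationError(f"unknown drug {drug!r}") from None
    if drug is Drug.NX210C:
        raise ValidationError(
            "NX210c is concentration-driven; use a DoseRegimen, not a SoC window"
        )
    return _SOC_CACHE[drug]


def soc_effect(drug: Drug | str, t_days: float) -> TreatmentEffect:
    """The drug's parameter multipliers active at ``t_days`` after therapy start."""
    reg = get_soc_regimen(drug)
    if not math.isfinite(t_days):
        raise ValidationError("t_days must be finite")
    return reg.effect_at(t_days)


def soc_effect_arrays(
    drugs: list[Drug | str], horizon_days: int
) -> dict[str, np.ndarray]:
    """Per-day composed multiplier arrays for a set of concurrent SoC drugs."""
    days = np.arange(horizon_days, dtype=float)
    dc = np.ones(horizon_days)
    prolif = np.ones(horizon_days)
    passthrough = np.ones(horizon_days)
    bdep = np.zeros(horizon_days)
    ldep = np.zeros(horizon_days)
    for drug in drugs:
        reg = get_soc_regimen(drug)
        active = np.zeros(horizon_days, dtype=bool)
        for d in reg.dose_days:
            lo = int(math.floor(d))
            hi = int(math.ceil(d + reg.persistence_days))
            if lo < horizon_days:
                active[max(lo, 0) : min(hi, horizon_days)] = True
        e = reg.effect
        dc[active] *= e.dc_activation_mult
        prolif[active] *= e.lymphocyte_prolif_mult
        passthrough[active] *= 1.0 - e.infiltration_block
        bdep[active] = np.maximum(bdep[active], e.bcell_depletion_frac)
        ldep[active] = np.maximum(ldep[active], e.lymphodepletion_frac)
    return {
        "time_days": days,
        "dc_activation_mult": dc,
        "lymphocyte_prolif_mult": prolif,
        "infiltration_block": 1.0 - passthrough,
        "bcell_depletion_frac": bdep,
        "lymphodepletion_frac": ldep,
    }
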