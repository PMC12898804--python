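"""Stochastic immune/disease layer coupling BBB state to relapse dynamics.

Self-antigen exposures arrive as a Poisson process (rate modulated per
patient).  Each exposure activates an autoreactive clone with the patient's
activation probability, scaled by the remaining autoreactive repertoire and
by any dendritic-cell / B-cell-presentation suppression.  An activation
expands effector lymphocytes (Th1/Th17/CTL) in blood; candidates cross into
the CNS at the barrier's infiltration probability (scaled by any
infiltration block), infiltrated effectors kill oligodendrocytes (ODC), and
the ODC population recovers logistically toward baseline once the
infiltrate clears.  Crossing cells also injure the barrier (damage feeds
adhesion upregulation), closing the inflammation loop.

Activations consume the autoreactive pool; thymic output replenishes it in
proportion to the patient's thymus efficiency.  In patients with low thymic
output and high activation propensity the pool starts saturated, producing
an early burst of relapses that settles to a lower quasi-steady rate — the
signature of the highly active phenotype over a decade.

Stochasticity lives in event triggering: exposure times, activation
Bernoulli draws, and per-event severity.  Conditional on those draws the
expansion/trafficking/kill dynamics are deterministic mean-field updates
(tau-leaping on expectations), which keeps paired-arm comparisons exactly
coupled under common random numbers.  Counts are cells/uL; time is days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .bbb import (
    BBBParams,
    BBBState,
    compute_permeability,
    infiltration_probability,
)
from .errors import ValidationError
from .population import VirtualPatient
from .treatments import IDENTITY_EFFECT, TreatmentEffect, compose_effects

DAYS_PER_YEAR = 365.0

DC_BASELINE = 40.0
TREG_BASELINE = 60.0
BCELL_BASELINE = 200.0
MICROGLIA_BASELINE = 5.0


@dataclass(frozen=True)
class ImmuneState:
    """Cell-population state (cells/uL or normalised titres).

    ``autoreactive_pool`` is the normalised autoreactive repertoire in
    [0, 1]; ``cns_infiltrate`` the effector cells currently inside the CNS.
    """

    dendritic_cells: float = DC_BASELINE
    th1: float = 0.0
    th2: float = 0.0
    th17: float = 0.0
    treg: float = TREG_BASELINE
    ctl: float = 0.0
    b_cells: float = BCELL_BASELINE
    antibody_titer: float = 0.0
    microglia_activated: float = MICROGLIA_BASELINE
    odc: float = 50000.0
    cns_infiltrate: float = 0.0
    autoreactive_pool: float = 1.0

    def validate(self, odc_baseline: float | None = None) -> "ImmuneState":
        for name in (
            "dendritic_cells",
            "th1",
            "th2",
            "th17",
            "treg",
            "ctl",
            "b_cells",
            "antibody_titer",
            "microglia_activated",
            "odc",
            "cns_infiltrate",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.autoreactive_pool <= 1.0:
            raise ValidationError("autoreactive_pool must lie in [0, 1]")
        if odc_baseline is not None and self.odc > odc_baseline + 1e-9:
            raise ValidationError("odc must not exceed odc_baseline")
        return self


@dataclass(frozen=True)
class DiseaseParams:
    """Rates and scales of the disease layer.

    ``odc_baseline`` = 50,000 cells/uL is the unique value making the two
    published relapse thresholds agree (a 15% drop landing exactly at the
    42,500 cells/uL clinical boundary).  The remaining rates are free
    parameters calibrated against the population relapse counts of the
    reference scenarios (see docs/methods.md).
    """

    odc_baseline: float = 50000.0
    antigen_event_rate: float = 6.0        # exposures / year before patient scaling
    activation_prob: float = 0.5           # fallback when no patient is supplied
    odc_kill_rate: float = 4.5             # ODC loss per infiltrated cell per day
    odc_recovery_rate: float = 0.075       # 1/day logistic recovery
    treg_suppression_gain: float = 0.0     # neutral default
    effector_decay: float = 0.18           # 1/day blood-effector contraction
    infiltrate_clearance: float = 0.25     # 1/day CNS clearance
    crossing_rate: float = 0.5             # candidate crossing attempts / day
    clone_size: float = 1500.0             # cells/uL per activation burst
    severity_sigma: float = 0.35           # lognormal sd of burst size
    pool_consumption: float = 0.25         # repertoire share consumed per activation
                                           # (absolute, clipped at zero)
    damage_tone_rate: float = 0.0       # intrinsic damage regrowth / day at unit
                                           # (activation_prob * antigen multiplier)^4
    thymus_replenish_rate: float = 0.40     # 1/year at full thymic efficiency
    bcell_presentation_weight: float = 0.85  # share of activation needing B cells
    bcell_expansion_weight: float = 0.5    # share of clonal expansion B-cell-supported
    adhesion_damage_weight: float = 1.3    # adhesion upregulation per unit damage
    adhesion_activity_weight: float = 0.42 # chronic adhesion upregulation per squared
                                           # intrinsic disease activity (not repaired)
    th1_share: float = 0.5
    th17_share: float = 0.3
    ctl_share: float = 0.2
    th2_share: float = 0.1                 # bystander arm, no ODC effect

    def validate(self) -> "DiseaseParams":
        positives = (
            "odc_baseline",
            "clone_size",
        )
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        non_negatives = (
            "antigen_event_rate",
            "odc_kill_rate",
            "odc_recovery_rate",
            "treg_suppression_gain",
            "effector_decay",
            "infiltrate_clearance",
            "crossing_rate",
            "severity_sigma",
            "thymus_replenish_rate",
            "adhesion_damage_weight",
            "adhesion_activity_weight",
            "damage_tone_rate",
        )
        for name in non_negatives:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "activation_prob",
            "pool_consumption",
            "bcell_presentation_weight",
            "bcell_expansion_weight",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        return self


def activation_probability(
    pool: float,
    base_prob: float,
    dc_mult: float,
    bcell_frac_remaining: float,
    treg: float,
    params: DiseaseParams,
) -> float:
    """Probability an exposure activates a clone, given suppression context."""
    w = params.bcell_presentation_weight
    presentation = (1.0 - w) + w * bcell_frac_remaining
    treg_factor = 1.0 / (
        1.0 + params.treg_suppression_gain * max(treg / TREG_BASELINE - 1.0, 0.0)
    )
    return min(1.0, base_prob * pool * dc_mult * presentation * treg_factor)


def _continuous_update(
    th1: float,
    th2: float,
    th17: float,
    ctl: float,
    b: float,
    ab: float,
    odc: float,
    infiltrate: float,
    pool: float,
    f_cross: float,
    thymus_eff: float,
    bdep: float,
    dt: float,
    p: DiseaseParams,
) -> tuple[float, float, float, float, float, float, float, float, float, float]:
    """One mean-field step of the non-event dynamics.  Returns the new
    populations plus the number of cells that crossed this step."""
    effectors = th1 + th17 + ctl
    crossings = effectors * f_cross
    decay = math.exp(-p.effector_decay * dt)
    keep = (1.0 - f_cross) * decay
    th1 *= keep
    th17 *= keep
    ctl *= keep
    th2 *= decay  # bystander arm does not traffic

    infiltrate = infiltrate * math.exp(-p.infiltrate_clearance * dt) + crossings

    odc = odc + p.odc_recovery_rate * odc * (1.0 - odc / p.odc_baseline) * dt
    odc -= p.odc_kill_rate * infiltrate * dt
    if odc < 1.0:
        odc = 1.0
    elif odc > p.odc_baseline:
        odc = p.odc_baseline

    b_target = BCELL_BASELINE * (1.0 - bdep)
    b += (b_target - b) * (1.0 - math.exp(-0.1 * dt))
    ab = ab * math.exp(-0.05 * dt) + 0.001 * b * infiltrate * dt

    pool += p.thymus_replenish_rate * thymus_eff * (1.0 - pool) * dt / DAYS_PER_YEAR
    if pool > 1.0:
        pool = 1.0
    return th1, th2, th17, ctl, b, ab, odc, infiltrate, pool, crossings


def step_immune(
    state: ImmuneState,
    patient: VirtualPatient,
    bbb: BBBState,
    effects: list[TreatmentEffect],
    params: DiseaseParams,
    rng: np.random.Generator,
    dt: float,
    bbb_params: BBBParams | None = None,
) -> ImmuneState:
    """Advance the immune state by ``dt`` days (single-patient API).

    Antigen exposures are drawn Poisson at the patient-modulated rate;
    treatment multipliers are applied before expansion and infiltration.
    The per-draw structure (one Poisson count, then one uniform and one
    severity draw per candidate) is treatment-independent, so arms sharing
    an rng stream stay synchronised.
    """
    if params is None:
        raise ValidationError("DiseaseParams required")
    params.validate()
    if patient is None:
        raise ValidationError("a VirtualPatient is required")
    if not isinstance(rng, np.random.Generator):
        raise ValidationError(
            "rng must be a seeded numpy.random.Generator (e.g. default_rng(seed))"
        )
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    state.validate(params.odc_baseline)
    bbb_params = (bbb_params or BBBParams()).validate()

    eff = compose_effects(effects) if effects else IDENTITY_EFFECT

    perm = compute_permeability(bbb, bbb_params)
    activity = patient.activation_prob * patient.antigen_rate_multiplier
    adhesion = (
        1.0
        + params.adhesion_damage_weight * bbb.damage
        + params.adhesion_activity_weight * activity**2
    )
    p_inf = infiltration_probability(
        perm, adhesion, eff.infiltration_block, bbb_params
    )
    f_cross = 1.0 - math.exp(-p_inf * params.crossing_rate * dt)

    th1, th2, th17, ctl = state.th1, state.th2, state.th17, state.ctl
    pool = state.autoreactive_pool
    lam_day = params.antigen_event_rate * patient.antigen_rate_multiplier / DAYS_PER_YEAR
    n_cand = int(rng.poisson(lam_day * dt)) if lam_day > 0 else 0
    for _ in range(n_cand):
        u = float(rng.uniform())
        sev = float(rng.lognormal(0.0, params.severity_sigma))
        p_act = activation_probability(
            pool,
            patient.activation_prob,
            eff.dc_activation_mult,
            1.0 - eff.bcell_depletion_frac,
            state.treg,
            params,
        )
        if u < p_act:
            pool = max(pool - params.pool_consumption, 0.0)
            burst = (
                params.clone_size
                * sev
                * eff.lymphocyte_prolif_mult
                * (1.0 - eff.lymphodepletion_frac)
                * (1.0 - params.bcell_expansion_weight * eff.bcell_depletion_frac)
            )
            th1 += params.th1_share * burst
            th17 += params.th17_share * burst
            ctl += params.ctl_share * burst
            th2 += params.th2_share * burst

    th1, th2, th17, ctl, b, ab, odc, infiltrate, pool, crossings = _continuous_update(
        th1,
        th2,
        th17,
        ctl,
        state.b_cells,
        state.antibody_titer,
        state.odc,
        state.cns_infiltrate,
        pool,
        f_cross,
        patient.thymus_efficiency,
        eff.bcell_depletion_frac,
        dt,
        params,
    )
    return replace(
        state,
        dendritic_cells=DC_BASELINE * eff.dc_activation_mult,
        th1=th1,
        th2=th2,
        th17=th17,
        ctl=ctl,
        b_cells=b,
        antibody_titer=ab,
        microglia_activated=MICROGLIA_BASELINE + 0.02 * infiltrate,
        odc=odc,
        cns_infiltrate=infiltrate,
        autoreactive_pool=pool,
    ).validate(params.odc_baseline)


@dataclass(frozen=True)
class PatientRun:
    """Daily-resolution output of one patient under one arm."""

    patient_id: int
    time_days: np.ndarray
    odc: np.ndarray
    cns_infiltrate: np.ndarray
    th1: np.ndarray
    th17: np.ndarray
    treg: np.ndarray
    b_cells: np.ndarray
    tjp: np.ndarray
    teer: np.ndarray
    min_tjp: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.time_days,
                "odc": self.odc,
                "cns_infiltrate": self.cns_infiltrate,
                "th1": self.th1,
                "th17": self.th17,
                "treg": self.treg,
                "b_cells": self.b_cells,
            }
        )


@dataclass(frozen=True)
class ArmArrays:
    """Per-day treatment inputs for one arm (length >= horizon_days)."""

    repair: np.ndarray
    block: np.ndarray
    dc_mult: np.ndarray
    prolif_mult: np.ndarray
    bdep: np.ndarray
    ldep: np.ndarray

    @classmethod
    def untreated(cls, horizon_days: int) -> "ArmArrays":
        z = np.zeros(horizon_days)
        o = np.ones(horizon_days)
        return cls(repair=z, block=z, dc_mult=o, prolif_mult=o, bdep=z, ldep=z)


def _draw_event_schedule(
    patient: VirtualPatient,
    params: DiseaseParams,
    horizon_days: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-draw exposure times, acceptance uniforms and severities.

    The schedule depends only on the patient and master seed — never on the
    arm — so every arm of a scenario sees identical candidate events
    (paired virtual-trial design).
    """
    lam_day = params.antigen_event_rate * patient.antigen_rate_multiplier / DAYS_PER_YEAR
    if lam_day <= 0:
        return np.empty(0), np.empty(0), np.empty(0)
    times = []
    t = rng.exponential(1.0 / lam_day)
    while t < horizon_days:
        times.append(t)
        t += rng.exponential(1.0 / lam_day)
    n = len(times)
    return (
        np.asarray(times),
        rng.uniform(size=n),
        rng.lognormal(0.0, params.severity_sigma, size=n),
    )


def simulate_patient(
    patient: VirtualPatient,
    horizon_days: int,
    disease_params: DiseaseParams,
    bbb_params: BBBParams,
    arm: ArmArrays,
    master_seed: int,
    dt: float = 0.25,
    disease: bool = True,
    clamp_bbb_healthy: bool = False,
) -> PatientRun:
    """Coupled BBB + immune simulation of one patient under one arm.

    The barrier state advances daily (exponential integrator, damage from
    the day's crossings); the immune layer advances at ``dt`` (default 6 h).
    Randomness comes from a substream keyed by (master_seed, patient.id),
    drawn before the loop so arms are exactly paired.  With
    ``clamp_bbb_healthy`` the infiltration gate is evaluated at the healthy
    baseline barrier regardless of the simulated one (mechanism probe).
    """
    disease_params.validate()
    bbb_params.validate()
    patient.validate()
    horizon_days = int(horizon_days)
    if horizon_days <= 0:
        raise ValidationError("horizon must be > 0")
    steps_per_day = int(round(1.0 / dt))
    if steps_per_day < 1 or abs(steps_per_day * dt - 1.0) > 1e-9:
        raise ValidationError("dt must evenly divide one day")

    rng = np.random.default_rng(
        np.random.SeedSequence(int(master_seed), spawn_key=(int(patient.id), 1))
    )
    times, us, sevs = _draw_event_schedule(patient, disease_params, horizon_days, rng)

    p = disease_params
    bp = bbb_params
    b0 = patient.baseline_bbb_integrity
    tjp = b0
    damage = patient.baseline_damage
    reserve = 0.0
    floor_frac = bp.tjp_floor_frac * b0
    cap = bp.repair_reserve_cap_frac * b0
    k_day = bp.healthy_decline_rate / DAYS_PER_YEAR
    if disease:
        k_day *= bp.disease_decline_multiplier
    decay_day = math.exp(-k_day)

    teer_floor = bp.teer_floor_frac * bp.teer_baseline
    healthy_x = 1.0  # leak-adhesion product at the healthy baseline
    # intrinsic inflammatory tone: ongoing subthreshold autoimmune activity
    # re-injures the barrier between relapses, faster in more active disease
    activity = patient.activation_prob * patient.antigen_rate_multiplier
    tone = p.damage_tone_rate * activity**4 if disease else 0.0
    chronic_adhesion = p.adhesion_activity_weight * activity**2 if disease else 0.0

    th1 = th2 = th17 = ctl = 0.0
    treg = TREG_BASELINE
    b_cells = BCELL_BASELINE
    ab = 0.0
    odc = p.odc_baseline
    infiltrate = 0.0
    pool = 1.0

    n_rec = horizon_days + 1
    rec_odc = np.empty(n_rec)
    rec_inf = np.empty(n_rec)
    rec_th1 = np.empty(n_rec)
    rec_th17 = np.empty(n_rec)
    rec_treg = np.empty(n_rec)
    rec_b = np.empty(n_rec)
    rec_tjp = np.empty(n_rec)
    rec_teer = np.empty(n_rec)
    rec_odc[0] = odc
    rec_inf[0] = 0.0
    rec_th1[0] = 0.0
    rec_th17[0] = 0.0
    rec_treg[0] = treg
    rec_b[0] = b_cells
    rec_tjp[0] = tjp
    teer0 = teer_floor + (bp.teer_baseline - teer_floor) * tjp**bp.teer_tjp_exponent
    rec_teer[0] = teer0
    min_tjp = tjp

    ci = 0
    n_cand = times.shape[0]
    mid_h = bp.infil_midpoint**bp.infil_hill
    p0_scale = bp.infil_baseline_prob * (1.0 + mid_h)

    for day in range(horizon_days):
        repair = arm.repair[day]
        block = arm.block[day]
        dc_mult = arm.dc_mult[day]
        prolif = arm.prolif_mult[day]
        bdep = arm.bdep[day]
        ldep = arm.ldep[day]

        # --- daily barrier update (same law as step_bbb) ---
        reserve = min(reserve + bp.repair_floor_gain * repair, cap)
        floor = floor_frac + reserve
        tjp = floor + (tjp - floor) * decay_day
        if tjp < min_tjp:
            min_tjp = tjp
        teer = teer_floor + (bp.teer_baseline - teer_floor) * tjp**bp.teer_tjp_exponent
        perm = bp.perm_baseline * bp.teer_baseline / teer
        adhesion = 1.0 + p.adhesion_damage_weight * damage + chronic_adhesion
        x = healthy_x if clamp_bbb_healthy else (perm / bp.perm_baseline) * adhesion
        xh = x**bp.infil_hill
        p_inf = p0_scale * xh / (mid_h + xh) * (1.0 - block)
        f_cross = 1.0 - math.exp(-p_inf * p.crossing_rate * dt)

        day_crossings = 0.0
        t_day = float(day)
        for s in range(steps_per_day):
            t_next = t_day + (s + 1) * dt
            while ci < n_cand and times[ci] < t_next:
                p_act = activation_probability(
                    pool, patient.activation_prob, dc_mult, 1.0 - bdep, treg, p
                )
                if us[ci] < p_act:
                    pool = max(pool - p.pool_consumption, 0.0)
                    burst = (
                        p.clone_size
                        * sevs[ci]
                        * prolif
                        * (1.0 - ldep)
                        * (1.0 - p.bcell_expansion_weight * bdep)
                    )
                    th1 += p.th1_share * burst
                    th17 += p.th17_share * burst
                    ctl += p.ctl_share * burst
                    th2 += p.th2_share * burst
                ci += 1
            (
                th1,
                th2,
                th17,
                ctl,
                b_cells,
                ab,
                odc,
                infiltrate,
                pool,
                crossings,
            ) = _continuous_update(
                th1,
                th2,
                th17,
                ctl,
                b_cells,
                ab,
                odc,
                infiltrate,
                pool,
                f_cross,
                patient.thymus_efficiency,
                bdep,
                dt,
                p,
            )
            day_crossings += crossings

        damage = (
            damage * math.exp(-bp.repair_damage_clearance * repair)
            + tone
            + bp.inflammation_injury_gain * day_crossings
        )

        rec_odc[day + 1] = odc
        rec_inf[day + 1] = infiltrate
        rec_th1[day + 1] = th1
        rec_th17[day + 1] = th17
        rec_treg[day + 1] = treg
        rec_b[day + 1] = b_cells
        rec_tjp[day + 1] = tjp
        rec_teer[day + 1] = teer

    return PatientRun(
        patient_id=patient.id,
        time_days=np.arange(n_rec, dtype=float),
        odc=rec_odc,
        cns_infiltrate=rec_inf,
        th1=rec_th1,
        th17=rec_th17,
        treg=rec_treg,
        b_cells=rec_b,
        tjp=rec_tjp,
        teer=rec_teer,
        min_tjp=min_tjp,
    )


def odc_trajectory(
    patient: VirtualPatient,
    horizon_days: int,
    disease_params: DiseaseParams | None = None,
    bbb_params: BBBParams | None = None,
    arm: ArmArrays | None = None,
    master_seed: int = 0,
    dt: float = 0.25,
) -> pd.DataFrame:
    """ODC (and companion population) time series for one patient.

    Deterministic under a fixed ``master_seed``; the series starts at
    ``odc_baseline`` and every excursion recovers toward it.
    """
    if horizon_days is None or int(horizon_days) <= 0:
        raise ValidationError("horizon must be > 0")
    disease_params = (disease_params or DiseaseParams()).validate()
    bbb_params = (bbb_params or BBBParams()).validate()
    arm = arm or ArmArrays.untreated(int(horizon_days))
    run = simulate_patient(
        patient,
        int(horizon_days),
        disease_params,
        bbb_params,
        arm,
        master_seed,
        dt=dt,
    )
    return run.to_frame()
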