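"""Mechanistic blood-brain-barrier integrity model.

The barrier is summarised by a small state vector: a composite tight-junction
protein level (claudin-5/occludin, normalised so 1 means the healthy age-40
baseline), endothelial (BMEC) density, pericyte coverage, and an accumulated
inflammatory ``damage`` burden.  Two functional readouts derive from that
state: transendothelial electrical resistance (TEER, higher = tighter) and an
apparent paracellular permeability (higher = leakier).  Permeability and
inflammatory damage together gate the probability that activated immune cells
cross into the CNS.

Ageing is modelled as first-order decay of the TJP composite toward a floor,
with the decay constant accelerated in relapsing-remitting MS.  Barrier
repair (the NX210c pharmacodynamic input) acts persistently: it clears the
damage burden and raises the decay set point, so a single treatment cycle
produces a separation between treated and untreated trajectories that does
not wash out over decades.

Units: time is measured in days internally; ages and decline rates are
expressed in years at the interface (one year = 365 days).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

DAYS_PER_YEAR = 365.0


def _require_finite(name: str, value: float) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name} must be a real number, got {value!r}") from exc
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value}")
    return value


def _require_fraction(name: str, value: float) -> float:
    value = _require_finite(name, value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class BBBState:
    """Instantaneous barrier state.

    ``tjp_level``, ``bmec_density`` and ``pericyte_coverage`` are
    dimensionless fractions in [0, 1] (1 = healthy age-40 baseline).
    ``damage`` is a non-negative accumulated inflammatory-injury burden; it
    only decreases through explicit repair input, never silently.
    ``repair_reserve`` is the persistent rise of the decay set point
    accumulated from repair, and ``tjp_baseline`` records the subject's
    starting TJP level so floors scale per subject.
    """

    tjp_level: float = 1.0
    bmec_density: float = 1.0
    pericyte_coverage: float = 1.0
    damage: float = 0.0
    repair_reserve: float = 0.0
    tjp_baseline: float = 1.0

    def validate(self) -> "BBBState":
        _require_fraction("tjp_level", self.tjp_level)
        _require_fraction("bmec_density", self.bmec_density)
        _require_fraction("pericyte_coverage", self.pericyte_coverage)
        damage = _require_finite("damage", self.damage)
        if damage < 0.0:
            raise ValidationError(f"damage must be non-negative, got {damage}")
        reserve = _require_finite("repair_reserve", self.repair_reserve)
        if reserve < 0.0:
            raise ValidationError(f"repair_reserve must be non-negative, got {reserve}")
        baseline = _require_finite("tjp_baseline", self.tjp_baseline)
        if not 0.0 < baseline <= 1.0:
            raise ValidationError(f"tjp_baseline must lie in (0, 1], got {baseline}")
        return self


@dataclass(frozen=True)
class BBBParams:
    """Parameters of the barrier model.

    Rates are per year at the interface.  ``teer_baseline`` and
    ``perm_baseline`` are normalised readout scales (1 = healthy age-40);
    ``teer_invitro_scale`` converts normalised TEER to ohm*cm^2 when the in
    vitro reporting mode is wanted.  The default decline multiplier, repair
    gain and TEER exponent are calibrated so the shipped presets reproduce
    the published 30-year population contrasts (see docs/methods.md).
    """

    healthy_decline_rate: float = 0.010          # fractional TJP loss / year
    disease_decline_multiplier: float = 1.9004   # RRMS acceleration, > 1
    tjp_floor_frac: float = 0.30                 # decay floor as fraction of baseline
    teer_baseline: float = 1.0
    teer_floor_frac: float = 0.10                # paracellular-leak TEER floor
    teer_tjp_exponent: float = 1.3335            # alpha, >= 1
    teer_bmec_exponent: float = 1.0              # beta, >= 1
    teer_pericyte_exponent: float = 0.25         # pericyte coupling weight
    perm_baseline: float = 1.0
    inflammation_injury_gain: float = 4.5e-4     # damage per infiltrated cell
    repair_floor_gain: float = 0.09916           # set-point rise per unit repair*day
    repair_damage_clearance: float = 12.0        # damage decay per unit repair / day
    repair_reserve_cap_frac: float = 0.65        # max set-point rise / baseline
    infil_baseline_prob: float = 0.0015           # crossing prob at healthy barrier
    infil_midpoint: float = 2.2                  # leak-adhesion product at half-max
    infil_hill: float = 8.0
    teer_invitro_scale: float = 1500.0           # ohm*cm^2 per normalised TEER unit

    def validate(self) -> "BBBParams":
        if not _require_finite("healthy_decline_rate", self.healthy_decline_rate) > 0:
            raise ValidationError("healthy_decline_rate must be > 0")
        if not _require_finite(
            "disease_decline_multiplier", self.disease_decline_multiplier
        ) >= 1:
            raise ValidationError("disease_decline_multiplier must be >= 1")
        _require_fraction("tjp_floor_frac", self.tjp_floor_frac)
        _require_fraction("teer_floor_frac", self.teer_floor_frac)
        if self.teer_baseline <= 0 or self.perm_baseline <= 0:
            raise ValidationError("teer_baseline and perm_baseline must be > 0")
        for name in ("teer_tjp_exponent", "teer_bmec_exponent"):
            if getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must be >= 1")
        if self.teer_pericyte_exponent < 0.0:
            raise ValidationError("teer_pericyte_exponent must be >= 0")
        for name in (
            "inflammation_injury_gain",
            "repair_floor_gain",
            "repair_damage_clearance",
        ):
            if getattr(self, name) < 0.0:
                raise ValidationError(f"{name} must be >= 0")
        _require_fraction("repair_reserve_cap_frac", self.repair_reserve_cap_frac)
        _require_fraction("infil_baseline_prob", self.infil_baseline_prob)
        if self.teer_invitro_scale <= 0:
            raise ValidationError("teer_invitro_scale must be > 0")
        if self.infil_midpoint <= 0 or self.infil_hill <= 0:
            raise ValidationError("infil_midpoint and infil_hill must be > 0")
        if self.infil_baseline_prob * (1.0 + self.infil_midpoint**self.infil_hill) > 1.0:
            raise ValidationError(
                "infiltration parameters allow probabilities above 1; lower "
                "infil_baseline_prob or infil_midpoint"
            )
        return self


def compute_teer(state: BBBState, params: BBBParams) -> float:
    """Transendothelial electrical resistance, normalised (1 = healthy).

    TEER = floor + (baseline - floor) * tjp^alpha * bmec^beta * pericyte^gamma.
    Strictly increasing in the TJP composite and in BMEC density; at
    ``tjp_level = 0`` it equals the configured paracellular-leak floor rather
    than zero, because residual transcellular resistance remains.
    """
    state.validate()
    params.validate()
    floor = params.teer_floor_frac * params.teer_baseline
    tight = (
        state.tjp_level**params.teer_tjp_exponent
        * state.bmec_density**params.teer_bmec_exponent
        * state.pericyte_coverage**params.teer_pericyte_exponent
    )
    return floor + (params.teer_baseline - floor) * tight


def teer_ohm_cm2(state: BBBState, params: BBBParams) -> float:
    """TEER on the in vitro scale (ohm*cm^2) for monolayer-style reporting."""
    return compute_teer(state, params) * params.teer_invitro_scale


def compute_permeability(state: BBBState, params: BBBParams) -> float:
    """Apparent paracellular permeability, normalised (1 = healthy).

    Inversely coupled to TEER: perm = perm_baseline * teer_baseline / TEER,
    so any ordering of two states by TEER is exactly reversed in
    permeability.  Bounded above by perm_baseline / teer_floor_frac.
    """
    teer = compute_teer(state, params)
    return params.perm_baseline * params.teer_baseline / teer


def infiltration_probability(
    permeability: float,
    adhesion_upregulation: float,
    block_factor: float,
    params: BBBParams,
) -> float:
    """Per-candidate, per-day probability that an effector cell enters the CNS.

    The gate responds steeply (Hill coefficient ``infil_hill``) to the
    product of normalised permeability and adhesion-molecule upregulation, so
    modest barrier restoration closes most trafficking.  Treatments that
    block transmigration (natalizumab) scale the result by
    ``1 - block_factor``.
    """
    params.validate()
    permeability = _require_finite("permeability", permeability)
    if permeability <= 0:
        raise ValidationError(f"permeability must be > 0, got {permeability}")
    adhesion = _require_finite("adhesion_upregulation", adhesion_upregulation)
    if adhesion < 0:
        raise ValidationError("adhesion_upregulation must be >= 0")
    block = _require_finite("block_factor", block_factor)
    if not 0.0 <= block <= 1.0:
        raise ValidationError(f"block_factor must lie in [0, 1], got {block}")
    x = (permeability / params.perm_baseline) * adhesion
    h = params.infil_hill
    mid = params.infil_midpoint**h
    p = params.infil_baseline_prob * (1.0 + mid) * x**h / (mid + x**h)
    return p * (1.0 - block)


def step_bbb(
    state: BBBState,
    params: BBBParams,
    age: float,
    disease: bool,
    infiltration_load: float,
    repair_input: float,
    dt: float,
) -> BBBState:
    """Advance the barrier state by ``dt`` days.

    The TJP composite decays exactly (exponential integrator) toward its
    per-subject floor; disease multiplies the decay constant.  Repair input
    raises the floor persistently (capped) and clears accumulated damage;
    infiltrating cells add damage.  ``age`` (years) is accepted for interface
    symmetry; the decline law is age-homogeneous, so it only participates in
    validation.
    """
    state.validate()
    params.validate()
    _require_finite("age", age)
    dt = _require_finite("dt", dt)
    if dt < 0:
        raise ValidationError(f"dt must be >= 0, got {dt}")
    load = _require_finite("infiltration_load", infiltration_load)
    if load < 0:
        raise ValidationError("infiltration_load must be >= 0")
    repair = _require_finite("repair_input", repair_input)
    if repair < 0:
        raise ValidationError("repair_input must be >= 0")
    if dt == 0.0:
        return state

    cap = params.repair_reserve_cap_frac * state.tjp_baseline
    reserve = min(state.repair_reserve + params.repair_floor_gain * repair * dt, cap)
    floor = params.tjp_floor_frac * state.tjp_baseline + reserve

    k_day = params.healthy_decline_rate / DAYS_PER_YEAR
    if disease:
        k_day *= params.disease_decline_multiplier
    tjp = floor + (state.tjp_level - floor) * math.exp(-k_day * dt)

    damage = (
        state.damage * math.exp(-params.repair_damage_clearance * repair * dt)
        + params.inflammation_injury_gain * load
    )

    new = replace(
        state,
        tjp_level=tjp,
        damage=damage,
        repair_reserve=reserve,
    )
    return new.validate()


def healthy_trajectory_endpoint(
    params: BBBParams, years: float, disease: bool = False, tjp0: float = 1.0
) -> float:
    """Closed-form TJP level after ``years`` of untreated decline.

    Analytic solution of tjp' = -k (tjp - floor); used as the independent
    oracle for the discrete stepper and for calibration arithmetic.
    """
    params.validate()
    k = params.healthy_decline_rate * (
        params.disease_decline_multiplier if disease else 1.0
    )
    floor = params.tjp_floor_frac * tjp0
    return floor + (tjp0 - floor) * math.exp(-k * years)


def simulate_bbb_cohort(
    tjp0: np.ndarray,
    params: BBBParams,
    disease: bool,
    horizon_days: int,
    repair_daily: np.ndarray | None = None,
    damage0: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Vectorised daily barrier simulation for a cohort (no immune coupling).

    ``tjp0``: per-subject starting TJP levels (also the per-subject
    baselines); ``repair_daily``: shared per-day repair input (length >=
    horizon_days), e.g. from a dosing regimen; zeros if omitted.

    Returns arrays of shape (n_subjects, horizon_days + 1): ``tjp``,
    ``teer``, ``perm``, ``damage`` plus ``time_days``.  The update rule is
    the same exponential integrator as :func:`step_bbb`.
    """
    params.validate()
    tjp0 = np.asarray(tjp0, dtype=float)
    if np.any(~np.isfinite(tjp0)) or np.any(tjp0 <= 0) or np.any(tjp0 > 1):
        raise ValidationError("tjp0 entries must lie in (0, 1]")
    horizon_days = int(horizon_days)
    if horizon_days <= 0:
        raise ValidationError("horizon_days must be > 0")
    if repair_daily is None:
        repair_daily = np.zeros(horizon_days)
    repair_daily = np.asarray(repair_daily, dtype=float)
    if repair_daily.shape[0] < horizon_days:
        raise ValidationError("repair_daily shorter than horizon")
    n = tjp0.shape[0]
    tjp = np.empty((n, horizon_days + 1))
    damage = np.empty((n, horizon_days + 1))
    tjp[:, 0] = tjp0
    damage[:, 0] = 0.0 if damage0 is None else np.asarray(damage0, dtype=float)

    k_day = params.healthy_decline_rate / DAYS_PER_YEAR
    if disease:
        k_day *= params.disease_decline_multiplier
    decay = math.exp(-k_day)
    cap = params.repair_reserve_cap_frac * tjp0
    reserve = np.zeros(n)
    for d in range(horizon_days):
        r = repair_daily[d]
        reserve = np.minimum(reserve + params.repair_floor_gain * r, cap)
        floor = params.tjp_floor_frac * tjp0 + reserve
        tjp[:, d + 1] = floor + (tjp[:, d] - floor) * decay
        damage[:, d + 1] = damage[:, d] * math.exp(
            -params.repair_damage_clearance * r
        )

    floor_teer = params.teer_floor_frac * params.teer_baseline
    teer = floor_teer + (params.teer_baseline - floor_teer) * tjp**params.teer_tjp_exponent
    perm = params.perm_baseline * params.teer_baseline / teer
    return {
        "time_days": np.arange(horizon_days + 1, dtype=float),
        "tjp": tjp,
        "teer": teer,
        "perm": perm,
        "damage": damage,
    }


def bbb_series_frame(series: dict[str, np.ndarray], subject: int) -> pd.DataFrame:
    """One subject's barrier time course as a tidy frame (CSV-ready)."""
    return pd.DataFrame(
        {
            "time_days": series["time_days"],
            "tjp_level": series["tjp"][subject],
            "teer": series["teer"][subject],
            "permeability": series["perm"][subject],
            "damage": series["damage"][subject],
        }
    )
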