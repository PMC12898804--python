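"""Scenario orchestration: arms, relapse detection, endpoint aggregation.

A scenario fixes a virtual population, a horizon, and a set of treatment
arms; every arm is simulated on the same patient roster with identical
per-patient random draws (paired virtual-trial design, variance reduction).
Relapses are detected on each patient's oligodendrocyte trajectory by
excursion segmentation: an event opens when ODC falls below
``baseline * (1 - subclinical_threshold_frac)`` and closes on recovery
above that level; the event is *clinical* when its nadir drops below 15%
of baseline (42,500 cells/uL at the 50,000 baseline), otherwise
*subclinical*.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError as PydanticValidationError

from .bbb import BBBParams, simulate_bbb_cohort
from .errors import ConfigError, ValidationError
from .immune import ArmArrays, DiseaseParams, PatientRun, simulate_patient
from .pk import PKParams, get_regimen
from .population import VirtualPatient, generate_population
from .treatments import Drug, PDParams, daily_repair_series, soc_effect_arrays

DAYS_PER_YEAR = 365.0


class RelapseClass(str, enum.Enum):
    CLINICAL = "clinical"
    SUBCLINICAL = "subclinical"


@dataclass(frozen=True)
class RelapseEvent:
    onset_day: float
    nadir_time_day: float
    nadir_odc: float
    classification: RelapseClass
    recovery_day: float | None = None
    patient_id: int | None = None


def detect_relapses(
    time_days: np.ndarray,
    odc: np.ndarray,
    baseline: float,
    subclinical_threshold_frac: float = 0.05,
    clinical_threshold_frac: float = 0.15,
) -> list[RelapseEvent]:
    """Segment transient ODC drops into classified relapse events.

    One event per excursion below the detection threshold; classification
    is by nadir against the clinical threshold (15% below baseline).
    """
    if baseline is None or baseline <= 0:
        raise ValidationError(f"baseline must be > 0, got {baseline}")
    if not 0.0 < subclinical_threshold_frac < clinical_threshold_frac:
        raise ValidationError(
            "subclinical_threshold_frac must lie in (0, clinical_threshold_frac)"
        )
    time_days = np.asarray(time_days, dtype=float)
    odc = np.asarray(odc, dtype=float)
    if time_days.shape != odc.shape:
        raise ValidationError("time and odc must have equal length")

    detect_level = baseline * (1.0 - subclinical_threshold_frac)
    clinical_level = baseline * (1.0 - clinical_threshold_frac)

    events: list[RelapseEvent] = []
    in_event = False
    onset = nadir_t = 0.0
    nadir = baseline
    for t, v in zip(time_days, odc):
        if not in_event:
            if v < detect_level:
                in_event = True
                onset = t
                nadir = v
                nadir_t = t
        else:
            if v < nadir:
                nadir = v
                nadir_t = t
            if v >= detect_level:
                events.append(
                    RelapseEvent(
                        onset_day=onset,
                        nadir_time_day=nadir_t,
                        nadir_odc=nadir,
                        classification=(
                            RelapseClass.CLINICAL
                            if nadir < clinical_level
                            else RelapseClass.SUBCLINICAL
                        ),
                        recovery_day=t,
                    )
                )
                in_event = False
    if in_event:
        events.append(
            RelapseEvent(
                onset_day=onset,
                nadir_time_day=nadir_t,
                nadir_odc=nadir,
                classification=(
                    RelapseClass.CLINICAL
                    if nadir < clinical_level
                    else RelapseClass.SUBCLINICAL
                ),
                recovery_day=None,
            )
        )
    return events


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------


class PopulationConfig(BaseModel):
    profile: Literal["healthy", "rrms_default", "rrms_highly_active"] = "rrms_default"
    n: int = Field(100, ge=1)
    age: Optional[float] = None  # fix the cohort age (e.g. 40) when set


class ArmConfig(BaseModel):
    name: str
    nx210c: Optional[str] = None       # NX210c regimen preset name
    soc: list[str] = Field(default_factory=list)
    profile: Optional[str] = None      # override the scenario population profile
    clamp_bbb_healthy: bool = False    # mechanism probe: gate at healthy barrier


class ScenarioConfig(BaseModel):
    name: str = "scenario"
    kind: Literal["bbb", "coupled"] = "coupled"
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    horizon_years: float = Field(2.0, gt=0)
    dt_days: float = 0.25
    master_seed: int = 20260129
    subclinical_threshold_frac: float = 0.05
    clinical_threshold_frac: float = 0.15
    arms: list[ArmConfig] = Field(min_length=1)
    comparator: Optional[str] = None   # defaults to the first arm

    def validated(self) -> "ScenarioConfig":
        names = [a.name for a in self.arms]
        problems = []
        if len(set(names)) != len(names):
            problems.append("arm names must be unique")
        comp = self.comparator or names[0]
        if comp not in names:
            problems.append(f"comparator {comp!r} is not an arm")
        for a in self.arms:
            if a.nx210c is not None:
                try:
                    get_regimen(a.nx210c)
                except ValidationError as exc:
                    problems.append(str(exc))
            for d in a.soc:
                try:
                    Drug(d)
                except ValueError:
                    problems.append(f"arm {a.name!r}: unknown SoC drug {d!r}")
        if problems:
            raise ConfigError("; ".join(problems))
        return self


def load_scenario(source: str | Path | dict) -> ScenarioConfig:
    """Parse a scenario from YAML/JSON text, a path, or a mapping."""
    import yaml

    if isinstance(source, (str, Path)) and Path(source).exists():
        source = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        source = yaml.safe_load(source)
    try:
        return ScenarioConfig.model_validate(source).validated()
    except PydanticValidationError as exc:
        items = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(items) from None


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class ArmResult:
    name: str
    events: list[list[RelapseEvent]]            # per patient
    final_tjp: np.ndarray
    final_teer: np.ndarray
    min_tjp: np.ndarray
    mean_odc: np.ndarray | None = None          # population-mean trajectory
    time_days: np.ndarray | None = None
    series: list[PatientRun] | None = None

    def counts(self, cls: RelapseClass | None = None) -> np.ndarray:
        return np.array(
            [
                sum(1 for e in evs if cls is None or e.classification is cls)
                for evs in self.events
            ],
            dtype=float,
        )

    @property
    def mean_clinical(self) -> float:
        return float(self.counts(RelapseClass.CLINICAL).mean())

    @property
    def mean_subclinical(self) -> float:
        return float(self.counts(RelapseClass.SUBCLINICAL).mean())

    @property
    def mean_total(self) -> float:
        return float(self.counts().mean())

    @property
    def sd_total(self) -> float:
        return float(self.counts().std(ddof=0))


@dataclass
class TrialResult:
    config: ScenarioConfig
    patients: list[VirtualPatient]
    arms: dict[str, ArmResult]

    def arm(self, name: str) -> ArmResult:
        try:
            return self.arms[name]
        except KeyError:
            raise ValidationError(
                f"unknown arm {name!r}; available: {sorted(self.arms)}"
            ) from None

    def bbb_endpoint(self, arm: str, comparator: str) -> dict[str, float]:
        """Population-mean signed percent difference of final TJP and TEER."""
        a = self.arm(arm)
        c = self.arm(comparator)
        if a.final_tjp.shape != c.final_tjp.shape:
            raise ValidationError("arms have misaligned cohorts")
        pct_tjp = 100.0 * float(np.mean(a.final_tjp / c.final_tjp - 1.0))
        pct_teer = 100.0 * float(np.mean(a.final_teer / c.final_teer - 1.0))
        return {"pct_tjp": pct_tjp, "pct_teer": pct_teer}

    def mean_trajectory_events(self, arm: str) -> list[RelapseEvent]:
        """Relapses counted on the population-mean ODC trajectory."""
        a = self.arm(arm)
        if a.mean_odc is None:
            raise ValidationError(f"arm {arm!r} has no ODC trajectory (BBB-only run)")
        return detect_relapses(
            a.time_days,
            a.mean_odc,
            DiseaseParams().odc_baseline,
            self.config.subclinical_threshold_frac,
            self.config.clinical_threshold_frac,
        )

    def summary(self) -> pd.DataFrame:
        comp = self.config.comparator or self.config.arms[0].name
        rows = []
        for name, arm in self.arms.items():
            ep = self.bbb_endpoint(name, comp)
            rows.append(
                {
                    "arm": name,
                    "mean_clinical": arm.mean_clinical,
                    "mean_subclinical": arm.mean_subclinical,
                    "mean_total": arm.mean_total,
                    "sd_total": arm.sd_total,
                    "final_tjp_mean": float(arm.final_tjp.mean()),
                    "final_teer_mean": float(arm.final_teer.mean()),
                    "pct_tjp_vs_comparator": ep["pct_tjp"],
                    "pct_teer_vs_comparator": ep["pct_teer"],
                }
            )
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "scenario": self.config.name,
            "comparator": self.config.comparator or self.config.arms[0].name,
            "arms": {
                row["arm"]: {k: v for k, v in row.items() if k != "arm"}
                for row in self.summary().to_dict(orient="records")
            },
        }

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for name, arm in self.arms.items():
            for pid, evs in enumerate(arm.events):
                for e in evs:
                    rows.append(
                        {
                            "arm": name,
                            "patient": pid,
                            "onset_day": e.onset_day,
                            "nadir_day": e.nadir_time_day,
                            "nadir_odc": e.nadir_odc,
                            "classification": e.classification.value,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "arm",
                "patient",
                "onset_day",
                "nadir_day",
                "nadir_odc",
                "classification",
            ],
        )


# ---------------------------------------------------------------------------
# scenario execution
# ---------------------------------------------------------------------------


def _arm_arrays(
    arm: ArmConfig,
    horizon_days: int,
    pk_params: PKParams,
    pd_params: PDParams,
) -> ArmArrays:
    if arm.nx210c is not None:
        repair = daily_repair_series(
            get_regimen(arm.nx210c), pk_params, pd_params, horizon_days
        )
    else:
        repair = np.zeros(horizon_days)
    if arm.soc:
        soc = soc_effect_arrays(list(arm.soc), horizon_days)
        return ArmArrays(
            repair=repair,
            block=soc["infiltration_block"],
            dc_mult=soc["dc_activation_mult"],
            prolif_mult=soc["lymphocyte_prolif_mult"],
            bdep=soc["bcell_depletion_frac"],
            ldep=soc["lymphodepletion_frac"],
        )
    base = ArmArrays.untreated(horizon_days)
    return ArmArrays(
        repair=repair,
        block=base.block,
        dc_mult=base.dc_mult,
        prolif_mult=base.prolif_mult,
        bdep=base.bdep,
        ldep=base.ldep,
    )


def run_scenario(
    config: ScenarioConfig | dict | str | Path,
    master_seed: int | None = None,
    bbb_params: BBBParams | None = None,
    disease_params: DiseaseParams | None = None,
    pk_params: PKParams | None = None,
    pd_params: PDParams | None = None,
    keep_series: bool = False,
    progress: bool = False,
) -> TrialResult:
    """Simulate every arm of a scenario on a shared patient roster."""
    if not isinstance(config, ScenarioConfig):
        config = load_scenario(config)
    config = config.validated()
    seed = int(master_seed) if master_seed is not None else config.master_seed
    bbb_params = (bbb_params or BBBParams()).validate()
    disease_params = (disease_params or DiseaseParams()).validate()
    pk_params = (pk_params or PKParams()).validate()
    pd_params = (pd_params or PDParams()).validate()

    horizon_days = int(round(config.horizon_years * DAYS_PER_YEAR))
    rosters: dict[str, list[VirtualPatient]] = {}

    def roster_for(profile: str) -> list[VirtualPatient]:
        if profile not in rosters:
            pats = generate_population(config.population.n, profile, seed)
            if config.population.age is not None:
                pats = [replace(p, age=config.population.age) for p in pats]
            rosters[profile] = pats
        return rosters[profile]

    arms: dict[str, ArmResult] = {}
    for arm_cfg in config.arms:
        profile = arm_cfg.profile or config.population.profile
        patients = roster_for(profile)
        arrays = _arm_arrays(arm_cfg, horizon_days, pk_params, pd_params)
        if progress:
            import sys

            print(f"[bbbqsp] arm {arm_cfg.name!r} ({profile})", file=sys.stderr)

        if config.kind == "bbb":
            tjp0 = np.array([p.baseline_bbb_integrity for p in patients])
            series = simulate_bbb_cohort(
                tjp0,
                bbb_params,
                disease=(profile != "healthy"),
                horizon_days=horizon_days,
                repair_daily=arrays.repair,
                damage0=np.array([p.baseline_damage for p in patients]),
            )
            arms[arm_cfg.name] = ArmResult(
                name=arm_cfg.name,
                events=[[] for _ in patients],
                final_tjp=series["tjp"][:, -1].copy(),
                final_teer=series["teer"][:, -1].copy(),
                min_tjp=series["tjp"].min(axis=1),
            )
            continue

        runs: list[PatientRun] = []
        events: list[list[RelapseEvent]] = []
        for patient in patients:
            run = simulate_patient(
                patient,
                horizon_days,
                disease_params,
                bbb_params,
                arrays,
                master_seed=seed,
                dt=config.dt_days,
                disease=(profile != "healthy"),
                clamp_bbb_healthy=arm_cfg.clamp_bbb_healthy,
            )
            runs.append(run)
            events.append(
                detect_relapses(
                    run.time_days,
                    run.odc,
                    disease_params.odc_baseline,
                    config.subclinical_threshold_frac,
                    config.clinical_threshold_frac,
                )
            )
        mean_odc = np.mean([r.odc for r in runs], axis=0)
        arms[arm_cfg.name] = ArmResult(
            name=arm_cfg.name,
            events=events,
            final_tjp=np.array([r.tjp[-1] for r in runs]),
            final_teer=np.array([r.teer[-1] for r in runs]),
            min_tjp=np.array([r.min_tjp for r in runs]),
            mean_odc=mean_odc,
            time_days=runs[0].time_days,
            series=runs if keep_series else None,
        )

    # reuse the first arm's patients attribute for the roster actually used
    main_profile = config.population.profile
    return TrialResult(
        config=config, patients=roster_for(main_profile), arms=arms
    )


def write_outputs(result: TrialResult, out_dir: str | Path, series: bool = False) -> None:
    """Persist summary.json, events.csv and optional per-patient series."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(json.dumps(result.to_json_dict(), indent=2))
    result.events_frame().to_csv(out / "events.csv", index=False)
    if series:
        sdir = out / "series"
        sdir.mkdir(exist_ok=True)
        for name, arm in result.arms.items():
            if arm.series is None:
                continue
            for run in arm.series:
                run.to_frame().to_csv(
                    sdir / f"{name}_patient{run.patient_id}.csv", index=False
                )
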