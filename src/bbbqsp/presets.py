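"""Reference scenario presets.

Each preset is a ready-to-run :class:`~bbbqsp.trial.ScenarioConfig`
mirroring one of the published simulation studies:

* ``fig5`` — 30-year barrier-only ageing study in 40-year-old healthy and
  RRMS cohorts, untreated or given one 4-week NX210c cycle (5 / 10 mg/kg).
* ``fig6`` — 2-year relapse study in 100 default RRMS patients: untreated
  versus a single 4-week cycle at 5 or 10 mg/kg.
* ``fig7`` — 10-year study in highly active patients: untreated versus
  repeated 4-week 10 mg/kg cycles every 6 months.
* ``fig8`` — 2-year combination study in highly active patients: untreated,
  five standard-of-care monotherapies, NX210c single cycle or repeated
  cycles, and every SoC combined with each NX210c regimen.
"""

from __future__ import annotations

from .errors import ValidationError
from .trial import ArmConfig, PopulationConfig, ScenarioConfig

_SOC = ["interferon_b1a", "teriflunomide", "natalizumab", "ocrelizumab", "cladribine"]


def _fig5() -> ScenarioConfig:
    return ScenarioConfig(
        name="fig5",
        kind="bbb",
        population=PopulationConfig(profile="rrms_default", n=100, age=40.0),
        horizon_years=30.0,
        arms=[
            ArmConfig(name="healthy_untreated", profile="healthy"),
            ArmConfig(name="healthy_nx210c_5", profile="healthy", nx210c="nx210c_5mgkg_cycle"),
            ArmConfig(name="healthy_nx210c_10", profile="healthy", nx210c="nx210c_10mgkg_cycle"),
            ArmConfig(name="rrms_untreated"),
            ArmConfig(name="rrms_nx210c_5", nx210c="nx210c_5mgkg_cycle"),
            ArmConfig(name="rrms_nx210c_10", nx210c="nx210c_10mgkg_cycle"),
        ],
        comparator="rrms_untreated",
    )


def _fig6() -> ScenarioConfig:
    return ScenarioConfig(
        name="fig6",
        kind="coupled",
        population=PopulationConfig(profile="rrms_default", n=100),
        horizon_years=2.0,
        arms=[
            ArmConfig(name="untreated"),
            ArmConfig(name="nx210c_5", nx210c="nx210c_5mgkg_cycle"),
            ArmConfig(name="nx210c_10", nx210c="nx210c_10mgkg_cycle"),
        ],
        comparator="untreated",
    )


def _fig7() -> ScenarioConfig:
    return ScenarioConfig(
        name="fig7",
        kind="coupled",
        population=PopulationConfig(profile="rrms_highly_active", n=100),
        horizon_years=10.0,
        arms=[
            ArmConfig(name="untreated"),
            ArmConfig(name="nx210c_10_q6m", nx210c="nx210c_10mgkg_q6m"),
        ],
        comparator="untreated",
    )


def _fig8() -> ScenarioConfig:
    arms = [ArmConfig(name="untreated")]
    for d in _SOC:
        arms.append(ArmConfig(name=d, soc=[d]))
    arms.append(ArmConfig(name="nx210c_single", nx210c="nx210c_10mgkg_cycle"))
    arms.append(ArmConfig(name="nx210c_q6m", nx210c="nx210c_10mgkg_q6m"))
    for d in _SOC:
        arms.append(
            ArmConfig(name=f"{d}+nx210c_single", soc=[d], nx210c="nx210c_10mgkg_cycle")
        )
    for d in _SOC:
        arms.append(
            ArmConfig(name=f"{d}+nx210c_q6m", soc=[d], nx210c="nx210c_10mgkg_q6m")
        )
    return ScenarioConfig(
        name="fig8",
        kind="coupled",
        population=PopulationConfig(profile="rrms_highly_active", n=100),
        horizon_years=2.0,
        arms=arms,
        comparator="untreated",
    )


_BUILDERS = {"fig5": _fig5, "fig6": _fig6, "fig7": _fig7, "fig8": _fig8}


def preset_names() -> list[str]:
    return sorted(_BUILDERS)


def get_preset(name: str) -> ScenarioConfig:
    try:
        return _BUILDERS[name]().validated()
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {preset_names()}"
        ) from None
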