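"""Virtual patient generation.

Patients carry the heterogeneity handles the disease layer consumes: an
abstract HLA repertoire (fixed-length binary strings per MHC-I locus A/B/C
and MHC-II locus DM/DO/DP/DQ/DR), thymic output efficiency, the probability
that an autoreactive clone activates on antigen exposure, a multiplier on
the self-antigen event rate, baseline barrier integrity, and a pre-existing
inflammatory damage burden.  Three profiles ship: ``healthy`` (no
autoimmune triggering), ``rrms_default``, and ``rrms_highly_active``
(shifted toward low thymic output, high activation propensity, high event
rate — the published risk-factor perturbation).

The HLA repertoire is an abstraction, not real allele tables: DQ/DR bits
deterministically modulate the activation probability (a popcount-based
factor), so class-II variation has phenotypic effect while permuting the
class-I loci leaves disease activity unchanged in expectation.

All sampling is reproducible: ``generate_patient(profile, seed)`` is a pure
function of its arguments, and ``generate_population`` derives per-patient
seeds from the master seed by index, so a longer roster extends a shorter
one without changing its common prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

HLA_LOCI = ("A", "B", "C", "DM", "DO", "DP", "DQ", "DR")
HLA_BITS_PER_LOCUS = 16


@dataclass(frozen=True)
class VirtualPatient:
    id: int
    age: float
    sex: str
    weight_kg: float
    hla: dict[str, str]
    thymus_efficiency: float
    activation_prob: float
    antigen_rate_multiplier: float
    baseline_bbb_integrity: float
    baseline_damage: float
    profile: str = "rrms_default"

    def validate(self) -> "VirtualPatient":
        if not 0.0 < self.thymus_efficiency <= 1.0:
            raise ValidationError("thymus_efficiency must lie in (0, 1]")
        if not 0.0 <= self.activation_prob <= 1.0:
            raise ValidationError("activation_prob must lie in [0, 1]")
        if self.antigen_rate_multiplier < 0.0:
            raise ValidationError("antigen_rate_multiplier must be >= 0")
        if not 0.0 < self.baseline_bbb_integrity <= 1.0:
            raise ValidationError("baseline_bbb_integrity must lie in (0, 1]")
        if self.baseline_damage < 0.0:
            raise ValidationError("baseline_damage must be >= 0")
        missing = [l for l in HLA_LOCI if l not in self.hla]
        if missing:
            raise ValidationError(f"missing HLA loci: {missing}")
        return self


@dataclass(frozen=True)
class ProfileSpec:
    """Distribution parameters for one population profile.

    Beta for the bounded supports (thymic efficiency, activation
    probability), log-normal for the right-skewed antigen event-rate
    multiplier and pre-existing damage, truncated normal for baseline
    barrier integrity; demographics follow typical RRMS trial ranges.
    """

    name: str
    thymus_beta: tuple[float, float]
    activation_beta: tuple[float, float]
    antigen_lognorm: tuple[float, float]       # (mu of log, sigma of log)
    integrity_norm: tuple[float, float]        # (mean, sd), truncated to (0.85, 1]
    damage_lognorm: tuple[float, float]
    antigen_zero: bool = False                 # healthy: no autoimmune triggering
    damage_zero: bool = False
    age_range: tuple[float, float] = (18.0, 55.0)
    weight_range: tuple[float, float] = (50.0, 100.0)


PROFILES: dict[str, ProfileSpec] = {
    "healthy": ProfileSpec(
        name="healthy",
        thymus_beta=(6.0, 3.0),
        activation_beta=(2.0, 8.0),
        antigen_lognorm=(0.0, 0.0),
        integrity_norm=(0.98, 0.015),
        damage_lognorm=(0.0, 0.0),
        antigen_zero=True,
        damage_zero=True,
    ),
    "rrms_default": ProfileSpec(
        name="rrms_default",
        thymus_beta=(5.0, 5.0),
        activation_beta=(3.5, 4.0),
        antigen_lognorm=(np.log(1.25), 0.20),
        integrity_norm=(0.98, 0.015),
        damage_lognorm=(np.log(0.60), 0.30),
    ),
    "rrms_highly_active": ProfileSpec(
        name="rrms_highly_active",
        thymus_beta=(2.0, 6.0),
        activation_beta=(6.0, 1.7),
        antigen_lognorm=(np.log(1.7), 0.30),
        integrity_norm=(0.96, 0.020),
        damage_lognorm=(np.log(1.3), 0.30),
    ),
}


def hla_activation_factor(hla: dict[str, str]) -> float:
    """Deterministic activation-probability modulation from HLA-DQ/DR bits.

    The fraction of set bits across the DQ and DR strings maps linearly to
    a factor in [0.85, 1.15]; class-I loci do not enter.
    """
    bits = hla["DQ"] + hla["DR"]
    frac = sum(b == "1" for b in bits) / len(bits)
    return 0.85 + 0.30 * frac


def _sample_hla(rng: np.random.Generator) -> dict[str, str]:
    return {
        locus: "".join(
            "1" if b else "0" for b in rng.integers(0, 2, HLA_BITS_PER_LOCUS)
        )
        for locus in HLA_LOCI
    }


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return float(x)
    return float(np.clip(mean, lo + 1e-9, hi))


def generate_patient(
    profile: str, seed: int, patient_id: int = 0
) -> VirtualPatient:
    """Sample one virtual patient; deterministic for fixed (profile, seed)."""
    if profile not in PROFILES:
        raise ValidationError(
            f"unknown profile {profile!r}; available: {sorted(PROFILES)}"
        )
    if seed is None:
        raise ValidationError("a seed is required")
    spec = PROFILES[profile]
    rng = np.random.default_rng(int(seed))

    age = float(rng.uniform(*spec.age_range))
    sex = "F" if rng.uniform() < 0.7 else "M"  # RRMS trials skew female ~2-3:1
    weight = float(rng.uniform(*spec.weight_range))
    hla = _sample_hla(rng)
    thymus = float(np.clip(rng.beta(*spec.thymus_beta), 1e-6, 1.0))
    act_raw = float(rng.beta(*spec.activation_beta))
    activation = float(np.clip(act_raw * hla_activation_factor(hla), 0.0, 1.0))
    if spec.antigen_zero:
        antigen_mult = 0.0
    else:
        antigen_mult = float(rng.lognormal(*spec.antigen_lognorm))
    integrity = _trunc_normal(rng, *spec.integrity_norm, 0.85, 1.0)
    damage = 0.0 if spec.damage_zero else float(rng.lognormal(*spec.damage_lognorm))
    return VirtualPatient(
        id=patient_id,
        age=age,
        sex=sex,
        weight_kg=weight,
        hla=hla,
        thymus_efficiency=thymus,
        activation_prob=activation,
        antigen_rate_multiplier=antigen_mult,
        baseline_bbb_integrity=integrity,
        baseline_damage=damage,
        profile=profile,
    ).validate()


def patient_seed(master_seed: int, index: int) -> int:
    """Per-patient substream seed, stable in the roster prefix."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_population(
    n: int, profile: str, master_seed: int
) -> list[VirtualPatient]:
    """A roster of ``n`` patients with per-patient seeds derived by index."""
    if n is None or int(n) < 1:
        raise ValidationError(f"population size must be >= 1, got {n}")
    return [
        generate_patient(profile, patient_seed(master_seed, i), patient_id=i)
        for i in range(int(n))
    ]


def roster_to_frame(patients: list[VirtualPatient]) -> pd.DataFrame:
    rows = []
    for p in patients:
        row = {
            "id": p.id,
            "profile": p.profile,
            "age": p.age,
            "sex": p.sex,
            "weight_kg": p.weight_kg,
            "thymus_efficiency": p.thymus_efficiency,
            "activation_prob": p.activation_prob,
            "antigen_rate_multiplier": p.antigen_rate_multiplier,
            "baseline_bbb_integrity": p.baseline_bbb_integrity,
            "baseline_damage": p.baseline_damage,
        }
        for locus in HLA_LOCI:
            row[f"hla_{locus}"] = p.hla[locus]
        rows.append(row)
    return pd.DataFrame(rows)


def roster_from_frame(frame: pd.DataFrame) -> list[VirtualPatient]:
    """Rebuild an identical cohort from an exported roster."""
    patients = []
    for _, row in frame.iterrows():
        hla = {locus: str(row[f"hla_{locus}"]) for locus in HLA_LOCI}
        patients.append(
            VirtualPatient(
                id=int(row["id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                weight_kg=float(row["weight_kg"]),
                hla=hla,
                thymus_efficiency=float(row["thymus_efficiency"]),
                activation_prob=float(row["activation_prob"]),
                antigen_rate_multiplier=float(row["antigen_rate_multiplier"]),
                baseline_bbb_integrity=float(row["baseline_bbb_integrity"]),
                baseline_damage=float(row["baseline_damage"]),
                profile=str(row["profile"]),
            ).validate()
        )
    return patients
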