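"""Effect profiles: the parameters every synthetic dataset is generated from.

A profile bundles the condition x time effects to inject (behavioral
z-score difference-in-differences, retinal caliber shifts in µm, causal
density shifts), the noise levels and population parameters around them,
and the mediation path coefficients.  The packaged ``paper_effects``
profile encodes the reference study's effect estimates; :func:`null_profile`
zeroes every effect while keeping the same noise structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

__all__ = [
    "ProfileError",
    "EffectProfile",
    "load_profile",
    "paper_effects",
    "null_profile",
]

CONDITIONS = ("SIT", "MIC", "VIC")
BLOCKS = ("baseline", "color_dual", "lexical_dual")
MEASURES = ("rt", "er", "ies")


class ProfileError(ValueError):
    """A profile field is missing or invalid; the message names the field."""


def _require_positive(value: float, fieldname: str) -> float:
    if not value > 0:
        raise ProfileError(f"{fieldname} must be > 0, got {value}")
    return float(value)


@dataclass
class CovariateParams:
    female_prop: float = 0.507
    age_mean: float = 20.94
    age_sd: float = 1.93
    bmi_mean: float = 21.67
    bmi_sd: float = 3.8

    def __post_init__(self) -> None:
        if not 0 <= self.female_prop <= 1:
            raise ProfileError("covariates.female_prop must be in [0, 1]")
        _require_positive(self.age_sd, "covariates.age_sd")
        _require_positive(self.bmi_sd, "covariates.bmi_sd")


@dataclass
class BehavioralParams:
    """Trial-level generator parameters for the dual-task Stroop blocks."""

    dids: dict[str, dict[str, float]] = field(default_factory=dict)
    calibration_condition: str = "MIC"
    rt_median_ms: float = 680.0
    rt_sigma_log: float = 0.20
    block_rt_scale: dict[str, float] = field(
        default_factory=lambda: {b: s for b, s in zip(BLOCKS, (1.0, 1.15, 1.25))}
    )
    er_mean: float = 0.10
    er_sd: float = 0.08
    rt_sex_effect_log: float = 0.04
    rt_age_effect_log_per_yr: float = 0.008
    omission_fraction: float = 0.2
    trials_per_sequence: int = 12
    sequences_per_block: int = 3

    def __post_init__(self) -> None:
        _require_positive(self.rt_median_ms, "behavioral.rt_median_ms")
        _require_positive(self.rt_sigma_log, "behavioral.rt_sigma_log")
        _require_positive(self.er_sd, "behavioral.er_sd")
        if not 0 < self.er_mean < 1:
            raise ProfileError("behavioral.er_mean must be in (0, 1)")
        if self.er_sd ** 2 >= self.er_mean * (1 - self.er_mean):
            raise ProfileError(
                "behavioral.er_sd too large for a Beta subject-error model"
            )
        for cond, d in self.dids.items():
            unknown = set(d) - set(MEASURES)
            if unknown:
                raise ProfileError(
                    f"behavioral.dids[{cond}] has unknown measures {sorted(unknown)}"
                )

    @property
    def trials_per_block(self) -> int:
        return self.trials_per_sequence * self.sequences_per_block

    @property
    def beta_params(self) -> tuple[float, float]:
        """(alpha, beta) of the subject error-probability distribution."""
        m, v = self.er_mean, self.er_sd ** 2
        nu = m * (1 - m) / v - 1
        return m * nu, (1 - m) * nu


@dataclass
class RetinalParams:
    interaction_um: dict[str, float] = field(
        default_factory=lambda: {"crae": 0.0, "crve": 0.0}
    )
    dids: dict[str, dict[str, float]] = field(default_factory=dict)
    crae_mean_um: float = 150.0
    crve_mean_um: float = 200.0
    between_subject_sd_um: float = 15.0
    residual_sd_um: float = 3.0

    def __post_init__(self) -> None:
        _require_positive(self.crae_mean_um, "retinal.crae_mean_um")
        _require_positive(self.crve_mean_um, "retinal.crve_mean_um")
        _require_positive(self.between_subject_sd_um, "retinal.between_subject_sd_um")
        _require_positive(self.residual_sd_um, "retinal.residual_sd_um")


@dataclass
class CausalDensityParams:
    interaction: float = 0.0
    dids: dict[str, float] = field(default_factory=dict)
    base: float = 0.3
    between_subject_sd: float = 0.08
    residual_sd: float = 0.10

    def __post_init__(self) -> None:
        _require_positive(self.between_subject_sd, "causal_density.between_subject_sd")
        _require_positive(self.residual_sd, "causal_density.residual_sd")


@dataclass
class MediationPaths:
    """Generating path coefficients; the total effect is c' + a*b by identity."""

    a: float = 0.0
    b: float = 0.0
    c_prime: float = 0.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        _require_positive(self.noise_sd, "mediation.noise_sd")

    @property
    def total(self) -> float:
        return self.c_prime + self.a * self.b


@dataclass
class EffectProfile:
    name: str
    n_subjects: int
    covariates: CovariateParams
    behavioral: BehavioralParams
    retinal: RetinalParams
    cd_resting: CausalDensityParams
    cd_task: CausalDensityParams
    mediation: MediationPaths

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ProfileError(f"n_subjects must be >= 2, got {self.n_subjects}")


def _from_mapping(payload: dict) -> EffectProfile:
    cd = payload.get("causal_density", {})
    return EffectProfile(
        name=payload.get("name", "unnamed"),
        n_subjects=int(payload["n_subjects"]),
        covariates=CovariateParams(**payload.get("covariates", {})),
        behavioral=BehavioralParams(**payload.get("behavioral", {})),
        retinal=RetinalParams(**payload.get("retinal", {})),
        cd_resting=CausalDensityParams(**cd.get("resting", {})),
        cd_task=CausalDensityParams(**cd.get("task", {})),
        mediation=MediationPaths(**payload.get("mediation", {})),
    )


def load_profile(path) -> EffectProfile:
    """Load an effect profile from a YAML file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    try:
        return _from_mapping(payload)
    except KeyError as exc:  # missing required key
        raise ProfileError(f"profile is missing field {exc}") from exc


def paper_effects() -> EffectProfile:
    """The packaged profile encoding the reference study's effects."""
    ref = resources.files("exercog.data").joinpath("paper_effects.yaml")
    with ref.open() as fh:
        return _from_mapping(yaml.safe_load(fh))


def null_profile(n_subjects: int = 71) -> EffectProfile:
    """Same noise structure as ``paper_effects`` with every effect zeroed."""
    prof = paper_effects()
    beh = replace(
        prof.behavioral,
        dids={c: {m: 0.0 for m in MEASURES} for c in prof.behavioral.dids},
    )
    ret = replace(
        prof.retinal,
        interaction_um={k: 0.0 for k in prof.retinal.interaction_um},
        dids={c: {k: 0.0 for k in d} for c, d in prof.retinal.dids.items()},
    )
    cd_r = replace(prof.cd_resting, interaction=0.0,
                   dids={k: 0.0 for k in prof.cd_resting.dids})
    cd_t = replace(prof.cd_task, interaction=0.0,
                   dids={k: 0.0 for k in prof.cd_task.dids})
    med = replace(prof.mediation, a=0.0, b=0.0, c_prime=0.0)
    return EffectProfile(
        name="null",
        n_subjects=n_subjects,
        covariates=prof.covariates,
        behavioral=beh,
        retinal=ret,
        cd_resting=cd_r,
        cd_task=cd_t,
        mediation=med,
    )
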