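"""Population model: covariates and random effects to individual PK
parameters, plus the residual-error model.

The final covariate model for this drug has clearance scaled by CYP2C19
phenotype, C-reactive protein (on normal and intermediate metabolizers
only), age, albumin and sex, and volume scaled by body weight:

    TVCL = CL_typ * 0.794^IM * 0.635^PM * exp(-0.155 * CRP/59) [NM, IM]
           * (AGE/71)^-0.582 * (ALB/34.8)^0.644 * 1.41^female
    TVV  = V_typ * (WT/65)^2.21

with exponential inter-individual variability on CL and V
(P_i = TVP * exp(eta_i)) and a combined exponential-proportional plus
additive residual (y = f * exp(eps1) + eps2).  The reference continuous
covariate values are the cohort medians; categorical factors equal 1 for
the reference male normal metabolizer, and the CRP factor is 1 at CRP = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .records import CovariateSet

FORMS = ("linear", "power", "exponential", "categorical_power")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate acting on one parameter.

    ``coef`` names the coefficient inside :class:`ThetaOmegaSigma`;
    ``mask`` optionally restricts the effect to a set of CYP2C19
    phenotypes (the CRP effect applies to NM and IM only).
    """

    covariate: str
    form: str
    center: float
    coef: str
    mask: frozenset | None = None

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form != "categorical_power" and self.center <= 0:
            raise ValueError("centering value must be > 0")
        if self.mask is not None:
            object.__setattr__(self, "mask", frozenset(self.mask))


@dataclass(frozen=True)
class ModelSpec:
    """Structural + covariate + error model definition."""

    structural: str = "one_compartment_linear"
    covariate_map: Mapping[str, tuple[CovariateEffect, ...]] = field(
        default_factory=dict)
    error_model: str = "combined"
    bql_method: str = "M1"

    def __post_init__(self) -> None:
        if self.structural not in ("one_compartment_linear", "one_compartment_mm"):
            raise ValueError(f"unknown structural model {self.structural!r}")
        object.__setattr__(self, "covariate_map", {
            k: tuple(v) for k, v in self.covariate_map.items()})

    def effects(self, parameter: str) -> tuple[CovariateEffect, ...]:
        return self.covariate_map.get(parameter, ())

    def with_effect(self, parameter: str, effect: CovariateEffect) -> "ModelSpec":
        cmap = {k: tuple(v) for k, v in self.covariate_map.items()}
        cmap[parameter] = cmap.get(parameter, ()) + (effect,)
        return replace(self, covariate_map=cmap)

    def without_effect(self, parameter: str, coef: str) -> "ModelSpec":
        cmap = {k: tuple(e for e in v if not (k == parameter and e.coef == coef))
                for k, v in self.covariate_map.items()}
        return replace(self, covariate_map=cmap)

    # -- YAML round trip so the final model ships as configuration --
    def to_dict(self) -> dict:
        return {
            "structural": self.structural,
            "error_model": self.error_model,
            "bql_method": self.bql_method,
            "covariate_map": {
                par: [{"covariate": e.covariate, "form": e.form,
                       "center": e.center, "coef": e.coef,
                       "mask": sorted(e.mask) if e.mask else None}
                      for e in effs]
                for par, effs in self.covariate_map.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        cmap = {
            par: tuple(CovariateEffect(
                covariate=e["covariate"], form=e["form"], center=e["center"],
                coef=e["coef"],
                mask=frozenset(e["mask"]) if e.get("mask") else None)
                for e in effs)
            for par, effs in d.get("covariate_map", {}).items()}
        return cls(structural=d.get("structural", "one_compartment_linear"),
                   covariate_map=cmap,
                   error_model=d.get("error_model", "combined"),
                   bql_method=d.get("bql_method", "M1"))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ThetaOmegaSigma:
    """Fixed effects, inter-individual variances, and residual variances.

    ``omega_*`` are the standard deviations of the log-scale random effects
    and ``sigma_prop``/``sigma_add`` the SDs of the proportional and
    additive residual components; all are displayed as percentages (x100)
    in tabulated output, following the approximate-CV convention.
    """

    cl: float = 3.83          # typical clearance, L/h
    v: float = 134.0          # typical volume, L
    f: float = 0.965          # oral bioavailability
    ka: float = 1.1           # absorption rate constant, 1/h (fixed)
    crp_slope: float = -0.155
    im_factor: float = 0.794
    pm_factor: float = 0.635
    alb_exp: float = 0.644
    sex_factor: float = 1.41
    age_exp: float = -0.582
    wt_exp: float = 2.21
    omega_cl: float = 0.389   # SD of eta_CL
    omega_v: float = 0.452    # SD of eta_V
    sigma_prop: float = 0.147
    sigma_add: float = 0.58   # ug/mL
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.cl, self.v, self.ka) <= 0:
            raise ValueError("CL, V and ka must be > 0")
        if not (0 < self.f <= 1.2):
            raise ValueError("F must be in (0, 1.2]")
        if min(self.omega_cl, self.omega_v, self.sigma_prop, self.sigma_add) < 0:
            raise ValueError("variability terms must be >= 0")
        object.__setattr__(self, "extra", dict(self.extra))

    def coef(self, name: str) -> float:
        if name in self.extra:
            return self.extra[name]
        return getattr(self, name)

    def with_coef(self, name: str, value: float) -> "ThetaOmegaSigma":
        if name in self.__dataclass_fields__ and name != "extra":
            return replace(self, **{name: value})
        extra = dict(self.extra)
        extra[name] = value
        return replace(self, extra=extra)

    def omega_matrix(self) -> np.ndarray:
        """Diagonal IIV covariance diag(omega_cl^2, omega_v^2)."""
        return np.diag([self.omega_cl ** 2, self.omega_v ** 2])


def final_model_spec() -> ModelSpec:
    """The selected covariate model (CRP pooled over NM+IM)."""
    return ModelSpec(covariate_map={
        "CL": (
            CovariateEffect("IM", "categorical_power", 1.0, "im_factor"),
            CovariateEffect("PM", "categorical_power", 1.0, "pm_factor"),
            CovariateEffect("CRP", "exponential", 59.0, "crp_slope",
                            mask=frozenset({"NM", "IM"})),
            CovariateEffect("AGE", "power", 71.0, "age_exp"),
            CovariateEffect("ALB", "power", 34.8, "alb_exp"),
            CovariateEffect("SEX", "categorical_power", 1.0, "sex_factor"),
        ),
        "V": (
            CovariateEffect("WT", "power", 65.0, "wt_exp"),
        ),
    })


def base_model_spec() -> ModelSpec:
    """Covariate-free structural model."""
    return ModelSpec()


def base_model_params() -> ThetaOmegaSigma:
    """Reference estimates of the covariate-free model for this cohort."""
    return ThetaOmegaSigma(cl=3.13, v=93.2, f=0.957, omega_cl=0.459,
                           omega_v=0.470, sigma_prop=0.163, sigma_add=0.78)


# Table-style reference estimates of the final model are simply the
# ThetaOmegaSigma defaults.
def final_model_params() -> ThetaOmegaSigma:
    return ThetaOmegaSigma()


def _effect_factor(effect: CovariateEffect, cov: CovariateSet,
                   theta: ThetaOmegaSigma) -> float:
    if effect.mask is not None and cov.phenotype not in effect.mask:
        return 1.0
    x = cov.value(effect.covariate)
    beta = theta.coef(effect.coef)
    if effect.form == "linear":
        # floored so a candidate fit cannot drive a parameter negative
        return max(1.0 + beta * (x / effect.center - 1.0), 1e-6)
    if effect.form == "power":
        return (x / effect.center) ** beta
    if effect.form == "exponential":
        return float(np.exp(beta * x / effect.center))
    # categorical power: factor^indicator
    return beta ** x if x else 1.0


def typical_value(parameter: str, cov: CovariateSet, theta: ThetaOmegaSigma,
                  spec: ModelSpec) -> float:
    """Typical (population) value of a parameter given covariates."""
    base = {"CL": theta.cl, "V": theta.v}[parameter]
    for effect in spec.effects(parameter):
        base *= _effect_factor(effect, cov, theta)
    return float(base)


def typical_cl(cov: CovariateSet, theta: ThetaOmegaSigma,
               spec: ModelSpec | None = None) -> float:
    """Typical clearance (L/h) under the covariate model."""
    return typical_value("CL", cov, theta, spec or final_model_spec())


def typical_v(cov: CovariateSet, theta: ThetaOmegaSigma,
              spec: ModelSpec | None = None) -> float:
    """Typical volume of distribution (L) under the covariate model."""
    return typical_value("V", cov, theta, spec or final_model_spec())


@dataclass(frozen=True)
class IndividualParameters:
    """Individual PK parameters after applying the random effects."""

    CL: float
    V: float
    ka: float
    F: float


def individual_params(cov: CovariateSet, theta: ThetaOmegaSigma,
                      eta: Sequence[float],
                      spec: ModelSpec | None = None) -> IndividualParameters:
    """P_i = TVP * exp(eta) for CL and V; ka and F carry no variability."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (2,):
        raise ValueError("eta must be a 2-vector (eta_CL, eta_V)")
    spec = spec or final_model_spec()
    return IndividualParameters(
        CL=typical_value("CL", cov, theta, spec) * float(np.exp(eta[0])),
        V=typical_value("V", cov, theta, spec) * float(np.exp(eta[1])),
        ka=theta.ka, F=theta.f)


def residual_model(pred, eps1, eps2):
    """Observed concentration y = f * exp(eps1) + eps2."""
    return np.asarray(pred) * np.exp(np.asarray(eps1)) + np.asarray(eps2)
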