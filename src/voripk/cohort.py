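"""Virtual-cohort generation.

Covariate marginals reproduce the summary statistics of the studied adult
inpatient cohort (n = 167, 232 steady-state troughs): truncated normals for
near-symmetric variables (age, weight, albumin, hemoglobin) and truncated
log-normals for the right-skewed laboratory values (CRP, transaminases,
bilirubin, creatinine, urate, platelets).  The truncated distribution is
moment-matched so that its OWN mean and SD equal the reported ones (naive
truncation of a normal with the reported moments would bias the mean, e.g.
by about -1 y for age).

Dosing reproduces the three observed regimen arms:

* 57/167 - IV loading (two doses on day 1) then IV maintenance bid,
* 4/167  - oral loading then 200 mg oral bid,
* 106/167 - flat 200 mg bid (IV or oral) without loading,

with infusion durations long enough to respect the 3 mg/kg/h rate cap.
Sampling is trough-only: day 3 of treatment for loading arms, day 5
otherwise, with a seeded Bernoulli second trough two days later so the
expected total is about 232 observations per 167 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .models import ModelSpec, ThetaOmegaSigma, final_model_spec, typical_value
from .records import (CovariateSet, DoseEvent, Observation, SubjectRecord,
                      DEFAULT_LLOQ, ROUTE_IV, ROUTE_ORAL)


@dataclass(frozen=True)
class DistSpec:
    """Marginal distribution target: mean/SD of the truncated law on
    [lo, hi].  kind is 'truncnorm' or 'lognormal'."""

    kind: str
    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("truncation interval requires lo < hi")


#: Cohort summary statistics (mean, SD, observed range) per covariate.
DEFAULT_COVARIATE_DISTS: Mapping[str, DistSpec] = {
    "AGE": DistSpec("truncnorm", 68.87, 14.87, 16.0, 97.0),
    "WT": DistSpec("truncnorm", 64.48, 12.24, 37.0, 100.0),
    "ALB": DistSpec("truncnorm", 36.36, 8.54, 18.3, 75.1),
    "HB": DistSpec("truncnorm", 97.96, 16.52, 64.0, 152.0),
    "CRP": DistSpec("lognormal", 77.10, 68.74, 0.9, 306.6),
    "AST": DistSpec("lognormal", 63.98, 109.94, 7.8, 1211.6),
    "ALT": DistSpec("lognormal", 44.42, 68.84, 2.6, 629.1),
    "TBIL": DistSpec("lognormal", 26.65, 46.64, 1.7, 514.8),
    "PLT": DistSpec("lognormal", 174.25, 114.66, 4.0, 624.0),
    "SCR": DistSpec("lognormal", 106.50, 84.18, 2.77, 641.0),
    "UA": DistSpec("lognormal", 196.97, 163.86, 27.4, 1917.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs; defaults emulate the study cohort."""

    n_subjects: int = 167
    covariate_dists: Mapping[str, DistSpec] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_DISTS))
    phenotype_freqs: tuple[float, float, float] = (0.395, 0.431, 0.174)
    p_male: float = 119 / 167
    p_ppi: float = 0.701
    p_steroid: float = 0.257
    # regimen arms: IV loading / oral loading / flat maintenance
    regimen_mix: tuple[float, float, float] = (57 / 167, 4 / 167, 106 / 167)
    oral_fraction_flat: float = 0.5
    infusion_duration: float = 2.0       # h; stretched if the rate cap binds
    max_infusion_rate: float = 3.0       # mg/kg/h
    second_trough_prob: float = 65 / 167  # gives ~232 troughs per 167 subjects
    lloq: float = DEFAULT_LLOQ
    #: optional Gaussian-copula correlation among continuous covariates:
    #: (names, correlation matrix)
    copula: tuple[tuple[str, ...], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.phenotype_freqs) - 1.0) > 1e-9:
            raise ValueError("phenotype frequencies must sum to 1")
        if abs(sum(self.regimen_mix) - 1.0) > 1e-9:
            raise ValueError("regimen mix fractions must sum to 1")


# ---------------------------------------------------------------------------
# Moment-matched truncated marginals

def _truncnorm_moments(mu: float, sigma: float, lo: float, hi: float):
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    za, zb = stats.norm.pdf(a), stats.norm.pdf(b)
    Z = stats.norm.cdf(b) - stats.norm.cdf(a)
    mean = mu + sigma * (za - zb) / Z
    var = sigma ** 2 * (1 + (a * za - b * zb) / Z - ((za - zb) / Z) ** 2)
    return mean, np.sqrt(var)


def _trunclognorm_moments(mu: float, sigma: float, lo: float, hi: float):
    a, b = (np.log(lo) - mu) / sigma, (np.log(hi) - mu) / sigma
    Z = stats.norm.cdf(b) - stats.norm.cdf(a)

    def raw(n):
        return (np.exp(n * mu + 0.5 * n ** 2 * sigma ** 2)
                * (stats.norm.cdf(b - n * sigma) - stats.norm.cdf(a - n * sigma))
                / Z)

    m1, m2 = raw(1), raw(2)
    return m1, np.sqrt(max(m2 - m1 ** 2, 0.0))


@lru_cache(maxsize=128)
def _solve_marginal(kind: str, mean: float, sd: float, lo: float, hi: float):
    """Latent (mu, sigma) whose truncated law has the requested moments."""
    if sd == 0:
        return mean, 0.0
    moments = _truncnorm_moments if kind == "truncnorm" else _trunclognorm_moments
    if kind == "truncnorm":
        x0 = np.array([mean, sd])
    else:
        s0 = np.sqrt(np.log(1 + (sd / mean) ** 2))
        x0 = np.array([np.log(mean) - 0.5 * s0 ** 2, s0])

    def eqs(x):
        m, s = moments(x[0], abs(x[1]), lo, hi)
        return [m - mean, s - sd]

    sol = optimize.root(eqs, x0, method="hybr")
    if not sol.success:
        raise RuntimeError(
            f"cannot moment-match {kind}({mean}, {sd}) on [{lo}, {hi}]: "
            f"{sol.message}")
    return float(sol.x[0]), float(abs(sol.x[1]))


def _marginal_ppf(dist: DistSpec, u: np.ndarray) -> np.ndarray:
    """Quantile function of the moment-matched truncated marginal."""
    if dist.sd == 0:
        return np.full_like(np.asarray(u, float), dist.mean)
    mu, sigma = _solve_marginal(dist.kind, dist.mean, dist.sd, dist.lo, dist.hi)
    lo, hi = ((dist.lo, dist.hi) if dist.kind == "truncnorm"
              else (np.log(dist.lo), np.log(dist.hi)))
    ca, cb = stats.norm.cdf((lo - mu) / sigma), stats.norm.cdf((hi - mu) / sigma)
    x = mu + sigma * stats.norm.ppf(ca + np.asarray(u) * (cb - ca))
    return x if dist.kind == "truncnorm" else np.exp(x)


def _sample_continuous(config: CohortConfig, rng: np.random.Generator,
                       n: int) -> dict[str, np.ndarray]:
    names = list(config.covariate_dists)
    u = {name: rng.uniform(size=n) for name in names}
    if config.copula is not None:
        cnames, R = config.copula
        z = rng.multivariate_normal(np.zeros(len(cnames)), np.asarray(R),
                                    size=n)
        for j, name in enumerate(cnames):
            u[name] = stats.norm.cdf(z[:, j])
    return {name: _marginal_ppf(config.covariate_dists[name], u[name])
            for name in names}


def sample_covariates(config: CohortConfig,
                      rng: np.random.Generator) -> CovariateSet:
    """Draw one covariate snapshot from the configured distributions."""
    return _sample_covariate_batch(config, rng, 1)[0]


def _sample_covariate_batch(config: CohortConfig, rng: np.random.Generator,
                            n: int) -> list[CovariateSet]:
    cont = _sample_continuous(config, rng, n)
    male = rng.uniform(size=n) < config.p_male
    pheno = rng.choice(np.array(["NM", "IM", "PM"]), size=n,
                       p=np.asarray(config.phenotype_freqs))
    ppi = rng.uniform(size=n) < config.p_ppi
    steroid = rng.uniform(size=n) < config.p_steroid
    return [CovariateSet(
        AGE=float(cont["AGE"][i]), WT=float(cont["WT"][i]),
        SEX="male" if male[i] else "female", ALB=float(cont["ALB"][i]),
        CRP=float(cont["CRP"][i]), phenotype=str(pheno[i]),
        ppi_flag=bool(ppi[i]), steroid_flag=bool(steroid[i]),
        AST=float(cont["AST"][i]), ALT=float(cont["ALT"][i]),
        TBIL=float(cont["TBIL"][i]), HB=float(cont["HB"][i]),
        PLT=float(cont["PLT"][i]), SCR=float(cont["SCR"][i]),
        UA=float(cont["UA"][i])) for i in range(n)]


# ---------------------------------------------------------------------------
# Dosing regimens

#: maintenance doses run through t = 156 h so a day-7 second trough at
#: t = 168 h still has a next-dose boundary.
_MAINT_DOSES = 12
_FLAT_DOSES = 14


def _iv_duration(amount: float, wt: float, config: CohortConfig) -> float:
    """Default 2-h infusion, stretched when 3 mg/kg/h would be exceeded."""
    return max(config.infusion_duration,
               amount / (config.max_infusion_rate * wt))


def assign_regimen(cov: CovariateSet, config: CohortConfig,
                   rng: np.random.Generator) -> list[DoseEvent]:
    """Draw a dosing history from the three-arm regimen mix."""
    arm = rng.choice(3, p=np.asarray(config.regimen_mix))
    if arm == 0:  # IV loading then IV maintenance
        load, maint = (600.0, 300.0) if cov.WT >= 70 else (400.0, 200.0)
        return [
            DoseEvent(0.0, load, ROUTE_IV, _iv_duration(load, cov.WT, config),
                      interval=12.0, n_doses=2),
            DoseEvent(24.0, maint, ROUTE_IV,
                      _iv_duration(maint, cov.WT, config),
                      interval=12.0, n_doses=_MAINT_DOSES),
        ]
    if arm == 1:  # oral loading then oral maintenance
        return [
            DoseEvent(0.0, 400.0, ROUTE_ORAL, interval=12.0, n_doses=2),
            DoseEvent(24.0, 200.0, ROUTE_ORAL, interval=12.0,
                      n_doses=_MAINT_DOSES),
        ]
    # flat 200 mg bid without loading, IV or oral
    if rng.uniform() < config.oral_fraction_flat:
        return [DoseEvent(0.0, 200.0, ROUTE_ORAL, interval=12.0,
                          n_doses=_FLAT_DOSES)]
    return [DoseEvent(0.0, 200.0, ROUTE_IV,
                      _iv_duration(200.0, cov.WT, config),
                      interval=12.0, n_doses=_FLAT_DOSES)]


def _has_loading(doses: Sequence[DoseEvent]) -> bool:
    return len({d.amount for d in doses}) > 1


# ---------------------------------------------------------------------------
# Observation simulation

def simulate_observations(subject: SubjectRecord, truth: ThetaOmegaSigma,
                          rng: np.random.Generator,
                          config: CohortConfig | None = None,
                          spec: ModelSpec | None = None) -> SubjectRecord:
    """Simulate trough observations for a dosed subject under ``truth``.

    Draws (eta_CL, eta_V), evaluates the model trough just before a dose on
    day 3 (loading arms) or day 5, adds the combined residual error, and
    flags/handles below-LLOQ values: a non-positive simulated concentration
    is truncated to lloq/2 and flagged BQL rather than resampled, so the
    M1 code path stays exercised.
    """
    from . import pk  # local import to avoid a cycle at module load

    config = config or CohortConfig()
    spec = spec or final_model_spec()
    eta = np.array([rng.normal(0.0, truth.omega_cl),
                    rng.normal(0.0, truth.omega_v)])
    cl = typical_value("CL", subject.covariates, truth, spec) * np.exp(eta[0])
    v = typical_value("V", subject.covariates, truth, spec) * np.exp(eta[1])
    p = pk.PKParameters(CL=cl, V=v, ka=truth.ka, F=truth.f)

    t_first = 48.0 if _has_loading(subject.doses) else 120.0
    times = [t_first]
    if rng.uniform() < config.second_trough_prob:
        times.append(t_first + 48.0)
    pred = pk.superpose(subject.doses, times, p)
    obs = []
    for t, c_hat in zip(times, np.atleast_1d(pred)):
        y = c_hat * np.exp(rng.normal(0.0, truth.sigma_prop)) \
            + rng.normal(0.0, truth.sigma_add)
        if y <= 0:
            y = config.lloq / 2.0
        obs.append(Observation(time=float(t), concentration=float(y),
                               lloq=config.lloq))
    return replace(subject, observations=tuple(obs))


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | np.random.Generator = 0,
                    truth: ThetaOmegaSigma | None = None,
                    spec: ModelSpec | None = None) -> list[SubjectRecord]:
    """Generate a full synthetic cohort (covariates, doses, troughs).

    Bit-reproducible for a fixed seed.
    """
    config = config or CohortConfig()
    truth = truth or ThetaOmegaSigma()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    covs = _sample_covariate_batch(config, rng, config.n_subjects)
    subjects = []
    for i, cov in enumerate(covs):
        doses = assign_regimen(cov, config, rng)
        bare = SubjectRecord(id=f"S{i + 1:04d}", covariates=cov,
                             doses=tuple(doses))
        subjects.append(simulate_observations(bare, truth, rng, config, spec))
    return subjects
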