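"""Model validation: residual diagnostics, nonparametric bootstrap,
visual predictive check, and normalized prediction distribution errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CohortDesign
from .foce import _linearized, eta_modes, fit
from .models import ModelSpec, ThetaOmegaSigma
from .records import SubjectRecord, apply_m1

logger = logging.getLogger(__name__)


def _design(data) -> CohortDesign:
    if isinstance(data, CohortDesign):
        return data
    return CohortDesign.from_subjects(apply_m1(list(data)))


def simulate_datasets(design: CohortDesign, theta: ThetaOmegaSigma,
                      spec: ModelSpec, n_sim: int,
                      rng: np.random.Generator,
                      include_residual: bool = True) -> np.ndarray:
    """Simulate ``n_sim`` replicate observation vectors under the model
    at the study design (same subjects, doses, sampling times).

    Returns an (n_sim, n_obs) array.
    """
    tvcl, tvv = design.typical_params(theta, spec)
    out = np.empty((n_sim, design.n_obs))
    for r in range(n_sim):
        eta = rng.normal(size=(design.n_subjects, 2)) \
            * np.array([theta.omega_cl, theta.omega_v])
        f = design.predict(tvcl * np.exp(eta[:, 0]), tvv * np.exp(eta[:, 1]),
                           theta.ka, theta.f)
        if include_residual:
            f = f * np.exp(rng.normal(0.0, theta.sigma_prop, design.n_obs)) \
                + rng.normal(0.0, theta.sigma_add, design.n_obs)
        out[r] = f
    return out


# ---------------------------------------------------------------------------
# Goodness of fit

def cwres_table(data, theta: ThetaOmegaSigma, spec: ModelSpec) -> pd.DataFrame:
    """Per-observation PRED, IPRED, IWRES and conditional weighted
    residuals (FOCE linearization, full-covariance decorrelation)."""
    design = _design(data)
    eta, _ = eta_modes(design, theta, spec)
    f, G, vv = _linearized(design, theta, spec, eta)
    tvcl, tvv = design.typical_params(theta, spec)
    pred = design.predict(tvcl, tvv, theta.ka, theta.f)  # population (eta=0)
    omega = theta.omega_matrix()
    cwres = np.empty(design.n_obs)
    counts = design.obs_per_subject
    offsets = np.concatenate([[0], np.cumsum(counts)])
    r_all = design.y - f + np.einsum("oi,oi->o", G, eta[design.sub_of_obs])
    for i in range(design.n_subjects):
        sl = slice(offsets[i], offsets[i + 1])
        Gi = G[sl]
        C = Gi @ omega @ Gi.T + np.diag(vv[sl])
        L = np.linalg.cholesky(C)
        cwres[sl] = np.linalg.solve(L, r_all[sl])
    iwres = (design.y - f) / np.sqrt(vv)
    time_after_dose = _time_after_last_dose(design)
    return pd.DataFrame({
        "id": [design.subjects[i].id for i in design.sub_of_obs],
        "time": design.obs_time, "time_after_dose": time_after_dose,
        "dv": design.y, "pred": pred, "ipred": f, "iwres": iwres,
        "cwres": cwres,
        "route": _obs_route(design),
    })


def _time_after_last_dose(design: CohortDesign) -> np.ndarray:
    dt = np.where((design.dose_dt > 0) & (design.dose_amt > 0),
                  design.dose_dt, np.inf)
    return dt.min(axis=1)


def _obs_route(design: CohortDesign) -> np.ndarray:
    """Route of the dose nearest before each observation."""
    dt = np.where((design.dose_dt > 0) & (design.dose_amt > 0),
                  design.dose_dt, np.inf)
    nearest = dt.argmin(axis=1)
    oral = design.dose_oral[np.arange(design.n_obs), nearest]
    return np.where(oral, "oral", "intravenous")


# ---------------------------------------------------------------------------
# Bootstrap

@dataclass
class BootstrapResult:
    medians: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_requested: int
    n_converged: int
    replicates: pd.DataFrame

    @property
    def convergence_fraction(self) -> float:
        return self.n_converged / self.n_requested if self.n_requested else 0.0


def bootstrap(subjects: list[SubjectRecord], spec: ModelSpec,
              inits: ThetaOmegaSigma, n_replicates: int = 1000,
              seed: int | np.random.Generator = 0,
              fit_kwargs: dict | None = None,
              indices: list[np.ndarray] | None = None) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects with replacement, refit,
    and report per-parameter medians and 2.5/97.5 percentile intervals.

    Non-converged replicates are counted but excluded from the
    percentiles.  ``indices`` overrides the resampling (one index array
    per replicate), e.g. the identity resample for validation.
    """
    subjects = apply_m1(subjects)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("compute_se", False)
    fit_kwargs.setdefault("polish", False)
    n = len(subjects)
    rows = []
    n_conv = 0
    for r in range(n_replicates):
        idx = (indices[r] if indices is not None
               else rng.integers(0, n, size=n))
        resampled = [_relabel(subjects[i], f"B{r}_{j}")
                     for j, i in enumerate(idx)]
        try:
            res = fit(resampled, spec, inits, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 - a bad replicate is data, not a crash
            logger.warning("bootstrap replicate %d failed: %s", r, exc)
            continue
        if not res.converged:
            continue
        n_conv += 1
        row = {"replicate": r, "ofv": res.ofv}
        row.update(_natural_params(res.estimates, spec))
        rows.append(row)
    reps = pd.DataFrame(rows)
    params = [c for c in reps.columns if c not in ("replicate", "ofv")]
    med = {p: float(reps[p].median()) for p in params}
    lo = {p: float(reps[p].quantile(0.025)) for p in params}
    hi = {p: float(reps[p].quantile(0.975)) for p in params}
    return BootstrapResult(medians=med, ci_low=lo, ci_high=hi,
                           n_requested=n_replicates, n_converged=n_conv,
                           replicates=reps)


def _relabel(s: SubjectRecord, new_id: str) -> SubjectRecord:
    from dataclasses import replace
    return replace(s, id=new_id)


def _natural_params(theta: ThetaOmegaSigma, spec: ModelSpec) -> dict[str, float]:
    out = {"cl": theta.cl, "v": theta.v, "f": theta.f,
           "omega_cl": theta.omega_cl, "omega_v": theta.omega_v,
           "sigma_prop": theta.sigma_prop, "sigma_add": theta.sigma_add}
    for par, effects in spec.covariate_map.items():
        for e in effects:
            out[e.coef] = theta.coef(e.coef)
    return out


# ---------------------------------------------------------------------------
# Visual predictive check

@dataclass
class VpcBand:
    stratum: str
    bin_mid: np.ndarray
    bin_edges: np.ndarray
    observed: dict[int, np.ndarray]         # percentile -> per-bin value
    sim_low: dict[int, np.ndarray]          # 2.5% of simulated percentile
    sim_high: dict[int, np.ndarray]         # 97.5% of simulated percentile


@dataclass
class VpcResult:
    bands: list[VpcBand]
    percentiles: tuple[int, ...] = (5, 50, 95)

    def coverage(self) -> float:
        """Fraction of observed percentile points inside their simulated
        confidence band."""
        inside = total = 0
        for b in self.bands:
            for p in self.observed_percentiles(b):
                ok = (b.observed[p] >= b.sim_low[p]) \
                    & (b.observed[p] <= b.sim_high[p])
                inside += int(ok.sum())
                total += ok.size
        return inside / total if total else float("nan")

    @staticmethod
    def observed_percentiles(band: VpcBand):
        return band.observed.keys()


def vpc(data, theta: ThetaOmegaSigma, spec: ModelSpec, n_sim: int = 1000,
        bins: int = 6, stratify_by_route: bool = True,
        seed: int | np.random.Generator = 0,
        percentiles: tuple[int, ...] = (5, 50, 95)) -> VpcResult:
    """Visual predictive check on time after last dose.

    Observed 5th/50th/95th percentiles per equal-count bin are compared
    with the 95% interval of the same percentiles across ``n_sim``
    simulated replicates of the design, optionally stratified by route.
    """
    design = _design(data)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sims = simulate_datasets(design, theta, spec, n_sim, rng)
    tad = _time_after_last_dose(design)
    routes = _obs_route(design)
    strata = (("oral", routes == "oral"), ("intravenous", routes != "oral")) \
        if stratify_by_route else (("all", np.ones_like(tad, dtype=bool)),)
    bands = []
    for name, mask in strata:
        if not mask.any():
            continue
        x = tad[mask]
        n_unique = np.unique(x).size
        nb = max(1, min(bins, n_unique))
        edges = np.unique(np.quantile(x, np.linspace(0, 1, nb + 1)))
        if edges.size < 2:  # all observations share one time after dose
            edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
        which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                        len(edges) - 2)
        mids, obs_p, lo_p, hi_p = [], {p: [] for p in percentiles}, \
            {p: [] for p in percentiles}, {p: [] for p in percentiles}
        for b in range(len(edges) - 1):
            sel = which == b
            if not sel.any():
                continue
            mids.append(float(np.median(x[sel])))
            ysel = design.y[mask][sel]
            ssel = sims[:, mask][:, sel]
            for p in percentiles:
                obs_p[p].append(float(np.percentile(ysel, p)))
                sim_pct = np.percentile(ssel, p, axis=1)
                lo_p[p].append(float(np.percentile(sim_pct, 2.5)))
                hi_p[p].append(float(np.percentile(sim_pct, 97.5)))
        bands.append(VpcBand(
            stratum=name, bin_mid=np.array(mids), bin_edges=edges,
            observed={p: np.array(v) for p, v in obs_p.items()},
            sim_low={p: np.array(v) for p, v in lo_p.items()},
            sim_high={p: np.array(v) for p, v in hi_p.items()}))
    return VpcResult(bands=bands, percentiles=percentiles)


# ---------------------------------------------------------------------------
# Normalized prediction distribution errors

@dataclass
class NpdeReport:
    npde: np.ndarray
    mean: float
    variance: float
    t_test_p: float
    fisher_variance_p: float
    shapiro_wilk_p: float

    @property
    def global_p(self) -> float:
        """Bonferroni-adjusted global p over the three tests."""
        return min(1.0, 3.0 * min(self.t_test_p, self.fisher_variance_p,
                                  self.shapiro_wilk_p))

    def summary(self) -> str:
        return (f"NPDE mean {self.mean:.4f}, variance {self.variance:.3f}; "
                f"t-test p={self.t_test_p:.3f}, "
                f"variance-test p={self.fisher_variance_p:.3f}, "
                f"Shapiro-Wilk p={self.shapiro_wilk_p:.3f}, "
                f"global p={self.global_p:.3f}")


def npde(data, theta: ThetaOmegaSigma, spec: ModelSpec, n_sim: int = 1000,
         seed: int | np.random.Generator = 0) -> NpdeReport:
    """Normalized prediction distribution errors with their tests.

    Per subject the observed vector and ``n_sim`` simulated vectors are
    decorrelated with the simulated mean and lower-Cholesky factor of the
    simulated covariance; the prediction-distribution error is the rank of
    the observation among its simulations, mapped through the inverse
    normal.  Exact rank ties are broken with seeded jitter of magnitude
    1e-10.
    """
    design = _design(data)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sims = simulate_datasets(design, theta, spec, n_sim, rng)
    counts = design.obs_per_subject
    offsets = np.concatenate([[0], np.cumsum(counts)])
    pde = np.empty(design.n_obs)
    for i in range(design.n_subjects):
        sl = slice(offsets[i], offsets[i + 1])
        y = design.y[sl]
        S = sims[:, sl]
        m = S.mean(axis=0)
        cov = np.cov(S, rowvar=False).reshape(y.size, y.size)
        floor = (1e-8 * (np.abs(m) + 1e-8)) ** 2  # guards exact-replica sims
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= floor):
            raise ValueError(
                f"degenerate simulated covariance for subject "
                f"{design.subjects[i].id}; increase n_sim or check the model")
        L = np.linalg.cholesky(cov + np.eye(y.size) * 1e-12)
        ystar = np.linalg.solve(L, y - m)
        sstar = np.linalg.solve(L, (S - m).T).T
        jit = rng.uniform(-1e-10, 1e-10, size=sstar.shape)
        pde[sl] = (sstar + jit < ystar).mean(axis=0)
    k = sims.shape[0]
    pde = np.clip(pde, 1.0 / (2 * k), 1.0 - 1.0 / (2 * k))
    values = stats.norm.ppf(pde)
    n = values.size
    t_p = float(stats.ttest_1samp(values, 0.0).pvalue)
    s2 = float(np.var(values, ddof=1))
    chi = (n - 1) * s2
    var_p = float(2 * min(stats.chi2.cdf(chi, n - 1),
                          stats.chi2.sf(chi, n - 1)))
    sw_p = float(stats.shapiro(values).pvalue)
    return NpdeReport(npde=values, mean=float(values.mean()), variance=s2,
                      t_test_p=t_p, fisher_variance_p=var_p,
                      shapiro_wilk_p=sw_p)
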