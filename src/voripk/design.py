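"""Compiled cohort design: flat arrays for fast vectorized prediction.

The estimation, simulation and diagnostics code paths all need the model
prediction f_ij(CL_i, V_i) and its derivatives with respect to CL and V for
every observation of every subject, thousands of times.  This module
compiles a list of SubjectRecords (after M1 exclusion) into padded numpy
arrays so one call evaluates the whole cohort.

The closed forms match :mod:`voripk.pk`; derivatives are analytic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ModelSpec, ThetaOmegaSigma, typical_value
from .records import ROUTE_ORAL, SubjectRecord


@dataclass
class CohortDesign:
    """Flattened cohort ready for vectorized evaluation."""

    subjects: list[SubjectRecord]
    # observations
    y: np.ndarray              # (n_obs,) observed concentrations
    obs_time: np.ndarray       # (n_obs,)
    sub_of_obs: np.ndarray     # (n_obs,) subject index per observation
    # per-observation dose design, padded over the max dose count
    dose_dt: np.ndarray        # (n_obs, D) obs_time - dose_time
    dose_amt: np.ndarray       # (n_obs, D) amount, 0 for padding
    dose_dur: np.ndarray       # (n_obs, D) infusion duration (0 oral)
    dose_oral: np.ndarray      # (n_obs, D) bool
    has_oral_obs: bool

    def __post_init__(self) -> None:
        # k-independent pieces of the closed forms, precomputed once
        self._active = (self.dose_dt > 0) & (self.dose_amt > 0)
        self._te = np.clip(self.dose_dt, 0.0, self.dose_dur)
        self._td = np.maximum(self.dose_dt - self.dose_dur, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            self._rate = np.where(
                self.dose_dur > 0,
                self.dose_amt / np.where(self.dose_dur > 0, self.dose_dur, 1.0),
                0.0)
        self._dtpos = np.maximum(self.dose_dt, 0.0)
        self._eka_cache: tuple[float, np.ndarray] | None = None

    def _eka(self, ka: float) -> np.ndarray:
        if self._eka_cache is None or self._eka_cache[0] != ka:
            self._eka_cache = (ka, np.exp(-ka * self._dtpos))
        return self._eka_cache[1]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def obs_per_subject(self) -> np.ndarray:
        return np.bincount(self.sub_of_obs, minlength=self.n_subjects)

    # ------------------------------------------------------------------
    @classmethod
    def from_subjects(cls, subjects: list[SubjectRecord]) -> "CohortDesign":
        y, t_obs, sub_idx = [], [], []
        dose_lists = []
        has_oral = False
        for i, s in enumerate(subjects):
            doses = s.expanded_doses()
            for o in s.observations:
                y.append(o.concentration)
                t_obs.append(o.time)
                sub_idx.append(i)
                row = [(o.time - d.time, d.amount, d.infusion_duration,
                        d.route == ROUTE_ORAL)
                       for d in doses if d.time < o.time]
                if any(r[3] for r in row):
                    has_oral = True
                dose_lists.append(row)
        n_obs = len(y)
        dmax = max((len(r) for r in dose_lists), default=0)
        dt = np.zeros((n_obs, dmax))
        amt = np.zeros((n_obs, dmax))
        dur = np.zeros((n_obs, dmax))
        oral = np.zeros((n_obs, dmax), dtype=bool)
        for j, row in enumerate(dose_lists):
            for d, (rdt, ramt, rdur, roral) in enumerate(row):
                dt[j, d], amt[j, d], dur[j, d], oral[j, d] = rdt, ramt, rdur, roral
        return cls(subjects=list(subjects), y=np.asarray(y, float),
                   obs_time=np.asarray(t_obs, float),
                   sub_of_obs=np.asarray(sub_idx, int),
                   dose_dt=dt, dose_amt=amt, dose_dur=dur, dose_oral=oral,
                   has_oral_obs=has_oral)

    # ------------------------------------------------------------------
    def typical_params(self, theta: ThetaOmegaSigma,
                       spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
        """Typical CL and V per subject under the covariate model."""
        tvcl = np.array([typical_value("CL", s.covariates, theta, spec)
                         for s in self.subjects])
        tvv = np.array([typical_value("V", s.covariates, theta, spec)
                        for s in self.subjects])
        return tvcl, tvv

    def predict(self, cl_sub: np.ndarray, v_sub: np.ndarray, ka: float,
                f_oral: float, grad: bool = False):
        """Model concentration per observation for individual CL/V.

        With ``grad=True`` also returns analytic df/dCL and df/dV
        (n_obs,), used for the inner Newton steps of the conditional
        estimation and for residual linearization.
        """
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._predict(cl_sub, v_sub, ka, f_oral, grad)

    def _predict(self, cl_sub, v_sub, ka, f_oral, grad):
        cl = np.asarray(cl_sub, float)[self.sub_of_obs][:, None]
        v = np.asarray(v_sub, float)[self.sub_of_obs][:, None]
        k = cl / v
        active, te, td, rate = self._active, self._te, self._td, self._rate

        # infusion cells
        ekte = np.exp(-k * te)
        ektd = np.exp(-k * td)
        u = 1.0 - ekte
        f_inf = (rate / cl) * u * ektd

        # oral cells
        ekdt = np.exp(-k * self._dtpos)
        ekadt = self._eka(ka)
        scale = f_oral * self.dose_amt * ka / v
        g = (ekdt - ekadt) / (ka - k)
        f_oral_cells = scale * g

        cells = np.where(self.dose_oral, f_oral_cells, f_inf)
        cells = np.where(active, cells, 0.0)
        f = cells.sum(axis=1)
        if not grad:
            return f

        # d f / d k per cell, then chain to CL and V
        df_dk_inf = (rate / cl) * (te * ekte * ektd - u * td * ektd)
        dg_dk = (-self.dose_dt * ekdt) / (ka - k) + g / (ka - k)
        df_dk_oral = scale * dg_dk
        df_dk = np.where(self.dose_oral, df_dk_oral, df_dk_inf)
        df_dk = np.where(active, df_dk, 0.0)

        direct_cl = np.where(self.dose_oral | ~active, 0.0, -cells / cl)
        direct_v = np.where(self.dose_oral & active, -cells / v, 0.0)
        dcl = (direct_cl + df_dk / v).sum(axis=1)
        dv = (direct_v + df_dk * (-k / v)).sum(axis=1)
        return f, dcl, dv
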