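"""MAP Bayesian forecasting: the Model/Results core of the package.

:class:`PopPKModel` binds one population-PK specification to one patient's
course.  With ``k_support = 0`` the model yields the a priori (population)
prediction, i.e. random effects at their prior mode eta = 0.  With k = 1..3
measured concentrations as *support*, :meth:`PopPKModel.fit` finds the
maximum a posteriori (MAP, empirical-Bayes) random-effect vector minimising

    OFV(eta) = sum_j [ (c_obs_j - f_j(eta))^2 / var_j(eta) + ln var_j(eta) ]
               + eta' Omega^{-1} eta,

where var_j is the residual variance at the model prediction f_j.  This is
-2 log posterior up to an additive constant, the objective NONMEM minimises
for post-hoc eta estimates.  The returned :class:`MapResults` carries the
eta estimates, their approximate posterior covariance, a per-observation
prediction table and a text summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConfigurationError, InsufficientDataError
from .events import PatientCourse
from .kinetics import InfusionSchedule
from .modelspec import EtaVector, ModelSpec

DEFAULT_LLOQ = 0.174  # mg/L, meropenem UPLC-MS/MS assay

__all__ = ["PopPKModel", "MapResults", "fit_cohort", "DEFAULT_LLOQ"]


class PopPKModel:
    """One population-PK model conditioned on one patient course.

    Parameters
    ----------
    spec : ModelSpec
        Fully specified population model (theta, covariate relations, omega,
        residual error).
    course : PatientCourse
        Covariates, dose history and observed concentrations.
    k_support : int
        Number of observations used to condition the random effects (0-3 in
        routine TDM use; 0 gives the pure population prediction).
    support_selection : {"first_k", "labels"}
        ``first_k`` takes the chronologically first ``k_support`` usable
        (non-BLQ) observations; ``labels`` takes observations whose labels
        appear in ``support_labels``.
    lloq : float
        Assay lower limit of quantification; BLQ observations are never used
        as support.
    """

    def __init__(self, spec: ModelSpec, course: PatientCourse, k_support: int = 0,
                 support_selection: str = "first_k",
                 support_labels: Optional[Sequence[str]] = None,
                 lloq: float = DEFAULT_LLOQ):
        self.spec = spec
        self.course = course
        self.k_support = int(k_support)
        self.lloq = lloq

        obs = course.observations
        if not obs:
            raise InsufficientDataError(f"patient {course.patient_id!r} has no observations")
        self._obs_times = np.array([o.time for o in obs])
        self._obs_conc = np.array([o.concentration for o in obs])
        self._obs_blq = np.array([o.below_lloq or o.concentration < lloq for o in obs])
        self._obs_labels = [o.label for o in obs]

        usable = np.nonzero(~self._obs_blq)[0]
        if support_selection == "first_k":
            if self.k_support > usable.size:
                raise InsufficientDataError(
                    f"k_support={self.k_support} exceeds the {usable.size} usable "
                    f"observations of patient {course.patient_id!r}"
                )
            support_idx = usable[: self.k_support]
        elif support_selection == "labels":
            if support_labels is None:
                raise ConfigurationError("support_selection='labels' needs support_labels")
            wanted = set(support_labels)
            support_idx = np.array(
                [i for i in usable if self._obs_labels[i] in wanted], dtype=int
            )
            self.k_support = support_idx.size
        else:
            raise ConfigurationError(f"unknown support_selection {support_selection!r}")
        self.support_index = support_idx
        self._is_support = np.zeros(len(obs), dtype=bool)
        self._is_support[support_idx] = True

        self._schedule = InfusionSchedule(course.doses, self._obs_times)
        self._base = spec.covariate_adjusted_params(course.covariates)

        d = spec.n_etas
        try:
            np.linalg.cholesky(spec.omega + 0.0)
            self._omega_inv = np.linalg.inv(spec.omega)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"omega of {spec.name!r} is singular; using pseudo-inverse prior",
                stacklevel=2,
            )
            self._omega_inv = np.linalg.pinv(spec.omega)
        self.n_etas = d

    # -- prediction ---------------------------------------------------------

    def _param_arrays(self, eta: np.ndarray) -> dict:
        """Structural parameter arrays for a (B, d) batch of etas."""
        eta = np.atleast_2d(eta)
        base = self._base.as_dict()
        out = {}
        for name, value in base.items():
            if name in self.spec.eta_names:
                j = self.spec.eta_names.index(name)
                out[name] = value * np.exp(eta[:, j])
            else:
                out[name] = np.full(eta.shape[0], value)
        return out

    def predict(self, eta: Optional[np.ndarray] = None,
                times: Optional[Sequence[float]] = None) -> np.ndarray:
        """Concentrations at ``times`` (default: the observation times)."""
        if eta is None:
            eta = np.zeros(self.n_etas)
        if isinstance(eta, EtaVector):
            eta = eta.values
        eta = np.asarray(eta, dtype=float)
        single = eta.ndim == 1
        schedule = (self._schedule if times is None
                    else InfusionSchedule(self.course.doses, times))
        conc = schedule.concentrations(**self._param_arrays(eta))
        return conc[0] if single else conc

    # -- objective ----------------------------------------------------------

    def map_objective(self, eta: np.ndarray) -> np.ndarray:
        """-2 log posterior (up to a constant); vectorised over an eta batch."""
        eta = np.asarray(eta, dtype=float)
        single = eta.ndim == 1
        eta2 = np.atleast_2d(eta)
        # extreme trial etas (e.g. Newton overshoots) may overflow exp();
        # such points get an infinite objective instead of warnings
        with np.errstate(all="ignore"):
            prior = np.einsum("bi,ij,bj->b", eta2, self._omega_inv, eta2)
            idx = self.support_index
            if idx.size:
                conc = self._schedule.concentrations(**self._param_arrays(eta2))[:, idx]
                var = self.spec.residual.variance(conc)
                var = np.maximum(var, 1e-12)
                resid = self._obs_conc[idx][np.newaxis, :] - conc
                loglik = np.sum(resid ** 2 / var + np.log(var), axis=1)
            else:
                loglik = np.zeros(eta2.shape[0])
            out = prior + loglik
        out = np.where(np.isfinite(out), out, np.inf)
        return out[0] if single else out

    # -- fitting ------------------------------------------------------------

    def _fd_derivatives(self, X: np.ndarray, h: float = 1e-5):
        """Batched FD gradient and Hessian of the objective at each row of X."""
        n, d = X.shape
        pts = [X]
        for i in range(d):
            e = np.zeros(d); e[i] = h
            pts += [X + e, X - e]
        cross = []
        for i in range(d):
            for j in range(i + 1, d):
                e = np.zeros(d); e[i] = h
                u = np.zeros(d); u[j] = h
                cross.append((i, j))
                pts += [X + e + u, X + e - u, X - e + u, X - e - u]
        vals = self.map_objective(np.concatenate(pts, axis=0))
        vals = vals.reshape(len(pts), n)
        f0 = vals[0]
        grad = np.empty((n, d))
        hess = np.empty((n, d, d))
        for i in range(d):
            fp, fm = vals[1 + 2 * i], vals[2 + 2 * i]
            grad[:, i] = (fp - fm) / (2 * h)
            hess[:, i, i] = (fp - 2 * f0 + fm) / h ** 2
        base = 1 + 2 * d
        for k, (i, j) in enumerate(cross):
            fpp, fpm, fmp, fmm = vals[base + 4 * k: base + 4 * k + 4]
            hij = (fpp - fpm - fmp + fmm) / (4 * h ** 2)
            hess[:, i, j] = hess[:, j, i] = hij
        return f0, grad, hess, len(pts) * n

    def fit(self, seed: Optional[int] = 0, maxeval: int = 2000, tol: float = 1e-8,
            n_starts: int = 5, start_scale: float = 0.5, polish: bool = True
            ) -> "MapResults":
        """Estimate the MAP eta by multi-start local optimisation.

        Starts at eta = 0 plus ``n_starts - 1`` seeded perturbations.  All
        starts are advanced in parallel by a damped Newton search on batched
        finite-difference derivatives (only improving steps are accepted, so
        the incumbent objective is non-increasing); the best point is then
        polished with L-BFGS-B.  Deterministic given ``seed``.
        """
        d = self.n_etas
        if self.k_support == 0 or self.support_index.size == 0:
            eta_hat = np.zeros(d)
            return self._results(eta_hat, float(self.map_objective(eta_hat)),
                                 converged=True, trace=[0.0], n_fev=1)

        rng = np.random.default_rng(seed)
        X = np.zeros((max(n_starts, 1), d))
        if n_starts > 1:
            X[1:] = rng.normal(0.0, start_scale, (n_starts - 1, d))
        F = self.map_objective(X)
        n_fev = X.shape[0]
        trace = [float(F.min())]
        alphas = np.array([1.0, 0.5, 0.25, 0.1, 0.02])
        stalled = np.zeros(X.shape[0], dtype=bool)
        for _ in range(100):
            if n_fev >= maxeval or stalled.all():
                break
            f0, grad, hess, used = self._fd_derivatives(X)
            n_fev += used
            steps = np.empty_like(X)
            for b in range(X.shape[0]):
                try:
                    w = np.linalg.eigvalsh(hess[b])
                    if w.min() > 1e-10:
                        steps[b] = -np.linalg.solve(hess[b], grad[b])
                    else:
                        raise np.linalg.LinAlgError
                except np.linalg.LinAlgError:
                    gn = np.linalg.norm(grad[b])
                    steps[b] = -grad[b] / max(gn, 1.0)
                norm = np.linalg.norm(steps[b])
                if not np.isfinite(norm) or norm > 5.0:  # e^5 on a PK parameter is absurd
                    steps[b] = steps[b] * (5.0 / norm) if np.isfinite(norm) else -grad[b] / max(np.linalg.norm(grad[b]), 1.0)
            # backtracking: try all damping factors in one batched call
            cand = X[None, :, :] + alphas[:, None, None] * steps[None, :, :]
            fc = self.map_objective(cand.reshape(-1, d)).reshape(len(alphas), -1)
            n_fev += cand.shape[0] * cand.shape[1]
            best_a = np.argmin(fc, axis=0)
            fbest = fc[best_a, np.arange(X.shape[0])]
            improved = fbest < F - 1e-15
            gain = F - fbest
            X[improved] = cand[best_a[improved], np.nonzero(improved)[0]]
            F[improved] = fbest[improved]
            stalled = ~improved | (gain < tol)
            trace.append(float(F.min()))

        ib = int(np.argmin(F))
        best_x, best_f = X[ib].copy(), float(F[ib])
        converged = bool(stalled[ib])

        if polish and n_fev < maxeval:
            def value_and_grad(x, h=1e-6):
                pts = [x[np.newaxis, :]]
                for i in range(d):
                    e = np.zeros(d); e[i] = h
                    pts += [(x + e)[np.newaxis, :], (x - e)[np.newaxis, :]]
                v = self.map_objective(np.concatenate(pts, axis=0))
                g = (v[1::2] - v[2::2]) / (2 * h)
                return v[0], g

            r = minimize(value_and_grad, best_x, jac=True, method="L-BFGS-B",
                         options={"maxiter": 100, "ftol": 1e-13, "gtol": 1e-10})
            n_fev += r.nfev * (1 + 2 * d)
            if r.fun <= best_f:
                best_x, best_f = np.asarray(r.x, dtype=float), float(r.fun)
                converged = converged or r.success
            trace.append(best_f)

        if not converged:
            warnings.warn(
                f"MAP optimisation did not formally converge for patient "
                f"{self.course.patient_id!r}; returning best objective {best_f:.6g}",
                stacklevel=2,
            )
        return self._results(best_x, best_f, converged=converged, trace=trace,
                             n_fev=n_fev)

    # -- assembling results --------------------------------------------------

    def _results(self, eta_hat: np.ndarray, objective: float, converged: bool,
                 trace: List[float], n_fev: int) -> "MapResults":
        c_pred = self.predict(np.zeros(self.n_etas))
        c_ipred = self.predict(eta_hat)
        predictions = pd.DataFrame({
            "patient": self.course.patient_id,
            "time": self._obs_times,
            "label": self._obs_labels,
            "c_obs": self._obs_conc,
            "c_pred": c_pred,
            "c_ipred": c_ipred,
            "support": self._is_support,
            "below_lloq": self._obs_blq,
        })
        return MapResults(model=self, eta_hat=eta_hat, objective_value=objective,
                          converged=converged, trace=trace, n_fev=n_fev,
                          predictions=predictions)


@dataclass
class MapResults:
    """Results of a MAP fit: eta estimates, diagnostics and predictions."""

    model: PopPKModel
    eta_hat: np.ndarray
    objective_value: float
    converged: bool
    trace: List[float]
    n_fev: int
    predictions: pd.DataFrame
    _cov: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        """Eta estimates, indexed by the random-effect-bearing parameter."""
        return pd.Series(self.eta_hat, index=list(self.model.spec.eta_names), name="eta")

    @property
    def individual_params(self):
        return self.model.spec.individual_params(self.model.course.covariates, self.eta_hat)

    def cov_params(self, step: float = 1e-4) -> np.ndarray:
        """Approximate posterior covariance: 2 H^{-1} with H the FD Hessian of OFV."""
        if self._cov is not None:
            return self._cov
        d = self.model.n_etas
        H = np.zeros((d, d))
        f0 = self.model.map_objective(self.eta_hat)
        for i in range(d):
            for j in range(i, d):
                ei = np.zeros(d); ei[i] = step
                ej = np.zeros(d); ej[j] = step
                if i == j:
                    fpp = self.model.map_objective(self.eta_hat + ei)
                    fmm = self.model.map_objective(self.eta_hat - ei)
                    H[i, i] = (fpp - 2 * f0 + fmm) / step ** 2
                else:
                    fpp = self.model.map_objective(self.eta_hat + ei + ej)
                    fpm = self.model.map_objective(self.eta_hat + ei - ej)
                    fmp = self.model.map_objective(self.eta_hat - ei + ej)
                    fmm = self.model.map_objective(self.eta_hat - ei - ej)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step ** 2)
        try:
            cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = 2.0 * np.linalg.pinv(H)
        self._cov = cov
        return cov

    @property
    def bse(self) -> pd.Series:
        diag = np.diag(self.cov_params())
        return pd.Series(np.sqrt(np.maximum(diag, 0.0)),
                         index=list(self.model.spec.eta_names), name="se")

    def prediction_errors(self, scope: str = "subsequent", kind: str = "ipred") -> np.ndarray:
        """Signed relative prediction errors (%) on the chosen observation scope.

        ``scope``: ``"subsequent"`` (non-support, the default forecasting
        read-out), ``"all"`` or ``"support"``.  BLQ observations are excluded.
        ``kind``: ``"ipred"`` (individual) or ``"pred"`` (population).
        """
        df = self.predictions
        ok = ~df["below_lloq"] & (df["c_obs"] > 0)
        if scope == "subsequent":
            mask = ok & ~df["support"]
        elif scope == "support":
            mask = ok & df["support"]
        elif scope == "all":
            mask = ok
        else:
            raise ConfigurationError(f"unknown scope {scope!r}")
        col = "c_ipred" if kind == "ipred" else "c_pred"
        sub = df[mask]
        return ((sub[col] - sub["c_obs"]) / sub["c_obs"] * 100.0).to_numpy()

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "MAP Bayesian forecast".center(58),
            "=" * 58,
            f"Model:          {spec.name}",
            f"Patient:        {self.model.course.patient_id}",
            f"Support obs:    {self.model.k_support}",
            f"OFV:            {self.objective_value:.4f}",
            f"Converged:      {self.converged}",
            "-" * 58,
            f"{'parameter':<12}{'eta':>10}{'se(eta)':>10}{'individual':>14}",
        ]
        bse = self.bse if self.model.k_support > 0 else pd.Series(
            np.sqrt(np.diag(spec.omega)), index=list(spec.eta_names))
        ind = self.individual_params.as_dict()
        for name, e in self.params.items():
            lines.append(f"{name:<12}{e:>10.4f}{bse[name]:>10.4f}{ind[name]:>14.4f}")
        lines.append("-" * 58)
        return "\n".join(lines)


def fit_cohort(spec: ModelSpec, courses: Sequence[PatientCourse], k_support: int = 0,
               seed: Optional[int] = 0, lloq: float = DEFAULT_LLOQ,
               **fit_kwargs) -> pd.DataFrame:
    """Fit every patient in a cohort and pool the prediction tables.

    Patients with fewer than ``k_support`` usable observations are fitted
    with all the usable observations they have (the clinical fallback);
    the effective support count is recorded per patient.
    """
    frames = []
    seeds = np.random.SeedSequence(seed).generate_state(len(courses)) % (2 ** 31)
    for course, s in zip(courses, seeds):
        n_usable = sum(
            1 for o in course.observations
            if not (o.below_lloq or o.concentration < lloq)
        )
        k_eff = min(k_support, n_usable)
        model = PopPKModel(spec, course, k_support=k_eff, lloq=lloq)
        res = model.fit(seed=int(s), **fit_kwargs)
        df = res.predictions.copy()
        df["k_support"] = k_eff
        df["rrt"] = bool(course.covariates.rrt)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
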