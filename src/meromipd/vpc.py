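"""Simulation-based visual predictive check.

Each replicate re-simulates the whole cohort at the original design (times,
doses, covariates): fresh etas per patient from omega, fresh residual noise
per observation from sigma.  Observations are binned on time after the end
of the most recent infusion — the axis used for meropenem intermittent
dosing, where the (0-1] h bin holds peaks, (1-6] h the intermediate samples
and (6-15] h the troughs — and the observed 5th/50th/95th percentile per bin
is compared with the 95% confidence band of the same percentile across
replicates.  An observed percentile above its band flags model
underprediction, below it overprediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DesignError
from .events import PatientCourse
from .kinetics import InfusionSchedule
from .modelspec import ModelSpec

DEFAULT_BINS: Tuple[Tuple[float, float], ...] = ((0.0, 1.0), (1.0, 6.0), (6.0, 15.0))
DEFAULT_N_REPLICATES = 500

__all__ = ["ReplicateSimulation", "VPCBands", "simulate_replicates", "compute_vpc",
           "DEFAULT_BINS", "DEFAULT_N_REPLICATES"]


@dataclass
class ReplicateSimulation:
    """Replicate-simulated observation sets aligned with the observed design."""

    meta: pd.DataFrame          # one row per observation: patient, times, dv, rrt
    sims: np.ndarray            # (n_replicates, n_observations)
    n_replicates: int
    seed: Optional[int]


@dataclass
class VPCBands:
    """Binned observed percentiles with simulated confidence bands."""

    table: pd.DataFrame
    n_replicates: int
    bins: Tuple[Tuple[float, float], ...]


def simulate_replicates(spec: ModelSpec, cohort: Sequence[PatientCourse],
                        n_rep: int = DEFAULT_N_REPLICATES,
                        seed: Optional[int] = None) -> ReplicateSimulation:
    """Simulate ``n_rep`` replicates of the cohort under ``spec``.

    Random effects and residual noise are redrawn per replicate; design
    times, doses and covariates stay fixed.  Reproducible given ``seed``.
    """
    omega_zero = np.allclose(spec.omega, 0.0)
    sigma_zero = spec.residual.sigma_add == 0 and spec.residual.sigma_prop == 0
    if omega_zero and sigma_zero:
        warnings.warn(
            "omega and sigma are both zero: every replicate equals the "
            "population prediction (degenerate simulation)",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    try:
        chol = np.linalg.cholesky(spec.omega)
    except np.linalg.LinAlgError:
        # PSD but singular omega: use the symmetric square root
        w, v = np.linalg.eigh(spec.omega)
        chol = v @ np.diag(np.sqrt(np.maximum(w, 0.0)))

    meta_rows = []
    sim_blocks = []
    for course in cohort:
        obs = course.observations
        if not obs:
            continue
        times = np.array([o.time for o in obs])
        etas = (chol @ rng.standard_normal((spec.n_etas, n_rep))).T  # (n_rep, d)
        base = spec.covariate_adjusted_params(course.covariates).as_dict()
        params = {}
        for name, value in base.items():
            if name in spec.eta_names:
                j = spec.eta_names.index(name)
                params[name] = value * np.exp(etas[:, j])
            else:
                params[name] = np.full(n_rep, value)
        conc = InfusionSchedule(course.doses, times).concentrations(**params)
        # same observation model as the data: concentrations cannot be negative
        sims = np.maximum(spec.residual.sample(conc, rng), 0.0)
        sim_blocks.append(sims)
        for o in obs:
            meta_rows.append({
                "patient": course.patient_id,
                "time": o.time,
                "time_after_infusion": course.time_after_infusion_end(o.time),
                "dv": o.concentration,
                "below_lloq": o.below_lloq,
                "label": o.label,
                "rrt": bool(course.covariates.rrt),
            })
    if not meta_rows:
        raise DesignError("cohort carries no observations to check")
    meta = pd.DataFrame(meta_rows)
    sims = np.concatenate(sim_blocks, axis=1)
    return ReplicateSimulation(meta=meta, sims=sims, n_replicates=n_rep, seed=seed)


def _assign_bins(tad: np.ndarray, bins: Sequence[Tuple[float, float]]) -> np.ndarray:
    """Bin index per observation using (lo, hi] intervals; -1 when unassigned."""
    idx = np.full(tad.shape, -1, dtype=int)
    for b, (lo, hi) in enumerate(bins):
        inside = (tad > lo) & (tad <= hi)
        if np.any(inside & (idx >= 0)):
            raise DesignError("VPC bins overlap")
        idx[inside] = b
    return idx


def compute_vpc(sim: ReplicateSimulation,
                bins: Sequence[Tuple[float, float]] = DEFAULT_BINS,
                stratify_rrt: bool = False,
                percentiles: Tuple[float, float, float] = (5.0, 50.0, 95.0),
                ci_level: float = 95.0) -> VPCBands:
    """Observed percentiles per bin with across-replicate confidence bands.

    Every observation must fall in exactly one bin; bins with fewer than two
    observations are kept but flagged ``unstable``.
    """
    bins = tuple((float(lo), float(hi)) for lo, hi in bins)
    for (lo, hi) in bins:
        if hi <= lo:
            raise DesignError(f"empty VPC bin ({lo}, {hi}]")
    if sorted(bins) != list(bins):
        raise DesignError("VPC bins must be ordered")

    meta = sim.meta
    tad = meta["time_after_infusion"].to_numpy()
    if np.any(~np.isfinite(tad)):
        raise DesignError("some observations precede the end of any infusion")
    bin_idx = _assign_bins(tad, bins)
    if np.any(bin_idx < 0):
        bad = np.count_nonzero(bin_idx < 0)
        raise DesignError(f"{bad} observations fall outside every VPC bin")

    alpha = (100.0 - ci_level) / 2.0
    strata = {"all": np.ones(len(meta), dtype=bool)}
    if stratify_rrt:
        rrt = meta["rrt"].to_numpy(dtype=bool)
        strata = {"RRT": rrt, "non-RRT": ~rrt}

    rows = []
    for stratum, smask in strata.items():
        for b, (lo, hi) in enumerate(bins):
            mask = smask & (bin_idx == b)
            n_obs = int(mask.sum())
            if n_obs == 0:
                rows.append({"stratum": stratum, "bin_low": lo, "bin_high": hi,
                             "n_obs": 0, "unstable": True})
                continue
            dv = meta.loc[mask, "dv"].to_numpy()
            obs_pcts = np.percentile(dv, percentiles)
            rep_pcts = np.percentile(sim.sims[:, mask], percentiles, axis=1)  # (3, n_rep)
            ci_lo = np.percentile(rep_pcts, alpha, axis=1)
            ci_hi = np.percentile(rep_pcts, 100.0 - alpha, axis=1)
            mid = np.percentile(rep_pcts, 50.0, axis=1)
            row = {"stratum": stratum, "bin_low": lo, "bin_high": hi,
                   "n_obs": n_obs, "unstable": n_obs < 2}
            for p, obs, lo_, hi_, mid_ in zip(percentiles, obs_pcts, ci_lo, ci_hi, mid):
                tag = f"p{int(p)}"
                row[f"obs_{tag}"] = obs
                row[f"sim_{tag}_lo"] = lo_
                row[f"sim_{tag}_hi"] = hi_
                row[f"sim_{tag}_mid"] = mid_
                row[f"{tag}_underpredicted"] = bool(obs > hi_)
                row[f"{tag}_overpredicted"] = bool(obs < lo_)
            rows.append(row)
    return VPCBands(table=pd.DataFrame(rows), n_replicates=sim.n_replicates, bins=bins)
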