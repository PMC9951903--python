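"""Bias/precision metrics for external model validation.

Relative prediction error PE% = (c_hat − c_obs)/c_obs × 100 measures bias;
RMSE = sqrt(mean(PE%²)) measures precision; a model is judged acceptable when
the interquartile range of PE% lies within ±30% (closed interval), with ±20%
drawn as a stricter reference line in the standard diagnostic plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError

ACCEPTABLE = "acceptable"
NOT_ACCEPTABLE = "not_acceptable"

DEFAULT_IQR_BOUND = 30.0  # percent
REFERENCE_LINE = 20.0  # percent, plotted for orientation only


def prediction_error_pct(c_hat: Union[float, np.ndarray],
                         c_obs: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Signed relative prediction error in percent.

    Scalar c_obs must be positive; use :func:`prediction_errors_batch` when
    zeros/negatives should be excluded rather than raised.
    """
    c_hat = np.asarray(c_hat, dtype=float)
    c_obs = np.asarray(c_obs, dtype=float)
    if np.any(c_obs <= 0):
        raise DomainError("observed concentration must be positive for PE%")
    pe = (c_hat - c_obs) / c_obs * 100.0
    return float(pe) if pe.ndim == 0 else pe


def prediction_errors_batch(c_hat: Sequence[float], c_obs: Sequence[float]
                            ) -> Tuple[np.ndarray, pd.DataFrame]:
    """PE% for valid pairs plus a table of excluded records with reasons."""
    c_hat = np.asarray(c_hat, dtype=float)
    c_obs = np.asarray(c_obs, dtype=float)
    bad = c_obs <= 0
    excluded = pd.DataFrame({
        "index": np.nonzero(bad)[0],
        "c_hat": c_hat[bad],
        "c_obs": c_obs[bad],
        "reason": "non-positive observed concentration",
    })
    pe = (c_hat[~bad] - c_obs[~bad]) / c_obs[~bad] * 100.0
    return pe, excluded


def rmse_of_pe(pe_values: Sequence[float]) -> float:
    """Root mean square of the PE% values (a percentage itself)."""
    pe = np.asarray(pe_values, dtype=float)
    if pe.size == 0:
        raise DomainError("RMSE of an empty PE list is undefined")
    return float(np.sqrt(np.mean(pe ** 2)))


@dataclass
class PEResult:
    """Summary of a PE% distribution for one (model, k, stratum) cell."""

    pe_values: np.ndarray
    n: int
    median: float
    iqr_low: float
    iqr_high: float
    rmse: float
    k_support: int = 0
    model_name: str = ""
    stratum: str = "all"

    def as_row(self) -> dict:
        return {
            "model": self.model_name,
            "k_support": self.k_support,
            "stratum": self.stratum,
            "n": self.n,
            "median_pe_pct": self.median,
            "iqr_low_pct": self.iqr_low,
            "iqr_high_pct": self.iqr_high,
            "rmse_pct": self.rmse,
        }


def summarize_pe(pe_values: Sequence[float], k_support: int = 0, model_name: str = "",
                 stratum: str = "all") -> PEResult:
    """Median, quartiles (linear-interpolation convention) and RMSE of PE%."""
    pe = np.asarray(pe_values, dtype=float)
    if pe.size == 0:
        raise InsufficientDataError("no PE values to summarise")
    q1, med, q3 = np.percentile(pe, [25, 50, 75])
    return PEResult(
        pe_values=pe, n=int(pe.size), median=float(med),
        iqr_low=float(q1), iqr_high=float(q3), rmse=rmse_of_pe(pe),
        k_support=k_support, model_name=model_name, stratum=stratum,
    )


def iqr_acceptance(result: PEResult, bound: float = DEFAULT_IQR_BOUND) -> str:
    """The ±30% interquartile-range rule (closed interval at the boundary)."""
    if result.n < 4:
        raise InsufficientDataError(
            f"IQR acceptance needs at least 4 PE values, got {result.n}"
        )
    ok = result.iqr_low >= -bound and result.iqr_high <= bound
    return ACCEPTABLE if ok else NOT_ACCEPTABLE


def gof_table(predictions: Union[pd.DataFrame, Iterable], model_name: str = "",
              ) -> pd.DataFrame:
    """Long-format goodness-of-fit records for unity-line plots.

    Accepts the pooled prediction table from :func:`meromipd.mapfit.fit_cohort`
    (or an iterable of :class:`MapResults`) and returns tidy records with one
    row per observation: model, patient, time, c_obs, c_pred, c_ipred, stratum.
    """
    if isinstance(predictions, pd.DataFrame):
        df = predictions.copy()
    else:
        frames = []
        for res in predictions:
            sub = res.predictions.copy()
            sub["rrt"] = bool(res.model.course.covariates.rrt)
            frames.append(sub)
        if not frames:
            raise InsufficientDataError("no prediction sets supplied")
        df = pd.concat(frames, ignore_index=True)
    if df.empty:
        raise InsufficientDataError("no prediction records supplied")
    out = pd.DataFrame({
        "model": model_name or df.get("model", ""),
        "patient": df["patient"],
        "time": df["time"],
        "c_obs": df["c_obs"],
        "c_pred": df["c_pred"],
        "c_ipred": df["c_ipred"],
        "stratum": np.where(df.get("rrt", pd.Series(False, index=df.index)).astype(bool),
                            "RRT", "non-RRT"),
    })
    return out


def validate_cohort(pooled: pd.DataFrame, model_name: str = "", k_support: int = 0,
                    kind: str = "ipred", scope: str = "subsequent",
                    stratify_rrt: bool = False, holdout_after: int = 3) -> pd.DataFrame:
    """PEResult rows (as a DataFrame) from a pooled cohort prediction table.

    ``scope`` selects which observations enter the PE pool: the non-support
    ("subsequent") observations by default; all non-BLQ observations
    ("all"); or a fixed holdout ("holdout") — the usable observations beyond
    the first ``holdout_after`` per patient, which is the same evaluation set
    for every support count k <= ``holdout_after`` and therefore the right
    comparator when studying how forecasts improve with k.
    """
    df = pooled[~pooled["below_lloq"] & (pooled["c_obs"] > 0)]
    if scope == "subsequent":
        df = df[~df["support"]]
    elif scope == "holdout":
        rank = df.groupby("patient").cumcount()
        df = df[rank >= holdout_after]
    elif scope != "all":
        raise DomainError(f"unknown scope {scope!r}")
    col = "c_ipred" if kind == "ipred" else "c_pred"
    strata = {"all": df}
    if stratify_rrt and "rrt" in df.columns:
        strata = {"RRT": df[df["rrt"]], "non-RRT": df[~df["rrt"]]}
    rows = []
    for name, sub in strata.items():
        pe = prediction_error_pct(sub[col].to_numpy(), sub["c_obs"].to_numpy())
        res = summarize_pe(pe, k_support=k_support, model_name=model_name, stratum=name)
        row = res.as_row()
        row["iqr_rule"] = iqr_acceptance(res) if res.n >= 4 else "insufficient-data"
        rows.append(row)
    return pd.DataFrame(rows)
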