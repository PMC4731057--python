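"""Calibration quality metrics.

The central criterion is the root-mean-square residual

    RMS = sqrt( sum_p sum_k (o_pk - o*_pk)^2 / (N * M) )

over N spectra and M outputs (M = 1 here: the contaminant cell count),
where o_pk is the experimental and o*_pk the calculated value.  Alongside
it: the slope k and determination coefficient R^2 of the OLS line of
predicted vs experimental counts, and a Wald-Wolfowitz runs test on the
signs of the residuals (ordered by experimental value) as an operational
check that residuals carry no systematic trend.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


def rms_eq1(experimental: np.ndarray, predicted: np.ndarray, M: int = 1) -> float:
    """Root mean square of residuals over N spectra and M outputs.

    Inputs may be (N,) vectors (then M must be 1) or (N, M) tables.
    """
    o = np.asarray(experimental, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValidationError(f"shape mismatch: {o.shape} vs {p.shape}")
    if o.size == 0:
        raise ValidationError("empty input")
    if o.ndim == 1:
        if M != 1:
            raise ValidationError("1-D input implies M=1")
        N = o.shape[0]
    elif o.ndim == 2:
        N, M = o.shape
    else:
        raise ValidationError("inputs must be 1-D or 2-D")
    return float(np.sqrt(np.sum((o - p) ** 2) / (N * M)))


def regression_diagnostics(
    experimental: np.ndarray, predicted: np.ndarray
) -> tuple[float, float, float]:
    """OLS of predicted on experimental: returns (slope k, intercept, R^2)."""
    x = np.asarray(experimental, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValidationError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValidationError("experimental values are all equal; slope undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def residual_randomness(residuals: np.ndarray) -> tuple[float, float]:
    """Wald-Wolfowitz runs test on the signs of residuals about zero.

    The caller orders residuals by experimental value.  Returns the normal
    z statistic for the observed number of sign runs and a two-sided
    p-value.  Exact zeros are dropped.  If every residual has the same
    sign the trend is maximal: z = -inf, p = 0.0.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 8:
        raise ValidationError("runs test needs at least 8 residuals")
    signs = np.sign(r)
    signs = signs[signs != 0]
    if signs.size == 0:
        raise ValidationError("all residuals are exactly zero")
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    if n_pos == 0 or n_neg == 0:
        return float("-inf"), 0.0
    n = n_pos + n_neg
    runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    mean = 1.0 + 2.0 * n_pos * n_neg / n
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return float("-inf"), 0.0
    z = (runs - mean) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class CalibrationResult:
    """Per-sample predicted vs experimental contaminant counts with the
    summary metrics (Eq-1 RMS, slope k, intercept, R^2, runs test)."""

    row_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    rms: float
    k: float
    intercept: float
    r2: float
    runs_z: float = float("nan")
    runs_p: float = float("nan")
    label: str = ""

    @property
    def residuals(self) -> np.ndarray:
        return self.y_true - self.y_pred

    @classmethod
    def from_predictions(
        cls,
        y_true: np.ndarray,
        y_pred: np.ndarray,
        row_ids: list[str] | None = None,
        label: str = "",
    ) -> "CalibrationResult":
        y_true = np.asarray(y_true, dtype=float)
        y_pred = np.asarray(y_pred, dtype=float)
        if row_ids is None:
            row_ids = [str(i) for i in range(len(y_true))]
        k, b, r2 = regression_diagnostics(y_true, y_pred)
        res = y_true - y_pred
        runs_z = runs_p = float("nan")
        if len(res) >= 8 and np.any(res != 0):
            order = np.argsort(y_true, kind="stable")
            runs_z, runs_p = residual_randomness(res[order])
        return cls(
            row_ids=list(row_ids),
            y_true=y_true,
            y_pred=y_pred,
            rms=rms_eq1(y_true, y_pred),
            k=k,
            intercept=b,
            r2=r2,
            runs_z=runs_z,
            runs_p=runs_p,
            label=label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row_id": self.row_ids,
                "y_true": self.y_true,
                "y_pred": self.y_pred,
                "residual": self.residuals,
            }
        )

    def summary(self) -> dict:
        return {
            "label": self.label,
            "n": len(self.y_true),
            "rms": self.rms,
            "k": self.k,
            "intercept": self.intercept,
            "r2": self.r2,
            "runs_z": self.runs_z,
            "runs_p": self.runs_p,
        }

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2))
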