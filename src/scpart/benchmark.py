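"""Benchmarking predicted against experimental partition coefficients.

Residuals are predicted minus experimental (negative = underprediction), the
RMSE is the root mean square of those residuals, and the QSPR relating
lipid/water to octanol/water partitioning is fit by least squares through the
origin: log K_lip = beta * log K_ow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class BenchmarkError(ValueError):
    pass


@dataclass
class SoluteRecord:
    """One benchmark row; optional fields are None when absent, never dropped."""

    name: str
    log_klip_exp: float | None = None
    log_kow: float | None = None
    log_kow_pred: float | None = None
    log_klip_pred: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise BenchmarkError("solute name must be non-empty")
        for label, value in (
            ("log_klip_exp", self.log_klip_exp),
            ("log_kow", self.log_kow),
            ("log_kow_pred", self.log_kow_pred),
        ):
            if value is not None and not np.isfinite(value):
                raise BenchmarkError(f"{label} of {self.name!r} is not finite")


@dataclass(frozen=True)
class QSPRFit:
    """Through-origin fit log K_lip = beta * log K_ow with fit diagnostics."""

    beta: float
    rmse_fit: float
    pearson_r: float
    n_points: int


@dataclass(frozen=True)
class BenchmarkStats:
    rmse: float
    residuals: np.ndarray


@dataclass(frozen=True)
class QuadrantCounts:
    q1: int  # (+, +)
    q2: int  # (-, +)
    q3: int  # (-, -)
    q4: int  # (+, -)
    on_axis: int

    @property
    def sign_agreement(self) -> float:
        in_quadrant = self.q1 + self.q2 + self.q3 + self.q4
        if in_quadrant == 0:
            return float("nan")
        return (self.q1 + self.q3) / in_quadrant


def residuals(pred: Sequence[float], exp: Sequence[float]) -> np.ndarray:
    """RES_i = predicted_i - experimental_i (log10 units)."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1:
        raise BenchmarkError(f"length mismatch: {pred.shape} vs {exp.shape}")
    if pred.size < 1:
        raise BenchmarkError("need at least one paired value")
    return pred - exp


def rmse(pred: Sequence[float], exp: Sequence[float]) -> float:
    res = residuals(pred, exp)
    return float(np.sqrt(np.mean(res**2)))


def benchmark_stats(pred: Sequence[float], exp: Sequence[float]) -> BenchmarkStats:
    res = residuals(pred, exp)
    return BenchmarkStats(rmse=float(np.sqrt(np.mean(res**2))), residuals=res)


def _require_log_kow(records: Iterable[SoluteRecord]) -> None:
    nameless = [r.name for r in records if r.log_kow is None]
    if nameless:
        raise BenchmarkError(f"records without experimental log_kow: {nameless}")


def exclude_extreme_lipophilic(
    records: Sequence[SoluteRecord], threshold: float = 5.0
) -> tuple[list[SoluteRecord], list[SoluteRecord]]:
    """Drop records with log K_ow strictly above the threshold.

    Returns (retained, removed). Measured K_lip of extremely lipophilic
    solutes depends on sample lipid content, so they are excluded outright.
    """
    _require_log_kow(records)
    retained = [r for r in records if r.log_kow <= threshold]
    removed = [r for r in records if r.log_kow > threshold]
    return retained, removed


def reduced_dataset(
    records: Sequence[SoluteRecord], threshold: float = 1.0
) -> tuple[list[SoluteRecord], list[SoluteRecord]]:
    """Keep only records with log K_ow >= threshold. Returns (retained, removed)."""
    _require_log_kow(records)
    retained = [r for r in records if r.log_kow >= threshold]
    removed = [r for r in records if r.log_kow < threshold]
    if not retained:
        warnings.warn("reduced dataset is empty: all solutes have log_kow below threshold")
    return retained, removed


def qspr_fit(log_klip: Sequence[float], log_kow: Sequence[float]) -> QSPRFit:
    """Least squares through the origin of y = log K_lip on x = log K_ow.

    beta = sum(x*y) / sum(x^2); rmse_fit is the RMS of y - beta*x; the Pearson
    correlation is computed on (x, y) directly and is independent of the fit.
    """
    y = np.asarray(log_klip, dtype=float)
    x = np.asarray(log_kow, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise BenchmarkError("paired vectors of equal length required")
    if x.size < 2:
        raise BenchmarkError("need at least two points to fit")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise BenchmarkError("non-finite values in fit input")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise BenchmarkError("degenerate fit: all log_kow values are zero")
    beta = float(np.sum(x * y) / sxx)
    resid = y - beta * x
    rmse_fit = float(np.sqrt(np.mean(resid**2)))
    with np.errstate(invalid="ignore"):
        r = float(np.corrcoef(x, y)[0, 1])
    return QSPRFit(beta=beta, rmse_fit=rmse_fit, pearson_r=r, n_points=int(x.size))


def quadrant_analysis(res_klip: Sequence[float], res_kow: Sequence[float]) -> QuadrantCounts:
    """Count residual pairs (x=res_kow, y=res_klip) per quadrant.

    Q1 = (+, +), Q2 = (-, +), Q3 = (-, -), Q4 = (+, -). Points with either
    residual exactly zero sit on an axis and belong to no quadrant.
    """
    y = np.asarray(res_klip, dtype=float)
    x = np.asarray(res_kow, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise BenchmarkError("paired residual vectors required")
    on_axis = int(np.sum((x == 0) | (y == 0)))
    q1 = int(np.sum((x > 0) & (y > 0)))
    q2 = int(np.sum((x < 0) & (y > 0)))
    q3 = int(np.sum((x < 0) & (y < 0)))
    q4 = int(np.sum((x > 0) & (y < 0)))
    return QuadrantCounts(q1=q1, q2=q2, q3=q3, q4=q4, on_axis=on_axis)


def benchmark_report(
    records: Sequence[SoluteRecord],
    systems: Sequence[str],
    fit_vs: str = "exp",
) -> dict:
    """Per-system RMSE (full and reduced sets) plus QSPR fits.

    ``fit_vs`` selects the x axis of the QSPR fit: experimental ("exp") or
    predicted ("pred") log K_ow.
    """
    if fit_vs not in ("exp", "pred"):
        raise BenchmarkError("fit_vs must be 'exp' or 'pred'")
    if not systems:
        raise BenchmarkError("at least one system required")
    gaps = {
        s: [r.name for r in records if s not in r.log_klip_pred]
        for s in systems
    }
    gaps = {s: names for s, names in gaps.items() if names}
    if gaps:
        raise BenchmarkError(f"missing predictions: {gaps}")
    no_exp = [r.name for r in records if r.log_klip_exp is None]
    if no_exp:
        raise BenchmarkError(f"records without experimental log_klip: {no_exp}")
    retained, removed = exclude_extreme_lipophilic(records)
    reduced, hydrophilic = reduced_dataset(retained)
    report: dict = {
        "n_input": len(records),
        "n_retained": len(retained),
        "n_reduced": len(reduced),
        "excluded_extreme_lipophilic": [r.name for r in removed],
        "removed_hydrophilic": [r.name for r in hydrophilic],
        "systems": {},
    }

    def xvals(recs: list[SoluteRecord]) -> np.ndarray:
        if fit_vs == "exp":
            return np.array([r.log_kow for r in recs])
        missing = [r.name for r in recs if r.log_kow_pred is None]
        if missing:
            raise BenchmarkError(f"records without predicted log_kow: {missing}")
        return np.array([r.log_kow_pred for r in recs])

    for s in systems:
        entry: dict = {}
        for label, recs in (("all", retained), ("reduced", reduced)):
            pred = np.array([r.log_klip_pred[s] for r in recs])
            exp = np.array([r.log_klip_exp for r in recs])
            stats = benchmark_stats(pred, exp)
            fit = qspr_fit(pred, xvals(recs))
            entry[label] = {
                "rmse": stats.rmse,
                "n": len(recs),
                "qspr": {
                    "beta": fit.beta,
                    "rmse_fit": fit.rmse_fit,
                    "pearson_r": fit.pearson_r,
                    "n_points": fit.n_points,
                },
            }
        report["systems"][s] = entry
    exp_y = np.array([r.log_klip_exp for r in retained])
    exp_fit = qspr_fit(exp_y, np.array([r.log_kow for r in retained]))
    report["experimental_qspr"] = {
        "beta": exp_fit.beta,
        "rmse_fit": exp_fit.rmse_fit,
        "pearson_r": exp_fit.pearson_r,
        "n_points": exp_fit.n_points,
    }
    return report
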