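"""Causal-effect estimators for two-sample MR: per-SNP Wald ratios,
random-effects inverse-variance-weighted (IVW) pooling, the weighted-median
estimator with parametric-bootstrap SE, and MR-Egger regression.

All estimates are reported on the log-odds-per-SD scale with a 95% interval
and, exponentiated, as odds ratios per SD of the exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    CollinearityError,
    DegenerateInstrumentError,
    DomainError,
    InsufficientInstrumentsError,
)
from .harmonize import HarmonizedInstrument

MIN_INSTRUMENTS_IVW = 2
MIN_INSTRUMENTS_WM = 3
MIN_INSTRUMENTS_EGGER = 3


@dataclass(frozen=True)
class WaldRatio:
    """Per-SNP ratio estimate with first-order SE and inverse-variance weight."""

    snp_id: str
    theta: float
    se: float

    @property
    def weight(self) -> float:
        return self.se ** -2


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on both the log-odds and OR scales."""

    method: str  # IVW | WM | MR-Egger
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)

    @classmethod
    def from_or(
        cls, method: str, or_value: float, or_low: float, or_high: float,
        pvalue: float, n_snps: int = 0,
    ) -> "MREstimate":
        """Build an estimate from published OR / 95% CI / p values, back-solving
        the SE from the interval width on the log scale."""
        beta = math.log(or_value)
        lo, hi = math.log(or_low), math.log(or_high)
        crit = stats.norm.ppf(0.975)
        return cls(
            method=method, beta=beta, se=(hi - lo) / (2 * crit),
            ci_low=lo, ci_high=hi, pvalue=pvalue, n_snps=n_snps,
        )


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope (the causal estimate) and intercept (average
    directional pleiotropy) with its test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def wald_ratio(inst: HarmonizedInstrument) -> WaldRatio:
    """theta = beta_out / beta_exp with first-order SE = se_out / |beta_exp|."""
    if inst.beta_exp == 0:
        raise DegenerateInstrumentError(f"{inst.snp_id}: beta_exp is zero")
    return WaldRatio(
        snp_id=inst.snp_id,
        theta=inst.beta_out / inst.beta_exp,
        se=inst.se_out / abs(inst.beta_exp),
    )


def _ratio_arrays(insts: Sequence[HarmonizedInstrument]) -> tuple[np.ndarray, np.ndarray]:
    ratios = [wald_ratio(i) for i in insts]
    return (
        np.array([r.theta for r in ratios]),
        np.array([r.se for r in ratios]),
    )


def to_odds_ratio(beta: float, se: float, crit: float = 1.959963984540054) -> tuple[float, float, float]:
    """Exponentiate an estimate and its +/- crit*se interval to the OR scale."""
    if se <= 0:
        raise DomainError(f"se must be > 0, got {se}")
    return math.exp(beta), math.exp(beta - crit * se), math.exp(beta + crit * se)


def ivw_from_ratios(theta: np.ndarray, se: np.ndarray) -> tuple[float, float, float, float]:
    """Multiplicative random-effects IVW on ratio estimates.

    Returns (beta_hat, se_fixed, q_stat, phi) where phi = max(1, sqrt(Q/(J-1)))
    is the random-effects scale; the reported SE is se_fixed * phi.
    """
    w = se ** -2.0
    beta_hat = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q_stat = float(np.sum(w * (theta - beta_hat) ** 2))
    j = theta.size
    phi = max(1.0, math.sqrt(q_stat / (j - 1))) if j > 1 else 1.0
    return beta_hat, se_fixed, q_stat, phi


def mr_ivw(insts: Sequence[HarmonizedInstrument]) -> tuple[MREstimate, float]:
    """Random-effects IVW estimate; also returns Cochran's Q.

    The point estimate is the precision-weighted mean of the Wald ratios —
    identically the weighted regression of beta_out on beta_exp through the
    origin with weights se_out^-2.  Under-dispersion never shrinks the SE
    below the fixed-effect value.
    """
    if len(insts) < MIN_INSTRUMENTS_IVW:
        raise InsufficientInstrumentsError(f"IVW needs >= {MIN_INSTRUMENTS_IVW} instruments, got {len(insts)}")
    theta, se = _ratio_arrays(insts)
    beta_hat, se_fixed, q_stat, phi = ivw_from_ratios(theta, se)
    se_re = se_fixed * phi
    crit = stats.norm.ppf(0.975)
    p = float(2.0 * stats.norm.sf(abs(beta_hat) / se_re))
    est = MREstimate(
        method="IVW", beta=beta_hat, se=se_re,
        ci_low=beta_hat - crit * se_re, ci_high=beta_hat + crit * se_re,
        pvalue=p, n_snps=len(insts),
    )
    return est, q_stat


def weighted_median_value(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted median with mid-weight interpolation.

    Sort values ascending carrying weights; with cumulative weights S_j and
    total S, define p_j = (S_j - w_j/2) / S and return the value linearly
    interpolated at p = 0.5 (boundary value when 0.5 falls outside [p_1, p_J]).
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0 or v.shape != w.shape:
        raise DomainError("values and weights must be equal-length and non-empty")
    if np.any(w <= 0):
        raise DomainError("weights must be strictly positive")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, v))


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for (n_rep, J) value matrices (bootstrap core)."""
    order = np.argsort(values, axis=1, kind="stable")
    v = np.take_along_axis(values, order, axis=1)
    w = np.broadcast_to(weights, values.shape)
    w = np.take_along_axis(w, order, axis=1)
    cum = np.cumsum(w, axis=1)
    p = (cum - 0.5 * w) / cum[:, -1:]
    below = p < 0.5
    idx_hi = below.sum(axis=1)  # first index with p >= 0.5
    j = values.shape[1]
    out = np.empty(values.shape[0])
    rows = np.arange(values.shape[0])
    interior = (idx_hi > 0) & (idx_hi < j)
    out[idx_hi == 0] = v[idx_hi == 0, 0]
    out[idx_hi == j] = v[idx_hi == j, -1]
    if np.any(interior):
        r = rows[interior]
        hi = idx_hi[interior]
        lo = hi - 1
        p_lo, p_hi = p[r, lo], p[r, hi]
        frac = np.where(p_hi > p_lo, (0.5 - p_lo) / np.where(p_hi > p_lo, p_hi - p_lo, 1.0), 0.0)
        out[interior] = v[r, lo] + frac * (v[r, hi] - v[r, lo])
    return out


def mr_weighted_median(
    insts: Sequence[HarmonizedInstrument], n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate is the inverse-variance weighted median of the Wald
    ratios.  Its SE is the standard deviation of ``n_boot`` replicates drawing
    theta_j* ~ Normal(theta_j, se_j) and recomputing the weighted median; p and
    CI follow a normal approximation.  Reproducible given ``seed``.
    """
    if len(insts) < MIN_INSTRUMENTS_WM:
        raise InsufficientInstrumentsError(f"WM needs >= {MIN_INSTRUMENTS_WM} instruments, got {len(insts)}")
    theta, se = _ratio_arrays(insts)
    w = se ** -2.0
    beta_hat = weighted_median_value(theta, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=theta, scale=se, size=(n_boot, theta.size))
    reps = _weighted_median_rows(draws, w)
    se_boot = float(np.std(reps, ddof=1))
    crit = stats.norm.ppf(0.975)
    p = float(2.0 * stats.norm.sf(abs(beta_hat) / se_boot)) if se_boot > 0 else (1.0 if beta_hat == 0 else 0.0)
    return MREstimate(
        method="WM", beta=beta_hat, se=se_boot,
        ci_low=beta_hat - crit * se_boot, ci_high=beta_hat + crit * se_boot,
        pvalue=p, n_snps=len(insts),
    )


def mr_egger(insts: Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept.

    Instruments are first oriented so beta_exp >= 0 (both betas negated when
    beta_exp < 0), weights are se_out^-2, and a multiplicative random-effects
    scale max(1, sqrt(RSS_w/(J-2))) inflates both coefficient SEs.  p-values
    and CIs use the t distribution with J-2 degrees of freedom.
    """
    j = len(insts)
    if j < MIN_INSTRUMENTS_EGGER:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= {MIN_INSTRUMENTS_EGGER} instruments, got {j}")
    bx = np.array([i.beta_exp for i in insts], dtype=float)
    by = np.array([i.beta_out for i in insts], dtype=float)
    sy = np.array([i.se_out for i in insts], dtype=float)
    flip = bx < 0
    bx = np.where(flip, -bx, bx)
    by = np.where(flip, -by, by)
    if np.ptp(bx) == 0:
        raise CollinearityError("zero variance in beta_exp; Egger slope unidentified")

    w = sy ** -2.0
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    try:
        cov_unit = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError("singular design in Egger regression") from exc
    coef = cov_unit @ (x.T @ (w * by))
    resid = by - x @ coef
    rss_w = float(np.sum(w * resid ** 2))
    df = j - 2
    phi = max(1.0, math.sqrt(rss_w / df))
    se_coef = np.sqrt(np.diag(cov_unit)) * phi
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(se_coef[0]), float(se_coef[1])
    crit = stats.t.ppf(0.975, df)
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, df)) if se_slope > 0 else (1.0 if slope == 0 else 0.0)
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_int, df)) if se_int > 0 else 1.0
    slope_est = MREstimate(
        method="MR-Egger", beta=slope, se=se_slope,
        ci_low=slope - crit * se_slope, ci_high=slope + crit * se_slope,
        pvalue=p_slope, n_snps=j,
    )
    return EggerResult(slope=slope_est, intercept=intercept, intercept_se=se_int, intercept_p=p_int)
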