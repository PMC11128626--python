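"""Causal-effect estimators and the sensitivity suite for two-sample MR.

Given J harmonized instruments with exposure effects beta_X (SE sigma_X) and
outcome effects beta_Y (SE sigma_Y), the per-variant Wald ratio is
beta_Y / beta_X and the panel comprises:

* IVW — inverse-variance-weighted meta-analysis of Wald ratios, equivalent to
  weighted regression of beta_Y on beta_X through the origin with weights
  sigma_Y^-2.  Default is a multiplicative random-effects model: the SE is
  inflated by sqrt(Q/(J-1)) whenever Cochran's Q exceeds its degrees of
  freedom.
* MR-Egger — the same regression with a free intercept (after orienting all
  instruments to positive exposure effect); a nonzero intercept indicates
  directional pleiotropy.
* Weighted median — consistent when at least half the weight lies on valid
  instruments; SE by parametric bootstrap.
* Simple and weighted mode — kernel-density mode of the Wald ratios
  (modified-Silverman bandwidth); consistent when the largest group of
  instruments sharing one ratio is valid; SE by parametric bootstrap.

Sensitivity: Cochran's Q heterogeneity test, MR-Egger intercept test,
leave-one-out IVW, and MR-PRESSO (global RSS test, per-variant outlier test
with Bonferroni correction, and a distortion test when outliers are found).

Estimates are on the log-odds scale for binary outcomes; odds ratios are
exposed via ``MREstimate.odds_ratio`` and ``or_from_beta``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError
from .summary_io import HarmonizedInstrument

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_variants: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def as_dict(self) -> dict:
        lo, hi = self.or_ci
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_variants": self.n_variants,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": lo,
            "or_ci_high": hi,
        }


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float


@dataclass
class PressoResult:
    rss_observed: float
    global_pvalue: float
    outlier_indices: tuple[int, ...]
    outlier_pvalues: np.ndarray
    distortion_pvalue: float | None
    n_simulations: int
    seed: int


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    bx = np.array([i.beta_exposure for i in instruments], dtype=float)
    sx = np.array([i.se_exposure for i in instruments], dtype=float)
    by = np.array([i.beta_outcome for i in instruments], dtype=float)
    sy = np.array([i.se_outcome for i in instruments], dtype=float)
    return bx, sx, by, sy


def _estimate(method: str, beta: float, se: float, j: int) -> MREstimate:
    if se > 0 and np.isfinite(se):
        p = 2 * stats.norm.sf(abs(beta) / se)
        ci = (beta - Z95 * se, beta + Z95 * se)
    else:
        p, ci = float("nan"), (float("nan"), float("nan"))
    return MREstimate(method, float(beta), float(se), ci[0], ci[1], float(p), j)


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Per-variant causal estimate beta_Y/beta_X with first-order SE
    sigma_Y/|beta_X|."""
    if inst.beta_exposure == 0:
        raise InputError(f"{inst.variant_id}: zero exposure effect")
    beta = inst.beta_outcome / inst.beta_exposure
    se = inst.se_outcome / abs(inst.beta_exposure)
    return _estimate("Wald-ratio", beta, se, 1)


def ivw(
    instruments: Sequence[HarmonizedInstrument], model: str = "random"
) -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``model="fixed"`` uses the fixed-effect SE; ``model="random"`` (default)
    is multiplicative random effects, inflating the SE by
    max(1, sqrt(Q/(J-1))).  A single instrument degrades to the Wald ratio.
    """
    if model not in ("fixed", "random"):
        raise InputError(f"unknown IVW model {model!r}")
    j = len(instruments)
    if j == 0:
        raise InputError("ivw requires at least one instrument")
    if j == 1:
        logger.info("single instrument: IVW degrades to the Wald ratio")
        est = wald_ratio(instruments[0])
        return MREstimate("IVW", est.beta, est.se, est.ci_low, est.ci_high, est.pvalue, 1)

    bx, _, by, sy = _arrays(instruments)
    if np.all(bx == 0):
        raise InputError("all exposure effects are zero")
    w = sy**-2
    denom = np.sum(w * bx**2)
    beta = np.sum(w * bx * by) / denom
    se = denom**-0.5
    if model == "random":
        q = np.sum(w * (by - beta * bx) ** 2)
        se *= max(1.0, math.sqrt(q / (j - 1)))
    return _estimate("IVW", beta, se, j)


def egger(instruments: Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger regression: weighted least squares of beta_Y on beta_X with a
    free intercept, weights sigma_Y^-2, after orienting every instrument so
    beta_X > 0.  SEs use a multiplicative random-effects scale
    max(1, sqrt(RSS/(J-2))); the intercept is tested two-sided against 0.
    """
    j = len(instruments)
    if j < 3:
        raise InputError(f"MR-Egger requires at least 3 instruments, got {j}")
    bx, _, by, sy = _arrays(instruments)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = sy**-2

    # Weighted normal equations for y = a + b*x.
    sw, swx = w.sum(), (w * bx).sum()
    swxx, swy, swxy = (w * bx * bx).sum(), (w * by).sum(), (w * bx * by).sum()
    det = sw * swxx - swx**2
    if det <= 0:
        raise InputError("degenerate design: exposure effects are collinear")
    a = (swxx * swy - swx * swxy) / det
    b = (sw * swxy - swx * swy) / det
    resid = by - a - b * bx
    scale = max(1.0, (w * resid**2).sum() / (j - 2))
    se_a = math.sqrt(scale * swxx / det)
    se_b = math.sqrt(scale * sw / det)

    slope = _estimate("Egger-slope", b, se_b, j)
    p_int = 2 * stats.norm.sf(abs(a) / se_a)
    return EggerResult(slope, float(a), float(se_a), float(p_int))


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    # cumulative weight at the midpoint of each observation
    p = np.cumsum(w) - w / 2
    return float(np.interp(0.5, p, r))


def _bootstrap_se(point_fn, bx, sx, by, sy, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for k in range(n_boot):
        bxk = rng.normal(bx, sx)
        byk = rng.normal(by, sy)
        draws[k] = point_fn(bxk, byk)
    return float(draws.std(ddof=1))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    *,
    n_boot: int = 5000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted median of the Wald ratios, weights (beta_X/sigma_Y)^2.

    The estimate interpolates the cumulative weight function at 0.5.  SE by
    seeded parametric bootstrap (``n_boot=0`` skips it, leaving SE/CI/p NaN).
    """
    j = len(instruments)
    if j < 3:
        raise InputError(f"weighted median requires at least 3 instruments, got {j}")
    if n_boot > 0 and seed is None:
        raise InputError("bootstrap requires an explicit seed")
    bx, sx, by, sy = _arrays(instruments)

    def point(bxk, byk):
        return _weighted_median(byk / bxk, (bxk / sy) ** 2)

    beta = point(bx, by)
    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed) if n_boot > 0 else float("nan")
    return _estimate("weighted-median", beta, se, j)


def _silverman_bandwidth(ratios: np.ndarray, phi: float) -> float:
    s = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    return phi * 0.9 * min(s, mad) * len(ratios) ** (-1 / 5)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, h: float, gridsize: int = 2048) -> float:
    if h == 0:
        # Degenerate scale (tied ratios): the h->0 limit of the KDE argmax is
        # the discrete weighted mode.
        vals, inv = np.unique(ratios, return_inverse=True)
        return float(vals[np.argmax(np.bincount(inv, weights=weights))])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, gridsize)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[np.argmax(dens)])


def mode_estimate(
    instruments: Sequence[HarmonizedInstrument],
    *,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 5000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimate: argmax of a normal-kernel density over the Wald
    ratios, bandwidth = bandwidth_factor x modified-Silverman scale.

    ``weighted=True`` weights each ratio by its inverse variance
    (beta_X/sigma_Y)^2; ``weighted=False`` is the simple mode.  SE by seeded
    parametric bootstrap.
    """
    j = len(instruments)
    if j < 3:
        raise InputError(f"mode estimator requires at least 3 instruments, got {j}")
    if bandwidth_factor <= 0:
        raise InputError("bandwidth_factor must be positive")
    if n_boot > 0 and seed is None:
        raise InputError("bootstrap requires an explicit seed")
    bx, sx, by, sy = _arrays(instruments)

    def point(bxk, byk):
        r = byk / bxk
        w = (bxk / sy) ** 2 if weighted else np.ones_like(r)
        w = w / w.sum()
        return _kde_mode(r, w, _silverman_bandwidth(r, bandwidth_factor))

    beta = point(bx, by)
    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed) if n_boot > 0 else float("nan")
    return _estimate("weighted-mode" if weighted else "simple-mode", beta, se, j)


def cochran_q(
    instruments: Sequence[HarmonizedInstrument],
    beta_ref: float | None = None,
) -> HeterogeneityResult:
    """Cochran's Q over per-variant Wald ratios with first-order weights
    (beta_X/sigma_Y)^2, referenced to the fixed-effect IVW estimate unless
    ``beta_ref`` is given.  p from chi-square with J-1 df.
    """
    j = len(instruments)
    if j < 2:
        raise InputError(f"Cochran's Q requires at least 2 instruments, got {j}")
    bx, _, by, sy = _arrays(instruments)
    if beta_ref is None:
        beta_ref = ivw(instruments, model="fixed").beta
    w = (bx / sy) ** 2
    q = float(np.sum(w * (by / bx - beta_ref) ** 2))
    return HeterogeneityResult(q, j - 1, float(stats.chi2.sf(q, j - 1)))


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument], model: str = "random"
) -> list[tuple[str, MREstimate]]:
    """IVW re-estimated J times, each time omitting one instrument."""
    j = len(instruments)
    if j < 3:
        raise InputError(f"leave-one-out requires at least 3 instruments, got {j}")
    out = []
    for k in range(j):
        rest = list(instruments[:k]) + list(instruments[k + 1 :])
        out.append((instruments[k].variant_id, ivw(rest, model=model)))
    return out


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW (fixed) slopes, vectorized.  Rows of bx/by may be 2-D
    (simulations x variants); w is the 1-D weight vector."""
    s1 = (w * bx * by).sum(axis=-1, keepdims=True)
    s2 = (w * bx * bx).sum(axis=-1, keepdims=True)
    return (s1 - w * bx * by) / (s2 - w * bx * bx)


def mr_presso(
    instruments: Sequence[HarmonizedInstrument],
    *,
    n_sim: int = 5000,
    seed: int,
    significance: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, per-variant outlier test, and
    distortion test.

    The observed statistic is the weighted residual sum of squares where each
    variant's prediction uses the IVW slope fitted without it.  The null
    distribution comes from ``n_sim`` parametric simulations under the
    no-pleiotropy model: exposure effects redrawn from normals centred on the
    observed values, outcome effects centred on the full-sample IVW slope
    times the redrawn exposure effect (a single generating slope — centring
    each variant on its own leave-one-out slope would plant heterogeneity in
    the null draws and make the test conservative).  Per-variant outlier
    p-values
    are the analogous single-residual tail probabilities, Bonferroni-adjusted
    across the J instruments.  When outliers are flagged, the distortion test
    compares the IVW estimate with and without them against the distortion
    obtained by removing random subsets of the same size.
    """
    j = len(instruments)
    if j < 4:
        raise InputError(f"MR-PRESSO requires at least 4 instruments, got {j}")
    if n_sim < 1000:
        raise InputError("n_sim must be at least 1000")
    bx, sx, by, sy = _arrays(instruments)
    w = sy**-2
    rng = np.random.default_rng(seed)

    slopes = _loo_slopes(bx[None, :], by[None, :], w)[0]
    resid_obs = w * (by - slopes * bx) ** 2
    rss_obs = float(resid_obs.sum())

    beta_full = _ivw_fixed(bx, by, w)
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(beta_full * bx_sim, sy, size=(n_sim, j))
    slopes_sim = _loo_slopes(bx_sim, by_sim, w)
    resid_sim = w * (by_sim - slopes_sim * bx_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))
    outlier_p = (1 + np.sum(resid_sim >= resid_obs, axis=0)) / (1 + n_sim)
    outlier_adj = np.minimum(1.0, outlier_p * j)
    outliers = tuple(int(i) for i in np.flatnonzero(outlier_adj < significance))

    distortion_p = None
    if outliers and j - len(outliers) >= 2:
        keep = np.setdiff1d(np.arange(j), outliers)
        beta_all = _ivw_fixed(bx, by, w)
        beta_out = _ivw_fixed(bx[keep], by[keep], w[keep])
        if beta_out != 0:
            d_obs = abs((beta_all - beta_out) / beta_out)
            d_sim = np.empty(n_sim)
            for k in range(n_sim):
                drop = rng.choice(j, size=len(outliers), replace=False)
                kp = np.setdiff1d(np.arange(j), drop)
                b = _ivw_fixed(bx[kp], by[kp], w[kp])
                d_sim[k] = abs((beta_all - b) / b) if b != 0 else np.inf
            distortion_p = float((1 + np.sum(d_sim >= d_obs)) / (1 + n_sim))

    return PressoResult(
        rss_observed=rss_obs,
        global_pvalue=global_p,
        outlier_indices=outliers,
        outlier_pvalues=outlier_adj,
        distortion_pvalue=distortion_p,
        n_simulations=n_sim,
        seed=seed,
    )


def _ivw_fixed(bx, by, w):
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


def or_from_beta(beta: float, se: float | None = None, ci: tuple[float, float] | None = None):
    """Odds ratio exp(beta) with a 95% CI.

    The CI comes from ``beta +/- 1.96*se`` or, when a log-scale CI is supplied
    directly, from exp-transforming its endpoints.
    """
    if ci is not None:
        lo, hi = ci
    elif se is not None:
        if se < 0:
            raise InputError("se must be non-negative")
        lo, hi = beta - Z95 * se, beta + Z95 * se
    else:
        lo = hi = float("nan")
    return math.exp(beta), math.exp(lo), math.exp(hi)


def estimator_panel(
    instruments: Sequence[HarmonizedInstrument],
    *,
    ivw_model: str = "random",
    n_boot: int = 5000,
    seed: int = 0,
) -> list[MREstimate]:
    """The five-estimator panel (IVW, MR-Egger slope, weighted median, simple
    mode, weighted mode) on one instrument set."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    panel = [ivw(instruments, model=ivw_model)]
    if len(instruments) >= 3:
        panel.append(egger(instruments).slope)
        panel.append(weighted_median(instruments, n_boot=n_boot, seed=int(seeds[0])))
        panel.append(mode_estimate(instruments, weighted=False, n_boot=n_boot, seed=int(seeds[1])))
        panel.append(mode_estimate(instruments, weighted=True, n_boot=n_boot, seed=int(seeds[2])))
    return panel
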