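"""Two-step mediation over Mendelian-randomization fits.

Three univariable MR estimates are combined:

* total effect   — exposure -> outcome (beta_total)
* direct effect A — exposure -> mediator (beta_1)
* direct effect B — mediator -> outcome (beta_2)

The indirect (mediated) effect is the product of coefficients beta_1*beta_2,
with its uncertainty either by the delta method,

    se = sqrt(beta_1^2 * se_2^2 + beta_2^2 * se_1^2),

or by seeded Monte-Carlo propagation (product of independent normal draws,
percentile interval).  The mediated proportion is the ratio of indirect to
total effect expressed as a percentage, with a delta or Monte-Carlo interval.

Note: direct effect B comes from the univariable mediator->outcome fit, which
assumes the mediator instruments act on the outcome only through the mediator
(no unadjusted exposure->outcome path for those variants).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InputError
from .estimators import MREstimate, Z95, cochran_q, egger, ivw, leave_one_out
from .instruments import InstrumentSet, LDMatrix, select_instruments
from .summary_io import VariantAssociation, harmonize

logger = logging.getLogger(__name__)


@dataclass
class Effect:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    method: str


@dataclass
class Proportion:
    percent: float
    ci_low: float
    ci_high: float
    method: str


@dataclass
class MediationResult:
    total: MREstimate
    direct_a: MREstimate
    direct_b: MREstimate
    indirect: Effect
    proportion: Proportion
    interval_method: str
    sensitivity: dict = field(default_factory=dict)

    def table1_row(self) -> dict:
        """One row shaped like the study's mediation summary table."""
        fmt = lambda e: f"{e.beta:.4f} ({e.ci_low:.4f}, {e.ci_high:.4f})"
        return {
            "Total effect": fmt(self.total),
            "Direct effect A": fmt(self.direct_a),
            "Direct effect B": fmt(self.direct_b),
            "Mediation effect": f"{self.indirect.estimate:.4f} "
            f"({self.indirect.ci_low:.4f}, {self.indirect.ci_high:.4f})",
            "P": f"{self.indirect.pvalue:.3g}",
            "Mediated proportion (%)": f"{self.proportion.percent:.1f} "
            f"({self.proportion.ci_low:.1f}, {self.proportion.ci_high:.1f})",
        }


def indirect_effect(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    method: str = "monte-carlo",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> Effect:
    """Product-of-coefficients indirect effect beta1*beta2 with SE, CI and p.

    ``delta`` gives the first-order SE with a symmetric normal interval;
    ``monte-carlo`` draws (b1, b2) from independent normals and takes the
    empirical 2.5/97.5 percentiles of b1*b2 (seeded).
    """
    if se1 < 0 or se2 < 0:
        raise InputError("standard errors must be non-negative")
    point = beta1 * beta2
    se_delta = math.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    p = 2 * stats.norm.sf(abs(point) / se_delta) if se_delta > 0 else float("nan")

    if method == "delta":
        return Effect(point, se_delta, point - Z95 * se_delta, point + Z95 * se_delta, p, "delta")
    if method == "monte-carlo":
        if seed is None:
            raise InputError("monte-carlo interval requires a seed")
        rng = np.random.default_rng(seed)
        prod = rng.normal(beta1, se1, n_draws) * rng.normal(beta2, se2, n_draws)
        lo, hi = np.percentile(prod, [2.5, 97.5])
        p_emp = max(2 * min(np.mean(prod >= 0), np.mean(prod <= 0)), 1.0 / n_draws)
        return Effect(point, float(prod.std(ddof=1)), float(lo), float(hi),
                      float(min(1.0, p_emp)), "monte-carlo")
    raise InputError(f"unknown interval method {method!r}")


def mediated_proportion(
    indirect: float,
    se_indirect: float,
    total: float,
    se_total: float,
    method: str = "monte-carlo",
    n_draws: int = 100_000,
    seed: int | None = None,
) -> Proportion:
    """Mediated proportion = indirect/total x 100%, with a delta-method or
    seeded Monte-Carlo interval for the ratio."""
    if total == 0:
        raise InputError("mediated proportion undefined: total effect is zero")
    point = indirect / total * 100.0
    if method == "delta":
        var = (se_indirect / total) ** 2 + (indirect * se_total / total**2) ** 2
        se = math.sqrt(var) * 100.0
        return Proportion(point, point - Z95 * se, point + Z95 * se, "delta")
    if method == "monte-carlo":
        if seed is None:
            raise InputError("monte-carlo interval requires a seed")
        rng = np.random.default_rng(seed)
        num = rng.normal(indirect, se_indirect, n_draws)
        den = rng.normal(total, se_total, n_draws)
        ratio = 100.0 * num / den
        lo, hi = np.percentile(ratio, [2.5, 97.5])
        return Proportion(point, float(lo), float(hi), "monte-carlo")
    raise InputError(f"unknown interval method {method!r}")


@dataclass
class TwoStepConfig:
    """Options for the two-step mediation fit.

    Mediator instruments are selected from the mediator summary statistics at
    ``mediator_p_threshold`` with LD clumping at ``r2_threshold``, the weak
    instrument filter at ``f_min``, and confounder screening against
    ``blocked_traits``.
    """

    mediator_p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    f_min: float | None = 10.0
    ld: LDMatrix | None = None
    annotations: Mapping[str, set] | None = None
    blocked_traits: Sequence[str] = ("low-density lipoprotein", "coronary artery disease")
    palindrome_policy: str = "infer"
    ivw_model: str = "random"
    interval_method: str = "monte-carlo"
    n_draws: int = 100_000
    seed: int = 0
    with_sensitivity: bool = True


def _leg_fit(exp_records, out_records, cfg: TwoStepConfig, label: str):
    try:
        harm = harmonize(exp_records, out_records, palindrome_policy=cfg.palindrome_policy)
        if not harm.instruments:
            raise InputError("no instruments survived harmonization")
        est = ivw(harm.instruments, model=cfg.ivw_model)
    except InputError as exc:
        raise InputError(f"stage {label}: {exc}") from exc
    sens = {}
    if cfg.with_sensitivity and len(harm.instruments) >= 3:
        eg = egger(harm.instruments)
        sens = {
            "cochran_q": cochran_q(harm.instruments),
            "egger_intercept": eg.intercept,
            "egger_intercept_pvalue": eg.intercept_pvalue,
            "leave_one_out": leave_one_out(harm.instruments, model=cfg.ivw_model),
        }
    return est, harm.instruments, sens


def run_two_step(
    exposure_instruments: Sequence[VariantAssociation],
    mediator_summary: Sequence[VariantAssociation],
    outcome_summary: Sequence[VariantAssociation],
    config: TwoStepConfig | None = None,
) -> MediationResult:
    """Two-step mediation MR.

    beta_total = IVW(exposure -> outcome) on the supplied exposure
    instruments; beta_1 = IVW(exposure -> mediator) on the same instruments;
    beta_2 = IVW(mediator -> outcome) on mediator instruments selected from
    ``mediator_summary`` per the config.  Indirect effect and mediated
    proportion follow by product of coefficients.
    """
    cfg = config or TwoStepConfig()
    total, _, sens_total = _leg_fit(exposure_instruments, outcome_summary, cfg, "total")
    direct_a, _, sens_a = _leg_fit(exposure_instruments, mediator_summary, cfg, "direct_a")

    med_set: InstrumentSet = select_instruments(
        mediator_summary,
        p_threshold=cfg.mediator_p_threshold,
        ld=cfg.ld,
        r2_threshold=cfg.r2_threshold,
        f_min=cfg.f_min,
        annotations=cfg.annotations,
        blocked_traits=cfg.blocked_traits,
    )
    if not med_set.instruments:
        raise InputError("stage direct_b: no mediator instruments selected")
    direct_b, _, sens_b = _leg_fit(med_set.instruments, outcome_summary, cfg, "direct_b")

    rng = np.random.default_rng(cfg.seed)
    s_ind, s_prop = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    ind = indirect_effect(
        direct_a.beta, direct_a.se, direct_b.beta, direct_b.se,
        method=cfg.interval_method, n_draws=cfg.n_draws, seed=s_ind,
    )
    prop = mediated_proportion(
        ind.estimate, ind.se, total.beta, total.se,
        method=cfg.interval_method, n_draws=cfg.n_draws, seed=s_prop,
    )
    return MediationResult(
        total=total,
        direct_a=direct_a,
        direct_b=direct_b,
        indirect=ind,
        proportion=prop,
        interval_method=cfg.interval_method,
        sensitivity={
            "total": sens_total,
            "direct_a": sens_a,
            "direct_b": sens_b,
            "mediator_selection": med_set.log_dict(),
        },
    )
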