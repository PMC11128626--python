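"""Synthetic GWAS summary statistics with known ground truth.

Summary statistics are simulated directly at the summary level: each
variant's observed effect is a normal draw around its true marginal effect,
with the analytic standard error implied by allele frequency and GWAS sample
size.  For a quantitative trait on the standardized scale,

    sigma_j = 1 / sqrt(2 * maf_j * (1 - maf_j) * n),

and for a binary trait on the log-odds scale the denominator gains the
case-fraction factor v*(1-v).  The causal graph is

    exposure --theta_em--> mediator --theta_mo--> outcome,
    exposure --theta_direct--> outcome,

with direct exposure effects gamma_j and direct mediator effects delta_j on
disjoint variant sets, so the marginal per-variant effects are gamma_j on the
exposure, theta_em*gamma_j + delta_j on the mediator, and
(theta_direct + theta_mo*theta_em)*gamma_j + theta_mo*delta_j
(+ optional pleiotropy alpha_j) on the outcome.  With LD blocks, marginal
effects and sampling noise are both
propagated through the block correlation matrix, as GWAS marginal statistics
are.

Defaults mirror the motivating study design: an HbA1c-scale exposure proxying
SGLT2 inhibition, venous thromboembolism as a binary mediator
(12,240 cases / 472,358 controls) and death due to cardiac causes as a rare
binary outcome (1,597 cases / 359,597 controls), with true effects
theta_em = -0.0502, theta_mo = 0.0304 and total effect -0.0171.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


import numpy as np
from scipy import stats

from .errors import ConfigError
from .instruments import LDMatrix
from .summary_io import VariantAssociation

_MIN_P = 5e-324  # smallest subnormal double; keeps p in (0,1]


@dataclass
class Pleiotropy:
    """Direct variant->outcome effects bypassing the exposure.

    kind: "none", "balanced" (mean-zero normal) or "directional"
    (normal with nonzero mean, which violates the exclusion restriction in a
    consistent direction while the InSIDE condition still holds).
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy kind {self.kind!r}")
        if self.kind == "balanced" and self.mean != 0:
            raise ConfigError("balanced pleiotropy must have mean 0")
        if self.kind != "none" and self.sd < 0:
            raise ConfigError("pleiotropy sd must be non-negative")


@dataclass
class SimulationConfig:
    n_variants: int = 200
    n_causal: int = 50  # variants with direct exposure effects
    n_causal_mediator: int = 50  # variants with direct mediator effects (disjoint)
    n_exposure: int = 300_000
    n_mediator: int = 484_598
    n_outcome: int = 361_194
    theta_em: float = -0.0502
    theta_mo: float = 0.0304
    theta_direct: float = -0.0155739  # total effect -0.0171 = direct + em*mo
    gamma_sd: float = 0.02  # scale of true per-allele exposure effects
    delta_sd: float = 0.10  # scale of direct per-allele mediator (log-odds) effects
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    ld_blocks: list[tuple[int, float]] | None = None  # (block size, within-block r)
    maf_range: tuple[float, float] = (0.05, 0.5)
    case_fraction: float = 1_597 / 361_194  # outcome cases / total
    case_fraction_mediator: float | None = 12_240 / 484_598
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 1 or not (1 <= self.n_causal <= self.n_variants):
            raise ConfigError("need 1 <= n_causal <= n_variants")
        if self.n_causal_mediator < 0 or self.n_causal + self.n_causal_mediator > self.n_variants:
            raise ConfigError("exposure- and mediator-causal sets must fit disjointly")
        for n in (self.n_exposure, self.n_mediator, self.n_outcome):
            if n < 2:
                raise ConfigError("sample sizes must be >= 2")
        if not (0 < self.case_fraction < 1):
            raise ConfigError("case_fraction must be in (0,1)")
        if self.case_fraction_mediator is not None and not (0 < self.case_fraction_mediator < 1):
            raise ConfigError("case_fraction_mediator must be in (0,1)")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.ld_blocks:
            for size, r in self.ld_blocks:
                if size < 1 or not (-1 < r < 1):
                    raise ConfigError("ld block needs size >= 1 and |r| < 1")

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.theta_em * self.theta_mo


@dataclass
class SyntheticStudy:
    exposure_stats: list[VariantAssociation]
    mediator_stats: list[VariantAssociation]
    outcome_stats: list[VariantAssociation]
    ld: LDMatrix
    truth: dict


def _analytic_se(maf: np.ndarray, n: int, case_fraction: float | None) -> np.ndarray:
    denom = 2 * maf * (1 - maf) * n
    if case_fraction is not None:
        denom = denom * case_fraction * (1 - case_fraction)
    return 1.0 / np.sqrt(denom)


def _block_correlation(n_variants: int, ld_blocks) -> np.ndarray:
    r_mat = np.eye(n_variants)
    if not ld_blocks:
        return r_mat
    start = 0
    for size, r in ld_blocks:
        stop = min(start + size, n_variants)
        k = stop - start
        if k > 1:
            block = np.full((k, k), r)
            np.fill_diagonal(block, 1.0)
            r_mat[start:stop, start:stop] = block
        start = stop
        if start >= n_variants:
            break
    return r_mat


def _records(ids, chrom, pos, ea, oa, maf, beta, se) -> list[VariantAssociation]:
    z = beta / se
    p = np.maximum(2 * stats.norm.sf(np.abs(z)), _MIN_P)
    return [
        VariantAssociation(
            variant_id=ids[j], chromosome=chrom[j], position=int(pos[j]),
            effect_allele=ea[j], other_allele=oa[j], beta=float(beta[j]),
            se=float(se[j]), pvalue=float(p[j]), eaf=float(maf[j]),
        )
        for j in range(len(ids))
    ]


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]


def simulate_two_sample(config: SimulationConfig) -> SyntheticStudy:
    """Simulate exposure, mediator and outcome summary statistics under the
    configured causal graph, with every random draw recorded in ``truth``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_variants

    maf = rng.uniform(*config.maf_range, size=m)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    ids = [f"rs{j + 1:06d}" for j in range(m)]
    chrom = ["1"] * m
    pos = 10_000 * (np.arange(m) + 1)

    perm = rng.permutation(m)
    causal = perm[: config.n_causal]
    causal_med = perm[config.n_causal : config.n_causal + config.n_causal_mediator]
    gamma = np.zeros(m)
    gamma[causal] = rng.normal(0.0, config.gamma_sd, size=config.n_causal)
    delta = np.zeros(m)
    delta[causal_med] = rng.normal(0.0, config.delta_sd, size=config.n_causal_mediator)

    alpha = np.zeros(m)
    pl = config.pleiotropy
    if pl.kind != "none":
        alpha = rng.normal(pl.mean if pl.kind == "directional" else 0.0, pl.sd, size=m)

    r_mat = _block_correlation(m, config.ld_blocks)
    chol = np.linalg.cholesky(r_mat + 1e-12 * np.eye(m))

    true_x = r_mat @ gamma
    true_m = config.theta_em * true_x + r_mat @ delta
    true_y = config.theta_total * true_x + r_mat @ (config.theta_mo * delta + alpha)

    se_x = _analytic_se(maf, config.n_exposure, None)
    se_m = _analytic_se(maf, config.n_mediator, config.case_fraction_mediator)
    se_y = _analytic_se(maf, config.n_outcome, config.case_fraction)

    def draw(true, se):
        return true + se * (chol @ rng.standard_normal(m))

    beta_x = draw(true_x, se_x)
    beta_m = draw(true_m, se_m)
    beta_y = draw(true_y, se_y)

    truth = {
        "config": asdict(config),
        "gamma": gamma.tolist(),
        "delta": delta.tolist(),
        "alpha": alpha.tolist(),
        "true_marginal_exposure": true_x.tolist(),
        "true_marginal_mediator": true_m.tolist(),
        "true_marginal_outcome": true_y.tolist(),
        "causal_indices": sorted(int(i) for i in causal),
        "causal_mediator_indices": sorted(int(i) for i in causal_med),
        "theta_total": config.theta_total,
    }
    return SyntheticStudy(
        exposure_stats=_records(ids, chrom, pos, ea, oa, maf, beta_x, se_x),
        mediator_stats=_records(ids, chrom, pos, ea, oa, maf, beta_m, se_m),
        outcome_stats=_records(ids, chrom, pos, ea, oa, maf, beta_y, se_y),
        ld=LDMatrix(ids, r_mat),
        truth=truth,
    )


def simulate_coloc_locus(
    n_variants: int = 100,
    shared: bool = True,
    signal_z: float = 8.0,
    seed: int = 0,
    se_scale: float = 0.02,
):
    """A cis-region pair of association vectors for colocalization tests.

    ``shared=True`` places the causal variant at the same index for both
    traits; ``shared=False`` at distinct indices.  Non-causal variants carry
    standard-normal z noise.
    """
    if n_variants < 10:
        raise ConfigError("need at least 10 variants for a locus")
    rng = np.random.default_rng(seed)
    idx1 = int(rng.integers(n_variants))
    if shared:
        idx2 = idx1
    else:
        idx2 = int(rng.integers(n_variants - 1))
        if idx2 >= idx1:
            idx2 += 1

    maf = rng.uniform(0.05, 0.5, size=n_variants)
    ids = [f"rs{j + 1:06d}" for j in range(n_variants)]
    chrom = ["16"] * n_variants
    pos = 1000 * (np.arange(n_variants) + 1)
    ea = ["A"] * n_variants
    oa = ["G"] * n_variants

    def trait(causal_idx):
        z = rng.standard_normal(n_variants)
        z[causal_idx] = signal_z * np.sign(rng.standard_normal() or 1.0)
        se = np.full(n_variants, se_scale)
        return _records(ids, chrom, pos, ea, oa, maf, z * se, se)

    return trait(idx1), trait(idx2)


def make_study_shaped_fixture(seed: int = 0) -> SyntheticStudy:
    """A study fixture engineered to mirror the motivating study's instrument
    counts: the mediator GWAS carries 13 genome-wide-significant variants of
    which 9 are clump indices, 4 are satellites in LD with an index, and 2
    indices carry confounder annotations (LDL / CAD) — so the full selection
    pipeline keeps exactly 7; the exposure is a 6-variant cis set.

    ``truth["annotations"]`` holds the confounder table and
    ``truth["cis_ids"]`` the cis-instrument ids.
    """
    rng = np.random.default_rng(seed)
    theta_em, theta_mo, theta_direct = -0.0502, 0.0304, -0.0155739
    theta_total = theta_direct + theta_em * theta_mo

    n_cis, n_index, n_sat, n_null = 6, 9, 4, 40
    m = n_cis + n_index + n_sat + n_null
    ids = [f"rs{j + 1:06d}" for j in range(m)]
    chrom = ["16"] * n_cis + ["1"] * (m - n_cis)
    pos = 10_000 * (np.arange(m) + 1)
    ea = ["A"] * m
    oa = ["G"] * m
    maf = rng.uniform(0.1, 0.5, size=m)

    cis = np.arange(n_cis)
    index = np.arange(n_cis, n_cis + n_index)
    sat = np.arange(n_cis + n_index, n_cis + n_index + n_sat)

    n_exp, n_med, n_out = 300_000, 484_598, 361_194
    se_x = _analytic_se(maf, n_exp, None)
    se_m = _analytic_se(maf, n_med, 12_240 / 484_598)
    se_y = _analytic_se(maf, n_out, 1_597 / 361_194)

    # Exposure: strong cis effects (HbA1c locus scale), null elsewhere.  The
    # background z noise is clipped well below every selection threshold so
    # the engineered instrument counts hold for any seed.
    gamma = np.zeros(m)
    gamma[cis] = rng.choice([-1, 1], n_cis) * rng.uniform(6.0, 9.0, n_cis) * se_x[cis]
    beta_x = gamma + se_x * np.clip(rng.standard_normal(m), -3.0, 3.0)
    beta_x[cis] = gamma[cis]  # keep the engineered z exact for the cis set

    # Mediator: planted genome-wide-significant signals plus the causal
    # contribution from the exposure locus.
    zm = np.clip(rng.standard_normal(m), -3.0, 3.0)
    zm[index] = rng.choice([-1, 1], n_index) * rng.uniform(8.0, 14.0, n_index)
    zm[sat] = rng.choice([-1, 1], n_sat) * rng.uniform(6.0, 7.5, n_sat)
    beta_m = zm * se_m
    beta_m[cis] = theta_em * gamma[cis] + 0.1 * se_m[cis] * rng.standard_normal(n_cis)

    # Outcome: total effect through the exposure locus, mediator effect on
    # the mediator's instruments.
    beta_y = se_y * rng.standard_normal(m)
    beta_y[cis] = theta_total * gamma[cis] + 0.1 * se_y[cis] * rng.standard_normal(n_cis)
    planted = np.concatenate([index, sat])
    beta_y[planted] = theta_mo * beta_m[planted] + 0.1 * se_y[planted] * rng.standard_normal(
        len(planted)
    )

    # LD: identity except each satellite is correlated (r=0.6) with one index.
    r_mat = np.eye(m)
    for k, s in enumerate(sat):
        partner = index[k % n_index]
        r_mat[s, partner] = r_mat[partner, s] = 0.6

    annotations = {
        ids[index[1]]: {"low-density lipoprotein"},
        ids[index[5]]: {"coronary artery disease"},
    }

    truth = {
        "seed": seed,
        "theta_em": theta_em,
        "theta_mo": theta_mo,
        "theta_direct": theta_direct,
        "theta_total": theta_total,
        "cis_ids": [ids[i] for i in cis],
        "mediator_index_ids": [ids[i] for i in index],
        "mediator_satellite_ids": [ids[i] for i in sat],
        "annotations": {k: sorted(v) for k, v in annotations.items()},
        "gamma": gamma.tolist(),
    }
    return SyntheticStudy(
        exposure_stats=_records(ids, chrom, pos, ea, oa, maf, beta_x, se_x),
        mediator_stats=_records(ids, chrom, pos, ea, oa, maf, beta_m, se_m),
        outcome_stats=_records(ids, chrom, pos, ea, oa, maf, beta_y, se_y),
        ld=LDMatrix(ids, r_mat),
        truth=truth,
    )
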