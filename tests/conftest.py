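import numpy as np
import pytest
from hypothesis import settings

from mrmediate.summary_io import HarmonizedInstrument, VariantAssociation

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def make_instruments():
    """Factory: harmonized instruments from effect/SE arrays."""

    def _make(bx, sx, by, sy):
        bx, sx, by, sy = (np.asarray(a, dtype=float) for a in (bx, sx, by, sy))
        return [
            HarmonizedInstrument(
                variant_id=f"rs{j + 1:04d}",
                effect_allele="A",
                other_allele="G",
                beta_exposure=float(bx[j]),
                se_exposure=float(sx[j]),
                beta_outcome=float(by[j]),
                se_outcome=float(sy[j]),
            )
            for j in range(len(bx))
        ]

    return _make


@pytest.fixture
def make_associations():
    """Factory: variant associations from a z-score array (se fixed)."""

    def _make(z, se=0.02, prefix="rs", chrom="1"):
        z = np.asarray(z, dtype=float)
        from scipy import stats

        return [
            VariantAssociation(
                variant_id=f"{prefix}{j + 1:04d}",
                chromosome=chrom,
                position=1000 * (j + 1),
                effect_allele="A",
                other_allele="G",
                beta=float(z[j] * se),
                se=se,
                pvalue=float(max(2 * stats.norm.sf(abs(z[j])), 5e-324)),
                eaf=0.3,
            )
            for j in range(len(z))
        ]

    return _make


@pytest.fixture
def random_instruments(make_instruments):
    """Factory: J instruments from a seeded generator, strong exposure
    effects, no pleiotropy, true causal effect theta."""

    def _make(j=10, theta=0.3, seed=0, sy=0.05):
        rng = np.random.default_rng(seed)
        gamma = rng.uniform(0.1, 0.4, j) * rng.choice([-1, 1], j)
        sx = np.full(j, 0.01)
        syv = np.full(j, sy)
        bx = rng.normal(gamma, sx)
        by = rng.normal(theta * gamma, syv)
        return make_instruments(bx, sx, by, syv)

    return _make
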