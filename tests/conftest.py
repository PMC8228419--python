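"""Shared fixtures and builders for the mrwald test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mrwald import HarmonizedInstrument, VariantAssociation, WaldEstimate


def make_assoc(**overrides) -> VariantAssociation:
    """A valid VariantAssociation with sensible defaults, overridable."""
    defaults = dict(
        rsid="rs1",
        effect_allele="A",
        other_allele="G",
        beta=0.03,
        se=0.005,
        pvalue=1e-9,
        eaf=0.3,
        n=7781,
    )
    defaults.update(overrides)
    return VariantAssociation(**defaults)


def make_harmonized(**overrides) -> HarmonizedInstrument:
    defaults = dict(
        rsid="rs1",
        effect_allele="A",
        other_allele="G",
        beta_exposure=0.1,
        se_exposure=0.01,
        beta_outcome=0.02,
        se_outcome=0.005,
        eaf_exposure=0.3,
        eaf_outcome=0.3,
        palindromic=False,
        flipped=False,
    )
    defaults.update(overrides)
    return HarmonizedInstrument(**defaults)


def random_wald_estimates(rng: np.random.Generator, n: int) -> list[WaldEstimate]:
    """A random but valid set of per-variant Wald estimates."""
    ratios = rng.normal(0.2, 0.5, size=n)
    ses = rng.uniform(0.02, 0.4, size=n)
    out = []
    for j in range(n):
        r, s = float(ratios[j]), float(ses[j])
        out.append(
            WaldEstimate(
                rsid=f"rs{j + 1}",
                ratio=r,
                se=s,
                ci_low=r - 1.96 * s,
                ci_high=r + 1.96 * s,
                pvalue=0.5,
            )
        )
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210605)
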