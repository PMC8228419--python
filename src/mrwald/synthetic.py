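"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the summary-level structure of a two-sample MR
study: a small panel of independent variants, each with a true per-allele
effect γ_j on the exposure, and an outcome affected by the exposure with
causal effect θ plus optional direct (pleiotropic) effects α_j.

Summary statistics are simulated directly — normal sampling of the
estimated betas around their true values with analytic standard errors —
rather than via individual-level genotypes.  For an additively coded
variant with allele frequency p_j estimated in a GWAS of n individuals on a
trait with phenotypic variance σ², the standard error of the per-allele
beta is approximately

    se_j = sqrt(σ² / (2 p_j (1-p_j) n))

and for a binary trait analysed on the log-odds scale with case fraction v,

    se_j = sqrt(1 / (2 p_j (1-p_j) n v (1-v))).

This is orders of magnitude faster than genotype-level simulation, matches
the two-sample summary-level scope exactly, and makes the SEs exact by
construction; weak-instrument and winner's-curse phenomena are only
partially representable this way (the exposure betas are noisy, but no
selection on their significance is re-applied).

The RNG stream is single and seeded once; sub-draws occur in a fixed,
documented order (frequencies, γ, α, β_X, β_Y, allele assignment, swap
selection) so output is bit-reproducible for a fixed seed and config.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError
from .summary_stats import VariantAssociation

_NONPALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("G", "A"), ("C", "A"),
    ("T", "G"), ("T", "C"), ("G", "T"), ("C", "T"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))

_TINY_P = 1e-300  # floor keeping simulated p-values inside (0, 1]


@dataclass
class SimulationConfig:
    """Full parameterization of the two-sample summary-statistics generator.

    Defaults encode the α-tocopherol → heel eBMD study design this package
    ships as its reference scenario: three instruments from an exposure
    GWAS of n=7781 on log serum α-tocopherol (phenotypic variance 0.0625,
    i.e. SD 0.25 on the log scale), an outcome GWAS of n=426,824 on a
    standardized continuous trait, true causal effect θ=0.28 outcome units
    per log-unit of exposure (0.07 per exposure SD), and no pleiotropy.

    ``gammas``, ``eafs``, ``rsids`` and ``allele_pairs`` may be given
    explicitly to pin per-variant values; otherwise γ_j are drawn uniform
    on ``gamma_range`` and frequencies uniform on ``eaf_range``.
    """

    n_snps: int = 3
    theta: float = 0.28
    gamma_range: tuple[float, float] = (0.025, 0.045)
    eaf_range: tuple[float, float] = (0.1, 0.9)
    n_exposure: int = 7781
    n_outcome: int = 426824
    exposure_variance: float = 0.0625
    outcome_variance: float = 1.0
    binary_outcome: bool = False
    n_cases: int | None = None
    n_controls: int | None = None
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    palindromic_fraction: float = 1.0 / 3.0
    allele_swap_fraction: float = 0.0
    seed: int = 0
    rsids: tuple[str, ...] | None = None
    eafs: tuple[float, ...] | None = None
    gammas: tuple[float, ...] | None = None
    allele_pairs: tuple[tuple[str, str], ...] | None = None
    exposure_trait: str = "exposure"
    outcome_trait: str = "outcome"

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise InputError("n_snps must be >= 1")
        lo, hi = self.eaf_range
        if not (0.05 <= lo <= hi <= 0.95):
            raise InputError(
                f"eaf_range must lie within [0.05, 0.95], got {self.eaf_range}"
            )
        if self.gamma_range[0] > self.gamma_range[1]:
            raise InputError(f"invalid gamma_range {self.gamma_range}")
        for name in ("palindromic_fraction", "allele_swap_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise InputError(f"{name} must be in [0,1]")
        if not (self.exposure_variance > 0 and self.outcome_variance > 0):
            raise InputError("phenotypic variances must be > 0")
        if not (self.n_exposure > 0 and self.n_outcome > 0):
            raise InputError("sample sizes must be positive")
        if self.pleiotropy_sd < 0:
            raise InputError("pleiotropy_sd must be >= 0")
        if self.binary_outcome:
            if not (self.n_cases and self.n_controls):
                raise InputError("binary outcome requires n_cases and n_controls")
            if self.n_cases + self.n_controls != self.n_outcome:
                raise InputError("n_outcome must equal n_cases + n_controls")
        for name in ("rsids", "eafs", "gammas", "allele_pairs"):
            value = getattr(self, name)
            if value is not None and len(value) != self.n_snps:
                raise InputError(f"{name} must have length n_snps={self.n_snps}")
        if self.eafs is not None and not all(0 < p < 1 for p in self.eafs):
            raise InputError("explicit eafs must lie strictly within (0,1)")


@dataclass
class SimulationTruth:
    """Ground truth underlying one simulated dataset."""

    theta: float
    gammas: tuple[float, ...]
    alphas: tuple[float, ...]
    eafs: tuple[float, ...]
    swapped: tuple[bool, ...]
    seed: int

    def save(self, path: str | Path) -> None:
        """Write the truth record as a small key=value text file."""
        with open(path, "w") as fh:
            fh.write(f"theta={self.theta!r}\n")
            fh.write(f"seed={self.seed}\n")
            fh.write("gammas=" + ",".join(repr(g) for g in self.gammas) + "\n")
            fh.write("alphas=" + ",".join(repr(a) for a in self.alphas) + "\n")
            fh.write("eafs=" + ",".join(repr(p) for p in self.eafs) + "\n")
            fh.write("swapped=" + ",".join(str(int(s)) for s in self.swapped) + "\n")


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, _TINY_P)


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[list[VariantAssociation], list[VariantAssociation], SimulationTruth]:
    """Simulate exposure-side and outcome-side summary statistics.

    Returns ``(exposure, outcome, truth)``.  The outcome records for a
    ``allele_swap_fraction`` of variants are emitted with swapped allele
    labels and negated beta (frequency complemented), exercising
    harmonization; the truth record's ``swapped`` mask says which.
    """
    rng = np.random.default_rng(config.seed)
    j = config.n_snps

    # Draw order is fixed: frequencies, gammas, alphas, beta_X, beta_Y,
    # allele assignment, swap selection.
    if config.eafs is not None:
        eafs = np.asarray(config.eafs, dtype=float)
        rng.uniform(size=j)  # keep stream alignment comparable across configs
    else:
        eafs = rng.uniform(config.eaf_range[0], config.eaf_range[1], size=j)
    if config.gammas is not None:
        gammas = np.asarray(config.gammas, dtype=float)
        rng.uniform(size=j)
    else:
        gammas = rng.uniform(config.gamma_range[0], config.gamma_range[1], size=j)
    if config.pleiotropy_sd > 0 or config.pleiotropy_mean != 0:
        alphas = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=j)
    else:
        alphas = np.zeros(j)

    het = 2.0 * eafs * (1.0 - eafs)
    se_x = np.sqrt(config.exposure_variance / (het * config.n_exposure))
    beta_x = rng.normal(gammas, se_x)

    if config.binary_outcome:
        v = config.n_cases / config.n_outcome
        se_y = np.sqrt(1.0 / (het * config.n_outcome * v * (1.0 - v)))
    else:
        se_y = np.sqrt(config.outcome_variance / (het * config.n_outcome))
    beta_y = rng.normal(config.theta * gammas + alphas, se_y)

    if config.allele_pairs is not None:
        pairs = [tuple(p) for p in config.allele_pairs]
    else:
        is_pal = rng.uniform(size=j) < config.palindromic_fraction
        pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=j)
        non_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=j)
        pairs = [
            _PALINDROMIC_PAIRS[pal_idx[k]] if is_pal[k] else _NONPALINDROMIC_PAIRS[non_idx[k]]
            for k in range(j)
        ]
    swapped = rng.uniform(size=j) < config.allele_swap_fraction

    rsids = (
        list(config.rsids)
        if config.rsids is not None
        else [f"snp{k + 1:04d}" for k in range(j)]
    )

    p_x = _two_sided_p(beta_x, se_x)
    p_y = _two_sided_p(beta_y, se_y)
    outcome_unit = "log-odds" if config.binary_outcome else "outcome units"

    exposure = [
        VariantAssociation(
            rsid=rsids[k],
            effect_allele=pairs[k][0],
            other_allele=pairs[k][1],
            beta=float(beta_x[k]),
            se=float(se_x[k]),
            pvalue=float(p_x[k]),
            eaf=float(eafs[k]),
            n=config.n_exposure,
            trait=config.exposure_trait,
            unit="exposure units",
        )
        for k in range(j)
    ]
    outcome = []
    for k in range(j):
        ea, oa = pairs[k]
        beta, eaf = float(beta_y[k]), float(eafs[k])
        if swapped[k]:
            ea, oa = oa, ea
            beta, eaf = -beta, 1.0 - eaf
        outcome.append(
            VariantAssociation(
                rsid=rsids[k],
                effect_allele=ea,
                other_allele=oa,
                beta=beta,
                se=float(se_y[k]),
                pvalue=float(p_y[k]),
                eaf=eaf,
                n=config.n_outcome,
                trait=config.outcome_trait,
                unit=outcome_unit,
            )
        )

    truth = SimulationTruth(
        theta=config.theta,
        gammas=tuple(float(g) for g in gammas),
        alphas=tuple(float(a) for a in alphas),
        eafs=tuple(float(p) for p in eafs),
        swapped=tuple(bool(s) for s in swapped),
        seed=config.seed,
    )
    return exposure, outcome, truth


def expected_two_sample(
    config: SimulationConfig,
) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Noise-free expectation of the generator: betas at their true means.

    Exposure betas are set to γ_j exactly and outcome betas to
    θ·γ_j + α's mean, with the same analytic standard errors the stochastic
    generator uses.  Useful as a deterministic consistency input: the
    pipeline run on these tables returns exactly θ (per exposure unit).
    Requires explicit ``eafs`` and ``gammas`` in the config (there is no
    draw to take an expectation over otherwise).
    """
    if config.eafs is None or config.gammas is None:
        raise InputError("expected_two_sample needs explicit eafs and gammas")
    noiseless = dataclasses.replace(config, allele_swap_fraction=0.0)
    rng_free = simulate_two_sample(noiseless)
    exposure, outcome, _ = rng_free
    eafs = np.asarray(config.eafs, dtype=float)
    gammas = np.asarray(config.gammas, dtype=float)
    mean_y = config.theta * gammas + config.pleiotropy_mean
    exp_out: list[VariantAssociation] = []
    out_out: list[VariantAssociation] = []
    for k, (e_rec, o_rec) in enumerate(zip(exposure, outcome)):
        se_x, se_y = e_rec.se, o_rec.se
        exp_out.append(
            dataclasses.replace(
                e_rec,
                beta=float(gammas[k]),
                pvalue=float(_two_sided_p(gammas[k : k + 1], np.array([se_x]))[0]),
            )
        )
        out_out.append(
            dataclasses.replace(
                o_rec,
                beta=float(mean_y[k]),
                pvalue=float(_two_sided_p(mean_y[k : k + 1], np.array([se_y]))[0]),
            )
        )
    return exp_out, out_out


# --------------------------------------------------------------------------
# Reference scenario: circulating α-tocopherol → heel eBMD / fracture.
# --------------------------------------------------------------------------

#: The three α-tocopherol instruments: rsid, locus, effect/other allele,
#: effect-allele frequency (European ancestry), and the exposure-GWAS
#: association p-value.  rs964184 is C/G, i.e. palindromic.
TOCOPHEROL_INSTRUMENTS = (
    ("rs964184", "11q23.3", "C", "G", 0.14, 7.8e-12),
    ("rs2108622", "19pter-p13.11", "T", "C", 0.29, 1.4e-10),
    ("rs11057830", "12q24.31", "A", "G", 0.15, 8.2e-9),
)

#: SD of log serum α-tocopherol (reference cohort), the per-SD multiplier.
TOCOPHEROL_LOG_SD = 0.25

EBMD_N = 426824
FRACTURE_CASES = 53184
FRACTURE_CONTROLS = 373611
#: Population mean heel eBMD in g/cm², by sex.
EBMD_MEAN_WOMEN = 0.51
EBMD_MEAN_MEN = 0.56


def _tocopherol_gammas() -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Per-variant exposure effects implied by the published p-values.

    Each instrument's |z| is recovered from its exposure-GWAS p-value and
    multiplied by the analytic SE at its allele frequency and n=7781,
    giving γ_j on the log-exposure scale.  The implied total variance
    explained (~1.6%) matches the reported ~1.7%.
    """
    eafs = tuple(row[4] for row in TOCOPHEROL_INSTRUMENTS)
    gammas = []
    for _, _, _, _, eaf, pval in TOCOPHEROL_INSTRUMENTS:
        z = float(stats.norm.isf(pval / 2.0))
        se = math.sqrt(TOCOPHEROL_LOG_SD**2 / (2 * eaf * (1 - eaf) * 7781))
        gammas.append(z * se)
    return eafs, tuple(gammas)


def _tocopherol_base_config(seed: int) -> dict:
    eafs, gammas = _tocopherol_gammas()
    return dict(
        n_snps=3,
        n_exposure=7781,
        exposure_variance=TOCOPHEROL_LOG_SD**2,
        rsids=tuple(row[0] for row in TOCOPHEROL_INSTRUMENTS),
        allele_pairs=tuple((row[2], row[3]) for row in TOCOPHEROL_INSTRUMENTS),
        eafs=eafs,
        gammas=gammas,
        exposure_trait="log serum alpha-tocopherol",
        seed=seed,
    )


def tocopherol_ebmd_config(seed: int = 0, theta: float = 0.07 / TOCOPHEROL_LOG_SD) -> SimulationConfig:
    """Study conditions for the α-tocopherol → heel eBMD arm.

    Outcome: standardized eBMD in 426,824 individuals.  The default true
    causal effect is 0.28 outcome units per log-unit of exposure, i.e.
    0.07 per one-SD increment of log α-tocopherol — the effect size this
    scenario emulates.
    """
    return SimulationConfig(
        theta=theta,
        n_outcome=EBMD_N,
        outcome_variance=1.0,
        outcome_trait="eBMD",
        **_tocopherol_base_config(seed),
    )


def tocopherol_fracture_config(
    seed: int = 0, theta: float = math.log(0.97) / TOCOPHEROL_LOG_SD
) -> SimulationConfig:
    """Study conditions for the α-tocopherol → fracture arm.

    Outcome: any fracture, 53,184 cases / 373,611 non-cases, analysed on
    the log-odds scale.  The default true effect corresponds to an odds
    ratio of 0.97 per one-SD increment of log α-tocopherol.
    """
    return SimulationConfig(
        theta=theta,
        n_outcome=FRACTURE_CASES + FRACTURE_CONTROLS,
        binary_outcome=True,
        n_cases=FRACTURE_CASES,
        n_controls=FRACTURE_CONTROLS,
        outcome_trait="fracture",
        **_tocopherol_base_config(seed),
    )
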