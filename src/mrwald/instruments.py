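"""Instrument selection, strength diagnostics and a confounder screen.

Selection keeps candidates below a genome-wide significance threshold
(strictly below 5e-8 by default) and optionally enforces one variant per
locus label as the operational stand-in for "uncorrelated" when no LD
reference is available.  Strength is summarized by the variance explained
r² = 2p(1-p)β²/Var(X) of an additively coded variant and the corresponding
F-statistic.  The confounder screen checks instruments against a local
variant-trait association table (e.g. a PhenoScanner export) for
associations with known outcome risk factors.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import InputError
from .summary_stats import VariantAssociation

logger = logging.getLogger(__name__)

#: Risk factors for low bone mineral density and fracture screened by default.
DEFAULT_CONFOUNDER_TRAITS = (
    "body mass index",
    "fat-free soft tissue body mass",
    "height",
    "type 2 diabetes",
    "smoking",
    "alcohol consumption",
    "estrogens",
    "testosterone",
    "cortisol",
)

#: Conventional genome-wide significance threshold.
GENOME_WIDE_SIGNIFICANCE = 5e-8


@dataclass
class InstrumentSet:
    """A selected set of instruments with the selection metadata."""

    members: list[str]
    pvalue_threshold: float
    loci: dict[str, str] = field(default_factory=dict)
    r2_total: float | None = None


@dataclass
class TraitAssociationRecord:
    """One variant-trait association from a lookup table."""

    rsid: str
    trait: str
    pvalue: float

    def __post_init__(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise InputError(
                f"{self.rsid}/{self.trait}: pvalue must be in (0,1], got {self.pvalue}"
            )


def select_instruments(
    candidates: Sequence[VariantAssociation],
    pvalue_threshold: float = GENOME_WIDE_SIGNIFICANCE,
    one_per_locus: bool = False,
    loci: Mapping[str, str] | None = None,
) -> InstrumentSet:
    """Select instruments significant strictly below ``pvalue_threshold``.

    With ``one_per_locus`` and locus labels supplied (rsid -> cytoband or
    gene-region string), only the smallest-p candidate per locus is kept,
    ties broken by smaller SE then lexicographic rsid.  An empty selection
    is a valid, logged outcome, not an error.
    """
    loci = dict(loci or {})
    significant = [c for c in candidates if c.pvalue < pvalue_threshold]

    if one_per_locus and loci:
        best: dict[str, VariantAssociation] = {}
        for cand in significant:
            locus = loci.get(cand.rsid, cand.rsid)  # unlabeled = own locus
            incumbent = best.get(locus)
            if incumbent is None or (cand.pvalue, cand.se, cand.rsid) < (
                incumbent.pvalue,
                incumbent.se,
                incumbent.rsid,
            ):
                best[locus] = cand
        significant = sorted(best.values(), key=lambda c: c.rsid)

    if not significant:
        logger.warning(
            "no candidate passed the p < %g significance filter", pvalue_threshold
        )
    return InstrumentSet(
        members=[c.rsid for c in significant],
        pvalue_threshold=pvalue_threshold,
        loci={c.rsid: loci.get(c.rsid, "") for c in significant},
    )


def variance_explained(
    assoc: VariantAssociation, trait_variance: float
) -> float | None:
    """Fraction of trait variance explained by one additively coded variant.

    r² = 2·p·(1-p)·β² / Var(trait).  Returns ``None`` (with a logged flag)
    when the effect-allele frequency is missing; the diagnostic is then
    unavailable but not fatal.
    """
    if not (trait_variance > 0):
        raise InputError(f"trait_variance must be > 0, got {trait_variance}")
    if assoc.eaf is None:
        logger.warning("%s: eaf missing, variance explained unavailable", assoc.rsid)
        return None
    return 2.0 * assoc.eaf * (1.0 - assoc.eaf) * assoc.beta**2 / trait_variance


def total_variance_explained(
    associations: Sequence[VariantAssociation], trait_variance: float
) -> float:
    """Sum of per-variant r² over an instrument set (missing-eaf variants skipped)."""
    total = 0.0
    for assoc in associations:
        r2 = variance_explained(assoc, trait_variance)
        if r2 is not None:
            total += r2
    return total


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Instrument-strength F-statistic from total variance explained.

    F = r²·(n-k-1) / ((1-r²)·k) for k instruments in a sample of size n;
    values above ~10 are conventionally taken to indicate low risk of
    weak-instrument bias.
    """
    if not (0 < r2_total < 1):
        raise InputError(f"r2_total must be in (0,1), got {r2_total}")
    if not (n > k + 1 >= 2):
        raise InputError(f"need n > k+1 >= 2, got n={n}, k={k}")
    return r2_total * (n - k - 1) / ((1.0 - r2_total) * k)


def confounder_screen(
    instruments: Sequence[str],
    table: Sequence[TraitAssociationRecord],
    confounder_traits: Sequence[str] = DEFAULT_CONFOUNDER_TRAITS,
    pvalue_threshold: float = 0.01,
) -> dict[str, list[str]]:
    """Flag instruments associated with listed confounder traits.

    For each instrument, returns the confounder traits having a table record
    with p strictly below ``pvalue_threshold``.  Trait matching is
    case-insensitive exact match on the supplied names.  An empty table
    yields an all-clear with a logged caveat.
    """
    if not table:
        logger.warning(
            "confounder screen ran against an empty table: all-clear is "
            "uninformative"
        )
    wanted = {t.lower(): t for t in confounder_traits}
    flags: dict[str, list[str]] = {rsid: [] for rsid in instruments}
    for rec in table:
        if rec.rsid not in flags:
            continue
        trait = wanted.get(rec.trait.lower())
        if trait is not None and rec.pvalue < pvalue_threshold:
            flags[rec.rsid].append(trait)
    for rsid, traits in flags.items():
        if traits:
            logger.warning("%s flagged for: %s", rsid, ", ".join(traits))
    return flags


def read_trait_table(path: str | Path) -> list[TraitAssociationRecord]:
    """Read a delimited variant-trait table with columns rsid, trait, pvalue."""
    path = Path(path)
    with open(path, newline="") as fh:
        header = fh.readline()
        if not header.strip():
            raise InputError(f"{path}: empty file")
        delim = "\t" if "\t" in header else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        missing = [c for c in ("rsid", "trait", "pvalue") if c not in (reader.fieldnames or [])]
        if missing:
            raise InputError(f"{path}: missing column(s) {', '.join(missing)}")
        return [
            TraitAssociationRecord(
                rsid=row["rsid"].strip(),
                trait=row["trait"].strip(),
                pvalue=float(row["pvalue"]),
            )
            for row in reader
        ]
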