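"""GWAS summary-statistics data model, I/O, and allele harmonization.

Two-sample Mendelian randomization starts from two delimited tables of
per-variant association statistics — one for the exposure, one for the
outcome — each row giving the effect allele, the other allele, the
per-effect-allele beta, its standard error, the p-value and, when available,
the effect-allele frequency (EAF) and sample size.  Before any ratio can be
taken the two tables must be expressed on a *common* effect-allele
orientation; this module owns that harmonization step.

Harmonization rules, per variant present in both tables:

* identical allele orientation: outcome beta copied unchanged;
* swapped alleles (outcome effect allele equals exposure other allele and
  vice versa): outcome beta negated, EAF complemented, ``flipped`` set;
* strand-complement codings (e.g. A/G vs T/C) are first mapped onto the
  exposure strand and then treated as above;
* palindromic variants (A/T or C/G — complementing does not disambiguate
  strand) are aligned by comparing effect-allele frequencies, and only when
  both frequencies are present and informative, i.e. the minor-allele
  frequency on both sides is at most ``eaf_ambiguity_threshold``; otherwise
  the variant is dropped with a logged reason (never guess strand);
* incompatible allele pairs are dropped with a logged reason.

Every drop and every sign flip is logged at WARNING so a silent-drop audit
is impossible.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: Canonical column names for summary-statistics tables.
CANONICAL_COLUMNS = (
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)
_MANDATORY_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pvalue")


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is A/T or C/G (strand-ambiguous)."""
    return frozenset((a1.upper(), a2.upper())) in _PALINDROMIC_PAIRS


@dataclass
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the additive per-effect-allele effect on the trait (trait
    units for continuous traits, log-odds for binary traits); ``se`` its
    standard error.  ``eaf`` and ``n`` may be missing (``None``).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None
    trait: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if self.effect_allele not in _VALID_ALLELES:
            raise InputError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not a "
                "single nucleotide A/C/G/T"
            )
        if self.other_allele not in _VALID_ALLELES:
            raise InputError(
                f"{self.rsid}: other allele {self.other_allele!r} is not a "
                "single nucleotide A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise InputError(f"{self.rsid}: effect and other allele are identical")
        if not (self.se > 0):
            raise InputError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise InputError(f"{self.rsid}: pvalue must be in (0,1], got {self.pvalue}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise InputError(f"{self.rsid}: eaf must be in [0,1], got {self.eaf}")
        if self.n is not None and not self.n > 0:
            raise InputError(f"{self.rsid}: n must be positive, got {self.n}")

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


@dataclass
class HarmonizedInstrument:
    """Exposure and outcome betas for one variant on a common orientation.

    ``flipped`` records whether the outcome record's sign was inverted
    during alignment; ``palindromic`` whether the allele pair is A/T or C/G.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    palindromic: bool = False
    flipped: bool = False

    def __post_init__(self) -> None:
        if not (self.se_exposure > 0 and self.se_outcome > 0):
            raise InputError(f"{self.rsid}: standard errors must be > 0")
        if self.palindromic != is_palindromic(self.effect_allele, self.other_allele):
            raise InputError(
                f"{self.rsid}: palindromic flag inconsistent with alleles "
                f"{self.effect_allele}/{self.other_allele}"
            )


@dataclass
class RowRejection:
    """Report of one input row that failed validation."""

    row_number: int
    reason: str
    raw: dict = field(default_factory=dict)


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_optional_float(value: str | None) -> float | None:
    if value is None:
        return None
    value = value.strip()
    if value == "" or value.upper() in {"NA", "NAN", "."}:
        return None
    return float(value)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait: str = "",
    unit: str = "",
) -> tuple[list[VariantAssociation], list[RowRejection]]:
    """Read a delimited summary-statistics table.

    The delimiter (tab or comma) is auto-detected from the header line.
    ``column_map`` maps canonical names (``rsid``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``, ``n``) to the
    file's column names; canonical names present in the file need no entry.

    Returns the list of valid records plus a per-row rejection report for
    rows violating type invariants (logged at WARNING, never silently
    dropped).

    Raises
    ------
    ConfigurationError
        if a mandatory column is absent after mapping.
    InputError
        if no row passes validation.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    with open(path, newline="") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise InputError(f"{path}: empty file")
        delim = _detect_delimiter(header_line)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        fieldnames = reader.fieldnames or []
        resolved: dict[str, str] = {}
        for canonical in CANONICAL_COLUMNS:
            source = column_map.get(canonical, canonical)
            if source in fieldnames:
                resolved[canonical] = source
        missing = [c for c in _MANDATORY_COLUMNS if c not in resolved]
        if missing:
            raise ConfigurationError(
                f"{path}: missing mandatory column(s) {', '.join(missing)} "
                "(after applying the column map)"
            )

        records: list[VariantAssociation] = []
        rejections: list[RowRejection] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                n_raw = _parse_optional_float(row.get(resolved.get("n", ""), None))
                records.append(
                    VariantAssociation(
                        rsid=row[resolved["rsid"]].strip(),
                        effect_allele=row[resolved["effect_allele"]].strip(),
                        other_allele=row[resolved["other_allele"]].strip(),
                        beta=float(row[resolved["beta"]]),
                        se=float(row[resolved["se"]]),
                        pvalue=float(row[resolved["pvalue"]]),
                        eaf=_parse_optional_float(
                            row.get(resolved.get("eaf", ""), None)
                        ),
                        n=int(n_raw) if n_raw is not None else None,
                        trait=trait,
                        unit=unit,
                    )
                )
            except (InputError, ValueError, KeyError) as exc:
                rejection = RowRejection(row_number=i, reason=str(exc), raw=dict(row))
                rejections.append(rejection)
                logger.warning("%s line %d rejected: %s", path, i, exc)

    if not records:
        raise InputError(f"{path}: zero valid rows")
    return records, rejections


def write_summary_stats(
    records: Iterable[VariantAssociation], path: str | Path
) -> None:
    """Write records as a tab-separated table with canonical headers.

    Floats are written with ``repr`` so a write/read round-trip preserves
    every field to full precision.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.rsid,
                    rec.effect_allele,
                    rec.other_allele,
                    "" if rec.eaf is None else repr(rec.eaf),
                    repr(rec.beta),
                    repr(rec.se),
                    repr(rec.pvalue),
                    "" if rec.n is None else rec.n,
                ]
            )


def _index_by_rsid(
    records: Sequence[VariantAssociation], side: str
) -> dict[str, VariantAssociation]:
    index: dict[str, VariantAssociation] = {}
    for rec in records:
        if rec.rsid in index:
            raise InputError(f"duplicate rsid {rec.rsid} in {side} table")
        index[rec.rsid] = rec
    return index


def _maf(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    eaf_ambiguity_threshold: float = 0.42,
) -> list[HarmonizedInstrument]:
    """Align outcome records onto the exposure's effect-allele orientation.

    See the module docstring for the rule set.  ``eaf_ambiguity_threshold``
    is the largest minor-allele frequency at which frequency comparison is
    trusted to orient a palindromic variant (default 0.42; near 0.5 the
    frequencies of the two strand readings are indistinguishable).

    Raises :class:`InputError` on duplicated rsids within either table.
    Variants absent from either side, ambiguous palindromes and
    incompatible allele pairs are dropped with a logged reason.  Disjoint
    tables yield an empty list plus a warning, not an error.
    """
    if not (0 <= eaf_ambiguity_threshold <= 0.5):
        raise InputError(
            f"eaf_ambiguity_threshold must be in [0, 0.5], got {eaf_ambiguity_threshold}"
        )
    exp_index = _index_by_rsid(exposure, "exposure")
    out_index = _index_by_rsid(outcome, "outcome")

    harmonized: list[HarmonizedInstrument] = []
    for rsid, exp in exp_index.items():
        if rsid not in out_index:
            logger.warning("%s dropped: absent from outcome table", rsid)
            continue
        out = out_index[rsid]
        result = _harmonize_pair(exp, out, eaf_ambiguity_threshold)
        if result is not None:
            harmonized.append(result)
    for rsid in out_index:
        if rsid not in exp_index:
            logger.warning("%s dropped: absent from exposure table", rsid)

    if not harmonized and exp_index and out_index:
        logger.warning("harmonization produced zero instruments")
    return harmonized


def _harmonize_pair(
    exp: VariantAssociation,
    out: VariantAssociation,
    eaf_ambiguity_threshold: float,
) -> HarmonizedInstrument | None:
    rsid = exp.rsid
    ea, oa = exp.effect_allele, exp.other_allele
    out_ea, out_oa = out.effect_allele, out.other_allele
    beta_out, eaf_out = out.beta, out.eaf

    if exp.palindromic:
        if frozenset((out_ea, out_oa)) != frozenset((ea, oa)):
            logger.warning(
                "%s dropped: incompatible alleles %s/%s vs %s/%s",
                rsid, ea, oa, out_ea, out_oa,
            )
            return None
        return _harmonize_palindromic(exp, out, eaf_ambiguity_threshold)

    # Map a strand-complement coding onto the exposure strand first.
    if {out_ea, out_oa} != {ea, oa} and {
        _COMPLEMENT[out_ea],
        _COMPLEMENT[out_oa],
    } == {ea, oa}:
        out_ea, out_oa = _COMPLEMENT[out_ea], _COMPLEMENT[out_oa]

    if (out_ea, out_oa) == (ea, oa):
        flipped = False
    elif (out_ea, out_oa) == (oa, ea):
        beta_out = -beta_out
        eaf_out = None if eaf_out is None else 1.0 - eaf_out
        flipped = True
        logger.warning("%s: outcome alleles swapped, beta sign inverted", rsid)
    else:
        logger.warning(
            "%s dropped: incompatible alleles %s/%s vs %s/%s",
            rsid, ea, oa, out.effect_allele, out.other_allele,
        )
        return None

    return HarmonizedInstrument(
        rsid=rsid,
        effect_allele=ea,
        other_allele=oa,
        beta_exposure=exp.beta,
        se_exposure=exp.se,
        beta_outcome=beta_out,
        se_outcome=out.se,
        eaf_exposure=exp.eaf,
        eaf_outcome=eaf_out,
        palindromic=False,
        flipped=flipped,
    )


def _harmonize_palindromic(
    exp: VariantAssociation,
    out: VariantAssociation,
    eaf_ambiguity_threshold: float,
) -> HarmonizedInstrument | None:
    """Orient a palindromic variant by effect-allele frequency.

    The nominal allele labels carry no strand information for an A/T or C/G
    pair, so the outcome record is first expressed with the exposure's
    effect-allele label (negating beta if the labels are crossed), then the
    frequencies decide: same side of 0.5 means the labels refer to the same
    allele; opposite sides mean the outcome is on the other strand reading
    and the sign is flipped.
    """
    rsid = exp.rsid
    if exp.eaf is None or out.eaf is None:
        logger.warning("%s dropped: palindromic with missing eaf", rsid)
        return None

    beta_out, eaf_out = out.beta, out.eaf
    label_crossed = out.effect_allele == exp.other_allele
    if label_crossed:
        beta_out = -beta_out
        eaf_out = 1.0 - eaf_out

    if (
        _maf(exp.eaf) > eaf_ambiguity_threshold
        or _maf(eaf_out) > eaf_ambiguity_threshold
    ):
        logger.warning(
            "%s dropped: palindromic with ambiguous frequencies "
            "(eaf %.3f vs %.3f, threshold %.2f)",
            rsid, exp.eaf, eaf_out, eaf_ambiguity_threshold,
        )
        return None

    same_side = (exp.eaf - 0.5) * (eaf_out - 0.5) > 0
    flipped = bool(label_crossed)
    if not same_side:
        beta_out = -beta_out
        eaf_out = 1.0 - eaf_out
        flipped = not flipped
    if flipped:
        logger.warning("%s: palindromic outcome re-oriented by eaf, sign inverted", rsid)

    return HarmonizedInstrument(
        rsid=rsid,
        effect_allele=exp.effect_allele,
        other_allele=exp.other_allele,
        beta_exposure=exp.beta,
        se_exposure=exp.se,
        beta_outcome=beta_out,
        se_outcome=out.se,
        eaf_exposure=exp.eaf,
        eaf_outcome=eaf_out,
        palindromic=True,
        flipped=flipped,
    )
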