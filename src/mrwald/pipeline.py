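"""End-to-end two-sample MR analysis: read, select, harmonize, estimate,
rescale, convert, screen, and emit forest-ready tables plus a run report.

The pipeline reproduces the canonical summary-level workflow: exposure and
outcome summary-statistics tables in, per-variant Wald ratios and a pooled
fixed-effects IVW estimate out, expressed per one-SD increment of the
exposure, with the pooled estimate exponentiated to an odds ratio for
binary (log-odds scale) outcomes.  All results are computed in full
precision; rounding (half away from zero, default 2 decimals) happens only
in the plain-text report.  Machine-readable outputs are byte-identical
across re-runs with identical config and inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import estimators, instruments, summary_stats
from .errors import InputError, MRWaldError, StateError
from .estimators import MRResult, OddsRatioResult, WaldEstimate
from .instruments import DEFAULT_CONFOUNDER_TRAITS
from .summary_stats import VariantAssociation

logger = logging.getLogger(__name__)


@dataclass
class OutcomeSpec:
    """One outcome table: path, label, and the scale its betas live on."""

    name: str
    path: str | Path
    scale: estimators.Scale = "linear"
    column_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log_odds"):
            raise InputError(f"{self.name}: scale must be linear or log_odds")


@dataclass
class AnalysisConfig:
    """Full parameterization of one pipeline run."""

    exposure_path: str | Path
    outcomes: list[OutcomeSpec]
    sd: float
    pvalue_threshold: float = instruments.GENOME_WIDE_SIGNIFICANCE
    eaf_ambiguity_threshold: float = 0.42
    se_order: estimators.SEOrder = "first"
    one_per_locus: bool = False
    loci: dict[str, str] = field(default_factory=dict)
    exposure_column_map: dict[str, str] = field(default_factory=dict)
    confounder_table_path: str | Path | None = None
    confounder_traits: tuple[str, ...] = DEFAULT_CONFOUNDER_TRAITS
    output_dir: str | Path | None = None
    report_rounding: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise InputError(f"sd must be > 0, got {self.sd}")
        paths = [str(self.exposure_path)] + [str(o.path) for o in self.outcomes]
        if len(set(paths)) != len(paths):
            raise InputError("exposure and outcome paths must be distinct")
        if not self.outcomes:
            raise InputError("at least one outcome is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config file; relative paths resolve against its location."""
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        outcomes = [
            OutcomeSpec(
                name=o["name"],
                path=_resolve(o["path"]),
                scale=o.get("scale", "linear"),
                column_map=o.get("column_map", {}),
            )
            for o in raw.get("outcomes", [])
        ]
        kwargs = dict(
            exposure_path=_resolve(raw["exposure_path"]),
            outcomes=outcomes,
            sd=float(raw["sd"]),
        )
        for key in (
            "pvalue_threshold",
            "eaf_ambiguity_threshold",
            "se_order",
            "one_per_locus",
            "report_rounding",
            "seed",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "loci" in raw:
            kwargs["loci"] = dict(raw["loci"])
        if "exposure_column_map" in raw:
            kwargs["exposure_column_map"] = dict(raw["exposure_column_map"])
        if "confounder_table_path" in raw and raw["confounder_table_path"]:
            kwargs["confounder_table_path"] = _resolve(raw["confounder_table_path"])
        if "confounder_traits" in raw:
            kwargs["confounder_traits"] = tuple(raw["confounder_traits"])
        if "output_dir" in raw and raw["output_dir"]:
            kwargs["output_dir"] = _resolve(raw["output_dir"])
        return cls(**kwargs)


@dataclass
class OutcomeAnalysis:
    """Results for one outcome: per-variant and pooled, both per-SD."""

    name: str
    scale: estimators.Scale
    per_snp: list[WaldEstimate]
    pooled: MRResult
    odds_ratio: OddsRatioResult | None
    forest: pd.DataFrame


@dataclass
class AnalysisResult:
    """Everything one pipeline run produced."""

    outcomes: dict[str, OutcomeAnalysis]
    instrument_set: instruments.InstrumentSet
    screen_flags: dict[str, list[str]] | None
    config: AnalysisConfig


class _Stage:
    """Context manager adding stage context to any pipeline failure."""

    def __init__(self, stage: str, detail: str = ""):
        self.stage = stage
        self.detail = detail

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, MRWaldError):
            where = f"{self.stage}" + (f" [{self.detail}]" if self.detail else "")
            exc.args = (f"{where}: {exc}",)
        return False


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (1.005 -> 1.01, -1.005 -> -1.01)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)) * (
        -1.0 if x < 0 else 1.0
    )


def forest_table(per_snp: Sequence[WaldEstimate], pooled: MRResult) -> pd.DataFrame:
    """Forest-plot-ready table: one row per variant plus a final IVW row.

    Columns: rsid, estimate, ci_low, ci_high, weight_pct.  Per-variant rows
    are ordered by rsid; weight percents are inverse-variance shares and
    sum to 100.
    """
    if pooled.n_snps != len(per_snp):
        raise StateError(
            f"pooled result covers {pooled.n_snps} variants but "
            f"{len(per_snp)} per-variant estimates supplied"
        )
    ordered = sorted(per_snp, key=lambda e: e.rsid)
    weights = [1.0 / e.se**2 for e in ordered]
    total_w = sum(weights)
    rows = [
        {
            "rsid": e.rsid,
            "estimate": e.ratio,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "weight_pct": 100.0 * w / total_w,
        }
        for e, w in zip(ordered, weights)
    ]
    rows.append(
        {
            "rsid": "IVW",
            "estimate": pooled.estimate,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows, columns=["rsid", "estimate", "ci_low", "ci_high", "weight_pct"])


def _analyse_outcome(
    spec: OutcomeSpec,
    selected_exposure: list[VariantAssociation],
    config: AnalysisConfig,
) -> OutcomeAnalysis:
    with _Stage("read", spec.name):
        outcome_records, _ = summary_stats.read_summary_stats(
            spec.path, column_map=spec.column_map, trait=spec.name
        )
    with _Stage("harmonize", spec.name):
        harmonized = summary_stats.harmonize(
            selected_exposure, outcome_records, config.eaf_ambiguity_threshold
        )
        if not harmonized:
            raise InputError(f"no instrument survived harmonization for {spec.name}")
    per_snp: list[WaldEstimate] = []
    for inst in harmonized:
        with _Stage("wald_ratio", inst.rsid):
            per_snp.append(estimators.wald_ratio(inst, se_order=config.se_order))
    with _Stage("ivw_pool", spec.name):
        pooled = estimators.ivw_pool(per_snp, model="fixed", scale=spec.scale)
    with _Stage("rescale_per_sd", spec.name):
        pooled = estimators.rescale_per_sd(pooled, config.sd)
        per_snp = [estimators.rescale_per_sd(e, config.sd) for e in per_snp]
    odds = None
    if spec.scale == "log_odds":
        with _Stage("to_odds_ratio", spec.name):
            odds = estimators.to_odds_ratio(pooled)
    return OutcomeAnalysis(
        name=spec.name,
        scale=spec.scale,
        per_snp=per_snp,
        pooled=pooled,
        odds_ratio=odds,
        forest=forest_table(per_snp, pooled),
    )


def run_mr_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Run the full analysis for every configured outcome.

    All outcomes are computed before any file is written, so a failure in
    any stage leaves no partial outputs on disk.  When ``output_dir`` is
    set, emits per-outcome forest tables (``forest_<name>.tsv``), a
    plain-text ``report.txt`` with rounded headline lines, a full-precision
    ``results.json``, and ``screen.tsv`` when a confounder table was given.
    """
    with _Stage("read", "exposure"):
        exposure_records, _ = summary_stats.read_summary_stats(
            config.exposure_path,
            column_map=config.exposure_column_map,
            trait="exposure",
        )
    with _Stage("select_instruments"):
        selection = instruments.select_instruments(
            exposure_records,
            pvalue_threshold=config.pvalue_threshold,
            one_per_locus=config.one_per_locus,
            loci=config.loci,
        )
        selected = [r for r in exposure_records if r.rsid in set(selection.members)]
        if not selected:
            raise InputError(
                f"no exposure variant passed p < {config.pvalue_threshold:g}"
            )

    analyses = {
        spec.name: _analyse_outcome(spec, selected, config)
        for spec in config.outcomes
    }

    screen_flags = None
    if config.confounder_table_path is not None:
        with _Stage("confounder_screen"):
            table = instruments.read_trait_table(config.confounder_table_path)
            screen_flags = instruments.confounder_screen(
                selection.members, table, config.confounder_traits
            )

    result = AnalysisResult(
        outcomes=analyses,
        instrument_set=selection,
        screen_flags=screen_flags,
        config=config,
    )
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir))
    return result


def format_report(result: AnalysisResult) -> str:
    """Human-readable run report with half-away-from-zero rounding."""
    nd = result.config.report_rounding

    def r(x: float) -> str:
        return f"{round_half_away(x, nd):.{nd}f}"

    lines = [
        "Two-sample summary-level MR analysis",
        f"instruments ({len(result.instrument_set.members)}): "
        + ", ".join(result.instrument_set.members),
        f"per-SD rescaling: exposure SD = {result.config.sd}",
        "",
    ]
    for name, a in result.outcomes.items():
        pooled = a.pooled
        if a.odds_ratio is not None:
            o = a.odds_ratio
            lines.append(
                f"{name}: OR {r(o.oratio)} ({r(o.ci_low)}, {r(o.ci_high)}) "
                f"per SD, p = {o.pvalue:.2g}"
            )
        else:
            lines.append(
                f"{name}: {r(pooled.estimate)} ({r(pooled.ci_low)}, "
                f"{r(pooled.ci_high)}) per SD, p = {pooled.pvalue:.2g}"
            )
        lines.append(
            f"  heterogeneity: Q = {pooled.q_stat:.3f}, df = {pooled.q_df}"
            + (
                f", p = {pooled.q_pvalue:.2g}"
                if pooled.q_pvalue is not None
                else ""
            )
        )
    if result.screen_flags is not None:
        lines.append("")
        lines.append("confounder screen (p < 0.01):")
        for rsid, traits in result.screen_flags.items():
            lines.append(
                f"  {rsid}: " + (", ".join(traits) if traits else "no associations")
            )
    return "\n".join(lines) + "\n"


def _result_payload(result: AnalysisResult) -> dict:
    payload: dict = {"instruments": result.instrument_set.members, "outcomes": {}}
    for name, a in result.outcomes.items():
        pooled = dataclasses.asdict(a.pooled)
        payload["outcomes"][name] = {
            "scale": a.scale,
            "pooled": pooled,
            "per_snp": [dataclasses.asdict(e) for e in a.per_snp],
            "odds_ratio": (
                dataclasses.asdict(a.odds_ratio) if a.odds_ratio is not None else None
            ),
        }
    if result.screen_flags is not None:
        payload["confounder_screen"] = result.screen_flags
    return payload


def _write_outputs(result: AnalysisResult, output_dir: Path) -> None:
    output_dir.mkdir(parents=True, exist_ok=True)
    for name, a in result.outcomes.items():
        a.forest.to_csv(
            output_dir / f"forest_{name}.tsv", sep="\t", index=False, float_format="%.17g"
        )
    with open(output_dir / "results.json", "w") as fh:
        json.dump(_result_payload(result), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(output_dir / "report.txt", "w") as fh:
        fh.write(format_report(result))
    if result.screen_flags is not None:
        with open(output_dir / "screen.tsv", "w") as fh:
            fh.write("rsid\tflagged_traits\n")
            for rsid, traits in result.screen_flags.items():
                fh.write(f"{rsid}\t{';'.join(traits)}\n")
    logger.info("outputs written to %s", output_dir)
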