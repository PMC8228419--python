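"""The α-tocopherol → bone study conditions, end to end through the pipeline.

Builds the noise-free expectation of the study-conditions scenario (three
instruments, exposure GWAS n=7781, heel-eBMD outcome n=426,824, fracture
outcome 53,184 cases / 373,611 non-cases), writes the summary-statistics
tables to a temporary directory, and runs the full pipeline: instrument
selection, harmonization, Wald ratios, fixed-effects IVW, per-SD rescaling
(log-exposure SD 0.25), and odds-ratio conversion for the binary outcome.
"""

import tempfile
from pathlib import Path

from mrwald import (
    AnalysisConfig,
    OutcomeSpec,
    format_report,
    relative_effect,
    run_mr_analysis,
    write_summary_stats,
)
from mrwald.synthetic import (
    expected_two_sample,
    tocopherol_ebmd_config,
    tocopherol_fracture_config,
)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    exposure, ebmd = expected_two_sample(tocopherol_ebmd_config(seed=0))
    _, fracture = expected_two_sample(tocopherol_fracture_config(seed=0))
    write_summary_stats(exposure, tmp / "exposure.tsv")
    write_summary_stats(ebmd, tmp / "ebmd.tsv")
    write_summary_stats(fracture, tmp / "fracture.tsv")

    result = run_mr_analysis(
        AnalysisConfig(
            exposure_path=tmp / "exposure.tsv",
            outcomes=[
                OutcomeSpec(name="eBMD", path=tmp / "ebmd.tsv", scale="linear"),
                OutcomeSpec(name="fracture", path=tmp / "fracture.tsv",
                            scale="log_odds"),
            ],
            sd=0.25,
            output_dir=tmp / "out",
        )
    )

print(format_report(result))
print(result.outcomes["eBMD"].forest.to_string(index=False))
pct = relative_effect(result.outcomes["eBMD"].pooled, 0.51)
print(f"\nrelative to women's mean heel eBMD (0.51 g/cm²): {pct:.1f}%")
# The eBMD line reads 0.07 (0.05, 0.09) per SD and the fracture line
# OR 0.97 — a clear BMD effect (>10% of the population mean) but no
# detectable effect on fracture odds.
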