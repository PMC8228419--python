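"""Screen instruments against known risk factors for the outcome.

The screen takes a local variant-trait association table (e.g. an export
from a phenome-wide lookup service) and flags any instrument associated
with a listed confounder trait at p < 0.01 — a violation signal for the
MR exclusion-restriction assumption.
"""

from mrwald import (
    DEFAULT_CONFOUNDER_TRAITS,
    TraitAssociationRecord,
    confounder_screen,
)

instruments = ["rs964184", "rs2108622", "rs11057830"]
table = [
    TraitAssociationRecord("rs964184", "Body Mass Index", 0.2),
    TraitAssociationRecord("rs964184", "triglycerides", 1e-30),  # not a listed trait
    TraitAssociationRecord("rs2108622", "height", 0.02),  # above the 0.01 cut
    TraitAssociationRecord("rs11057830", "smoking", 0.004),  # flagged
]

print("screened traits:", ", ".join(DEFAULT_CONFOUNDER_TRAITS))
flags = confounder_screen(instruments, table, pvalue_threshold=0.01)
for rsid, traits in flags.items():
    print(f"{rsid}: {', '.join(traits) if traits else 'no associations at p < 0.01'}")
# Only rs11057830 is flagged (smoking, p=0.004): associations with
# unlisted traits or at p >= 0.01 do not count.
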