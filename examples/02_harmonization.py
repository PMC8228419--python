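"""Allele harmonization: swapped codings, palindromic variants, drops.

The outcome table below codes rs2108622 with swapped alleles (so its beta
must be negated), includes the palindromic C/G variant rs964184 (oriented
by comparing effect-allele frequencies), and a variant with incompatible
alleles (dropped with a logged reason).
"""

import logging

from mrwald import VariantAssociation, harmonize

logging.basicConfig(level=logging.WARNING, format="%(levelname)s: %(message)s")

exposure = [
    VariantAssociation("rs2108622", "T", "C", beta=0.02, se=0.005, pvalue=1e-10, eaf=0.29),
    VariantAssociation("rs964184", "C", "G", beta=0.04, se=0.006, pvalue=1e-11, eaf=0.14),
    VariantAssociation("rs11057830", "A", "G", beta=0.03, se=0.006, pvalue=1e-8, eaf=0.15),
]
outcome = [
    # swapped allele coding: beta refers to the C allele here
    VariantAssociation("rs2108622", "C", "T", beta=0.005, se=0.001, pvalue=1e-6, eaf=0.71),
    # palindromic, same nominal coding; frequencies agree (both well below 0.5)
    VariantAssociation("rs964184", "C", "G", beta=0.010, se=0.002, pvalue=1e-6, eaf=0.13),
    # incompatible allele pair: dropped
    VariantAssociation("rs11057830", "A", "C", beta=0.002, se=0.002, pvalue=0.3, eaf=0.15),
]

harmonized = harmonize(exposure, outcome, eaf_ambiguity_threshold=0.42)
print(f"\n{len(harmonized)} of {len(exposure)} variants harmonized:")
for h in harmonized:
    print(f"  {h.rsid}: beta_outcome={h.beta_outcome:+.4f} "
          f"flipped={h.flipped} palindromic={h.palindromic}")
# rs2108622's outcome beta comes out as -0.005 (sign inverted with the
# allele swap); rs964184 is retained because both frequencies identify the
# same allele as minor; rs11057830 is dropped.
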