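"""The logistic detection-probability model and its applied arithmetic.

Uses the published coefficients to answer: how likely is a CDR3 to be
seen at a given abundance/depth, and how deep must one sequence for a 50 %
chance of catching a monoclonal infiltrate in a tumor with 2 % TIL?
"""

from tcrseek import (
    PUBLISHED_COEFFICIENTS,
    fraction_to_tpm,
    min_depth_for_detection,
    predict_detection,
    til_to_tcr_fraction,
)

fraction = til_to_tcr_fraction(til_percent=2.0)
tpm = fraction_to_tpm(fraction)
print(f"2 % TIL -> TCR transcript fraction {fraction:.1e} ({tpm:.0f} TPM)")
print(f"pure lymphocytes -> fraction {til_to_tcr_fraction(100):.1e} "
      f"(one TCR transcript in {1 / til_to_tcr_fraction(100):.0f})")

p = predict_detection(PUBLISHED_COEFFICIENTS, tpm=10, depth=7e7,
                      read_length=50, cdr3_length=45)
print(f"P(detect 45-nt CDR3 at 10 TPM, 70M x 50-nt reads) = {p:.3f}")

exact, rounded = min_depth_for_detection(
    PUBLISHED_COEFFICIENTS, tpm=10, read_length=50, cdr3_length=45, target_p=0.5
)
print(f"depth for 50 % detection: {exact:.3e} reads, i.e. {rounded:.0e} "
      "rounded up to the nearest 10 million")
# Abundance dominates: the log10-TPM odds ratio is
print(f"odds ratios: {PUBLISHED_COEFFICIENTS.odds_ratios()}")
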