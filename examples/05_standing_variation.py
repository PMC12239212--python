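"""Standing genetic variation versus de novo aneuploidy.

Before treatment, aneuploids segregate at the missegregation-selection
balance fraction f = u_pre * lambda_s / c.  This prints that fraction, the
expected initial composition of a 1e7-cell tumor, and the threshold-size
ratios that decide whether rescue is driven by pre-existing or de novo
aneuploid cells (ratios > 1 mean de novo variation dominates).
"""

from evorescue import (
    derived_rates,
    initial_state_with_standing_variation,
    preset,
    threshold_ratios,
)

mel = preset("melanoma_a375")
d = derived_rates(mel)
print(f"standing aneuploid fraction f = u_pre*lambda_s/c = {d.f_standing:.4%}")

state = initial_state_with_standing_variation(mel, "expected")
print(f"expected initial composition of N = {mel.n_init:g}: "
      f"s0 = {state.s}, a0 = {state.a}, m0 = {state.m}")

ratio_ad, ratio_sa, ratio_sd = threshold_ratios(mel)
print(f"standing/de-novo threshold ratio  (u/u_pre)(c/|r_s|) = {ratio_sa:.3g}")
print(f"standing/direct threshold ratio                      = {ratio_sd:.3g}")
print("both ratios exceed 1: de novo aneuploidy, not standing variation,")
print("drives rescue at these rates (the drug induces missegregation).")
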