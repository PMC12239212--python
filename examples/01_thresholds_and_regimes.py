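"""Threshold tumor sizes and rescue regimes for the literature presets.

For each preset this prints the net growth rates, the rescue regime (which
mutational route dominates), and the threshold tumor sizes: Nm* for rescue
by direct mutation, Na* with the aneuploid stepping-stone route, and the
standing-variation threshold.  A tumor larger than the threshold is likely
to survive drug treatment by evolving resistance.
"""

from evorescue import classify_regime, derived_rates, preset, theory_summary

for name in ("melanoma_a375", "tnbc_sa609", "tnbc_sa1035", "tnbc_sa535"):
    p = preset(name)
    d = derived_rates(p)
    rep = classify_regime(p)
    res = theory_summary(p)
    print(f"--- {name}")
    print(f"    r_s={d.r_s:+.4f}/d  r_a={d.r_a:+.4f}/d  r_m={d.r_m:+.4f}/d  "
          f"ra*T*={d.ra_tstar:.4g}")
    print(f"    regime: {rep.regime} (aneuploid type: {rep.conditions['aneuploid_type']})")
    print(f"    Nm* = {res.n_star_direct:.3g} cells   Na* = {res.n_star_aneuploid:.3g} "
          f"[{res.branch}]   Na*/Nm* = {res.ratio_aneuploid_direct:.3g}")
    print(f"    P(rescue | N = {res.n_init:g}) = {res.rescue_prob_exact:.3f}")
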