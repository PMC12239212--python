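"""Mean rescue, recurrence, and detection times across tumor sizes.

At the published melanoma parameters, prints the conditional mean waiting
time for the first successful resistant lineage (rescue time), the mean
time for the resistant population to regrow to the pretreatment size N
(recurrence time), and the mean time to reach a fixed detection size
M = 1e7 cells.  Small tumors are dominated by the slow aneuploid
stepping-stone route (~1e4 days); for large tumors the recurrence time
approaches a constant ~1,500 days independent of N.
"""

from evorescue import mean_detection_time, mean_recurrence_time, mean_rescue_time, preset

mel = preset("melanoma_a375")
M = 1e7

print(f"{'N':>8} | {'rescue (d)':>12} | {'recurrence (d)':>16} | {'detection (d)':>14}")
for n in (1e5, 1e6, 1e7, 1e10):
    tau = mean_rescue_time(mel, n)
    rec = mean_recurrence_time(mel, n, seed=1)
    det = mean_detection_time(mel, n, M, seed=1)
    err = f" +/- {rec.stderr:.0f}" if rec.stderr else ""
    print(f"{n:8.0g} | {tau.value:8.0f} [{tau.method[:9]}] | "
          f"{rec.value:8.0f}{err} [{rec.method[:11]}] | {det.value:8.0f} [{det.method}]")
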