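"""Weibull psychometric fit of simulated grating-orientation judgments.

Generates 2AFC trials for the baseline and block sessions (the blocked
finger's generating threshold pushed beyond the tested gratings), fits
the Weibull curve, and reports the 82%-accuracy thresholds.
"""

from handmap import psychophys, synth

for session, thr in [("baseline", synth.BASELINE_THRESHOLD_MM),
                     ("block", synth.BLOCKED_THRESHOLD_MM)]:
    trials = synth.generate_psychophys_trials(
        threshold=thr, slope=synth.PSYCHOMETRIC_SLOPE, n_per_width=20, seed=5
    )
    fit = psychophys.fit_weibull(trials)
    note = " (extrapolated beyond tested widths)" if fit.extrapolated else ""
    print(f"{session:>8}: threshold = {fit.threshold:.2f} mm{note}, "
          f"slope = {fit.slope:.3f}, R^2 = {fit.r_squared:.2f}, "
          f"accuracy at threshold = {100 * fit.predict(fit.threshold):.0f}%")

print("\nThe baseline threshold sits inside the grating range; under the "
      "block, accuracy stays near chance so the 82% point lies far beyond "
      "the widest grating and is flagged as an extrapolation.")
print(f"light-touch sensitivity example: d' = "
      f"{psychophys.dprime(0.95, 0.05, 20):.2f} (hit 0.95, FA 0.05, 20 trials)")
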