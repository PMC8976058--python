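"""Clinical efficacy statistics for a 2x2 FMT trial.

Remission = total Mayo score <= 2 at first follow-up with endoscopic
improvement >= 1.  Arm contrasts use the two-sided Fisher exact test;
the trial's own remission counts are used here as a worked example.
"""

from straintrack import fisher_exact

# remission by antibiotic pretreatment, patients with follow-up only
excl = fisher_exact([[6, 3], [2, 9]])
print("Excluding withdrawals (6/9 ABX+ vs 2/11 ABX-):")
print(f"  two-sided Fisher p = {excl.p_two_sided:.3f}")

# withdrawals (worsening symptoms, no follow-up) coded as non-remission
incl = fisher_exact([[6, 5], [2, 9]])
lo, hi = incl.wald_ci_95
print("\nIncluding withdrawals as non-remission (6/11 vs 2/11):")
print(f"  two-sided Fisher p = {incl.p_two_sided:.2f}")
print(f"  sample log odds    = {incl.sample_log_odds:.2f}")
print(f"  95% Wald CI        = ({lo:.2f}, {hi:.2f})")

print("\nThe first contrast trends toward more remission with antibiotic"
      "\npretreatment (p = 0.065); including the two withdrawals attenuates"
      "\nit (p = 0.18, log OR 1.69 with CI crossing zero).")
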