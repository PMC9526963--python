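"""Monte Carlo power for one 3-2-1 mediation design.

A cluster-randomized implementation trial: 40 organizations (half assigned to
the strategy), 5 providers each, 6 patients per provider.  Large standardized
indirect paths (a3 = b3 = 0.59), medium direct effect, large ICCs.
"""

from medpower321 import DesignSpec, run_design

spec = DesignSpec(a3=0.59, b3=0.59, c3p=0.39, b2=0.39,
                  icc_m3=0.2, icc_y2=0.2, icc_y3=0.2,
                  n3=40, n2=5, n1=6)

est = run_design(spec, estimator="mvm", reps=500, seed=1)

print(f"design: n3={spec.n3} clusters, n2={spec.n2} units, n1={spec.n1} obs "
      f"(total N = {spec.n3 * spec.n2 * spec.n1})")
print(f"power, 2-sided Sobel test at alpha=0.05: {est.power_two:.3f}")
print(f"power, 1-sided Sobel test at alpha=0.05: {est.power_one:.3f}")
print(f"Monte Carlo SE: {est.mc_se:.4f}  "
      f"(completed {est.reps_completed}/{est.reps_requested} replications)")
print()
print("Reading: the 2-sided power is the fraction of simulated trials in")
print("which the Sobel z for the indirect effect a3*b3 exceeds 1.96 in")
print("magnitude; 1-sided testing in the hypothesized direction buys a")
print("substantial gain at no extra cost.")
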