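"""Simulate one hierarchical dataset and estimate the mediation paths twice.

The manifest (MVM) fit regresses the outcome on the *observed* cluster mean
of the mediator, which carries sampling error and attenuates the between
slope; the latent (MSEM-style) fit removes that error by method-of-moments
decomposition.  With many clusters the contrast is visible directly.
"""

from medpower321 import (
    DesignSpec, derive_components, fit_msem, fit_mvm, generate, sobel,
)
from medpower321.population import mvm_between_slope_limit

spec = DesignSpec(a3=0.59, b3=0.59, c3p=0.39, b2=0.39,
                  icc_m3=0.2, icc_y2=0.1, icc_y3=0.2,
                  n3=500, n2=5, n1=3)
params = derive_components(spec)
print(f"true raw paths: a = {params.a_raw:.4f}, b3 = {params.b3_raw:.4f} "
      f"(manifest large-sample limit {mvm_between_slope_limit(params, 5):.4f})")

data = generate(params, spec.n3, spec.n2, spec.n1, seed=42)

mvm = fit_mvm(data)
msem = fit_msem(data, bootstrap_reps=400, seed=7)
for fr in (mvm, msem):
    s = sobel(fr.a_hat, fr.se_a, fr.b3_hat, fr.se_b3)
    print(f"{fr.estimator_tag:>4}: a = {fr.a_hat:.4f} ({fr.se_a:.4f}), "
          f"b3 = {fr.b3_hat:.4f} ({fr.se_b3:.4f}), "
          f"indirect = {s.ab_hat:.4f}, z = {s.z:.2f}")

print()
print("Reading: the MVM b3 sits near the attenuated limit while the MSEM b3")
print("recovers the generating value — at the price of a larger standard")
print("error, which is why MSEM tests of mediation have lower power.")
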