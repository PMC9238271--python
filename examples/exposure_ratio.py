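"""Daily serum exposure from a biexponential kinetic profile.

After an intraperitoneal peptide dose, serum concentration follows a
distribution/early phase (0-30 min, A e^-alpha*t) and a terminal phase
(30-180 min, B e^-beta*t).  The daily exposure is the closed-form
integral of that profile over 24 h, and the biological-relevance check
is its ratio over the constant endogenous level (0.329 nM).
"""

from entfkit import kinetics, synthetic

true = synthetic.pk_params_for_ratio(ratio=5.0, endogenous_nm=0.329)
print(f"generating profile: A={true.A:.2f} nM, alpha={true.alpha}/min, "
      f"B={true.B:.2f} nM, beta={true.beta}/min")

tc = synthetic.gen_pk_profile(seed=0, profile=true, cv=0.05)
fit = kinetics.fit_biexponential(tc)
print(f"fitted profile:     A={fit.A:.2f} nM, alpha={fit.alpha:.4f}/min, "
      f"B={fit.B:.2f} nM, beta={fit.beta:.4f}/min")

expo = kinetics.exposure(fit, 1440.0)
fold = kinetics.exposure_ratio(fit, endogenous_conc_nm=0.329)
print(f"\nexposure over 24 h: {expo:.0f} nM*min")
print(f"fold over endogenous (0.329 nM constant): {fold:.2f}")
print("\nThe profile was constructed to encode a 5-fold exposure ratio; "
      "the fit recovers it from noisy samples.")
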