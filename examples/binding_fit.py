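"""One-site binding fit: apparent Kd from a pulldown-style titration.

Y = Bmax·X/(Kd + X) fitted by nonlinear least squares over a 75–1250 nM
five-point design with three replicates and 10% multiplicative noise.
"""

from fretscope import fit_one_site, generate_binding_curve, predict_one_site

data = generate_binding_curve(bmax=1.0, kd=60.0, noise_sd=0.1, seed=2,
                              n_replicates=3, relative_noise=True)
fit = fit_one_site(data)

print(f"Kd   = {fit.kd:6.1f} ± {fit.kd_stderr:.1f} nM   (true 60 nM)")
print(f"Bmax = {fit.bmax:6.3f} ± {fit.bmax_stderr:.3f} au (true 1.0)")
print(f"R²   = {fit.r2:.4f}")
half = predict_one_site(fit, fit.kd)
print(f"fitted curve at X = Kd gives {half:.3f} = Bmax/2, the "
      "half-saturation property of the monovalent isotherm")
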