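"""Parameter recovery on synthetic data with known ground truth.

Generates a 24-week series from known constants under the study-like net
intake profile with 0.3 kg Gaussian observation noise, then refits.  The
relative errors show how well the two constants are identified from one
noisy realisation of the design.
"""

from weightdiffusion import DiffusionParams, ScemConfig, SyntheticSpec, fit, generate

true = DiffusionParams(alpha=0.016337, beta=1.7096, initial_weight=69.39)
spec = SyntheticSpec(true_params=true, weeks=24, noise_sd=0.3, seed=42)
series, latent = generate(spec)

result = fit(series, (1, 24), cfg=ScemConfig(seed=7))
rel_a = abs(result.params.alpha - true.alpha) / true.alpha
rel_b = abs(result.params.beta - true.beta) / true.beta

print(f"true  alpha={true.alpha:.6f}  beta={true.beta:.4f}")
print(f"fitted alpha={result.params.alpha:.6f}  beta={result.params.beta:.4f}")
print(f"relative errors: alpha {rel_a:.2%}, beta {rel_b:.2%}")
print("\nbeta is pinned tightly by the decline shape; alpha is identified")
print("mainly by the late-starvation weeks where net intake turns positive,")
print("so its error is larger at the same noise level.")
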