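"""Echolocation call structure under deterrent playback.

Deterrent noise masks returning echoes; P. pygmaeus responds by narrowing
its calls — lower bandwidth and start frequency, with end frequency, peak
frequency, duration and pulse interval unchanged. This example simulates
the call-measurement stream (150 passes per arm, three calls per pass) and
fits the Gaussian mixed model with the nested site/night/pair/block/sequence
random effects and a Bonferroni correction over the six responses.
"""

from batrack import CallParamSimParams, fit_call_param_model, simulate_call_params

calls = simulate_call_params(CallParamSimParams(seed=7), n_passes_per_arm=150)
print(f"{calls['sequence'].nunique()} passes, {len(calls)} calls")

for response in ("bandwidth", "start_frequency", "end_frequency", "fmaxe"):
    res = fit_call_param_model(calls, response)
    shift = res.coef("treatment[deterrent]")
    p = res.lrt_treatment["p"]
    p_adj = res.lrt_treatment["p_adjusted"]
    print(f"{response:>16s}: treatment shift {shift:+6.2f} kHz, "
          f"LRT p = {p:.2g} (Bonferroni-adjusted {p_adj:.2g})")
# Bandwidth and start frequency recover the simulated -5.79 / -5.68 kHz
# shifts and stay significant after correction; the unshifted parameters
# do not.
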