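"""Measure the kinetics of a single ACh-puff inward current.

Builds the noiseless mean-neuron voltage-clamp template for a 10 ms,
1 mM ACh puff and quantifies it with the pipeline's operators.
"""

from puffquant import quantify, synth

ONSET = 0.2  # puff time within the sweep, s

trace = synth.make_template_current()  # 50 kHz voltage-clamp sweep
baseline = quantify.estimate_baseline(trace, ONSET)
peak = quantify.peak_amplitude(trace, baseline, ONSET, 2.0)
rise = quantify.rise_time_10_90(trace, baseline, ONSET, 2.0)
fit = quantify.fit_exponential_decay(trace, baseline, ONSET, 2.0)
area = quantify.response_area(trace, baseline, ONSET, 2.0)

print(f"peak amplitude : {peak:8.1f} pA   (negative = inward current)")
print(f"10-90% rise    : {rise:8.1f} ms")
print(f"decay tau      : {fit.tau_ms:8.1f} ms   (single-exponential fit)")
print(f"charge flux    : {abs(area)/1000:8.1f} pA*s (area under the current)")
print()
print("A brief 10 ms puff evokes a current that rises for ~100 ms and")
print("decays over ~half a second: the receptors stay active long after")
print("the agonist is gone, which is what lets puff trains summate.")
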