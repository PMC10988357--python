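"""Identify light-responsive (projection) units with the spike-latency test.

Simulates the tagging protocol (10 trains x 10 pulses, 10 ms pulses at
5 Hz) for one opsin-expressing unit and one untagged unit, then applies the
three criteria: light-induced rate increase, SALT p < 0.01, and evoked-vs-
spontaneous waveform correlation r > 0.9.
"""

from vocalmod import optotagging, synth

spec = synth.TaggingSpec(latency_mean=3.0, latency_jitter_sd=1.0, reliability=0.8)

for tagged in (True, False):
    pulses, spikes, wfs = synth.gen_tagging_session(
        spec, background_rate=5.0, tagged=tagged, seed=7 if tagged else 8)
    res = optotagging.classify_tag(
        spikes, pulses, wfs["evoked"], wfs["spontaneous"])
    kind = "tagged" if tagged else "untagged"
    print(f"{kind} unit: salt_p={res.salt_p:.4f}  "
          f"rate_ratio={res.rate_ratio:.2f}  r={res.waveform_r:.3f}  "
          f"-> light_responsive={res.light_responsive}")

print()
print("salt_p is the rank of the test epoch's median latency-histogram")
print("distance within the pairwise baseline distances (105 pairs from 15")
print("baseline epochs); the smallest attainable value is 1/106 = 0.0094.")
print("rate_ratio compares firing in the 10 ms post-pulse window with the")
print("-150..0 ms baseline; r is the Pearson waveform correlation.")
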