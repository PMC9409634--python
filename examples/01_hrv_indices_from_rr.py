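"""Compute the 11 HRV indices for one 300-beat NN series.

Generates a supine-like series (mean NN 900 ms, LF and HF sinusoidal
modulation, 1/f-ish fractal noise), cleans it, and prints every index.
"""

from hrvpart import RRGenParams, clean_rr, generate_rr, hrv_indices, select_segment

nn = generate_rr(RRGenParams(seed=42), posture="supine", subject_id="demo")
nn = select_segment(clean_rr(nn.intervals, posture="supine", subject_id="demo"))

idx = hrv_indices(nn)
for name, value in idx.as_dict().items():
    print(f"{name:>8}: {value:10.3f}")

# meanNN/SDNN/RMSSD are in ms, pNN20 in %, LF/HF in ms², LFn/HFn in
# normalized units (they sum to 100), alpha1 and SampEn dimensionless.
# With amp_hf > amp_lf this series is vagally dominated: HFn > LFn.
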