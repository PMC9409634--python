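"""Supine vs active standing: the Δ (supine − standing) response.

Standing shortens the mean NN interval, withdraws vagal (HF) power,
boosts relative LF power and raises the short-term scaling exponent.
The deltas therefore come out ΔmeanNN>0, ΔHFn>0, ΔLFn<0, Δα₁<0.
"""

from hrvpart import (
    PostureShift,
    RRGenParams,
    delta,
    generate_posture_pair,
    hrv_indices,
)

supine, standing = generate_posture_pair(
    RRGenParams(seed=7), PostureShift(), subject_id="demo"
)
d = delta(hrv_indices(supine), hrv_indices(standing))

print(f"ΔmeanNN = {d.d_mean_nn_s:+.3f} s   (expected > 0)")
print(f"ΔHFn    = {d.d_hfn:+.1f} n.u. (expected > 0)")
print(f"ΔLFn    = {d.d_lfn:+.1f} n.u. (expected < 0, mirror of ΔHFn)")
print(f"Δα₁     = {d.d_alpha1:+.3f}     (expected < 0)")
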