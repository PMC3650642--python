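"""How much signal measured over the habenula originates elsewhere?

Standard fMRI smoothing kernels (5-10 mm FWHM) exceed the ~3 mm size of
the habenula.  The contamination fraction places unit signal on all
labelled tissue, smooths, and reports the share of the post-smoothing
signal averaged over the habenula ROI that came from *outside* it.
"""

from habseg import LABELS, PhantomSpec, contamination_curve, generate_phantom

phantom = generate_phantom(PhantomSpec(seed=11))
curve = contamination_curve(
    phantom.labels, LABELS["habenula_right"], [0, 2, 3, 5, 8, 12]
)
print(curve.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# At 0 mm nothing mixes in; already at 2-3 mm (a kernel the size of the
# habenula) over half the measured signal is of external origin, and at
# the 5-10 mm kernels used by standard pipelines the ROI average is
# dominated by neighbouring structures such as the MD thalamus.
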