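"""Inter-rater reliability of habenula volumes via ICC(2,1).

Two raters are simulated by perturbing ground-truth masks with smooth
random boundary displacement fields; the two-way random-effects,
absolute-agreement, single-measures ICC quantifies how much of the
volume variance is between subjects rather than between raters.
"""

import numpy as np

from habseg import (
    PhantomSpec,
    RaterTable,
    generate_phantom,
    icc_2_1,
    mask_volume,
    simulate_rater,
)

rng = np.random.default_rng(42)
ratings = []
for subject in range(24):
    target = float(np.clip(rng.normal(30.0, 4.0), 22.0, 38.0))
    phantom = generate_phantom(
        PhantomSpec(seed=int(rng.integers(1, 2**31 - 1)), noise_sigma=0.0,
                    habenula_volume_target=target, grid_shape=(48, 80, 48))
    )
    truth = phantom.true_masks["right"]
    ratings.append(
        [mask_volume(simulate_rater(truth, boundary_sd=0.15, bias=0.0,
                                    seed=int(rng.integers(1, 2**31 - 1))))
         for _ in range(2)]
    )

result = icc_2_1(RaterTable(np.asarray(ratings), "right_volume_mm3"))
print(f"ICC(2,1) = {result.estimate:.3f} "
      f"(95% CI {result.ci_low:.3f}-{result.ci_high:.3f}), '{result.band}'")
print(f"mean squares: subjects {result.ms_rows:.2f}, "
      f"raters {result.ms_cols:.2f}, error {result.ms_error:.2f}")
# At 0.15 mm boundary noise the per-rating volume error is ~1-2 mm^3 —
# the precision trained human raters achieve — and most volume variance
# is between subjects.  Raising boundary_sd degrades agreement and the
# ICC drops through the qualitative bands.
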