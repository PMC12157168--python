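"""Fit a GP surrogate and ask the LCB acquisition for the next experiments.

The GP (Matérn 5/2 on unit-scaled inputs) models 40 screening observations;
the balanced strategy (κ = 1.96) trades off low predicted titer loss against
high posterior uncertainty.  The suggested formulations are where the next
wet-lab batch would go; lower acquisition value = more promising.
"""

import formubo as fb

land = fb.reduced_landscape()
design = fb.sample_design(land.space, 40, scheme="latin", seed=1)
screen = fb.generate_dataset(land.oracle(1), design, replicates=1, seed=1,
                             response_name="titer_loss", space=land.space)

U, _ = fb.scale_to_unit(screen)
gp = fb.fit_gp(U, screen.y, fb.GPFitConfig(seed=1))
print(f"fitted GP: length-scale {gp.params.length_scale:.3f}, "
      f"signal variance {gp.params.signal_variance:.3f}, "
      f"noise sd {gp.noise_variance_original**0.5:.3f} log10")

batch = fb.suggest_batch(gp, land.space,
                         fb.AcquisitionConfig(strategy="balanced", batch_size=5, seed=1))
table = batch.candidates.round(3)
table["LCB"] = batch.acquisition_values.round(3)
print(table.to_string(index=False))
print("each row is one suggested formulation (original units); "
      "LCB = predicted loss minus 1.96 posterior sd")
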