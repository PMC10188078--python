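"""Generate a synthetic layer-hen Mn trial with known dose-response truth.

The built-in reference design has 10 diets — an unsupplemented control
(10.4 mg/kg analyzed Mn) plus 30/60/90 mg/kg added Mn from oxide, sulphate
and organic sources — with 6 replicate cages of 12 hens over three 4-week
periods.  Egg production follows per-source broken-line curves; replicate
noise is calibrated to the reference trial's treatment-mean SEs.
"""

import layreq as lq
from layreq import trial

design = trial.reference_design()
replicates = lq.simulate_replicates(design, lq.default_truths(noise=True),
                                    seed=20230315)
eggs = lq.simulate_eggs(design, seed=20230315)

print(replicates.head(6).to_string(index=False))
print(f"\n{len(replicates)} replicate-period records "
      f"({len(design.treatments)} diets x {design.n_replicates} replicates "
      f"x {design.n_periods} periods), {len(eggs)} sampled eggs.")
print("Each record's egg counts, egg mass and feed weights are mutually "
      "consistent, so every downstream trait recovers the generative curve "
      "when noise is off.")
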