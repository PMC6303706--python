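"""Generate a synthetic two-species sensilla study and inspect its design.

Builds the bundled 103-female study design (two damselfly species across
28 sites in three patry classes), simulates every female's plate with two
digitization replicates, and prints the per-species count regime.
"""

import numpy as np

from platemorph import generate_study

study = generate_study(master_seed=1)
by_female = study.records_by_female()
print(f"simulated {len(by_female)} females, {len(study.records)} plate records")

counts = {}
for sid, recs in by_female.items():
    counts.setdefault(recs[0].species, []).append(
        np.mean([r.sensilla_count for r in recs])
    )
for species, values in counts.items():
    print(
        f"  {species}: n = {len(values):3d} females, "
        f"mean sensilla count = {np.mean(values):.1f} +/- "
        f"{np.std(values) / np.sqrt(len(values)):.1f} (SEM)"
    )
# The two species are planted ~21 sensilla apart (means ~49 vs ~28),
# matching the regime the downstream statistics are asked to recover.
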