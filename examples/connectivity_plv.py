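"""Phase-locking connectivity within and between cortical compartments.

Generates a small cohort with the default coupling profile (strongest within
the tumor), computes per-band PLV matrices and prints the within-compartment
mean PLV per band.
"""

import pandas as pd

from ecogpipe import (COMPARTMENTS, PLV_BANDS, SynthConfig,
                      compartment_plv_summary, generate_recording, plv_matrix)

config = SynthConfig(sampling_rate=500.0, duration=60.0,
                     channels_per_compartment={k: 8 for k in COMPARTMENTS},
                     seed=2)
recording, truth = generate_recording(config)
labels = [truth.labels[c] for c in recording.channel_ids]

rows = {}
for band in PLV_BANDS:
    summary = compartment_plv_summary(plv_matrix(recording, band), labels)
    rows[band] = {g: summary.matrix.loc[g, g] for g in COMPARTMENTS}

table = pd.DataFrame(rows).T.round(3)
print("mean within-compartment PLV per band:")
print(table.to_string())
print("\nPLV is the modulus of the time-averaged unit phasor of the phase")
print("difference: 1 = perfect locking, ~sqrt(pi/4N) for independent noise.")
print("The tumoral column is highest in every band, reflecting the stronger")
print("shared component the generator injects within the tumor group.")
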