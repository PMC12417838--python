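"""Welch spectra, line-noise removal, band powers and the aperiodic fit.

Generates one channel per compartment, estimates each power spectrum, strips
the 50 Hz mains bins, and prints the relative band powers and the fitted
aperiodic offset/exponent per compartment.
"""

from ecogpipe import (COMPARTMENTS, SynthConfig, aperiodic_feature_block,
                      band_powers, generate_recording, remove_line_noise,
                      welch_psd)

config = SynthConfig(sampling_rate=500.0, duration=60.0,
                     channels_per_compartment={k: 1 for k in COMPARTMENTS},
                     seed=1)
recording, truth = generate_recording(config)

spectrum = welch_psd(recording)                  # 2 s Hann windows, 50% overlap
spectrum = remove_line_noise(spectrum, 50.0)     # drop mains +/- 1 Hz bins
bands = band_powers(spectrum)                    # abs/rel power per band
aperiodic = aperiodic_feature_block(spectrum)    # offset + six slopes

print("relative band powers (fraction of retained total power):")
rel = bands[[c for c in bands.columns if c.startswith("rel_")]].round(3)
rel.index = [truth.labels[c] for c in rel.index]
print(rel.to_string())

print("\naperiodic fit over 1-200 Hz (offset = log10 power at 1 Hz,")
print("exponent = 1/f decay; generative truth in parentheses):")
for cid in recording.channel_ids:
    label = truth.labels[cid]
    print(f"  {label:>18s}: offset {aperiodic.loc[cid, 'offset']:.2f} "
          f"({truth.offsets[cid]:.1f}), "
          f"exponent {aperiodic.loc[cid, 'slope_1_200']:.2f} "
          f"({truth.exponents[cid]:.2f})")
# The tumoral channel shows the highest relative delta and the lowest offset;
# peritumoral channels show elevated relative beta.  Fitted exponents for the
# wide range track the generative values; narrow-range slopes additionally
# reflect oscillatory structure, as intended for the slope features.
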