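"""Generate synthetic single-lead ECG and inspect the two class cues.

Builds one sinus-rhythm and one AF record with the default generator and
prints the statistics a cardiologist (or the classifier) keys on: RR
spread (regular vs irregular) and P-wave / f-wave content.
"""

import numpy as np

from msres import af_spec, generate_record, normal_spec

sinus = generate_record(normal_spec(), duration=30.0, seed=1, name="N00001")
af = generate_record(af_spec(), duration=30.0, seed=2, name="A00001")

for rec, name in ((sinus, "sinus"), (af, "AF")):
    rr = np.asarray(rec.rr)
    cv = rr.std() / rr.mean()
    print(f"{name:>5}: {rec.duration:.0f} s at {rec.fs:.0f} Hz, "
          f"{len(rr)} beats, mean RR {rr.mean():.3f} s, RR CV {cv:.3f}")

# Spectral content of the baseline between beats: AF carries a ~7 Hz f-wave.
for rec, name in ((sinus, "sinus"), (af, "AF")):
    spectrum = np.abs(np.fft.rfft(rec.samples)) ** 2
    freqs = np.fft.rfftfreq(len(rec.samples), 1 / rec.fs)
    band = (freqs > 4) & (freqs < 10)
    print(f"{name:>5}: spectral power in the 4-10 Hz fibrillatory band: "
          f"{spectrum[band].sum() / spectrum[1:].sum():.3f} of total")

# The RR coefficient of variation is the headline discriminator: ~0.05 for
# sinus rhythm versus ~0.25 for AF at the default generator settings.
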