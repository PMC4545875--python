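"""Simulate one subject and compute band-specific PLI connectivity.

Generates a control-group recording (4 epochs x 19 channels x 4096
samples at 500 Hz), runs the preprocessing chain (common average
reference -> band-pass -> instantaneous phase) and prints the regional
Phase Lag Index per band.
"""

import numpy as np

from hubshift import (
    DEFAULT_BANDS,
    SimulationSpec,
    bandpass,
    common_average_reference,
    instantaneous_phase,
    pli_matrix,
    regional_pli,
    simulate_subject,
    standard_montage,
)

montage = standard_montage()
spec = SimulationSpec()
rec = simulate_subject(spec, 0, montage, np.random.default_rng(0), "sub-001")
print(
    f"{rec.subject_id}: {rec.n_epochs} epochs x {rec.n_channels} channels "
    f"x {rec.epoch_len} samples ({rec.epoch_duration} s each), "
    f"sex={rec.sex}, MMSE={rec.mmse:.0f}"
)

referenced = common_average_reference(rec.data)
print(f"\n{'band':12s} {'anterior':>9s} {'central':>9s} {'posterior':>10s} {'global':>8s}")
for band in DEFAULT_BANDS:
    filtered = bandpass(referenced, band, rec.sampling_rate)
    phases = instantaneous_phase(filtered, band)
    reg = regional_pli(pli_matrix(phases), montage)
    v = reg.values
    print(
        f"{band.name:12s} {v['anterior']:9.3f} {v['central']:9.3f} "
        f"{v['posterior']:10.3f} {v['global']:8.3f}"
    )

print(
    "\nPLI is 0 for no (or purely zero-lag) coupling and 1 for a fully "
    "consistent nonzero phase lag; regional values average all "
    "within-region channel pairs."
)
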