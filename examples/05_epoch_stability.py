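"""How many epochs make a stable PLI estimate?

Simulates subjects with 8 epochs and reports the mean absolute
difference between the k-epoch and 8-epoch global PLI for several k.
Four epochs of 8.192 s are already within 0.02 of the 8-epoch value.
"""

from hubshift import epoch_stability_report

report = epoch_stability_report(
    epochs_list=(1, 2, 4, 8), n_subjects=12, seed=0
)
print(report.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "\nmean_abs_delta is the average |global PLI(k epochs) - global "
    "PLI(8 epochs)| across subjects; it shrinks as k grows and is 0 at "
    "k = 8 by construction."
)
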