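"""Generation arithmetic of a serial-passage evolution experiment.

Transferring 0.75 mL of a saturated culture into 200 mL of fresh medium
is a 1:266 dilution; regrowing to saturation takes log2(266) ~ 8.1
doublings. One hundred such cycles give at least 800 generations
(ignoring cell death, so this is a lower bound).
"""

from covploid import PassageScheme, dilution_factor, generations_per_transfer, total_generations

scheme = PassageScheme(transfer_volume=0.75, culture_volume=200, n_cycles=100)
print(f"dilution factor:          1:{dilution_factor(scheme)}")
print(f"generations per transfer: {generations_per_transfer(scheme):.2f}")
print(f"total generations:        {total_generations(scheme):.1f}")
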