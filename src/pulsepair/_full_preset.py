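"""Frozen dimensions of the `full` encoder preset.

Found by ``scripts/calibrate_full_preset.py``: among ResNet50-like candidates
(bottleneck stages, depth layout (3, 4, 6, 3), widths approximately doubling
per stage) this is the configuration closest to canonical width doubling
whose single-output classifier variant counts exactly 9,218,369 trainable
parameters.
"""

FULL_PRESET_KWARGS = dict(
    stage_blocks=(3, 4, 6, 3),
    stage_widths=(40, 80, 160, 268),
    kernel_size=13,
    use_bottleneck=True,
    stem_width=36,
    stem_kernel=15,
)
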