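"""Calibration search for the `full` encoder preset.

The trunk's free dimensions (stage widths, kernel sizes, stem width) are not
pinned down by the architecture description alone; the one hard constraint is
that the end-to-end classifier variant (single-output head) must count exactly
9,218,369 trainable parameters.  This script enumerates ResNet50-like
candidates — bottleneck stages with depth layout (3, 4, 6, 3), widths roughly
doubling per stage — and reports every configuration whose closed-form
parameter count hits the target exactly, ranked by how closely the widths
follow the canonical doubling pattern.

The winning configuration is frozen in ``src/pulsepair/_full_preset.py``.

Run:  python scripts/calibrate_full_preset.py
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pulsepair.encoder import EncoderConfig, count_parameters_formula  # noqa: E402

TARGET = 9_218_369
STAGE_BLOCKS = (3, 4, 6, 3)  # ResNet50 depth layout


def search() -> list[tuple[float, EncoderConfig]]:
    """Enumerate (kernel, stem kernel, stage widths); solve the stem width.

    The stem width s enters the total linearly with coefficient
    c = 2*stem_kernel + 2 + 5*w1 (stem conv + stem BN + first bottleneck's
    input conv and projection shortcut), so for each candidate we solve
    s = (TARGET - rest) / c and keep integer solutions in a sensible range.
    """
    hits: list[tuple[float, EncoderConfig]] = []
    for kernel in (3, 5, 7, 9, 11, 13):
        for stem_kernel in (3, 5, 7, 9, 11, 15):
            for w1 in range(16, 68, 2):
                w2, w3 = 2 * w1, 4 * w1
                coef = 2 * stem_kernel + 2 + 5 * w1
                # last stage width left free: scan even widths near 2*w3
                for w4 in range(w3, 6 * w3 + 1, 2):
                    probe = EncoderConfig(
                        stage_blocks=STAGE_BLOCKS,
                        stage_widths=(w1, w2, w3, w4),
                        kernel_size=kernel, use_bottleneck=True,
                        stem_width=1, stem_kernel=stem_kernel, preset="full")
                    rest = count_parameters_formula(probe, "classifier") - coef
                    num = TARGET - rest
                    if num <= 0 or num % coef:
                        continue
                    stem_width = num // coef
                    if not 16 <= stem_width <= 96:
                        continue
                    cfg = EncoderConfig(
                        stage_blocks=STAGE_BLOCKS,
                        stage_widths=(w1, w2, w3, w4),
                        kernel_size=kernel, use_bottleneck=True,
                        stem_width=stem_width, stem_kernel=stem_kernel,
                        preset="full")
                    assert count_parameters_formula(cfg, "classifier") == TARGET
                    # rank by deviation from the canonical ResNet50 pattern:
                    # widths double each stage, stem width equals w1
                    score = abs(w4 / (8 * w1) - 1.0) + abs(stem_width / w1 - 1.0)
                    hits.append((score, cfg))
    return sorted(hits, key=lambda t: t[0])


if __name__ == "__main__":
    hits = search()
    if not hits:
        print("no exact configuration found — widen the search space")
        raise SystemExit(1)
    print(f"{len(hits)} exact configurations; best (closest to width doubling):\n")
    for score, cfg in hits[:10]:
        print(f"  score={score:.4f}  widths={cfg.stage_widths} "
              f"kernel={cfg.kernel_size} stem=({cfg.stem_width},{cfg.stem_kernel})")
    best = hits[0][1]
    print("\nfreeze this into src/pulsepair/_full_preset.py:")
    print(f"  stage_blocks={best.stage_blocks}, stage_widths={best.stage_widths},")
    print(f"  kernel_size={best.kernel_size}, use_bottleneck=True,")
    print(f"  stem_width={best.stem_width}, stem_kernel={best.stem_kernel}")
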