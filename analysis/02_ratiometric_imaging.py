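#!/usr/bin/env python
"""Ratiometric 920/860 nm discrimination on synthetic image pairs.

Generates collagen-like (ratio 1.73) and myosin-like (ratio 1.03) fields
with Poisson noise and a small acquisition drift, registers each pair,
builds the false-colour composite (920 nm -> red+blue, 860 nm -> green)
and tabulates the label fractions.  A combined field (myosin left,
collagen right) reproduces the two-material overlay.  Outputs under
results/: composites (PNG) and ratiometric_stats.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from shgspec.io import write_rgb
from shgspec.ratiometric import ShgImage, ratio_composite, register_pair
from shgspec.synthetic import SceneConfig, make_image_pair

RESULTS = Path(__file__).resolve().parents[1] / "results"


def combined_field(seed):
    """Myosin on the left half, collagen on the right half of one field."""
    col920, col860, _ = make_image_pair(SceneConfig(material="collagen_like",
                                                    seed=seed))
    myo920, myo860, _ = make_image_pair(SceneConfig(material="myosin_like",
                                                    seed=seed + 100))
    w = col920.pixels.shape[1] // 2
    px920 = np.hstack([myo920.pixels[:, :w], col920.pixels[:, w:]])
    px860 = np.hstack([myo860.pixels[:, :w], col860.pixels[:, w:]])
    return (ShgImage(pixels=px920, excitation_nm=920.0),
            ShgImage(pixels=px860, excitation_nm=860.0))


def main():
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for material, seed in (("collagen_like", 0), ("myosin_like", 0)):
        img920, img860, truth = make_image_pair(
            SceneConfig(material=material, seed=seed, shift=(3, -2))
        )
        pair = register_pair(img920, img860)
        comp = ratio_composite(pair)
        mask = truth["fibre_mask"]
        measured = img920.pixels[mask].mean() / np.roll(
            img860.pixels, pair.shift, axis=(0, 1))[mask].mean()
        rows.append({
            "field": material, "seed": seed,
            "recovered_shift_dy_dx": str(pair.shift),
            "true_ratio": truth["ratio_920_860"],
            "measured_fibre_ratio": round(measured, 3),
            "purple_fraction": round(comp.purple_fraction, 3),
            "green_fraction": round(comp.green_fraction, 3),
            "gray_fraction": round(comp.gray_fraction, 3),
        })
        write_rgb(RESULTS / f"composite_{material}.png", comp.rgb)
        print(f"{material}: shift {pair.shift}, fibre ratio "
              f"{measured:.3f} (true {truth['ratio_920_860']}), "
              f"purple {comp.purple_fraction:.3f} / gray {comp.gray_fraction:.3f}")

    img920, img860 = combined_field(seed=1)
    comp = ratio_composite(register_pair(img920, img860))
    write_rgb(RESULTS / "composite_combined.png", comp.rgb)
    h, w = comp.labels.shape
    left = comp.labels[:, : w // 2]
    right = comp.labels[:, w // 2 :]
    left_purple = (left == "purple").sum() / max((left != "").sum(), 1)
    right_purple = (right == "purple").sum() / max((right != "").sum(), 1)
    rows.append({
        "field": "combined", "seed": 1, "recovered_shift_dy_dx": "(0, 0)",
        "true_ratio": np.nan, "measured_fibre_ratio": np.nan,
        "purple_fraction": round(comp.purple_fraction, 3),
        "green_fraction": round(comp.green_fraction, 3),
        "gray_fraction": round(comp.gray_fraction, 3),
    })
    print(f"combined field: purple share left (myosin) {left_purple:.2f} vs "
          f"right (collagen) {right_purple:.2f} — the collagen half lights up "
          "purple, the myosin half stays greyscale.")
    pd.DataFrame(rows).to_csv(RESULTS / "ratiometric_stats.csv", index=False)
    print(f"wrote {RESULTS/'ratiometric_stats.csv'} and three composites")


if __name__ == "__main__":
    main()
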