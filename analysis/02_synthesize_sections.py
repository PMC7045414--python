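#!/usr/bin/env python
"""Render synthetic labelled cross-sections with known tissue fractions.

Generates one stem-like and one twig-like scene, writes the label rasters
(8-bit PNG + JSON sidecar) and their exact pixel-count ground truth, and a
quick-look figure of the stem scene.
"""

import argparse
import json
from pathlib import Path

from woodfrac.stereology import write_label_map
from woodfrac.synthesis import SceneParams, generate_section_scene

SCENES = {
    # stem: wide vessels, 2 x 3 mm analysis window (6 mm^2)
    "stem": SceneParams(width_um=2000.0, height_um=3000.0,
                        conduit_fraction=0.10, ray_fraction=0.15,
                        conduit_d_median_um=80.0),
    # twig: narrow vessels, 1 mm^2 window
    "twig": SceneParams(width_um=1000.0, height_um=1000.0,
                        conduit_fraction=0.10, ray_fraction=0.12,
                        conduit_d_median_um=35.0, ray_width_um=15.0,
                        sheath_thickness_um=6.0),
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results/scenes"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    truths = {}
    for organ, params in SCENES.items():
        scene = generate_section_scene(params, seed=args.seed)
        path = args.out_dir / f"{organ}_scene.png"
        write_label_map(scene.label_map, path, seed=args.seed)
        truths[organ] = scene.true_fractions
        frac = ", ".join(f"{k} {v:.3f}" for k, v in
                         scene.true_fractions.items())
        print(f"{organ}: {len(scene.conduit_ellipses)} conduits; {frac}")

    (args.out_dir / "true_fractions.json").write_text(
        json.dumps(truths, indent=2) + "\n")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scene = generate_section_scene(SCENES["stem"], seed=args.seed)
    fig, ax = plt.subplots(figsize=(5, 7))
    ax.imshow(scene.label_map.raster, cmap="tab10", vmin=0, vmax=9,
              interpolation="nearest")
    ax.set_title("synthetic stem section (category codes)")
    ax.set_axis_off()
    fig.savefig(args.out_dir / "stem_scene_preview.png", dpi=120,
                bbox_inches="tight")
    print(f"scenes written to {args.out_dir}/")


if __name__ == "__main__":
    main()
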