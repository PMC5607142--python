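"""GP maps of the nanodomain and endosome phantoms, confocal vs STED.

For each phantom and PSF preset: render, compute the pixel-wise GP map,
save a red-to-blue rendering, and tabulate ROI GP statistics.  The point
of the comparison: the 500-nm disordered nanodomain keeps its full GP
contrast (domain -0.19 vs surround +0.08) only at STED resolution, and
the 150-nm internal vesicle (GP 0.11) separates from the plasma membrane
(GP 0.32) the same way.
"""

import os

import imageio.v3 as iio
import pandas as pd

from memgp import preset, render_gp_colormap, render_phantom
from memgp.gp_mapping import ChannelPair, compute_gp_map, gp_pipeline, interdomain_difference

RESULTS = "results"
SCRATCH = "scratch/gp_maps"

CASES = {
    "fig5-nanodomain": ["domain", "surround"],
    "fig5-endosome": ["vesicle", "plasma_membrane"],
}


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    os.makedirs(SCRATCH, exist_ok=True)
    rows = []
    for name, labels in CASES.items():
        per_mode = {}
        for mode in ("confocal", "sted"):
            stack, gt, rois = render_phantom(preset(name, mode=mode, seed=7))
            gp_map, stats = gp_pipeline(stack, rois, roi_labels=labels)
            pair = ChannelPair.from_stack(stack)
            iio.imwrite(os.path.join(SCRATCH, f"{name}_{mode}.png"),
                        render_gp_colormap(gp_map, intensity=pair.I1 + pair.I2))
            per_mode[mode] = {s.label: s for s in stats}
            for s in stats:
                rows.append({"phantom": name, "mode": mode, "roi": s.label,
                             "mean_gp": s.mean_gp, "sd_gp": s.sd_gp,
                             "n_pixels": s.n_pixels,
                             "gp_true": gt.gp_true[s.label]})
                print(f"{name} [{mode}] {s.label}: GP = {s.mean_gp:+.3f} "
                      f"± {s.sd_gp:.3f} (truth {gt.gp_true[s.label]:+.3f})")
        a, b = labels
        for mode in ("confocal", "sted"):
            d = interdomain_difference(per_mode[mode][b], per_mode[mode][a])
            print(f"{name} [{mode}] interdomain ΔGP ({b} - {a}) = "
                  f"{d.difference:+.3f} ± {d.sd:.3f}")
    pd.DataFrame(rows).to_csv(os.path.join(RESULTS, "gp_roi_stats.csv"), index=False)
    print(f"\nwrote {RESULTS}/gp_roi_stats.csv and renderings under {SCRATCH}/")


if __name__ == "__main__":
    main()
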