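"""Photobleaching of a 20-frame sequential series.

Renders the bleaching phantom (per-frame survival 0.9875, Poisson noise),
extracts the membrane-ROI bleach curve, fits the single-parameter
geometric decay, and reports the fractional loss after 20 frames —
expected near 21%, comfortably below the 25% working bound for a probe
usable in time-lapse imaging.
"""

import os

import pandas as pd

from memgp import (
    bleach_curve,
    fit_decay,
    fractional_loss,
    phantom_rois,
    preset,
    render_bleach_series,
)

RESULTS = "results"


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    spec = preset("bleach-20", mode="sted", seed=7)
    series = render_bleach_series(spec)
    curve = bleach_curve(series, phantom_rois(spec)["membrane"], roi_label="membrane")
    pd.DataFrame({
        "frame": curve.frame_index,
        "normalized_intensity": curve.normalized_intensity,
    }).to_csv(os.path.join(RESULTS, "bleach_curve.csv"), index=False)
    s, rss = fit_decay(curve)
    loss = fractional_loss(curve, 20)
    pd.DataFrame([{"survival_per_frame": s, "rss": rss,
                   "fractional_loss_20_frames": loss,
                   "true_survival": spec.bleach_survival_per_frame}]).to_csv(
        os.path.join(RESULTS, "bleach_fit.csv"), index=False)
    print(f"fitted per-frame survival: {s:.4f} (truth {spec.bleach_survival_per_frame})")
    print(f"signal loss after 20 frames: {100 * loss:.1f}% "
          f"(closed form {100 * (1 - 0.9875**19):.1f}%)")
    print(f"\nwrote {RESULTS}/bleach_curve.csv and {RESULTS}/bleach_fit.csv")


if __name__ == "__main__":
    main()
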