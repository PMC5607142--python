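"""λ-stack spectral analysis of the phase-separated and GFP phantoms.

Extracts ordered/disordered-phase emission spectra from the 9-nm-window
stack, reports the peak shift (truth: 40 nm), the per-window intensity
ratio between the phases, and demonstrates two-band recombination that
separates a GFP-like lumen (500-530 nm) from the membrane probe
(570-693 nm).
"""

import os

import numpy as np
import pandas as pd

from memgp import (
    channel_intensity_ratio,
    extract_spectrum,
    peak_shift,
    peak_wavelength,
    preset,
    recombine_bands,
    render_phantom,
)

RESULTS = "results"


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    stack, _, rois = render_phantom(preset("spectra-shift", mode="confocal", seed=7))
    traces = {
        label: extract_spectrum(stack, rois[label], normalize=True)
        for label in ("ordered", "disordered")
    }
    rows = [
        {"roi": lb, "wavelength_nm": w, "normalized_intensity": v}
        for lb, tr in traces.items()
        for w, v in zip(tr.wavelengths_nm, tr.intensities)
    ]
    pd.DataFrame(rows).to_csv(os.path.join(RESULTS, "phase_spectra.csv"), index=False)
    for lb, tr in traces.items():
        print(f"{lb} phase peak: {peak_wavelength(tr).peak_nm:.1f} nm")
    shift = peak_shift(traces["ordered"], traces["disordered"])
    print(f"ordered→disordered red shift: {shift:.1f} nm (truth 40)")

    ratio = channel_intensity_ratio(stack, rois["ordered"], rois["disordered"])
    pd.DataFrame(ratio, columns=["wavelength_nm", "ordered_over_disordered"]).to_csv(
        os.path.join(RESULTS, "phase_intensity_ratio.csv"), index=False
    )
    lam_cross = next(w for (w, r) in ratio if r < 1.0)
    print(f"ordered/disordered ratio drops below 1 at {lam_cross:.1f} nm")

    gfp_stack, _, _ = render_phantom(preset("gfp-gpmv", mode="confocal", seed=7))
    pair = recombine_bands(gfp_stack, (500, 530), (570, 693))
    h, w = gfp_stack.shape
    lumen_gp = (pair.I1[h // 2, w // 2] - pair.I2[h // 2, w // 2]) / max(
        pair.I1[h // 2, w // 2] + pair.I2[h // 2, w // 2], 1e-9
    )
    print(f"two-band recombination: lumen pixel channel asymmetry {lumen_gp:+.3f} "
          "(GFP signal confined to the 500-530 nm band)")
    print(f"\nwrote {RESULTS}/phase_spectra.csv and {RESULTS}/phase_intensity_ratio.csv")


if __name__ == "__main__":
    main()
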