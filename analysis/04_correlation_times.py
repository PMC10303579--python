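#!/usr/bin/env python
"""Chain-end rotational correlation times and motional anisotropy.

Simulates fast-motion spectra of the 16-PC label for the three membrane
models with τ2B < τ2C splittings that mimic cholesterol-dependent motional
anisotropy (largest in the cholesterol-rich plasma membrane, smallest in
the cholesterol-poor old disc membrane), and recovers both times and the
anisotropy index through the amplitude-ratio formulas.

Writes results/correlation_times.tsv.
"""

from pathlib import Path

import pandas as pd

from memepr.features import measure_three_lines
from memepr.observables import anisotropy_index, correlation_times
from memepr.simulate import FastMotionParams, simulate_fast_isotropic
from memepr.spectrum import SpectrumMeta

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 16293

# (tau_2B, tau_2C) targets in ns: anisotropy tracks cholesterol content
TARGETS = {"PM": (1.4, 2.0), "YDM": (1.7, 2.0), "ODM": (1.9, 2.0)}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for k, (cls, (t2b_ns, t2c_ns)) in enumerate(TARGETS.items()):
        spec = simulate_fast_isotropic(
            FastMotionParams(
                tau_2B_target=t2b_ns * 1e-9, tau_2C_target=t2c_ns * 1e-9,
                base_linewidth=2.5, seed=SEED + k,
            ),
            meta=SpectrumMeta(temperature_K=310.0, spin_label="16-PC",
                              membrane_class=cls),
        )
        lf = measure_three_lines(spec, smoothing_window=0.4)
        t2b, t2c = correlation_times(lf)
        rows.append(
            {
                "membrane": cls,
                "tau_2B_ns": t2b * 1e9,
                "tau_2C_ns": t2c * 1e9,
                "anisotropy_pct": anisotropy_index(t2b, t2c),
                "tau_2B_target_ns": t2b_ns,
                "tau_2C_target_ns": t2c_ns,
            }
        )
    frame = pd.DataFrame(rows)
    path = OUT / "correlation_times.tsv"
    frame.to_csv(path, sep="\t", index=False, float_format="%.4g")

    print(frame.to_string(index=False))
    print()
    print("tau_2C exceeds tau_2B everywhere; the anisotropy index falls from")
    print("~30% in the cholesterol-rich PM model to <10% in the fluid ODM")
    print("model, mirroring the restriction cholesterol puts on label motion.")
    print(f"table -> {path}")


if __name__ == "__main__":
    main()
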