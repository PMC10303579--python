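#!/usr/bin/env python
"""MD-style post-processing on a synthetic chain ensemble.

Generates a trajectory whose segmental orientation distributions imitate an
acyl chain (a plateau of moderate order near the glycerol backbone decaying
to disorder at the chain end), recovers the per-carbon Smol profile with
7-block standard errors, and demonstrates geometric hydrogen-bond counting
with a membrane-residency filter.

Writes results/md_smol_profile.tsv and results/md_hbonds.tsv.
"""

from pathlib import Path

import numpy as np

from memepr.mdframes import TrajectoryFrames
from memepr.mdorder import (
    ChainTopology,
    HBondCriteria,
    count_hbonds,
    phosphate_z_band,
    resident_mask,
    smol_profile,
    synth_trajectory,
)

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 57312

# <cos^2 theta> targets per interior carbon: plateau then decay to isotropy
COS2_TARGETS = [0.62, 0.62, 0.60, 0.55, 0.48, 0.42, 0.37, 1.0 / 3.0]


def hbond_demo() -> "object":
    """Two retinoid-like donors, one expelled from the membrane slab."""
    coords = np.zeros((1, 9, 3))
    coords[0, 0:2] = [[0, 0, -15.0], [1, 0, -15.0]]  # lower phosphate plane
    coords[0, 2:4] = [[0, 1, 15.0], [1, 1, 15.0]]  # upper phosphate plane
    coords[0, 4:6] = [[3, 3, 0.0], [3.96, 3.28, 0.0]]  # resident donor + H
    coords[0, 6:8] = [[6, 6, 40.0], [6.96, 6.28, 40.0]]  # expelled donor + H
    coords[0, 8] = [5.0, 3.5, 0.5]  # acceptor oxygen, ~14 deg off the O-H axis
    frames = TrajectoryFrames(
        mol_ids=[1, 1, 2, 2, 3, 3, 4, 4, 5],
        resnames=["POPC"] * 4 + ["RET"] * 4 + ["WAT"],
        atom_names=["P1", "P2", "P3", "P4", "O1", "H1", "O2", "H2", "OW"],
        coords=coords,
    )
    band = phosphate_z_band(frames, [0, 1, 2, 3], margin=5.0)
    mask = resident_mask(frames, [3, 4], band)
    return count_hbonds(
        frames, HBondCriteria(3.5, 30.0), [(4, 5), (6, 7)], {"RET-WATER": [8]},
        donor_frame_mask=mask,
    )


def main() -> None:
    OUT.mkdir(exist_ok=True)
    frames = synth_trajectory(
        COS2_TARGETS, n_molecules=250, n_frames=140, seed=SEED
    )
    names = [f"C{k + 1}" for k in range(len(COS2_TARGETS) + 2)]
    profile = smol_profile(frames, ChainTopology(chains={"sn1": names}), n_blocks=7)
    table = profile.table()
    path = OUT / "md_smol_profile.tsv"
    table.to_csv(path, sep="\t", index=False, float_format="%.5g")
    print(table.to_string(index=False))
    expected = [0.5 * (3 * t - 1) for t in COS2_TARGETS]
    worst = float(np.max(np.abs(table["smol"].to_numpy() - expected)))
    print(f"max |Smol - prescribed| = {worst:.4f} "
          f"(block errors ~{table['block_error'].mean():.4f})")

    hb = hbond_demo()
    hb_table = hb.table()
    hb_path = OUT / "md_hbonds.tsv"
    hb_table.to_csv(hb_path, sep="\t", index=False, float_format="%.4g")
    print()
    print(hb_table.to_string(index=False))
    print("only the membrane-resident donor is counted: the expelled molecule")
    print("is excluded by the phosphate-plane z-band filter.")
    print(f"tables -> {path}, {hb_path}")


if __name__ == "__main__":
    main()
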