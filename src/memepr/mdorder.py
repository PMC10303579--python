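"""Acyl-chain order parameters and hydrogen-bond counts from trajectory frames.

The molecular order parameter of chain carbon n is

    Smol(n) = 0.5 · (3⟨cos²θn⟩ − 1)

where θn is the instantaneous angle between the segmental vector joining
carbons n−1 and n+1 and the bilayer normal, averaged over molecules and
frames.  Smol spans [−0.5, 1]: 1 for a segment aligned with the normal, 0
for isotropic wobbling, −0.5 for in-plane segments.  Errors are standard
errors over equal contiguous trajectory blocks (default 7).

For an sp² (double-bond) carbon pair (Ci, Cj) the segmental vectors are
taken along C(i−1)→Cj and Ci→C(j+1).  For adjacent pairs this coincides
with the plain (n−1, n+1) definition, so for standard chain topologies the
convention changes which carbons are *flagged* rather than the numbers;
the flag can be toggled off for sensitivity checks.

Hydrogen bonds use geometric criteria (donor–acceptor distance and
H–donor–acceptor angle); counts are reported per acceptor class with
mean ± sd over frames, optionally restricted to membrane-resident donor
molecules through a z-band rule around the phosphate planes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mdframes import TrajectoryFrames

__all__ = [
    "ChainTopology",
    "SmolProfile",
    "HBondCriteria",
    "HBondResult",
    "MdOrderError",
    "smol_profile",
    "count_hbonds",
    "resident_mask",
    "phosphate_z_band",
    "synth_trajectory",
]


class MdOrderError(ValueError):
    """Invalid MD post-processing input."""


@dataclass
class ChainTopology:
    """Ordered carbon names per chain and the double-bonded index pairs.

    ``double_bond_pairs`` maps a chain name to (i, j) 0-based index pairs of
    sp² carbons; pairs must be adjacent in the chain ordering.
    """

    chains: Mapping[str, Sequence[str]]
    double_bond_pairs: Mapping[str, Sequence[tuple[int, int]]] = field(
        default_factory=dict
    )
    resname: Optional[str] = None  # restrict to molecules of this residue name

    def __post_init__(self) -> None:
        for chain, carbons in self.chains.items():
            if len(carbons) < 3:
                raise MdOrderError(
                    f"chain {chain!r} has {len(carbons)} carbons; the segmental "
                    "vector needs at least 3"
                )
        for chain, pairs in self.double_bond_pairs.items():
            if chain not in self.chains:
                raise MdOrderError(f"double-bond pairs name unknown chain {chain!r}")
            n = len(self.chains[chain])
            for i, j in pairs:
                if j != i + 1:
                    raise MdOrderError(
                        f"double-bond pair ({i}, {j}) in chain {chain!r} is not adjacent"
                    )
                if i < 0 or j >= n:
                    raise MdOrderError(
                        f"double-bond pair ({i}, {j}) outside chain {chain!r}"
                    )


@dataclass
class SmolProfile:
    """Per-chain, per-carbon molecular order parameters with block errors."""

    chains: dict[str, dict]  # chain -> {carbons, smol, block_error, mean_cos2, ...}
    n_blocks: int

    def table(self) -> pd.DataFrame:
        rows = []
        for chain, data in self.chains.items():
            for k, carbon in enumerate(data["carbons"]):
                rows.append(
                    {
                        "chain": chain,
                        "carbon": carbon,
                        "carbon_index": data["indices"][k],
                        "smol": data["smol"][k],
                        "block_error": data["block_error"][k],
                        "double_bond": data["indices"][k] in data["double_bond_carbons"],
                    }
                )
        return pd.DataFrame(rows)


def _segment_vectors(
    pos: np.ndarray, pairs: Sequence[tuple[int, int]], use_correction: bool
) -> tuple[np.ndarray, list[int]]:
    """Segmental vectors for interior carbons of one chain.

    ``pos``: (n_frames, n_mol, n_carbons, 3).  Returns vectors of shape
    (n_frames, n_mol, n_interior, 3) and the flagged sp² carbon indices.
    """
    n_carbons = pos.shape[2]
    lo = pos[:, :, :-2, :]  # carbon n-1 for interior n = 1..n_carbons-2
    hi = pos[:, :, 2:, :]  # carbon n+1
    vectors = hi - lo
    flagged: list[int] = []
    if use_correction:
        for i, j in pairs:
            # vector for Ci along C(i-1) -> Cj, for Cj along Ci -> C(j+1);
            # for adjacent pairs these equal the plain segmental vectors, so
            # only interior membership and flagging can differ.
            if 1 <= i <= n_carbons - 2:
                vectors[:, :, i - 1, :] = pos[:, :, j, :] - pos[:, :, i - 1, :]
                flagged.append(i)
            if 1 <= j <= n_carbons - 2:
                vectors[:, :, j - 1, :] = pos[:, :, j + 1, :] - pos[:, :, i, :]
                flagged.append(j)
    return vectors, flagged


def smol_profile(
    frames: TrajectoryFrames,
    topo: ChainTopology,
    n_blocks: int = 7,
    double_bond_correction: bool = True,
) -> SmolProfile:
    """Compute Smol per chain carbon, averaged over molecules and frames.

    Block standard errors are taken over ``n_blocks`` equal contiguous
    frame blocks (trailing remainder frames are dropped from the error
    estimate only; the mean uses every frame).
    """
    if n_blocks < 2:
        raise MdOrderError("need at least 2 blocks for a block error")
    index = frames.atom_index()
    axis = frames.normal_axis
    results: dict[str, dict] = {}
    if topo.resname is None:
        candidate_mols = sorted(set(int(m) for m in frames.mol_ids))
    else:
        candidate_mols = sorted(
            set(
                int(m)
                for m, r in zip(frames.mol_ids, frames.resnames)
                if str(r) == topo.resname
            )
        )
    for chain, carbons in topo.chains.items():
        carbons = list(carbons)
        mol_rows = []
        for mol in candidate_mols:
            try:
                rows = [index[(mol, name)] for name in carbons]
            except KeyError as exc:
                missing = exc.args[0]
                if all((mol, name) not in index for name in carbons):
                    continue  # molecule lacks this chain entirely
                raise MdOrderError(
                    f"molecule {mol} is missing chain atom {missing[1]!r} "
                    f"of chain {chain!r}"
                )
            mol_rows.append(rows)
        if not mol_rows:
            raise MdOrderError(f"no molecule carries chain {chain!r}")
        pos = frames.coords[:, np.array(mol_rows), :]  # (F, M, C, 3)
        pairs = list(topo.double_bond_pairs.get(chain, ()))
        vectors, flagged = _segment_vectors(pos, pairs, double_bond_correction)
        norm = np.linalg.norm(vectors, axis=-1)
        if np.any(norm == 0):
            raise MdOrderError(f"zero-length segmental vector in chain {chain!r}")
        cos2 = (vectors[..., axis] / norm) ** 2  # (F, M, N_interior)
        mean_cos2 = cos2.mean(axis=(0, 1))
        smol = 0.5 * (3.0 * mean_cos2 - 1.0)
        n_frames = cos2.shape[0]
        block_len = n_frames // n_blocks
        if block_len < 1:
            raise MdOrderError(
                f"{n_frames} frames cannot form {n_blocks} blocks"
            )
        trimmed = cos2[: block_len * n_blocks]
        blocks = trimmed.reshape(n_blocks, block_len, *cos2.shape[1:])
        block_smol = 0.5 * (3.0 * blocks.mean(axis=(1, 2)) - 1.0)  # (B, N)
        block_error = block_smol.std(axis=0, ddof=1) / math.sqrt(n_blocks)
        results[chain] = {
            "carbons": carbons[1:-1],
            "indices": list(range(1, len(carbons) - 1)),
            "smol": smol,
            "block_error": block_error,
            "mean_cos2": mean_cos2,
            "double_bond_carbons": set(flagged),
            "n_molecules": len(mol_rows),
        }
    return SmolProfile(chains=results, n_blocks=n_blocks)


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criteria (defaults: 3.5 Å, 30°)."""

    distance_cutoff: float = 3.5
    angle_cutoff_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise MdOrderError("distance cutoff must be positive")
        if not 0.0 < self.angle_cutoff_deg <= 90.0:
            raise MdOrderError("angle cutoff must lie in (0, 90] degrees")


def _min_image(delta: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def _frame_counts(
    coords: np.ndarray,
    box: Optional[np.ndarray],
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    criteria: HBondCriteria,
) -> int:
    """H-bond count in one frame via a periodic KD-tree neighbour search."""
    d_xyz = coords[donors]
    a_xyz = coords[acceptors]
    if box is not None:
        wrap = lambda p: np.mod(p, box)
        tree = cKDTree(wrap(a_xyz), boxsize=box)
        candidates = tree.query_ball_point(wrap(d_xyz), criteria.distance_cutoff)
    else:
        tree = cKDTree(a_xyz)
        candidates = tree.query_ball_point(d_xyz, criteria.distance_cutoff)
    cos_cut = math.cos(math.radians(criteria.angle_cutoff_deg))
    count = 0
    for k, neighbours in enumerate(candidates):
        if not neighbours:
            continue
        d = coords[donors[k]]
        h = coords[hydrogens[k]]
        dh = _min_image(h - d, box)
        dh_norm = np.linalg.norm(dh)
        for idx in neighbours:
            acc = acceptors[idx]
            if acc == donors[k] or acc == hydrogens[k]:
                continue
            da = _min_image(a_xyz[idx] - d, box)
            da_norm = np.linalg.norm(da)
            if da_norm == 0 or dh_norm == 0:
                continue
            cos_angle = float(np.dot(dh, da) / (dh_norm * da_norm))
            if cos_angle >= cos_cut:
                count += 1
    return count


@dataclass
class HBondResult:
    """Per-acceptor-class H-bond statistics over frames."""

    classes: tuple[str, ...]
    per_frame: np.ndarray  # (n_frames, n_classes), possibly normalized
    normalizer: Optional[np.ndarray]  # per-frame molecule count or None

    @property
    def means(self) -> np.ndarray:
        return self.per_frame.mean(axis=0)

    @property
    def sds(self) -> np.ndarray:
        return self.per_frame.std(axis=0, ddof=1 if self.per_frame.shape[0] > 1 else 0)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"acceptor_class": self.classes, "mean": self.means, "sd": self.sds}
        )


def phosphate_z_band(
    frames: TrajectoryFrames,
    phosphate_indices: Sequence[int],
    margin: float = 5.0,
) -> np.ndarray:
    """Per-frame membrane z-band: [lower phosphate plane − margin, upper + margin].

    Leaflets are split by the per-frame median phosphate z.
    """
    z = frames.coords[:, np.asarray(phosphate_indices, dtype=int), frames.normal_axis]
    mid = np.median(z, axis=1, keepdims=True)
    lower = np.where(z <= mid, z, np.nan)
    upper = np.where(z > mid, z, np.nan)
    lo = np.nanmean(lower, axis=1) - margin
    hi = np.nanmean(upper, axis=1) + margin
    return np.stack([lo, hi], axis=1)


def resident_mask(
    frames: TrajectoryFrames,
    mol_ids: Sequence[int],
    z_band: np.ndarray,
) -> np.ndarray:
    """(n_frames, n_mols) mask: molecule COM inside the per-frame z band."""
    z_band = np.asarray(z_band, dtype=float)
    if z_band.ndim == 1:
        z_band = np.broadcast_to(z_band, (frames.n_frames, 2))
    mask = np.empty((frames.n_frames, len(mol_ids)), dtype=bool)
    for m, mol in enumerate(mol_ids):
        rows = np.flatnonzero(frames.mol_ids == mol)
        if rows.size == 0:
            raise MdOrderError(f"unknown molecule id {mol}")
        com_z = frames.coords[:, rows, frames.normal_axis].mean(axis=1)
        mask[:, m] = (com_z >= z_band[:, 0]) & (com_z <= z_band[:, 1])
    return mask


def count_hbonds(
    frames: TrajectoryFrames,
    criteria: HBondCriteria,
    donors: Sequence[tuple[int, int]],
    acceptors_by_class: Mapping[str, Sequence[int]],
    donor_frame_mask: Optional[np.ndarray] = None,
    per_molecule: bool = False,
) -> HBondResult:
    """Count hydrogen bonds per frame, broken out by acceptor class.

    Parameters
    ----------
    donors : (donor_atom_index, hydrogen_atom_index) pairs.
    acceptors_by_class : acceptor class name -> acceptor atom indices
        (e.g. phosphate Op, carbonyl Oc, water, retinoid oxygens).
    donor_frame_mask : optional (n_frames, n_donors) mask selecting the
        donors active in each frame (e.g. membrane-resident retinoids).
    per_molecule : divide each frame's count by the number of distinct
        active donor molecules that frame (Table-style per-molecule means).
    """
    donors = np.asarray(donors, dtype=int)
    if donors.size == 0:
        raise MdOrderError("empty donor set")
    if donors.ndim != 2 or donors.shape[1] != 2:
        raise MdOrderError("donors must be (donor_index, hydrogen_index) pairs")
    if any(len(v) == 0 for v in acceptors_by_class.values()) or not acceptors_by_class:
        raise MdOrderError("empty acceptor set")
    for name, idxs in acceptors_by_class.items():
        if np.max(idxs) >= frames.n_atoms or np.min(idxs) < 0:
            raise MdOrderError(f"acceptor class {name!r} names unknown atoms")
    if np.max(donors) >= frames.n_atoms or np.min(donors) < 0:
        raise MdOrderError("donor assignment names unknown atoms")
    classes = tuple(acceptors_by_class)
    per_frame = np.zeros((frames.n_frames, len(classes)))
    normalizer = np.zeros(frames.n_frames) if per_molecule else None
    for f in range(frames.n_frames):
        box = frames.box[f] if frames.box is not None else None
        if donor_frame_mask is not None:
            active = donors[donor_frame_mask[f]]
        else:
            active = donors
        if per_molecule:
            mols = np.unique(frames.mol_ids[active[:, 0]]) if active.size else []
            normalizer[f] = len(mols)
        if active.size == 0:
            continue
        for c, name in enumerate(classes):
            per_frame[f, c] = _frame_counts(
                frames.coords[f],
                box,
                active[:, 0],
                active[:, 1],
                np.asarray(acceptors_by_class[name], dtype=int),
                criteria,
            )
    if per_molecule:
        with np.errstate(invalid="ignore", divide="ignore"):
            per_frame = np.where(
                normalizer[:, None] > 0, per_frame / np.maximum(normalizer, 1)[:, None], 0.0
            )
    return HBondResult(classes=classes, per_frame=per_frame, normalizer=normalizer)


def _sample_cos_theta(rng: np.random.Generator, target: float, size: int) -> np.ndarray:
    """Sample cosθ with E[cos²θ] = target from a one-parameter uniform family.

    target >= 1/3: |cosθ| ~ U[a, 1] with a = (−1 + √(12t − 3))/2;
    target <  1/3: |cosθ| ~ U[0, √(3t)].  Signs are random.  target = 1/3 is
    the isotropic uniform-in-cosθ distribution; target = 1 is degenerate
    (all segments along the normal).
    """
    if not 0.0 <= target <= 1.0:
        raise MdOrderError(f"target <cos^2 theta> must lie in [0, 1], got {target}")
    if target >= 1.0:
        mag = np.ones(size)
    elif target >= 1.0 / 3.0:
        a = (-1.0 + math.sqrt(12.0 * target - 3.0)) / 2.0
        mag = rng.uniform(a, 1.0, size)
    else:
        mag = rng.uniform(0.0, math.sqrt(3.0 * target), size)
    sign = rng.choice([-1.0, 1.0], size)
    return sign * mag


def synth_trajectory(
    cos2_targets: Sequence[float],
    n_molecules: int = 100,
    n_frames: int = 50,
    seed: int = 0,
    segment_length: float = 2.5,
    resname: str = "CHN",
    grid_spacing: float = 8.0,
) -> TrajectoryFrames:
    """Generate chain frames whose segmental vectors realise prescribed ⟨cos²θ⟩.

    ``cos2_targets[k]`` prescribes the orientation distribution of interior
    carbon k+1 (0-based); the chain has ``len(cos2_targets) + 2`` carbons.
    Carbons are placed so that the (n−1, n+1) segmental vectors *are* the
    sampled orientation vectors (even- and odd-index carbons accumulate two
    interleaved walks), making the generator an exact ground truth for
    :func:`smol_profile`.  Deterministic under ``seed``.
    """
    targets = [float(t) for t in cos2_targets]
    if not targets:
        raise MdOrderError("need at least one target")
    for t in targets:
        if not 0.0 <= t <= 1.0:
            raise MdOrderError(f"infeasible target {t}; must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_carbons = len(targets) + 2
    n_interior = len(targets)
    # orientation vectors per (frame, molecule, interior carbon)
    cos_t = np.stack(
        [
            _sample_cos_theta(rng, t, n_frames * n_molecules).reshape(
                n_frames, n_molecules
            )
            for t in targets
        ],
        axis=-1,
    )
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = rng.uniform(0.0, 2.0 * np.pi, cos_t.shape)
    vec = segment_length * np.stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=-1
    )  # (F, M, N_int, 3)
    # interleaved accumulation: r[n+1] = r[n-1] + v[n]
    side = int(np.ceil(np.sqrt(n_molecules)))
    origins = np.array(
        [
            [grid_spacing * (m % side), grid_spacing * (m // side), 30.0]
            for m in range(n_molecules)
        ]
    )
    pos = np.zeros((n_frames, n_molecules, n_carbons, 3))
    pos[:, :, 0, :] = origins[None, :, :]
    pos[:, :, 1, :] = origins[None, :, :] + np.array([0.5, 0.5, 1.0])
    for n in range(1, n_carbons - 1):
        pos[:, :, n + 1, :] = pos[:, :, n - 1, :] + vec[:, :, n - 1, :]
    extent = grid_spacing * side + 20.0
    box = np.tile(
        np.array([extent, extent, 60.0 + 3.0 * n_carbons]), (n_frames, 1)
    )
    mol_ids = np.repeat(np.arange(1, n_molecules + 1), n_carbons)
    atom_names = np.array(
        [f"C{k + 1}" for _ in range(n_molecules) for k in range(n_carbons)],
        dtype=object,
    )
    resnames = np.array([resname] * (n_molecules * n_carbons), dtype=object)
    coords = pos.reshape(n_frames, n_molecules * n_carbons, 3)
    return TrajectoryFrames(
        mol_ids=mol_ids,
        resnames=resnames,
        atom_names=atom_names,
        coords=coords,
        box=box,
    )
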