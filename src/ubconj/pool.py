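"""Random conformer pools for a two-rigid-body conjugate with a flexible linker.

Each conformer keeps the substrate rigid body fixed in its input frame, grows
the linker — a lysine side-chain pseudo-bead (the isopeptide joint at Nz)
followed by the flexible ubiquitin tail 76..73 — bead by bead with random
directions under a pseudo-bond-angle constraint, and finally attaches the
ubiquitin 1-72 rigid body in a random orientation at the tail end. Conformers
are self-avoiding: any non-bonded bead pair from different segments must be
at least the clash distance apart. Sampling is counter-based (one substream
per conformer index), so pools are bit-reproducible and independent of
generation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from ubconj.linearize import UBIQUITIN_LENGTH, LinearizedModel
from ubconj.structures import BeadStructure, radius_of_gyration

__all__ = [
    "LinkerParams",
    "Conformer",
    "ConformerPool",
    "SamplingError",
    "generate_conformer",
    "generate_pool",
]


class SamplingError(RuntimeError):
    """Raised when a clash-free conformer cannot be grown within the attempt budget."""


@dataclass(frozen=True)
class LinkerParams:
    """Geometry of the flexible joint between the two rigid bodies.

    bond_length : CA-CA virtual bond, Å (3.8 is the trans peptide value).
    angle_range : pseudo-bond angle bounds in degrees; sampled uniformly.
    clash_distance : minimum allowed distance between non-bonded beads, Å.
    spacer_length : substrate CA -> isopeptide joint pseudo-bead distance, Å
        (one bead approximating the lysine side-chain reach to Nz).
    max_attempts : whole-conformer regrowth budget before giving up.
    """

    bond_length: float = 3.8
    angle_range: tuple[float, float] = (90.0, 145.0)
    clash_distance: float = 3.4
    spacer_length: float = 4.0
    max_attempts: int = 200

    def __post_init__(self) -> None:
        if self.bond_length <= 0:
            raise ValueError("bond_length must be > 0")
        if self.clash_distance >= 2 * self.bond_length:
            raise ValueError("clash_distance must be < 2 * bond_length")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


@dataclass
class Conformer:
    """One pool member: beads in linearized numbering plus cached Rg/Dmax (Å)."""

    beads: BeadStructure
    seed_record: tuple
    rg: float
    dmax: float


@dataclass
class ConformerPool:
    conformers: list[Conformer]
    params: LinkerParams
    seed: int

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def rg(self) -> np.ndarray:
        return np.array([c.rg for c in self.conformers])

    @property
    def dmax(self) -> np.ndarray:
        return np.array([c.dmax for c in self.conformers])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.sqrt(v @ v)


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.array(
        [a[1] * b[2] - a[2] * b[1], a[2] * b[0] - a[0] * b[2], a[0] * b[1] - a[1] * b[0]]
    )


def _bond_direction(prev: np.ndarray, params: LinkerParams, rng: np.random.Generator) -> np.ndarray:
    """New bond direction at a uniform pseudo-bond angle to the previous bond."""
    theta = np.deg2rad(rng.uniform(*params.angle_range))
    phi = np.pi - theta  # deflection from the previous bond direction
    psi = rng.uniform(0.0, 2.0 * np.pi)
    u = prev / np.sqrt(prev @ prev)
    # orthonormal frame around u
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _cross(u, a)
    e1 /= np.sqrt(e1 @ e1)
    e2 = _cross(u, e1)
    return np.cos(phi) * u + np.sin(phi) * (np.cos(psi) * e1 + np.sin(psi) * e2)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (Shoemake quaternion method)."""
    u1, u2, u3 = rng.uniform(size=3)
    q = np.array(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ]
    )
    x, y, z, w = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _clashes(new_pts: np.ndarray, placed: np.ndarray, clash: float) -> bool:
    if placed.size == 0 or new_pts.size == 0:
        return False
    return bool((cdist(np.atleast_2d(new_pts), placed) < clash).any())


def generate_conformer(
    model: LinearizedModel, params: LinkerParams, rng: np.random.Generator,
    seed_record: tuple = (),
) -> Conformer:
    """Grow one clash-free conformer of the linearized conjugate.

    The substrate stays at its input frame; the linker (joint pseudo-bead,
    then ubiquitin 76, 75, 74, 73) is grown bead by bead; the ubiquitin 1-72
    rigid body is attached at residue 73 in a random orientation. The whole
    growth is resampled on clash failure, up to ``params.max_attempts``.

    Raises
    ------
    SamplingError
        If no clash-free conformer is found within the attempt budget; the
        error message carries ``seed_record`` for reproduction.
    """
    beads = model.beads
    new_ids = beads.res_ids
    ub_core_idx = np.flatnonzero(new_ids <= 72)
    sub_idx = np.flatnonzero(new_ids >= UBIQUITIN_LENGTH + 1)
    ub_template = beads.coords[ub_core_idx]  # residues 1..72 in order
    sub_coords = beads.coords[sub_idx]
    attach_pos = beads.coords[new_ids == UBIQUITIN_LENGTH + 1][0]

    n_tail = len(model.flexible)  # ubiquitin 76..73 grown in reverse order
    bl, clash = params.bond_length, params.clash_distance
    clash2 = clash * clash
    n_sub = sub_coords.shape[0]
    attach_row = int(np.flatnonzero(new_ids[sub_idx] == UBIQUITIN_LENGTH + 1)[0])
    # fixed-layout clash reference: substrate rows, then joint, then tail beads
    ref = np.empty((n_sub + 1 + n_tail, 3))
    ref[:n_sub] = sub_coords

    def _min_d2(point: np.ndarray, block: np.ndarray, skip: int | None = None) -> float:
        d = block - point
        d2 = np.einsum("ij,ij->i", d, d)
        if skip is not None:
            d2[skip] = np.inf
        return float(d2.min()) if d2.size else np.inf

    for _attempt in range(params.max_attempts):
        ok = True

        # lysine side-chain pseudo-bead (isopeptide joint); bonded to the
        # attachment CA, which is exempt from the clash check
        for _ in range(30):
            joint = attach_pos + params.spacer_length * _random_unit(rng)
            if params.spacer_length == 0.0 or _min_d2(joint, ref[:n_sub], attach_row) >= clash2:
                break
        else:
            continue
        ref[n_sub] = joint

        # flexible tail: ubiquitin 76, 75, 74, 73
        prev_bond = joint - attach_pos
        if prev_bond @ prev_bond < 1e-18:
            prev_bond = _random_unit(rng)
        prev_pos = joint
        for t in range(n_tail):
            n_placed = n_sub + 1 + t  # rows of ref currently valid
            for _ in range(30):
                direction = _bond_direction(prev_bond, params, rng)
                cand = prev_pos + bl * direction
                # the immediately preceding bead is bonded: last valid row
                if _min_d2(cand, ref[:n_placed], n_placed - 1) >= clash2:
                    break
            else:
                ok = False
                break
            ref[n_placed] = cand
            prev_bond = cand - prev_pos
            prev_pos = cand
        if not ok:
            continue
        tail = ref[n_sub + 1 : n_sub + 1 + n_tail].copy()

        # rigid ubiquitin core: residue 72 bonds to residue 73 (= tail[-1])
        for _ in range(60):
            direction = _bond_direction(prev_bond, params, rng)
            anchor = prev_pos + bl * direction  # where residue 72 goes
            R = _random_rotation(rng)
            core = (ub_template - ub_template[71]) @ R.T + anchor
            dmat = cdist(core, ref)
            # residue 72 is bonded to residue 73, the last reference row
            dmat[71, -1] = np.inf
            if not (dmat < clash).any():
                break
        else:
            continue

        # assemble beads in linearized order: Ub 1..72, tail 73..76, substrate, joint
        coords = np.empty((len(beads) + 1, 3))
        coords[ub_core_idx] = core
        tail_rev = tail[::-1]  # stored order is residue 73, 74, 75, 76
        flex_idx = np.flatnonzero((new_ids >= 73) & (new_ids <= 76))
        coords[flex_idx] = tail_rev
        coords[sub_idx] = sub_coords
        coords[-1] = joint
        out = BeadStructure(
            chain_ids=list(beads.chain_ids) + ["X"],
            res_ids=np.concatenate([beads.res_ids, [1]]),
            res_names=list(beads.res_names) + ["LYS"],
            coords=coords,
            label=beads.label + " conformer",
        )
        rg = radius_of_gyration(out)
        dmax = float(pdist(coords).max())
        return Conformer(beads=out, seed_record=seed_record, rg=rg, dmax=dmax)

    raise SamplingError(
        f"no clash-free conformer within {params.max_attempts} attempts "
        f"(seed record {seed_record!r})"
    )


def substream(seed: int, index: int) -> np.random.Generator:
    """The per-conformer random substream: counter-based, order-independent."""
    return np.random.default_rng([seed, index])


def generate_pool(
    model: LinearizedModel, n: int, params: LinkerParams | None = None, seed: int = 0
) -> ConformerPool:
    """Generate ``n`` independent conformers from per-index substreams of ``seed``.

    Equal ``(model, params, seed)`` always reproduce the identical pool.
    Sampling failures are re-raised with the failing conformer index.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or LinkerParams()
    conformers = []
    for i in range(n):
        try:
            conformers.append(
                generate_conformer(model, params, substream(seed, i), seed_record=(seed, i))
            )
        except SamplingError as exc:
            raise SamplingError(f"conformer {i}: {exc}") from exc
    return ConformerPool(conformers=conformers, params=params, seed=seed)
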