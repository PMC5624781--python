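"""Branched-to-linear re-representation of a monoubiquitinated protein.

Ensemble-optimization tools for flexible multidomain proteins expect a single
linear chain with rigid domains and flexible residues. A monoubiquitinated
protein is branched: ubiquitin G76 is attached through an isopeptide bond to
the Nz of a substrate lysine. The conjugate is re-expressed as one linear
chain in four steps:

1. the sequence starts with ubiquitin 1-76, followed by the substrate from
   the attachment lysine k to its C-terminus, then the substrate N-terminus
   up to residue k-1;
2. substrate residues are renumbered to match that order (residue k becomes
   76 + 1 = 77);
3. ubiquitin's C-terminal tail 73-76 is designated flexible (it carries no
   secondary structure; Arg72 closes the last beta strand and stays rigid);
4. the native isopeptide linkage is assumed at the joint.

This module records the topology only; linker geometry is sampled in
:mod:`ubconj.pool`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ubconj.structures import BeadStructure

__all__ = [
    "ConjugateSpec",
    "LinearizedModel",
    "renumber_map",
    "build_linearized_model",
    "emit_eom_inputs",
    "THREE_TO_ONE",
]

UBIQUITIN_LENGTH = 76
#: flexible C-terminal tail of ubiquitin (LRGG), 1-based ubiquitin numbering
FLEXIBLE_UB_RESIDUES = (73, 74, 75, 76)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}


@dataclass
class ConjugateSpec:
    """A substrate with one ubiquitin attached at residue ``site``.

    ``substrate`` and ``ubiquitin`` are CA-bead structures; ``ubiquitin`` must
    have exactly 76 residues. The attachment residue must be a lysine unless
    ``allow_non_lysine`` is set (atypical serine ubiquitination exists but the
    lysine isopeptide is the default contract).
    """

    substrate: BeadStructure
    ubiquitin: BeadStructure
    site: int
    linkage: str = "isopeptide"
    allow_non_lysine: bool = False

    def __post_init__(self) -> None:
        if len(self.ubiquitin) != UBIQUITIN_LENGTH:
            raise ValueError(
                f"ubiquitin must have {UBIQUITIN_LENGTH} residues, got {len(self.ubiquitin)}"
            )
        L = len(self.substrate)
        if not 1 <= self.site <= L:
            raise IndexError(f"attachment site {self.site} outside substrate 1..{L}")
        if self.linkage != "isopeptide":
            raise ValueError(f"unsupported linkage {self.linkage!r}")
        resname = self.substrate.res_names[self.site - 1]
        if resname != "LYS" and not self.allow_non_lysine:
            raise ValueError(
                f"attachment residue {self.site} is {resname}, not LYS "
                "(set allow_non_lysine=True to override)"
            )


@dataclass
class LinearizedModel:
    """The conjugate re-expressed as one renumbered linear chain.

    ``order`` lists ``(source, source_residue_index, new_index)`` triples in
    linearized order; new indices are a bijection onto 1..76+L with ubiquitin
    occupying 1..76 and the attachment residue at 77. ``beads`` holds the
    reordered coordinates (chain 'A', new numbering). ``rigid_ub`` /
    ``rigid_substrate`` are new-index tuples of the two rigid bodies;
    ``flexible`` is the new-index tuple of ubiquitin 73-76.
    """

    order: list[tuple[str, int, int]]
    beads: BeadStructure
    rigid_ub: tuple[int, ...]
    rigid_substrate: tuple[int, ...]
    flexible: tuple[int, ...]
    site: int
    substrate_length: int

    @property
    def length(self) -> int:
        return UBIQUITIN_LENGTH + self.substrate_length

    @property
    def attachment_new_index(self) -> int:
        return UBIQUITIN_LENGTH + 1


def renumber_map(L: int, k: int) -> dict[int, int]:
    """Map old substrate residue index -> new linearized index.

    Substrate residues k..L follow ubiquitin directly (k -> 77), and residues
    1..k-1 are appended after the C-terminus:

    old i >= k -> 76 + (i - k + 1); old i < k -> 76 + (L - k + 1) + i.

    The map is a bijection of 1..L onto 77..76+L for every 1 <= k <= L.
    """
    if not 1 <= k <= L:
        raise IndexError(f"site {k} outside 1..{L}")
    out = {}
    for i in range(1, L + 1):
        if i >= k:
            out[i] = UBIQUITIN_LENGTH + (i - k + 1)
        else:
            out[i] = UBIQUITIN_LENGTH + (L - k + 1) + i
    return out


def build_linearized_model(spec: ConjugateSpec) -> LinearizedModel:
    """Apply the four-step construction to a conjugate spec.

    The output order is N-[Ub 1-76]-[substrate k..L]-[substrate 1..k-1]-C.
    Internal coordinates of the two rigid bodies (ubiquitin 1-72, full
    substrate) are copied unchanged from the inputs, so all intra-segment
    distances are preserved exactly.
    """
    L = len(spec.substrate)
    k = spec.site
    rmap = renumber_map(L, k)

    order: list[tuple[str, int, int]] = []
    for j in range(1, UBIQUITIN_LENGTH + 1):
        order.append(("ubiquitin", j, j))
    sub_old_order = list(range(k, L + 1)) + list(range(1, k))
    for i in sub_old_order:
        order.append(("substrate", i, rmap[i]))

    chain_ids = ["A"] * (UBIQUITIN_LENGTH + L)
    res_ids = np.array([new for _, _, new in order])
    res_names = [spec.ubiquitin.res_names[j - 1] for j in range(1, UBIQUITIN_LENGTH + 1)]
    res_names += [spec.substrate.res_names[i - 1] for i in sub_old_order]
    coords = np.vstack([spec.ubiquitin.coords, spec.substrate.coords[[i - 1 for i in sub_old_order]]])
    beads = BeadStructure(chain_ids, res_ids, res_names, coords,
                          label=f"linearized conjugate, site {k}")

    return LinearizedModel(
        order=order,
        beads=beads,
        rigid_ub=tuple(range(1, 73)),
        rigid_substrate=tuple(sorted(rmap.values())),
        flexible=FLEXIBLE_UB_RESIDUES,
        site=k,
        substrate_length=L,
    )


def emit_eom_inputs(model: LinearizedModel) -> tuple[str, str]:
    """Emit the (sequence, rigid-domain coordinate file) pair for the model.

    The sequence is the one-letter concatenation in linearized order. The
    coordinate file contains two rigid-domain blocks — ubiquitin 1-72 and the
    renumbered substrate — with the flexible ubiquitin tail 73-76 omitted;
    each block is a run of fixed-column ATOM records separated by TER.
    """
    seq = []
    for resname in model.beads.res_names:  # beads are stored in linearized order
        try:
            seq.append(THREE_TO_ONE[resname])
        except KeyError:
            raise ValueError(f"cannot translate residue name {resname!r}") from None
    sequence = "".join(seq)

    from ubconj.structures import write_pdb  # local import avoids cycle at module load

    new_ids = model.beads.res_ids
    ub_mask = new_ids <= 72
    sub_mask = new_ids >= UBIQUITIN_LENGTH + 1
    ub_block = write_pdb(model.beads.subset(ub_mask, label="ubiquitin core"))
    sub_block = write_pdb(model.beads.subset(sub_mask, label="substrate"))
    coord_text = ub_block.replace("END\n", "TER\n") + sub_block
    return sequence, coord_text
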