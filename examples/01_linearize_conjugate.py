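"""Re-express a monoubiquitinated GTPase as a single linear chain.

Ensemble-modelling tools expect one linear sequence with rigid domains, so
the branched conjugate (ubiquitin attached to a substrate lysine through an
isopeptide bond) is reordered: ubiquitin 1-76 first, then the substrate from
the attachment lysine to its C-terminus, then its N-terminal part.
"""

import numpy as np

import ubconj as u
from ubconj import synthetic as syn
from ubconj.linearize import emit_eom_inputs

# stand-ins for ubiquitin (76 residues) and a Rab5-sized substrate (215 residues)
ubiquitin = syn.make_dummy_rigid_body(76, 11.8, seed=1,
                                      res_names=["ALA"] * 75 + ["GLY"])
substrate = syn.make_dummy_rigid_body(215, 16.5, seed=2, res_names=["LYS"] * 215)

spec = u.ConjugateSpec(substrate=substrate, ubiquitin=ubiquitin, site=140)
model = u.build_linearized_model(spec)

print(f"conjugate length: {model.length} residues (76 ubiquitin + 215 substrate)")
print(f"attachment residue K140 is renumbered to {model.attachment_new_index}")
rm = u.renumber_map(215, 140)
print(f"substrate residue 139 (last before the split) becomes {rm[139]}")
print(f"flexible ubiquitin tail (new numbering): {model.flexible}")

sequence, coords = emit_eom_inputs(model)
n_atoms = sum(1 for line in coords.splitlines() if line.startswith("ATOM"))
print(f"emitted sequence of {len(sequence)} residues; "
      f"coordinate file holds {n_atoms} rigid beads "
      f"(the 4 flexible tail residues are omitted)")
# The renumbering is what lets a single-chain ensemble tool treat the
# ubiquitin moiety as just another domain of the substrate protein.
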