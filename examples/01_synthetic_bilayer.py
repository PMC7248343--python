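"""Build a striped phase-separated bilayer with adsorbed peptides.

The generator lays two leaflets of coarse-grained lipids on jittered
lattices: a saturated-lipid (DPPC) + cholesterol stripe stands in for the
liquid-ordered phase, an unsaturated (DLiPC) stripe for the disordered one.
Peptide backbones, solvent and neutralizing chloride are added on top, and
the analytic ground truth (stripe boundaries, planned oligomer orders) is
written alongside the coordinates.
"""

from memphase import synthgen as sg
from memphase.trajio import write_coordinates

spec = sg.MembraneSpec(box=(40.0, 10.0, 10.0), stripe_boundaries=(20.0,),
                       seed=1)
frame, truth = sg.build_stripe_bilayer(spec)

groups = (sg.PeptideGroup(order=2, gap=0.5, region="Ld"),
          sg.PeptideGroup(order=1, region="Lo"))
frame, plan = sg.add_peptides(
    frame, sg.PeptidePlacement(groups=groups, depth_offset=0.5, seed=1), truth)
frame = sg.add_solvent_and_ions(frame, seed=1)

write_coordinates(frame, "stripe_system.gro")
sg.ground_truth_sidecar("stripe_system.truth.json", membrane=truth,
                        peptides=plan)

n_lip = len(set(frame.molecule_ids[frame.classes() == "lipid"]))
print(f"beads: {frame.n_beads}, lipids: {n_lip}, "
      f"net charge: {frame.charges.sum():+.0f} e")
print(f"stripe dividers at x = {truth['boundaries']} nm "
      "(ground truth for the segmentation example)")
# every peptide's intended oligomer order is known, so cluster detection
# can be checked exactly
for p in plan:
    print(f"  planned {p['kind']} of order {p['order']} in {p['region']}")
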