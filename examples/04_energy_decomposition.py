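"""Dynamic-group nonbonded energy decomposition and its closure check.

The switched Lennard-Jones (0.9-1.2 nm) and shifted Coulomb (eps_r = 15)
potentials are summed between groups redefined every frame: lipids split by
phase (Ld/Lo, interfacial excluded) and peptide proximity (near/far within
the 1.2 nm cutoff), peptide residues split by region.  Summing the
discriminated peptide energies over regions must reproduce the single-pass
undiscriminated total — the closure check that validates the bookkeeping.
"""

from memphase import synthgen as sg
from memphase.energetics import closure_check, decompose, transfer_enthalpy
from memphase.phasemap import segment_frame

tables = []
for seed in range(10):
    spec = sg.MembraneSpec(box=(24.0, 8.0, 9.0), stripe_boundaries=(12.0,),
                           seed=seed)
    frame, truth = sg.build_stripe_bilayer(spec)
    groups = (sg.PeptideGroup(order=2, gap=0.5, region="Ld"),
              sg.PeptideGroup(order=1, region="Lo"),
              sg.PeptideGroup(order=1, region="Ld", leaflet="bottom"),
              sg.PeptideGroup(order=1, region="Lo", leaflet="bottom"))
    frame, _ = sg.add_peptides(
        frame, sg.PeptidePlacement(groups=groups, depth_offset=0.5, seed=seed),
        truth)
    frame = sg.add_solvent_and_ions(frame, seed=seed)
    if seed == 0:
        ff = sg.toy_forcefield(sorted(set(frame.bead_types)), seed=0)
    pm = segment_frame(frame)
    tab = decompose(frame, pm, ff)
    tables.append(tab)
    if seed == 0:
        cc = closure_check(frame, tab, ff)
        print(f"closure: |discriminated - total| = {cc['abs_diff']:.2e} "
              f"kJ/mol ({cc['rel_diff_ppm']:.2e} ppm)")
        print("meaning: region-split peptide energies add up to the "
              "one-pass total to floating-point accuracy")

st, meta = transfer_enthalpy(tables, n_boot=500, seed=0)
print(f"lipid-lipid transfer enthalpy Lo->Ld: {st.mean:+.1f} kJ/mol per "
      f"peptide (95% CI [{st.ci_low:+.1f}, {st.ci_high:+.1f}], "
      f"{meta['frames_used']} frames)")
print("meaning: the sign says which phase's lipid-lipid interactions are "
      "perturbed more by having a peptide nearby; on this toy force field "
      "it is a bookkeeping demonstration, not a physical prediction")
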