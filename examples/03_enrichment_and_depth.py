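"""Region enrichment ratios and peptide insertion depth.

Backbone beads are counted per region and normalized by the counts a
uniform-by-area distribution would give: a ratio of 1 means no preference,
3 means three-fold enrichment.  Depth is the z-distance of each backbone
bead to the center of mass of same-leaflet phosphates within 2 nm, positive
toward the solvent.
"""

from memphase import synthgen as sg
from memphase.partition import (assign_backbone_regions, enrichment_ratios,
                                insertion_depth)
from memphase.phasemap import segment_frame

frames, pms, asgs = [], [], []
for seed in range(8):
    spec = sg.MembraneSpec(seed=seed)
    frame, truth = sg.build_stripe_bilayer(spec)
    groups = (sg.PeptideGroup(order=1, region="Ld"),
              sg.PeptideGroup(order=1, region="Ld", leaflet="bottom"),
              sg.PeptideGroup(order=1, region="Lo"))
    frame, _ = sg.add_peptides(
        frame, sg.PeptidePlacement(groups=groups, depth_offset=0.3, seed=seed),
        truth)
    pm = segment_frame(frame)
    frames.append(frame)
    pms.append(pm)
    asgs.append(assign_backbone_regions(frame, pm))

rep = enrichment_ratios(asgs, pms, n_boot=500, seed=0)
print(rep.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("meaning: two of three peptides sit in Ld (~42% of the area) and one "
      "in Lo, so Ld shows ~1.6x enrichment and the interface, holding no "
      "peptides, is depleted to 0")

d = insertion_depth(frames[0])
ok = d.dropna(subset=["depth"])
print(f"mean depth: {ok.depth.mean():+.3f} nm "
      "(positive = toward solvent; peptides were placed 0.3 nm above the "
      "phosphate plane)")
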