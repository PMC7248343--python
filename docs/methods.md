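# Methods

This note documents the models, parameter choices and numerical conventions
behind `memphase`, and what its synthetic fixtures do and do not establish
about real trajectories.

## Scope and assumptions

The package analyzes coarse-grained configurations of a flat, orthorhombic,
periodic bilayer: phospholipids carry a PO4 phosphate, a GL1 glycerol and
C1A/C1B-led tails; cholesterol carries an ROH hydroxyl; peptides are chains
of BB backbone beads.  Membranes are assumed flat (no curvature or buckling
correction) and phase domains in registry across leaflets.  Molecule classes
(lipid / solvent / peptide) come from a configurable registry keyed on
molecule type, defaulting to {DPPC, DLiPC, CHOL} = lipid and
{W, WF, ions} = solvent, everything else peptide.  Coordinates are nm
throughout (GRO native); only orthorhombic boxes are accepted — triclinic
box lines are rejected rather than silently truncated.

## Phase segmentation

Fields: the first tail beads (C1A, C1B) of DPPC and of DLiPC are flattened
to xy, binned on a grid of spacing h = 0.1 nm, and convolved with an
isotropic Gaussian of σ = 1.0 nm under periodic wrap.  Binning + wrap
convolution is mathematically the same as padding with image copies and
cropping, but exact at every truncation level; the kernel is truncated at
max(pad/σ, 4σ).  Both leaflets are pooled by default (domains are in
registry); a per-leaflet mode exists for per-leaflet energetics.
Cholesterol never enters the fields.

Edges: Canny hysteresis detection runs on Δρ = ρ_DLiPC − ρ_DPPC, padded
periodically wider than the detector's full stencil reach so the crop is
exactly translation-equivariant.  Thresholds are 10% / 20% of the maximum
gradient of the normalized field.  The internal Canny smoothing defaults to
3 grid cells (0.3 nm): with less, single-frame bead-density ripple leaves
several local gradient maxima across the ~3 nm composition ramp and one
boundary is traced as multiple parallel lines (on the stripe fixture this
doubled the interface area).  3 cells is the smallest tested width that
makes the ramp gradient unimodal, and it does not measurably shift the
detected line (worst error on pure-stripe fixtures: half a cell, 0.05 nm).
All of these are exposed parameters.

Labels: cells whose center is within the interface radius (default 1.5 nm,
roughly two phosphate neighbor shells; robustness scanned over 1.2–2.0 nm)
of an edge cell are interface; remaining cells are Ld where Δρ > 0, Lo
where Δρ < 0, and the measure-zero tie Δρ = 0 goes to interface for
determinism.  Cells are half-open, origin at the box corner.  Region areas
are cell counts × h²; on the 0.1 nm grid the interface band is quantized to
one cell per boundary side, so the analytic 0.15 fraction of the
40 nm/1.5 nm fixture is measured as 0.155.

## Partitioning and depth

Backbone beads take the label of their containing cell (wrapped first,
never an error).  Enrichment normalizes observed per-region counts by
N·area_fraction; the identity Σ_r ratio_r·a_r = 1 holds per frame exactly
and is asserted in tests.  The default estimator averages per-frame ratios
over time (a pooled-counts mode is available; on static frames they agree).
Frames where a region has zero area are excluded for that region and
counted.  Peptides are counted bead-wise; a whole-peptide majority vote is
offered as a secondary statistic.

Depth = z(bead) − z(COM of same-leaflet phosphates within 2 nm xy), sign
flipped on the bottom leaflet so positive always points toward solvent
(config-flippable).  A bead with no phosphate in range is flagged
unassigned and excluded from averages.  Peptide leaflet comes from the
bead's z against the mean z of the local (2 nm) phosphates, consistent with
the depth metric.

The analysis window defaults to the final third of the frames, mirroring
the practice of analyzing only the equilibrated tail of long production
runs; `stats.frames_in_window(20_000, 30) = 666` reproduces the standard
20 μs / 30 ns-per-frame bookkeeping.

## Nonbonded energetics

The cutoff scheme is the shift function: for exponent p, inner radius r1
and cutoff rc (d = rc − r1),

    A = −p[(p+4)rc − (p+1)r1] / [rc^(p+2) d²]
    B =  p[(p+3)rc − (p+1)r1] / [rc^(p+2) d³]
    C =  1/rc^p − (A/3)d³ − (B/4)d⁴

    Φ_p(r) = r⁻ᵖ − C                     (r ≤ r1)
           = r⁻ᵖ − (A/3)(r−r1)³ − (B/4)(r−r1)⁴ − C   (r1 < r ≤ rc)
           = 0                           (r > rc)

with Φ and Φ′ both zero at rc.  LJ: V = 4εσ¹²Φ₁₂ − 4εσ⁶Φ₆ with
(r1, rc) = (0.9, 1.2) nm.  Coulomb: V = (f/ε_r)q_iq_jΦ₁ with r1 = 0,
ε_r = 15, f = 138.935 kJ·mol⁻¹·nm·e⁻².  A force-integration quadrature
oracle in the test suite pins the convention to 1e−9; (r1, rc) are
configurable.  No long-range corrections and no mesh electrostatics: the
model is strictly cutoff-based.

Pair enumeration uses a periodic k-d tree (falling back to brute force when
an edge is shorter than twice the cutoff), validated against the 27-image
all-pairs double loop by exact pair-set equality.  Pairs within one
molecule are excluded: this removes intrapeptide nonbonded contributions
and stands in for bonded-neighbor exclusions, which is adequate because all
reported quantities compare intermolecular groups.

Groups: per leaflet, lipids are classified by the label under their
reference bead (PO4; ROH for cholesterol, which has no phosphate) and as
near/far depending on whether any lipid bead is within the 1.2 nm cutoff
of any peptide bead.  Interfacial lipids are excluded from energy groups.
Cholesterol is assigned per frame to any leaflet whose phosphates come
within 2 nm of its hydroxyl (it can satisfy both; matching neither leaves
it unassigned and counted).  Cholesterol counts as a lipid in the near/far
normalization.  Empty groups keep their table row with NaN energies — a
null flag, never a zero.  The closure check — region-summed peptide–lipid
plus peptide–solvent energies vs. a single-pass total — agrees to
~1e−13 kJ/mol here (same code path, different summation grouping) and is
asserted against the engine-reference bars of 8×10⁻³ kJ/mol absolute and
3 ppm relative.

Transfer enthalpy (a package definition; the underlying figure-level
quantity has no published formula): per phase,
perturbation = (e_near − e_far) · N_near / N_peptides-in-phase with e the
per-lipid lipid–lipid energy of the near/far group summed over leaflets;
ΔH(Lo→Ld) = perturbation_Ld − perturbation_Lo, time-averaged with a
corrected-bootstrap CI.  Frames in which a phase holds no peptides are
excluded and counted — rare visits make the estimate meaningless.

## Clustering

The contact graph links backbone beads of distinct peptides within 0.6 nm.
Rule (i) seeds clusters from pairs with ≥ 3 contacting beads on *each*
side (which automatically excludes peptides shorter than 3 beads); rule
(ii) accretes a peptide when ≥ 3 of its beads touch ≥ 3 distinct cluster
beads, pooled across cluster members — the conjunction reading; a looser
single-condition mode is exposed; rule (iii) merges clusters sharing
peptides.  Accretion iterates to a fixed point in ascending molecule-id
order, so the result is deterministic and independent of input order.
Distributions are reported as the fraction of all peptides per oligomer
order, k·n_k/N, which sums to 1 per frame.

## Statistics

IACT: τ = 1 + 2Σρ(k) truncated at the first non-positive empirical
autocorrelation (parameter-free, standard; the estimator is pluggable),
clamped to [1, n]; a constant series is degenerate with τ = 1.  The
corrected bootstrap draws n_eff = max(1, round(n/τ)) points per resample —
round() reproduces the 666 → 333 worked example — with percentile (not BCa)
95% intervals from 1000 resamples, fully seeded and bit-reproducible.
Coverage on iid Gaussian replicates measures 94–95%.

## Synthetic fixtures: what they show and what they do not

The generator builds striped bilayers (straight interfaces, analytically
known boundaries, continuous across y-periodicity), rigid straight peptide
backbones, lattice solvent and neutralizing chloride.  Defaults chosen once
at coarse-grained scales: 0.8 nm lipid lattice spacing (~0.64 nm² per
lipid), phosphate planes ±2.0 nm from the midplane, 0.35 nm backbone rise,
0.05 nm positional jitter, water bead density 8.35 nm⁻³ (4-to-1 mapped
bulk water), +6 e on an 11-residue peptide.  The toy force field draws a
symmetric pair table with ε ∈ [1, 6] kJ/mol and σ ∈ [0.43, 0.62] nm.
Cholesterol is placed preferentially in the saturated stripes, but
segmentation ground truth is defined by the phospholipid stripes alone,
matching the use of only DPPC/DLiPC tail beads in the fields.  A
displaced-cholesterol fixture (mid-membrane or mirrored) exercises leaflet
assignment.

These fixtures validate the *machinery* — segmentation accuracy, counting
identities, energy bookkeeping, cluster rules, CI calibration — against
exact ground truth.  They do not reproduce thermodynamics: lipids have no
conformational disorder, domains do not fluctuate, peptides do not
diffuse, and the toy force field is not parametrized against anything.
Passing tests therefore certify correct analysis of a given configuration,
not the biological numbers any particular force field would produce.
Problem sizes in the tests and the acceptance script (24–40 nm boxes,
~600–1200 lipids, 8–20 frames, 500 bootstrap-coverage replicates) are the
package's validation defaults.

## Known limitations

- No curved/buckled membrane support; segmentation is strictly 2D.
- No bonded terms, virial or forces — energies only.
- Whole-molecule nonbonded exclusions rather than bonded-neighbor
  exclusions (intermolecular comparisons are unaffected).
- The pooled-vs-per-frame enrichment averaging and the rule-(ii) pooling
  are genuinely underdetermined conventions; both modes are implemented
  and the defaults documented above.
- XTC reading requires MDAnalysis and carries that reader's conventions
  (Å → nm, ps → ns conversion at the boundary).
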