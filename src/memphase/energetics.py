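"""Cutoff nonbonded energetics between dynamically defined groups.

MD engines precompute their interaction groups, so they cannot decompose
energies by criteria that change every frame (which lipids are near a peptide,
which phase a residue sits in).  This module re-implements the coarse-grained
nonbonded potentials — Lennard-Jones switched to zero between 0.9 and 1.2 nm
and Coulomb with implicit dielectric screening (eps_r = 15) shifted to zero
from 0 to 1.2 nm — and sums them over bead pairs between arbitrary,
per-frame-defined groups.

The cutoff scheme is the classic shift function: a cubic+quartic polynomial
correction added to r^-p beyond an inner radius r1 so that the potential and
the force both go smoothly to zero at the cutoff rc.  For exponent p with
d = rc - r1:

    A = -p * ((p + 4) rc - (p + 1) r1) / (rc^(p+2) d^2)
    B =  p * ((p + 3) rc - (p + 1) r1) / (rc^(p+2) d^3)
    C =  1/rc^p - A/3 d^3 - B/4 d^4

    Phi_p(r) = r^-p - C                                    r <= r1
             = r^-p - A/3 (r-r1)^3 - B/4 (r-r1)^4 - C      r1 < r <= rc
             = 0                                           r > rc

LJ uses V = C12 Phi_12 - C6 Phi_6 with C12 = 4 eps sigma^12, C6 = 4 eps
sigma^6; Coulomb uses V = (f / eps_r) qi qj Phi_1 with r1 = 0.  No long-range
corrections and no mesh electrostatics: the model is strictly cutoff-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajio import Frame, minimum_image_displacement

__all__ = [
    "ForceFieldTable",
    "EnergyTable",
    "shifted_power_term",
    "shift_coefficients",
    "lj_energy",
    "coulomb_energy",
    "group_pair_energy",
    "leaflet_assignment",
    "classify_lipids",
    "decompose",
    "transfer_enthalpy",
    "apply_charges",
]

COULOMB_PREFACTOR = 138.935  # kJ mol^-1 nm e^-2


# -- force-field table -----------------------------------------------------


@dataclass
class ForceFieldTable:
    """Symmetric (eps, sigma) pair table plus electrostatics constants.

    ``pairs`` maps unordered bead-type pairs to (eps kJ/mol, sigma nm);
    lookup is symmetric.  ``charges`` maps bead types to default charges (e)
    for frames read from coordinate files, which carry none.
    """

    pairs: dict[tuple[str, str], tuple[float, float]]
    charges: dict[str, float] = field(default_factory=dict)
    dielectric: float = 15.0
    r1_lj: float = 0.9
    r_cut: float = 1.2
    prefactor: float = COULOMB_PREFACTOR

    def __post_init__(self) -> None:
        if not (0.0 <= self.r1_lj < self.r_cut):
            raise ValueError("need 0 <= r1 < r_cut")
        norm = {}
        for (a, b), (eps, sig) in self.pairs.items():
            if eps < 0 or sig <= 0:
                raise ValueError(f"bad (eps, sigma) for ({a}, {b}): {(eps, sig)}")
            key = (a, b) if a <= b else (b, a)
            if key in norm and norm[key] != (eps, sig):
                raise ValueError(f"conflicting entries for pair {key}")
            norm[key] = (eps, sig)
        self.pairs = norm

    def lookup(self, a: str, b: str) -> tuple[float, float]:
        key = (a, b) if a <= b else (b, a)
        try:
            return self.pairs[key]
        except KeyError:
            raise KeyError(f"no force-field entry for bead-type pair {key}") from None

    def types(self) -> list[str]:
        return sorted({t for pair in self.pairs for t in pair})

    # flat TSV persistence: keeps the package force-field-agnostic
    @classmethod
    def from_tsv(cls, pair_path, charge_path=None, **kwargs) -> "ForceFieldTable":
        df = pd.read_csv(pair_path, sep="\t", comment="#")
        pairs = {(str(r.typeA), str(r.typeB)): (float(r.eps), float(r.sigma))
                 for r in df.itertuples()}
        charges = {}
        if charge_path is not None:
            cdf = pd.read_csv(charge_path, sep="\t", comment="#")
            charges = {str(r.type): float(r.charge) for r in cdf.itertuples()}
        return cls(pairs=pairs, charges=charges, **kwargs)

    def to_tsv(self, pair_path, charge_path=None) -> None:
        rows = [{"typeA": a, "typeB": b, "eps": e, "sigma": s}
                for (a, b), (e, s) in sorted(self.pairs.items())]
        pd.DataFrame(rows).to_csv(pair_path, sep="\t", index=False)
        if charge_path is not None:
            pd.DataFrame(
                [{"type": t, "charge": q} for t, q in sorted(self.charges.items())]
            ).to_csv(charge_path, sep="\t", index=False)


def apply_charges(frame: Frame, ff: ForceFieldTable) -> Frame:
    """Copy of ``frame`` with charges filled from the table's defaults."""
    out = frame.copy()
    out.charges = np.array([ff.charges.get(t, 0.0) for t in out.bead_types])
    return out


# -- shifted potentials ----------------------------------------------------


def shift_coefficients(p: int, r1: float, rc: float) -> tuple[float, float, float]:
    """(A, B, C) of the shift polynomial for exponent ``p``."""
    if rc <= r1:
        raise ValueError("need r1 < rc")
    d = rc - r1
    A = -p * ((p + 4) * rc - (p + 1) * r1) / (rc ** (p + 2) * d ** 2)
    B = p * ((p + 3) * rc - (p + 1) * r1) / (rc ** (p + 2) * d ** 3)
    C = 1.0 / rc ** p - A / 3.0 * d ** 3 - B / 4.0 * d ** 4
    return A, B, C


def shifted_power_term(r, p: int, r1: float, rc: float):
    """Shift-function form of r^-p; scalar or array ``r`` (nm)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    A, B, C = shift_coefficients(p, r1, rc)
    out = np.zeros_like(r)
    inner = r <= r1
    mid = (r > r1) & (r <= rc)
    out[inner] = r[inner] ** -float(p) - C
    dr = r[mid] - r1
    out[mid] = r[mid] ** -float(p) - A / 3.0 * dr ** 3 - B / 4.0 * dr ** 4 - C
    return out if out.ndim else float(out)


def lj_energy(r, eps: float, sigma: float, ff: ForceFieldTable):
    """Switched Lennard-Jones energy (kJ/mol) at distance(s) ``r`` nm."""
    c6 = 4.0 * eps * sigma ** 6
    c12 = 4.0 * eps * sigma ** 12
    return (c12 * shifted_power_term(r, 12, ff.r1_lj, ff.r_cut)
            - c6 * shifted_power_term(r, 6, ff.r1_lj, ff.r_cut))


def coulomb_energy(r, qi: float, qj: float, ff: ForceFieldTable):
    """Shifted Coulomb energy (kJ/mol); shifted to zero from 0 to the cutoff."""
    q2 = np.asarray(qi, dtype=float) * np.asarray(qj, dtype=float)
    if np.all(q2 == 0.0):
        return np.zeros_like(np.asarray(r, dtype=float) * 1.0) if np.ndim(r) else 0.0
    return (ff.prefactor / ff.dielectric) * q2 * shifted_power_term(
        r, 1, 0.0, ff.r_cut)


# -- pair enumeration and group energies ----------------------------------


def _wrapped(frame: Frame) -> np.ndarray:
    pos = np.mod(frame.positions, frame.box)
    # guard against components landing exactly on the upper box face
    return np.where(pos >= frame.box, 0.0, pos)


def neighbor_pairs(frame: Frame, sel_a: np.ndarray, sel_b: np.ndarray,
                   cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i in sel_a, j in sel_b) with periodic distance < cutoff.

    Unique unordered pairs, i != j; uses a periodic k-d tree.  Selections must
    be disjoint or identical.
    """
    pos = _wrapped(frame)
    sel_a = np.asarray(sel_a)
    sel_b = np.asarray(sel_b)
    if len(sel_a) == 0 or len(sel_b) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    if np.any(frame.box < 2 * cutoff):
        # periodic KDTree needs box >= 2*cutoff; fall back to brute force
        return _brute_pairs(frame, sel_a, sel_b, cutoff)
    identical = len(sel_a) == len(sel_b) and np.array_equal(sel_a, sel_b)
    if identical:
        tree = cKDTree(pos[sel_a], boxsize=frame.box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        return sel_a[pairs[:, 0]], sel_a[pairs[:, 1]]
    tree_b = cKDTree(pos[sel_b], boxsize=frame.box)
    lists = tree_b.query_ball_point(pos[sel_a], cutoff)
    ii, jj = [], []
    for k, hits in enumerate(lists):
        if hits:
            ii.extend([sel_a[k]] * len(hits))
            jj.extend(sel_b[h] for h in hits)
    ii = np.asarray(ii, dtype=int)
    jj = np.asarray(jj, dtype=int)
    if len(ii):
        keep = _exact_within(frame, ii, jj, cutoff)
        ii, jj = ii[keep], jj[keep]
    return ii, jj


def _exact_within(frame, ii, jj, cutoff):
    d = minimum_image_displacement(frame.positions[ii], frame.positions[jj],
                                   frame.box)
    return (d * d).sum(axis=1) < cutoff * cutoff


def _brute_pairs(frame, sel_a, sel_b, cutoff):
    identical = len(sel_a) == len(sel_b) and np.array_equal(sel_a, sel_b)
    if identical:
        ii, jj = np.triu_indices(len(sel_a), k=1)
        ii, jj = sel_a[ii], sel_a[jj]
    else:
        ii = np.repeat(sel_a, len(sel_b))
        jj = np.tile(sel_b, len(sel_a))
    keep = _exact_within(frame, ii, jj, cutoff)
    return ii[keep], jj[keep]


def group_pair_energy(frame: Frame, sel_a, sel_b, ff: ForceFieldTable,
                      exclude_same_molecule: bool = True) -> tuple[float, float]:
    """(E_LJ, E_Coulomb) in kJ/mol between bead selections A and B.

    Each unordered bead pair within the cutoff is counted once.  Pairs inside
    one molecule are excluded by default: this removes intrapeptide nonbonded
    contributions and stands in for bonded-neighbor exclusions, since all the
    analyses compare intermolecular groups.
    """
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    ii, jj = neighbor_pairs(frame, sel_a, sel_b, ff.r_cut)
    if len(ii) == 0:
        return 0.0, 0.0
    if exclude_same_molecule:
        keep = frame.molecule_ids[ii] != frame.molecule_ids[jj]
        ii, jj = ii[keep], jj[keep]
        if len(ii) == 0:
            return 0.0, 0.0
    d = minimum_image_displacement(frame.positions[ii], frame.positions[jj],
                                   frame.box)
    r = np.sqrt((d * d).sum(axis=1))

    types = sorted(set(frame.bead_types[ii]) | set(frame.bead_types[jj]))
    code = {t: k for k, t in enumerate(types)}
    eps_m = np.empty((len(types), len(types)))
    sig_m = np.empty((len(types), len(types)))
    for a in types:
        for b in types:
            eps_m[code[a], code[b]], sig_m[code[a], code[b]] = ff.lookup(a, b)
    ca = np.array([code[t] for t in frame.bead_types[ii]])
    cb = np.array([code[t] for t in frame.bead_types[jj]])
    eps = eps_m[ca, cb]
    sig = sig_m[ca, cb]

    phi12 = shifted_power_term(r, 12, ff.r1_lj, ff.r_cut)
    phi6 = shifted_power_term(r, 6, ff.r1_lj, ff.r_cut)
    e_lj = float(np.sum(4.0 * eps * (sig ** 12 * phi12 - sig ** 6 * phi6)))

    q2 = frame.charges[ii] * frame.charges[jj]
    if np.any(q2 != 0.0):
        phi1 = shifted_power_term(r, 1, 0.0, ff.r_cut)
        e_c = float(np.sum((ff.prefactor / ff.dielectric) * q2 * phi1))
    else:
        e_c = 0.0
    return e_lj, e_c


# -- leaflet and lipid classification --------------------------------------


def leaflet_assignment(frame: Frame, chol_cutoff: float = 2.0) -> dict[str, set]:
    """Split lipids into leaflets; cholesterol is assigned dynamically.

    Phospholipids go by their PO4 z against the mean phosphate z (the flat
    midplane).  Cholesterol flip-flops, so each molecule is claimed by any
    leaflet with a phosphate bead within ``chol_cutoff`` nm (3D periodic
    distance) of its hydroxyl; a cholesterol matching neither leaflet is
    returned under "unassigned" and excluded from per-leaflet groups.
    """
    is_po4 = frame.names == "PO4"
    if not np.any(is_po4):
        raise ValueError("no phosphate beads; cannot assign leaflets")
    mid_z = frame.positions[is_po4, 2].mean()
    out: dict[str, set] = {"top": set(), "bottom": set(), "unassigned": set()}
    po4_mol = frame.molecule_ids[is_po4]
    po4_top = frame.positions[is_po4, 2] > mid_z
    for mol, topside in zip(po4_mol, po4_top):
        out["top" if topside else "bottom"].add(int(mol))

    is_roh = frame.names == "ROH"
    if np.any(is_roh):
        pos = _wrapped(frame)
        roh_idx = np.flatnonzero(is_roh)
        for leaflet, mask in (("top", po4_top), ("bottom", ~po4_top)):
            p_idx = np.flatnonzero(is_po4)[mask]
            if len(p_idx) == 0:
                continue
            tree = cKDTree(pos[p_idx], boxsize=frame.box)
            dist, _ = tree.query(pos[roh_idx])
            for k in np.flatnonzero(dist <= chol_cutoff):
                out[leaflet].add(int(frame.molecule_ids[roh_idx[k]]))
        assigned = out["top"] | out["bottom"]
        for mol in np.unique(frame.molecule_ids[is_roh]):
            if int(mol) not in assigned:
                out["unassigned"].add(int(mol))
    return out


def classify_lipids(frame: Frame, phasemap, peptide_sel, cutoff: float = 1.2
                    ) -> pd.DataFrame:
    """Per-lipid (phase, proximity) classification.

    Phase comes from the segmentation label under the lipid's reference bead
    (PO4 for phospholipids; ROH for cholesterol, which has no phosphate).
    A lipid is "near" if any of its beads is within ``cutoff`` of any peptide
    bead (3D minimum image), else "far".  Interface-labeled lipids are kept in
    the output but are excluded from energy groups downstream.
    """
    classes = frame.classes()
    lipid_mask = classes == "lipid"
    ref_mask = lipid_mask & ((frame.names == "PO4") | (frame.names == "ROH"))
    ref_idx = np.flatnonzero(ref_mask)
    labels = phasemap.label_at(frame.positions[ref_idx, :2])

    peptide_sel = np.asarray(peptide_sel, dtype=int)
    near_mols: set[int] = set()
    if len(peptide_sel):
        lip_idx = np.flatnonzero(lipid_mask)
        ii, _ = neighbor_pairs(frame, lip_idx, peptide_sel, cutoff)
        near_mols = set(frame.molecule_ids[ii].tolist())

    rows = []
    for k, idx in enumerate(ref_idx):
        mol = int(frame.molecule_ids[idx])
        rows.append({"molecule_id": mol,
                     "molecule_type": frame.molecule_types[idx],
                     "phase": labels[k],
                     "proximity": "near" if mol in near_mols else "far"})
    return pd.DataFrame(rows)


# -- decomposition ---------------------------------------------------------


@dataclass
class EnergyTable:
    """Group-pair energies for one frame.

    ``df`` rows are keyed by (leaflet, group_a, group_b) with LJ/Coulomb
    energies, group sizes and per-molecule/per-residue normalizations; empty
    groups keep their row with NaN energies (a null flag, not a zero).
    ``n_peptides`` counts whole peptides per (leaflet, phase) by residue
    majority; ``excluded`` counts interfacial lipids and unassigned
    cholesterols dropped from the discriminated groups.
    """

    df: pd.DataFrame
    n_peptides: dict
    excluded: dict
    time: float = 0.0

    def energy(self, leaflet: str, group_a: str, group_b: str) -> tuple[float, float]:
        row = self.df[(self.df.leaflet == leaflet) & (self.df.group_a == group_a)
                      & (self.df.group_b == group_b)]
        if len(row) != 1:
            raise KeyError(f"no unique row ({leaflet}, {group_a}, {group_b})")
        return float(row.e_lj.iloc[0]), float(row.e_coulomb.iloc[0])


PHASES = ("Ld", "Lo")
PROXIMITIES = ("near", "far")


def _peptide_molecules(frame: Frame) -> dict[int, np.ndarray]:
    classes = frame.classes()
    pep_idx = np.flatnonzero(classes == "peptide")
    out: dict[int, np.ndarray] = {}
    for mol in np.unique(frame.molecule_ids[pep_idx]):
        out[int(mol)] = pep_idx[frame.molecule_ids[pep_idx] == mol]
    return out


def decompose(frame: Frame, phasemap, ff: ForceFieldTable,
              near_cutoff: float = 1.2) -> EnergyTable:
    """Phase/proximity-discriminated nonbonded energy table for one frame.

    Per leaflet, the four lipid groups {Ld, Lo} x {near, far} (interfacial
    lipids and unassigned cholesterols excluded) are paired with the
    undiscriminated groups of all lipids, all peptides and all solvent.
    Peptide residues, grouped by the region under their backbone bead, are
    paired with all lipids and all solvent; summed over regions these must
    reproduce single-pass undiscriminated totals — the closure check.
    """
    classes = frame.classes()
    lipid_idx = np.flatnonzero(classes == "lipid")
    pep_idx = np.flatnonzero(classes == "peptide")
    solv_idx = np.flatnonzero(classes == "solvent")

    leaflets = leaflet_assignment(frame)
    cls = classify_lipids(frame, phasemap, pep_idx, cutoff=near_cutoff)
    phase_of = dict(zip(cls.molecule_id, cls.phase))
    prox_of = dict(zip(cls.molecule_id, cls.proximity))

    # peptide residue regions from backbone beads
    bb_idx = pep_idx[frame.names[pep_idx] == "BB"]
    bb_regions = phasemap.label_at(frame.positions[bb_idx, :2]) if len(bb_idx) else []
    region_of_bb = dict(zip(bb_idx.tolist(), bb_regions))

    # whole-peptide counts per (leaflet, majority phase)
    is_po4 = frame.names == "PO4"
    mid_z = frame.positions[is_po4, 2].mean() if np.any(is_po4) else frame.box[2] / 2
    n_peptides: dict[tuple[str, str], int] = {}
    for mol, idxs in _peptide_molecules(frame).items():
        leaf = "top" if frame.positions[idxs, 2].mean() > mid_z else "bottom"
        regs = [region_of_bb[i] for i in idxs if i in region_of_bb]
        if not regs:
            continue
        vals, counts = np.unique(regs, return_counts=True)
        maj = str(vals[np.argmax(counts)])
        n_peptides[(leaf, maj)] = n_peptides.get((leaf, maj), 0) + 1

    mol_arr = frame.molecule_ids
    rows = []

    def add_row(leaflet, name_a, sel_a, n_mol_a, name_b, sel_b):
        if len(sel_a) == 0 or len(sel_b) == 0:
            rows.append({"leaflet": leaflet, "group_a": name_a, "group_b": name_b,
                         "e_lj": np.nan, "e_coulomb": np.nan,
                         "n_a": n_mol_a, "n_b": len(sel_b),
                         "e_per_a": np.nan})
            return
        e_lj, e_c = group_pair_energy(frame, sel_a, sel_b, ff)
        rows.append({"leaflet": leaflet, "group_a": name_a, "group_b": name_b,
                     "e_lj": e_lj, "e_coulomb": e_c,
                     "n_a": n_mol_a, "n_b": len(sel_b),
                     "e_per_a": (e_lj + e_c) / n_mol_a if n_mol_a else np.nan})

    partners = (("all-lipids", lipid_idx), ("all-peptides", pep_idx),
                ("all-solvent", solv_idx))
    for leaflet in ("top", "bottom"):
        members = leaflets[leaflet]
        for phase in PHASES:
            for prox in PROXIMITIES:
                mols = {m for m in members
                        if phase_of.get(m) == phase and prox_of.get(m) == prox}
                sel = lipid_idx[np.isin(mol_arr[lipid_idx], list(mols))] \
                    if mols else np.empty(0, dtype=int)
                for pname, psel in partners:
                    add_row(leaflet, f"{phase}-{prox}", sel, len(mols), pname, psel)

    for region in ("Ld", "Lo", "interface"):
        sel = np.array([i for i in bb_idx if region_of_bb[i] == region], dtype=int)
        # a residue's beads = its backbone bead in this coarse representation
        for pname, psel in (("all-lipids", lipid_idx), ("all-solvent", solv_idx)):
            add_row("both", f"peptide-{region}", sel, len(sel), pname, psel)

    excluded = {
        "interfacial_lipids": int((cls.phase == "interface").sum()),
        "unassigned_cholesterol": len(leaflets["unassigned"]),
    }
    return EnergyTable(df=pd.DataFrame(rows), n_peptides=n_peptides,
                       excluded=excluded, time=frame.time)


def closure_check(frame: Frame, table: EnergyTable, ff: ForceFieldTable
                  ) -> dict[str, float]:
    """Compare region-summed peptide energies against single-pass totals.

    Returns the absolute and relative (ppm) differences between the sum of
    phase-discriminated peptide–lipid + peptide–solvent energies and the
    undiscriminated totals computed in one pass over all peptide beads.
    """
    classes = frame.classes()
    lipid_idx = np.flatnonzero(classes == "lipid")
    solv_idx = np.flatnonzero(classes == "solvent")
    pep_idx = np.flatnonzero(classes == "peptide")
    bb_idx = pep_idx[frame.names[pep_idx] == "BB"]

    disc = 0.0
    for region in ("Ld", "Lo", "interface"):
        for partner in ("all-lipids", "all-solvent"):
            e_lj, e_c = table.energy("both", f"peptide-{region}", partner)
            if not (np.isnan(e_lj) or np.isnan(e_c)):
                disc += e_lj + e_c
    tot = 0.0
    for psel in (lipid_idx, solv_idx):
        e_lj, e_c = group_pair_energy(frame, bb_idx, psel, ff)
        tot += e_lj + e_c
    abs_diff = abs(disc - tot)
    rel_ppm = abs_diff / abs(tot) * 1e6 if tot != 0 else 0.0
    return {"discriminated": disc, "total": tot,
            "abs_diff": abs_diff, "rel_diff_ppm": rel_ppm}


def transfer_enthalpy(tables: Sequence[EnergyTable], n_boot: int = 1000,
                      seed: int = 0):
    """Lipid–lipid enthalpy change per peptide moved from Lo to Ld.

    For each frame and phase, the peptide-induced lipid–lipid perturbation per
    peptide is (e_near - e_far) * N_near / N_peptides-in-phase, with e the
    lipid–(all lipids) energy per lipid molecule of the near/far group summed
    over leaflets.  The transfer enthalpy is the Ld perturbation minus the Lo
    perturbation, time-averaged with a corrected-bootstrap CI.  Frames where a
    phase holds no peptides are excluded (their count is reported): too few
    visits make the estimate meaningless.
    """
    from .stats import corrected_bootstrap

    series = []
    skipped = 0
    for tab in tables:
        pert = {}
        ok = True
        for phase in PHASES:
            n_pep = sum(v for (leaf, ph), v in tab.n_peptides.items() if ph == phase)
            if n_pep == 0:
                ok = False
                break
            total = 0.0
            for leaflet in ("top", "bottom"):
                sub = tab.df[(tab.df.leaflet == leaflet)
                             & (tab.df.group_b == "all-lipids")]
                row_n = sub[sub.group_a == f"{phase}-near"]
                row_f = sub[sub.group_a == f"{phase}-far"]
                e_near = row_n.e_per_a.iloc[0]
                e_far = row_f.e_per_a.iloc[0]
                n_near = row_n.n_a.iloc[0]
                if np.isnan(e_near) or np.isnan(e_far):
                    continue
                total += (e_near - e_far) * n_near
            pert[phase] = total / n_pep
        if ok:
            series.append(pert["Ld"] - pert["Lo"])
        else:
            skipped += 1
    if not series:
        raise ValueError("transfer enthalpy undefined: a phase holds no "
                         "peptides in any frame")
    arr = np.asarray(series)
    if len(arr) >= 8:
        stats = corrected_bootstrap(arr, n_boot=n_boot, seed=seed)
    else:
        from .stats import SeriesStats
        stats = SeriesStats(n=len(arr), tau=1.0, n_eff=len(arr),
                            mean=float(arr.mean()), ci_low=np.nan,
                            ci_high=np.nan, n_boot=0, seed=seed)
    return stats, {"frames_used": len(series), "frames_skipped": skipped,
                   "series": np.asarray(series)}
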