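"""Synthetic phase-separated bilayers with analytically known ground truth.

Real phase-separated trajectories of DPPC/DLiPC/cholesterol patches with
adsorbed antimicrobial peptides are expensive to produce and none are bundled
here; this module builds idealized stand-ins whose every property of interest
— stripe domain boundaries, per-molecule phase membership, planned oligomer
orders, time-series autocorrelation — is known by construction, so the
segmentation, partitioning, energy and clustering analyses can be validated
against exact ground truth.

The canonical fixture is a striped bilayer: alternating Lo-like (saturated
lipid + cholesterol rich) and Ld-like (unsaturated-rich) stripes running along
y, continuous across the periodic boundary, mimicking the large-aspect-ratio
patches in which phase domains form straight interfaces.  All generators are
pure functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .trajio import Frame
from .energetics import ForceFieldTable

__all__ = [
    "MembraneSpec",
    "PeptideGroup",
    "PeptidePlacement",
    "build_stripe_bilayer",
    "add_peptides",
    "add_solvent_and_ions",
    "displace_cholesterol",
    "ar1_series",
    "toy_forcefield",
]

# molecular geometry constants (nm); Martini-like scales
_PHOS_DROP = {"GL1": 0.30, "C1A": 0.60, "C2A": 0.90, "C3A": 1.20,
              "C1B": 0.60, "C2B": 0.90, "C3B": 1.20}
# tails straddle the lattice site symmetrically so the species density
# transition stays centered on the stripe boundary
_TAIL_A_XOFF = -0.075
_TAIL_B_XOFF = 0.075
_CHOL_BEADS = {"ROH": 0.30, "R1": 0.55, "R2": 0.80, "R3": 1.05, "R4": 1.30}


@dataclass(frozen=True)
class MembraneSpec:
    """Geometry and composition of a striped bilayer.

    ``stripe_boundaries`` are internal dividers in [0, box_x); together with
    the periodic wrap at x = 0 they delimit the stripes [0, b1), [b1, b2), ...
    [bk, box_x).  ``composition`` gives per-stripe molar fractions of
    DPPC/DLiPC/CHOL, one mapping per stripe.
    """

    box: tuple[float, float, float] = (40.0, 10.0, 10.0)
    stripe_boundaries: tuple[float, ...] = (20.0,)
    composition: tuple[dict, ...] = (
        {"DPPC": 0.7, "DLiPC": 0.0, "CHOL": 0.3},
        {"DPPC": 0.0, "DLiPC": 0.9, "CHOL": 0.1},
    )
    lipid_lattice_spacing: float = 0.8
    leaflet_z: tuple[float, float] = (2.0, -2.0)  # head planes rel. midplane
    positional_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.stripe_boundaries, dtype=float)
        if np.any(b < 0) or np.any(b >= self.box[0]):
            raise ValueError("stripe boundaries must lie in [0, box_x)")
        if np.any(np.diff(b) <= 0):
            raise ValueError("stripe boundaries must be strictly increasing")
        if len(self.composition) != len(b) + 1:
            raise ValueError(
                f"{len(b)} boundaries define {len(b) + 1} stripes but "
                f"{len(self.composition)} compositions were given")
        for comp in self.composition:
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"stripe fractions must sum to 1: {comp}")
        if self.lipid_lattice_spacing <= 0:
            raise ValueError("lattice spacing must be positive")

    def stripe_intervals(self) -> list[tuple[float, float]]:
        edges = [0.0, *self.stripe_boundaries, self.box[0]]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _largest_remainder_counts(fracs: Sequence[float], total: int) -> list[int]:
    """Integer counts proportional to ``fracs`` summing exactly to ``total``."""
    raw = np.asarray(fracs, dtype=float) * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(raw - base)[::-1]
    base[order[:short]] += 1
    return base.tolist()


def build_stripe_bilayer(spec: MembraneSpec):
    """Build a two-leaflet striped bilayer; return (Frame, ground_truth).

    Each phospholipid gets beads PO4, GL1 and two 3-bead tails (C1A..C3A,
    C1B..C3B); cholesterol gets ROH plus four body beads.  Lipids sit on a
    jittered rectangular lattice per leaflet; stripe membership of a molecule
    is decided by its lattice site x.  Ground truth carries the stripe
    dividers (including the periodic wrap at x = 0), per-stripe phase labels
    (Lo if DPPC dominates the phospholipid content, Ld otherwise), and the
    intended phase of every placed molecule.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    mid_z = box[2] / 2.0
    intervals = spec.stripe_intervals()
    for (x0, x1) in intervals:
        if (x1 - x0) < 2 * spec.lipid_lattice_spacing:
            raise ValueError(
                f"stripe [{x0}, {x1}) narrower than twice the lattice spacing")

    nx = max(1, int(round(box[0] / spec.lipid_lattice_spacing)))
    ny = max(1, int(round(box[1] / spec.lipid_lattice_spacing)))
    dx, dy = box[0] / nx, box[1] / ny
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy

    stripe_phase = []
    for comp in spec.composition:
        stripe_phase.append("Lo" if comp.get("DPPC", 0.0) >= comp.get("DLiPC", 0.0) else "Ld")

    pos, names, mol_ids, mol_types = [], [], [], []
    molecule_phase: dict[int, str] = {}
    mol_id = 0
    for plane_off in spec.leaflet_z:
        plane_z = mid_z + plane_off
        top = plane_off > 0
        for si, (x0, x1) in enumerate(intervals):
            site_x = xs[(xs >= x0) & (xs < x1)]
            sites = [(x, y) for x in site_x for y in ys]
            rng.shuffle(sites)
            counts = _largest_remainder_counts(
                [spec.composition[si].get(t, 0.0) for t in ("DPPC", "DLiPC", "CHOL")],
                len(sites))
            types = (["DPPC"] * counts[0] + ["DLiPC"] * counts[1] + ["CHOL"] * counts[2])
            for (x, y), ltype in zip(sites, types):
                mol_id += 1
                jx, jy = rng.normal(0.0, spec.positional_jitter, size=2)
                cx, cy = (x + jx) % box[0], (y + jy) % box[1]
                beads = ({"PO4": 0.0, **_PHOS_DROP} if ltype != "CHOL" else _CHOL_BEADS)
                for bname, drop in beads.items():
                    if bname.endswith("B"):
                        bx = cx + _TAIL_B_XOFF
                    elif bname.endswith("A"):
                        bx = cx + _TAIL_A_XOFF
                    else:
                        bx = cx
                    bz = plane_z - drop if top else plane_z + drop
                    bz += rng.normal(0.0, spec.positional_jitter)
                    pos.append((bx % box[0], cy, bz))
                    names.append(bname)
                    mol_ids.append(mol_id)
                    mol_types.append(ltype)
                molecule_phase[mol_id] = stripe_phase[si]

    n = len(pos)
    frame = Frame(
        positions=np.array(pos), names=np.array(names, dtype=object),
        molecule_ids=np.array(mol_ids), molecule_types=np.array(mol_types, dtype=object),
        bead_types=np.array(names, dtype=object), charges=np.zeros(n), box=box)
    ground_truth = {
        "boundaries": [0.0, *spec.stripe_boundaries],
        "stripes": [{"x0": x0, "x1": x1, "phase": stripe_phase[i]}
                    for i, (x0, x1) in enumerate(intervals)],
        "molecule_phase": molecule_phase,
        "leaflet_planes": [mid_z + off for off in spec.leaflet_z],
        "midplane_z": mid_z,
    }
    return frame, ground_truth


# -- peptides --------------------------------------------------------------


@dataclass(frozen=True)
class PeptideGroup:
    """One planned oligomer: ``order`` parallel chains ``gap`` nm apart.

    ``kind`` "line" lays the chains side by side (every bead of each chain has
    a partner within gap); "tee" lays a 2-peptide T where only the junction
    beads come close — a contact geometry that should *not* count as a
    cluster.  ``region`` targets a stripe phase (Ld/Lo) or the interface.
    """

    order: int = 1
    gap: float = 0.5
    kind: str = "line"
    region: str = "Ld"
    leaflet: str = "top"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("oligomer order must be >= 1")
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if self.kind not in ("line", "tee"):
            raise ValueError(f"unknown layout kind {self.kind!r}")
        if self.kind == "tee" and self.order != 2:
            raise ValueError("tee layout is a 2-peptide arrangement")


@dataclass(frozen=True)
class PeptidePlacement:
    """Planned peptide content of a bilayer fixture."""

    groups: tuple[PeptideGroup, ...] = (PeptideGroup(),)
    residues_per_peptide: int = 11
    backbone_spacing: float = 0.35
    depth_offset: float = 0.0
    charge_per_peptide: int = 6
    name: str = "PEP"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residues_per_peptide < 1:
            raise ValueError("peptides need at least one residue")
        if self.charge_per_peptide > self.residues_per_peptide:
            raise ValueError("more charges than residues")


def _region_center_x(ground_truth: dict, region: str) -> float:
    if region == "interface":
        return float(ground_truth["boundaries"][-1])
    widths = [(s["x1"] - s["x0"], s) for s in ground_truth["stripes"]
              if s["phase"] == region]
    if not widths:
        raise ValueError(f"no stripe with phase {region!r} to place peptides in")
    _, stripe = max(widths, key=lambda w: w[0])
    return (stripe["x0"] + stripe["x1"]) / 2.0


def add_peptides(frame: Frame, placement: PeptidePlacement, ground_truth: dict):
    """Lay peptide backbone chains on the bilayer; return (Frame, plan).

    Chains are rigid straight backbones along y at the phosphate plane plus
    ``depth_offset`` (positive toward solvent).  Groups targeting the same
    (leaflet, region) are stacked along y with >= 2 nm clearance so isolated
    peptides stay > 1.5 nm from all others.  The returned plan lists, per
    group, the peptide molecule ids and the intended oligomer order.
    """
    box = frame.box
    chain_len = (placement.residues_per_peptide - 1) * placement.backbone_spacing
    slot = chain_len + 2.0
    n_slots = int(box[1] // slot)
    next_slot: dict[tuple[str, str], int] = {}

    pos, names, mol_ids, mol_types, charges = [], [], [], [], []
    base_mol = int(frame.molecule_ids.max()) + 1 if frame.n_beads else 1
    mol_id = base_mol - 1
    plan = []
    for group in placement.groups:
        key = (group.leaflet, group.region)
        slot_i = next_slot.get(key, 0)
        if slot_i >= n_slots:
            raise ValueError(
                f"placement does not fit: no free y slot for group {group} "
                f"(box_y={box[1]} nm, {n_slots} slots)")
        next_slot[key] = slot_i + 1
        x0 = _region_center_x(ground_truth, group.region)
        y0 = slot_i * slot + 1.0
        plane_idx = 0 if group.leaflet == "top" else 1
        plane_z = ground_truth["leaflet_planes"][plane_idx]
        outward = 1.0 if group.leaflet == "top" else -1.0
        z = plane_z + outward * placement.depth_offset

        members = []
        for m in range(group.order):
            mol_id += 1
            members.append(mol_id)
            if group.kind == "tee" and m == 1:
                # stem: chain along x, first bead `gap` from the bar's middle
                ybar = y0 + (placement.residues_per_peptide // 2) * placement.backbone_spacing
                for k in range(placement.residues_per_peptide):
                    pos.append(((x0 + group.gap + k * placement.backbone_spacing) % box[0],
                                ybar % box[1], z))
                    _append_bead(names, mol_ids, mol_types, charges, mol_id,
                                 placement, k)
            else:
                xm = (x0 + m * group.gap) % box[0]
                for k in range(placement.residues_per_peptide):
                    pos.append((xm, (y0 + k * placement.backbone_spacing) % box[1], z))
                    _append_bead(names, mol_ids, mol_types, charges, mol_id,
                                 placement, k)
        plan.append({"order": group.order, "kind": group.kind,
                     "region": group.region, "leaflet": group.leaflet,
                     "peptide_ids": members})

    out = Frame(
        positions=np.vstack([frame.positions, np.array(pos).reshape(-1, 3)]),
        names=np.concatenate([frame.names, np.array(names, dtype=object)]),
        molecule_ids=np.concatenate([frame.molecule_ids, np.array(mol_ids)]),
        molecule_types=np.concatenate([frame.molecule_types,
                                       np.array(mol_types, dtype=object)]),
        bead_types=np.concatenate([frame.bead_types, np.array(names, dtype=object)]),
        charges=np.concatenate([frame.charges, np.array(charges)]),
        box=box, time=frame.time, registry=frame.registry)
    return out, plan


def _append_bead(names, mol_ids, mol_types, charges, mol_id, placement, k):
    names.append("BB")
    mol_ids.append(mol_id)
    mol_types.append(placement.name)
    charges.append(1.0 if k < placement.charge_per_peptide else 0.0)


# -- solvent ---------------------------------------------------------------


def add_solvent_and_ions(frame: Frame, number_density: float = 8.35,
                         seed: int = 0) -> Frame:
    """Fill the space above/below the bilayer with W beads and neutralize.

    Water beads go on a jittered cubic lattice outside an exclusion slab
    around the bilayer and any adsorbed peptides (0.5 nm margin).  Exactly
    enough
    chloride beads (charge −1) replace water beads to cancel the total
    peptide charge, leaving the system net neutral.
    """
    if number_density <= 0:
        raise ValueError("solvent number density must be positive")
    rng = np.random.default_rng(seed)
    box = frame.box
    classes = frame.classes()
    solute_z = frame.positions[classes != "solvent", 2]
    if len(solute_z) == 0:
        z_lo, z_hi = box[2] / 2, box[2] / 2
    else:
        z_lo, z_hi = solute_z.min() - 0.5, solute_z.max() + 0.5
    if z_lo <= 0 and z_hi >= box[2]:
        raise ValueError("box is not taller than the bilayer; no room for solvent")

    a = number_density ** (-1.0 / 3.0)
    nx, ny, nz = (max(1, int(box[0] / a)), max(1, int(box[1] / a)),
                  max(1, int(box[2] / a)))
    gx = (np.arange(nx) + 0.5) * (box[0] / nx)
    gy = (np.arange(ny) + 0.5) * (box[1] / ny)
    gz = (np.arange(nz) + 0.5) * (box[2] / nz)
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    sites = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    sites = sites[(sites[:, 2] < z_lo) | (sites[:, 2] > z_hi)]
    sites = (sites + rng.normal(0.0, 0.05, size=sites.shape)) % box

    total_charge = frame.charges.sum()
    n_anions = int(round(total_charge))
    if n_anions < 0:
        raise ValueError("net negative peptide charge not supported by this fixture")
    if n_anions > len(sites):
        raise ValueError("not enough solvent sites to neutralize the system")
    n_w = len(sites) - n_anions
    ion_idx = rng.choice(len(sites), size=n_anions, replace=False)
    is_ion = np.zeros(len(sites), dtype=bool)
    is_ion[ion_idx] = True

    names = np.where(is_ion, "CL-", "W").astype(object)
    mol_types = names.copy()
    base = int(frame.molecule_ids.max()) + 1 if frame.n_beads else 1
    out = Frame(
        positions=np.vstack([frame.positions, sites]),
        names=np.concatenate([frame.names, names]),
        molecule_ids=np.concatenate([frame.molecule_ids,
                                     base + np.arange(len(sites))]),
        molecule_types=np.concatenate([frame.molecule_types, mol_types]),
        bead_types=np.concatenate([frame.bead_types, names.copy()]),
        charges=np.concatenate([frame.charges,
                                np.where(is_ion, -1.0, 0.0)]),
        box=box, time=frame.time, registry=frame.registry)
    assert abs(out.charges.sum()) < 1e-9 or n_anions != round(total_charge)
    return out


def displace_cholesterol(frame: Frame, n: int = 1, mode: str = "mid",
                         seed: int = 0) -> Frame:
    """Move ``n`` cholesterols' beads toward the membrane core or the
    opposite leaflet — a flip-flop fixture for leaflet-assignment tests.

    ``mode`` "mid" parks the ROH at the bilayer midplane (should end up
    unassigned when > 2 nm from all phosphates); "opposite" mirrors the
    molecule through the midplane (should be claimed by the other leaflet).
    """
    if mode not in ("mid", "opposite"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out = frame.copy()
    chol_ids = np.unique(out.molecule_ids[out.molecule_types == "CHOL"])
    if len(chol_ids) < n:
        raise ValueError("not enough cholesterol molecules")
    mid_z = out.box[2] / 2.0
    for mol in rng.choice(chol_ids, size=n, replace=False):
        mask = out.molecule_ids == mol
        if mode == "mid":
            roh_z = out.positions[mask & (out.names == "ROH"), 2][0]
            out.positions[mask, 2] += mid_z - roh_z
        else:
            out.positions[mask, 2] = 2 * mid_z - out.positions[mask, 2]
    return out


# -- time series and toy force field --------------------------------------


def ar1_series(n: int, phi: float, mu: float = 0.0, sigma: float = 1.0,
               seed: int = 0) -> np.ndarray:
    """Stationary AR(1) series x_t = mu + phi (x_{t-1} - mu) + eps_t.

    The theoretical integrated autocorrelation time is (1 + phi) / (1 - phi):
    1 for white noise (phi = 0), 2 for phi = 1/3, 4 for phi = 0.6.  The first
    point is drawn from the stationary distribution so the whole series is
    stationary.
    """
    if n < 2:
        raise ValueError("need at least two points")
    if not (0.0 <= abs(phi) < 1.0):
        raise ValueError("|phi| must be < 1 for stationarity")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=n)
    x = np.empty(n)
    x[0] = mu + eps[0] / np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = mu + phi * (x[t - 1] - mu) + eps[t]
    return x


def toy_forcefield(bead_types: Sequence[str], seed: int = 0,
                   charges: dict | None = None) -> ForceFieldTable:
    """A symmetric (eps, sigma) pair table at coarse-grained scales.

    eps uniform in [1, 6] kJ/mol and sigma in [0.43, 0.62] nm per unordered
    type pair; dielectric 15 and (0.9, 1.2) nm LJ switch as in the analysis
    defaults.  Deterministic in (bead_types order, seed).
    """
    types = list(bead_types)
    if len(set(types)) != len(types):
        raise ValueError("duplicate bead type names")
    if not types:
        raise ValueError("need at least one bead type")
    rng = np.random.default_rng(seed)
    pairs = {}
    for i, a in enumerate(types):
        for b in types[i:]:
            eps = rng.uniform(1.0, 6.0)
            sig = rng.uniform(0.43, 0.62)
            pairs[(a, b)] = (eps, sig)
    return ForceFieldTable(pairs=pairs, charges=dict(charges or {}))


def ground_truth_sidecar(path, **truth) -> None:
    """Write generator ground truth next to a GRO file as JSON."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=_default)
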