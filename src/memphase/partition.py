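"""Peptide partitioning: region assignment, enrichment ratios, insertion depth.

Peptide backbone beads are assigned to the Ld, Lo, or interface region by
their z-flattened xy position on the segmentation grid; counts are normalized
by the counts expected from a uniform-by-area random distribution, giving a
dimensionless enrichment ratio per region (1 = no preference).  Insertion
depth is the z-distance of a backbone bead to the center of mass of the
same-leaflet phosphate beads within a 2 nm xy radius, positive toward the
solvent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .phasemap import PhaseMap, REGIONS
from .stats import SeriesStats, corrected_bootstrap
from .trajio import Frame

__all__ = [
    "RegionAssignment",
    "EnrichmentReport",
    "assign_backbone_regions",
    "enrichment_ratios",
    "insertion_depth",
    "peptide_majority_regions",
]


@dataclass
class RegionAssignment:
    """Per backbone bead: region, leaflet, and the owning peptide."""

    bead_index: np.ndarray       # indices into the frame
    molecule_id: np.ndarray
    region: np.ndarray           # {"Ld", "Lo", "interface"}
    leaflet: np.ndarray          # {"top", "bottom"}
    time: float = 0.0

    def counts(self) -> dict[str, int]:
        return {r: int((self.region == r).sum()) for r in REGIONS}


def _backbone_indices(frame: Frame) -> np.ndarray:
    classes = frame.classes()
    pep = np.flatnonzero(classes == "peptide")
    return pep[frame.names[pep] == "BB"]


def _local_phosphate_xy_tree(frame: Frame):
    is_po4 = frame.names == "PO4"
    idx = np.flatnonzero(is_po4)
    if len(idx) == 0:
        raise ValueError("no phosphate beads in frame")
    xy = np.mod(frame.positions[idx, :2], frame.box[:2])
    xy = np.where(xy >= frame.box[:2], 0.0, xy)
    return idx, cKDTree(xy, boxsize=frame.box[:2])


def assign_backbone_regions(frame: Frame, phasemap: PhaseMap,
                            leaflet_radius: float = 2.0) -> RegionAssignment:
    """Label every peptide backbone bead with its region and leaflet.

    Region is the phase-map label of the grid cell under the bead's wrapped
    xy position.  Leaflet is the sign of the bead's z against the mean z of
    all phosphates within ``leaflet_radius`` nm in xy (the local midplane);
    with no local phosphate, the global phosphate midplane is used.
    """
    bb = _backbone_indices(frame)
    regions = phasemap.label_at(frame.positions[bb, :2])

    po4_idx, tree = _local_phosphate_xy_tree(frame)
    po4_z = frame.positions[po4_idx, 2]
    xy = np.mod(frame.positions[bb, :2], frame.box[:2])
    xy = np.where(xy >= frame.box[:2], 0.0, xy)
    hits = tree.query_ball_point(xy, leaflet_radius)
    global_mid = po4_z.mean()
    leaflets = np.empty(len(bb), dtype=object)
    for k, h in enumerate(hits):
        mid = po4_z[h].mean() if h else global_mid
        leaflets[k] = "top" if frame.positions[bb[k], 2] > mid else "bottom"
    return RegionAssignment(bead_index=bb, molecule_id=frame.molecule_ids[bb],
                            region=np.asarray(regions, dtype=object),
                            leaflet=leaflets, time=frame.time)


def peptide_majority_regions(assignment: RegionAssignment) -> dict[int, str]:
    """Whole-peptide region by majority vote of its backbone beads."""
    out = {}
    for mol in np.unique(assignment.molecule_id):
        regs = assignment.region[assignment.molecule_id == mol]
        vals, counts = np.unique(regs, return_counts=True)
        out[int(mol)] = str(vals[np.argmax(counts)])
    return out


@dataclass
class EnrichmentReport:
    """Time-averaged per-region enrichment with corrected-bootstrap CIs."""

    table: pd.DataFrame  # region, ratio, ci_low, ci_high, observed, expected, area_fraction
    per_frame: pd.DataFrame  # frame, region, observed, expected, ratio
    n_frames: int
    excluded_frames: dict[str, int]
    stats: dict[str, SeriesStats]


def enrichment_ratios(assignments: Sequence[RegionAssignment],
                      phasemaps: Sequence[PhaseMap],
                      mode: str = "per-frame",
                      n_boot: int = 1000, level: float = 0.95,
                      seed: int = 0) -> EnrichmentReport:
    """Region enrichment relative to a uniform random distribution.

    Per frame, ratio_r = observed_r / (N_total * area_r / area_total); the
    identity sum_r ratio_r * areafrac_r = 1 holds exactly.  Mode "per-frame"
    (default) averages the per-frame ratio series with a corrected-bootstrap
    CI; "pooled" sums counts and areas over frames before normalizing (CI
    then comes from bootstrap over per-frame observed counts is not defined,
    so pooled mode reports the point estimate only).  Frames where a region
    has zero area are excluded for that region and counted.
    """
    if len(assignments) != len(phasemaps):
        raise ValueError("one phase map per assignment required")
    if len(assignments) == 0:
        raise ValueError("need at least one frame")
    if mode not in ("per-frame", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    excluded = {r: 0 for r in REGIONS}
    for t, (asg, pm) in enumerate(zip(assignments, phasemaps)):
        counts = asg.counts()
        n_total = sum(counts.values())
        fracs = pm.area_fractions()
        for r in REGIONS:
            if fracs[r] == 0.0:
                excluded[r] += 1
                continue
            expected = n_total * fracs[r]
            rows.append({"frame": t, "region": r, "observed": counts[r],
                         "expected": expected,
                         "ratio": counts[r] / expected if expected else np.nan,
                         "area_fraction": fracs[r]})
    per_frame = pd.DataFrame(rows)

    summary_rows = []
    stats: dict[str, SeriesStats] = {}
    for r in REGIONS:
        sub = per_frame[per_frame.region == r]
        if len(sub) == 0:
            continue
        if mode == "pooled":
            ratio = sub.observed.sum() / sub.expected.sum()
            lo = hi = np.nan
        else:
            series = sub.ratio.to_numpy()
            if len(series) >= 8:
                st = corrected_bootstrap(series, n_boot=n_boot, level=level,
                                         seed=seed + hash(r) % 10_000)
                stats[r] = st
                ratio, lo, hi = st.mean, st.ci_low, st.ci_high
            else:
                ratio, lo, hi = float(series.mean()), np.nan, np.nan
        summary_rows.append({"region": r, "ratio": ratio,
                             "ci_low": lo, "ci_high": hi,
                             "observed": sub.observed.mean(),
                             "expected": sub.expected.mean(),
                             "area_fraction": sub.area_fraction.mean()})
    return EnrichmentReport(table=pd.DataFrame(summary_rows),
                            per_frame=per_frame, n_frames=len(assignments),
                            excluded_frames=excluded, stats=stats)


def insertion_depth(frame: Frame, radius: float = 2.0) -> pd.DataFrame:
    """Backbone-bead depth relative to the local phosphate plane.

    depth = z_bead - z_COM(same-leaflet phosphates within ``radius`` nm in
    xy), sign flipped on the bottom leaflet so positive always points toward
    the solvent.  Beads with no phosphate in range are flagged unassigned
    (NaN depth) and should be excluded from averages.
    """
    bb = _backbone_indices(frame)
    po4_idx, tree = _local_phosphate_xy_tree(frame)
    po4_z = frame.positions[po4_idx, 2]
    global_mid = po4_z.mean()

    xy = np.mod(frame.positions[bb, :2], frame.box[:2])
    xy = np.where(xy >= frame.box[:2], 0.0, xy)
    hits = tree.query_ball_point(xy, radius)
    rows = []
    for k, h in enumerate(hits):
        z = frame.positions[bb[k], 2]
        if not h:
            rows.append({"bead_index": bb[k],
                         "molecule_id": int(frame.molecule_ids[bb[k]]),
                         "leaflet": "unassigned", "depth": np.nan})
            continue
        local_z = po4_z[h]
        mid = local_z.mean()
        top = z > mid if not np.allclose(local_z, local_z[0]) else z > global_mid
        same = local_z[local_z > mid] if top else local_z[local_z <= mid]
        if len(same) == 0:
            same = local_z
        com = same.mean()
        depth = (z - com) if top else (com - z)
        rows.append({"bead_index": bb[k],
                     "molecule_id": int(frame.molecule_ids[bb[k]]),
                     "leaflet": "top" if top else "bottom",
                     "depth": float(depth)})
    return pd.DataFrame(rows)
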