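"""End-to-end orchestration: frames in, phase/enrichment/energy reports out.

The pipeline reads a configuration (TOML or keyword overrides), loads or
generates frames, restricts to the analysis window (the final third of frames
by default, echoing the use of only the equilibrated tail of long production
runs), and runs every stage whose inputs are available.  All numeric reports
are written as tidy TSV with a fixed float format so reruns with the same
inputs and seed are byte-identical; a JSON manifest records the configuration
echo, the package version and the seeds used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .energetics import ForceFieldTable, closure_check, decompose, transfer_enthalpy
from .oligomer import backbone_contact_graph, find_clusters, size_distribution
from .partition import assign_backbone_regions, enrichment_ratios, insertion_depth
from .phasemap import difference_field, interface_edges, label_regions
from .trajio import Frame, iter_trajectory

log = logging.getLogger("memphase")

__all__ = ["PipelineConfig", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """All knobs of the orchestrated analysis; defaults are the standard
    analysis parameters (1.0 nm smoothing, 0.1 nm grid, 1.5 nm interface
    radius, 1.2 nm energy cutoff, 0.6 nm cluster cutoff, 2.0 nm depth and
    cholesterol-leaflet radii, 1000 bootstrap resamples at 95%)."""

    coordinates: str | None = None
    trajectory: str | None = None
    forcefield: str | None = None        # pair TSV
    charges: str | None = None           # per-type charge TSV
    window_fraction: float = 1.0 / 3.0   # final fraction of frames analyzed
    sigma: float = 1.0
    spacing: float = 0.1
    pad: float = 2.0
    interface_radius: float = 1.5
    radius_scan: tuple[float, ...] = ()
    energy_cutoff: float = 1.2
    cluster_cutoff: float = 0.6
    depth_radius: float = 2.0
    chol_leaflet_cutoff: float = 2.0
    n_boot: int = 1000
    level: float = 0.95
    seed: int = 0
    outdir: str = "memphase_out"

    def __post_init__(self) -> None:
        for name in ("interface_radius", "energy_cutoff", "cluster_cutoff",
                     "depth_radius", "chol_leaflet_cutoff", "sigma", "spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.window_fraction <= 1.0):
            raise ValueError("window_fraction must be in (0, 1]")

    @classmethod
    def from_toml(cls, path, overrides: dict | None = None) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update(overrides or {})
        if "radius_scan" in data:
            data["radius_scan"] = tuple(data["radius_scan"])
        return cls(**data)


def analysis_window(frames: Sequence[Frame], fraction: float) -> list[Frame]:
    """The final ``fraction`` of the frame sequence (at least one frame)."""
    n = len(frames)
    start = min(n - 1, n - max(1, int(round(n * fraction))))
    return list(frames[start:])


def run_pipeline(config: PipelineConfig, frames: Sequence[Frame] | None = None
                 ) -> dict:
    """Run every stage and write reports under ``config.outdir``.

    ``frames`` may be passed directly (e.g. from the synthetic generator);
    otherwise they are loaded from the configured coordinate/trajectory
    paths.  Returns a dict of the in-memory stage results.  A missing
    force-field table disables only the energy stage, with a warning.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if frames is None:
        if config.coordinates is None:
            raise ValueError("no frames given and no coordinates configured")
        frames = list(iter_trajectory(config.coordinates, config.trajectory))
    frames = analysis_window(frames, config.window_fraction)
    log.info("analysis window: %d frames", len(frames))

    radii = [config.interface_radius, *config.radius_scan]
    results: dict = {"n_frames": len(frames)}

    # -- segmentation (edges computed once per frame, labeled per radius) --
    phasemaps: dict[float, list] = {r: [] for r in radii}
    area_rows = []
    for t, fr in enumerate(frames):
        delta = difference_field(fr, sigma=config.sigma, spacing=config.spacing,
                                 pad=config.pad)
        edges = interface_edges(delta)
        for r in radii:
            pm = label_regions(edges, delta, radius=r)
            phasemaps[r].append(pm)
            for region, area in pm.areas.items():
                area_rows.append({"frame": t, "radius": r, "region": region,
                                  "area": area})
    areas = pd.DataFrame(area_rows)
    _write(areas, out / "phase_areas.tsv")
    results["areas"] = areas
    for r in radii:
        fracs = pd.DataFrame([pm.area_fractions() for pm in phasemaps[r]])
        log.info("radius %.2f nm: mean area fractions %s", r,
                 fracs.mean().round(3).to_dict())

    # -- enrichment (per radius) and depth ---------------------------------
    has_peptides = any((fr.classes() == "peptide").any() for fr in frames)
    if has_peptides:
        assignments = {r: [assign_backbone_regions(fr, pm)
                           for fr, pm in zip(frames, phasemaps[r])]
                       for r in radii}
        results["enrichment"] = {}
        for r in radii:
            rep = enrichment_ratios(assignments[r], phasemaps[r],
                                    n_boot=config.n_boot, level=config.level,
                                    seed=config.seed)
            tag = f"{r:.2f}".replace(".", "p")
            _write(rep.table, out / f"enrichment_r{tag}.tsv")
            _write(rep.per_frame, out / f"enrichment_per_frame_r{tag}.tsv")
            results["enrichment"][r] = rep

        depth_rows = []
        for t, fr in enumerate(frames):
            df = insertion_depth(fr, radius=config.depth_radius)
            df.insert(0, "frame", t)
            depth_rows.append(df)
        depth = pd.concat(depth_rows, ignore_index=True)
        _write(depth, out / "depth.tsv")
        results["depth"] = depth

        # -- clustering ----------------------------------------------------
        clustersets = []
        member_rows = []
        for t, fr in enumerate(frames):
            g = backbone_contact_graph(fr, cutoff=config.cluster_cutoff)
            cs = find_clusters(g, fr)
            clustersets.append(cs)
            for ci, c in enumerate(sorted(cs.clusters, key=min)):
                for p in sorted(c):
                    member_rows.append({"frame": t, "cluster": ci,
                                        "order": len(c), "peptide": p})
        dist = size_distribution(clustersets, n_boot=config.n_boot,
                                 level=config.level, seed=config.seed)
        _write(pd.DataFrame(member_rows), out / "clusters.tsv")
        _write(dist.table, out / "cluster_distribution.tsv")
        results["clusters"] = clustersets
        results["distribution"] = dist
    else:
        log.info("no peptides found; skipping enrichment, depth and clustering")

    # -- energetics --------------------------------------------------------
    if config.forcefield is not None:
        ff = ForceFieldTable.from_tsv(config.forcefield, config.charges)
        tables, closure_rows, energy_rows = [], [], []
        for t, fr in enumerate(frames):
            tab = decompose(fr, phasemaps[config.interface_radius][t], ff,
                            near_cutoff=config.energy_cutoff)
            tables.append(tab)
            cc = closure_check(fr, tab, ff)
            closure_rows.append({"frame": t, **cc})
            df = tab.df.copy()
            df.insert(0, "frame", t)
            energy_rows.append(df)
        _write(pd.concat(energy_rows, ignore_index=True), out / "energy.tsv")
        closure = pd.DataFrame(closure_rows)
        _write(closure, out / "closure.tsv")
        results["energy_tables"] = tables
        results["closure"] = closure
        try:
            st, meta = transfer_enthalpy(tables, n_boot=config.n_boot,
                                         seed=config.seed)
            results["transfer_enthalpy"] = (st, meta)
            with open(out / "transfer_enthalpy.json", "w") as fh:
                json.dump({"mean_kj_per_mol": st.mean, "ci_low": st.ci_low,
                           "ci_high": st.ci_high, "tau": st.tau,
                           "n_eff": st.n_eff, **{k: v for k, v in meta.items()
                                                 if k != "series"}}, fh, indent=1)
        except ValueError as exc:
            log.warning("transfer enthalpy undefined: %s", exc)
    elif config.forcefield is None:
        log.warning("no force-field table configured; energy stage disabled")

    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in dataclasses.asdict(config).items()},
                "version": __version__, "n_frames": len(frames),
                "seed": config.seed}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return results


def _write(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
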