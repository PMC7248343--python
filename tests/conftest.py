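import numpy as np
import pytest

from memphase import synthgen as sg


@pytest.fixture(scope="session")
def stripe_system():
    """Canonical 40x10 nm two-stripe bilayer: pure DPPC left, DLiPC right,
    so the analytic boundaries (x = 0 and 20 nm) are exactly known."""
    spec = sg.MembraneSpec(composition=({"DPPC": 1.0}, {"DLiPC": 1.0}), seed=11)
    return sg.build_stripe_bilayer(spec), spec


@pytest.fixture(scope="session")
def peptide_system():
    """Bilayer with a planned dimer (Ld), a T-pair (Ld, bottom leaflet),
    and isolated peptides in Lo and at the interface."""
    spec = sg.MembraneSpec(seed=7)
    frame, truth = sg.build_stripe_bilayer(spec)
    groups = (
        sg.PeptideGroup(order=2, gap=0.5, region="Ld", leaflet="top"),
        sg.PeptideGroup(order=2, gap=0.5, kind="tee", region="Ld", leaflet="bottom"),
        sg.PeptideGroup(order=1, region="Lo", leaflet="top"),
        sg.PeptideGroup(order=1, region="interface", leaflet="top"),
    )
    placement = sg.PeptidePlacement(groups=groups, depth_offset=0.5, seed=7)
    frame, plan = sg.add_peptides(frame, placement, truth)
    return frame, truth, plan


def make_energy_frame(seed: int, with_solvent: bool = True):
    """Small solvated fixture with peptides on both phases, for energetics."""
    spec = sg.MembraneSpec(box=(24.0, 8.0, 9.0), stripe_boundaries=(12.0,),
                          seed=seed)
    frame, truth = sg.build_stripe_bilayer(spec)
    groups = (
        sg.PeptideGroup(order=2, gap=0.5, region="Ld", leaflet="top"),
        sg.PeptideGroup(order=1, region="Lo", leaflet="top"),
        sg.PeptideGroup(order=1, region="Ld", leaflet="bottom"),
        sg.PeptideGroup(order=1, region="Lo", leaflet="bottom"),
    )
    placement = sg.PeptidePlacement(groups=groups, depth_offset=0.5, seed=seed)
    frame, plan = sg.add_peptides(frame, placement, truth)
    if with_solvent:
        frame = sg.add_solvent_and_ions(frame, number_density=8.35, seed=seed)
    frame.time = float(seed)
    return frame, truth, plan


@pytest.fixture(scope="session")
def energy_system():
    return make_energy_frame(seed=3)


@pytest.fixture(scope="session")
def toy_ff(energy_system):
    frame, _, _ = energy_system
    return sg.toy_forcefield(sorted(set(frame.bead_types)), seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
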