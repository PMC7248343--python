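import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from memphase import synthgen as sg
from memphase.energetics import (EnergyTable, ForceFieldTable, apply_charges,
                                 classify_lipids, closure_check, coulomb_energy,
                                 decompose, group_pair_energy,
                                 leaflet_assignment, lj_energy, neighbor_pairs,
                                 shift_coefficients, shifted_power_term,
                                 transfer_enthalpy)
from memphase.phasemap import segment_frame
from memphase.trajio import Frame
from conftest import make_energy_frame


def quadrature_phi(r, p, r1, rc):
    """Independent oracle: Phi_p(r) = integral of the shifted force r..rc."""
    A, B, C = shift_coefficients(p, r1, rc)

    def force(s):
        f = p * s ** -(p + 1.0)
        if s > r1:
            f += A * (s - r1) ** 2 + B * (s - r1) ** 3
        return f

    if r >= rc:
        return 0.0
    val, _ = quad(force, r, rc, limit=400, epsabs=1e-13, epsrel=1e-13)
    return val


class TestShiftedPotentials:
    @pytest.mark.parametrize("p,r1", [(1, 0.0), (6, 0.9), (12, 0.9)])
    def test_vanishes_at_cutoff_with_zero_slope(self, p, r1):
        rc = 1.2
        assert abs(shifted_power_term(rc, p, r1, rc)) <= 1e-10
        h = 1e-6
        deriv = (shifted_power_term(rc, p, r1, rc)
                 - shifted_power_term(rc - h, p, r1, rc)) / h
        assert abs(deriv) <= 1e-8 * max(1.0, p)

    @pytest.mark.parametrize("p,r1", [(1, 0.0), (6, 0.9), (12, 0.9)])
    @pytest.mark.parametrize("r", [0.45, 0.8, 0.95, 1.1, 1.19])
    def test_matches_force_integration_oracle(self, p, r1, r):
        rc = 1.2
        got = shifted_power_term(r, p, r1, rc)
        want = quadrature_phi(r, p, r1, rc)
        assert got == pytest.approx(want, abs=1e-9 * max(1.0, abs(want)))

    def test_beyond_cutoff_and_domain_errors(self):
        assert shifted_power_term(1.5, 6, 0.9, 1.2) == 0.0
        with pytest.raises(ValueError):
            shifted_power_term(0.0, 6, 0.9, 1.2)
        with pytest.raises(ValueError):
            shift_coefficients(6, 1.2, 0.9)


class TestPairPotentials:
    @pytest.fixture
    def ff(self):
        return ForceFieldTable(pairs={("A", "A"): (1.0, 0.47)})

    def test_lj_zero_cases(self, ff):
        assert lj_energy(1.2, 1.0, 0.47, ff) == 0.0
        assert lj_energy(1.3, 1.0, 0.47, ff) == 0.0
        assert lj_energy(0.5, 0.0, 0.47, ff) == 0.0

    def test_lj_matches_quadrature(self, ff):
        eps, sig, r = 1.0, 0.47, 0.5
        want = (4 * eps * sig ** 12 * quadrature_phi(r, 12, 0.9, 1.2)
                - 4 * eps * sig ** 6 * quadrature_phi(r, 6, 0.9, 1.2))
        assert lj_energy(r, eps, sig, ff) == pytest.approx(want, abs=1e-9)

    def test_coulomb_zero_and_quadrature(self, ff):
        assert coulomb_energy(1.0, 0.0, 1.0, ff) == 0.0
        assert coulomb_energy(1.25, 1.0, 1.0, ff) == 0.0
        want = (138.935 / 15.0) * quadrature_phi(1.0, 1, 0.0, 1.2)
        assert coulomb_energy(1.0, 1.0, 1.0, ff) == pytest.approx(want, abs=1e-9)


def _random_frame(n, box, seed, charged=True):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, 1, size=(n, 3)) * box
    q = rng.choice([-1.0, 0.0, 1.0], size=n) if charged else np.zeros(n)
    return Frame(positions=pos, names=["X"] * n,
                 molecule_ids=np.arange(1, n + 1),
                 molecule_types=["PEP"] * n, bead_types=["X"] * n,
                 charges=q, box=box)


@pytest.fixture(scope="module")
def xx_ff():
    return ForceFieldTable(pairs={("X", "X"): (2.0, 0.5)})


class TestGroupPairEnergy:

    def test_beyond_cutoff_zero(self, xx_ff):
        fr = _random_frame(2, np.array([10.0, 10, 10]), 0)
        fr.positions[:] = [[1, 1, 1], [3, 1, 1]]
        assert group_pair_energy(fr, [0], [1], xx_ff) == (0.0, 0.0)

    def test_symmetry(self, xx_ff):
        fr = _random_frame(100, np.array([5.0, 5, 5]), 1)
        a, b = np.arange(50), np.arange(50, 100)
        e_ab = group_pair_energy(fr, a, b, xx_ff)
        e_ba = group_pair_energy(fr, b, a, xx_ff)
        # identical pair set; only the summation order differs
        assert e_ab == pytest.approx(e_ba, rel=1e-12)

    def test_kdtree_pairs_equal_brute_force(self, xx_ff):
        """Accelerated pair enumeration = all-pairs double loop, exactly."""
        fr = _random_frame(500, np.array([4.0, 5.0, 6.0]), 2)
        sel = np.arange(500)
        ii, jj = neighbor_pairs(fr, sel, sel, 1.2)
        got = {(min(a, b), max(a, b)) for a, b in zip(ii, jj)}
        from memphase.trajio import minimum_image_displacement
        diff = minimum_image_displacement(fr.positions[:, None, :],
                                          fr.positions[None, :, :], fr.box)
        d = np.sqrt((diff ** 2).sum(axis=-1))
        want = {(i, j) for i in range(500) for j in range(i + 1, 500)
                if d[i, j] < 1.2}
        assert got == want

    def test_energy_matches_brute_force_loop(self, xx_ff):
        fr = _random_frame(300, np.array([4.0, 4.0, 4.0]), 3)
        sel = np.arange(300)
        e_lj, e_c = group_pair_energy(fr, sel, sel, xx_ff,
                                      exclude_same_molecule=False)
        from memphase.trajio import minimum_image_distance
        lj = c = 0.0
        for i in range(300):
            for j in range(i + 1, 300):
                r = minimum_image_distance(fr.positions[i], fr.positions[j],
                                           fr.box)
                if r < 1.2:
                    lj += lj_energy(r, 2.0, 0.5, xx_ff)
                    c += coulomb_energy(r, fr.charges[i], fr.charges[j], xx_ff)
        assert e_lj == pytest.approx(lj, rel=1e-10)
        assert e_c == pytest.approx(c, rel=1e-10)

    def test_translation_invariance(self, xx_ff):
        fr = _random_frame(200, np.array([5.0, 5, 5]), 4)
        sel = np.arange(200)
        e0 = group_pair_energy(fr, sel, sel, xx_ff)
        fr2 = fr.copy()
        fr2.positions = fr2.positions + np.array([1.7, -2.3, 0.9])
        e1 = group_pair_energy(fr2, sel, sel, xx_ff)
        assert e0[0] == pytest.approx(e1[0], rel=1e-9)
        assert e0[1] == pytest.approx(e1[1], rel=1e-9)

    def test_unknown_type_reported(self):
        fr = _random_frame(10, np.array([3.0, 3, 3]), 5)
        ff = ForceFieldTable(pairs={("Y", "Y"): (1.0, 0.5)})
        with pytest.raises(KeyError, match="X"):
            group_pair_energy(fr, np.arange(5), np.arange(5, 10), ff)


class TestLeafletAssignment:
    def test_phospholipids_split_by_construction(self, stripe_system):
        (frame, truth), _ = stripe_system
        leaf = leaflet_assignment(frame)
        po4 = frame.names == "PO4"
        top_plane = max(truth["leaflet_planes"])
        for mol, z in zip(frame.molecule_ids[po4], frame.positions[po4, 2]):
            want = "top" if abs(z - top_plane) < 1.0 else "bottom"
            assert int(mol) in leaf[want]

    def test_cholesterol_near_top_plane_is_top(self):
        spec = sg.MembraneSpec(box=(20.0, 8.0, 12.0), stripe_boundaries=(),
                               composition=({"DPPC": 0.7, "CHOL": 0.3},),
                               seed=1)
        frame, truth = sg.build_stripe_bilayer(spec)
        leaf = leaflet_assignment(frame)
        roh = frame.names == "ROH"
        top_plane = max(truth["leaflet_planes"])
        for mol, z in zip(frame.molecule_ids[roh], frame.positions[roh, 2]):
            if abs(z - (top_plane - 0.3)) < 0.5:
                assert int(mol) in leaf["top"]

    def test_midmembrane_cholesterol_unassigned(self):
        # thick bilayer so the midplane is > 2 nm from both phosphate planes
        spec = sg.MembraneSpec(box=(20.0, 8.0, 14.0), stripe_boundaries=(),
                               composition=({"DPPC": 0.7, "CHOL": 0.3},),
                               leaflet_z=(2.8, -2.8), seed=2)
        frame, _ = sg.build_stripe_bilayer(spec)
        moved = sg.displace_cholesterol(frame, n=2, mode="mid", seed=0)
        leaf = leaflet_assignment(moved)
        assert len(leaf["unassigned"]) == 2

    def test_flipped_cholesterol_changes_leaflet(self):
        spec = sg.MembraneSpec(box=(20.0, 8.0, 14.0), stripe_boundaries=(),
                               composition=({"DPPC": 0.7, "CHOL": 0.3},),
                               leaflet_z=(2.8, -2.8), seed=3)
        frame, _ = sg.build_stripe_bilayer(spec)
        before = leaflet_assignment(frame)
        chol = np.unique(frame.molecule_ids[frame.molecule_types == "CHOL"])
        flipped = sg.displace_cholesterol(frame, n=1, mode="opposite", seed=1)
        after = leaflet_assignment(flipped)
        moved = [m for m in chol
                 if (m in before["top"]) != (m in after["top"])]
        assert len(moved) >= 1


@pytest.fixture(scope="module")
def system(energy_system, toy_ff):
    frame, truth, plan = energy_system
    pm = segment_frame(frame)
    return frame, truth, plan, pm, toy_ff


class TestClassifyAndDecompose:

    def test_far_and_near_rules(self, system):
        frame, truth, plan, pm, ff = system
        pep_sel = np.flatnonzero(frame.classes() == "peptide")
        cls = classify_lipids(frame, pm, pep_sel, cutoff=1.2)
        from memphase.trajio import minimum_image_distance
        pep_pos = frame.positions[pep_sel]
        for row in cls.itertuples():
            lip = frame.positions[frame.molecule_ids == row.molecule_id]
            dmin = min(minimum_image_distance(b, pep_pos, frame.box).min()
                       for b in lip)
            assert (row.proximity == "near") == (dmin < 1.2)

    def test_group_counts_account_for_exclusions(self, system):
        frame, truth, plan, pm, ff = system
        tab = decompose(frame, pm, ff)
        four = tab.df[(tab.df.leaflet.isin(["top", "bottom"]))
                      & (tab.df.group_b == "all-lipids")]
        n_in_groups = four.drop_duplicates(["leaflet", "group_a"]).n_a.sum()
        n_lipids = len(np.unique(
            frame.molecule_ids[frame.classes() == "lipid"]))
        assert (n_in_groups + tab.excluded["interfacial_lipids"]
                + tab.excluded["unassigned_cholesterol"]) == n_lipids

    def test_closure_within_engine_bars(self, system):
        """Discriminated sums equal single-pass totals within the reference
        bars of 8e-3 kJ/mol absolute and 3 ppm relative."""
        frame, truth, plan, pm, ff = system
        tab = decompose(frame, pm, ff)
        cc = closure_check(frame, tab, ff)
        assert cc["abs_diff"] <= 8e-3
        assert cc["rel_diff_ppm"] <= 3.0

    def test_no_peptides_near_groups_empty(self, stripe_system, toy_ff):
        (frame, _), _ = stripe_system
        ff = sg.toy_forcefield(sorted(set(frame.bead_types)), seed=0)
        pm = segment_frame(frame)
        tab = decompose(frame, pm, ff)
        near = tab.df[tab.df.group_a.str.endswith("-near")]
        assert (near.n_a == 0).all()
        assert near.e_lj.isna().all()

    def test_rigid_translation_leaves_energies(self, system):
        frame, truth, plan, pm, ff = system
        sel = np.flatnonzero(frame.classes() == "peptide")
        lip = np.flatnonzero(frame.classes() == "lipid")
        e0 = group_pair_energy(frame, sel, lip, ff)
        fr2 = frame.copy()
        fr2.positions = fr2.positions + np.array([3.1, 0.7, 1.9])
        e1 = group_pair_energy(fr2, sel, lip, ff)
        assert e0[0] == pytest.approx(e1[0], rel=1e-9)
        assert e0[1] == pytest.approx(e1[1], rel=1e-9)


def _toy_table(e_near_ld, e_far_ld, e_near_lo, e_far_lo,
               n_near_ld=2, n_near_lo=2, n_pep_ld=1, n_pep_lo=1):
    rows = []
    for leaflet in ("top", "bottom"):
        vals = {("Ld", "near"): (e_near_ld, n_near_ld),
                ("Ld", "far"): (e_far_ld, 10),
                ("Lo", "near"): (e_near_lo, n_near_lo),
                ("Lo", "far"): (e_far_lo, 10)}
        for (phase, prox), (e, n) in vals.items():
            if leaflet == "bottom":
                e, n = np.nan, 0  # single-leaflet toy
            rows.append({"leaflet": leaflet, "group_a": f"{phase}-{prox}",
                         "group_b": "all-lipids", "e_lj": e, "e_coulomb": 0.0,
                         "n_a": n, "n_b": 0,
                         "e_per_a": e / n if n else np.nan})
    return EnergyTable(df=pd.DataFrame(rows),
                       n_peptides={("top", "Ld"): n_pep_ld,
                                   ("top", "Lo"): n_pep_lo},
                       excluded={})


class TestTransferEnthalpy:
    def test_identical_near_far_gives_zero(self):
        tabs = [_toy_table(-20.0, -100.0, -30.0, -150.0)] * 10
        # per-lipid energies equal: near -10 vs far -10 in both phases
        st, meta = transfer_enthalpy(tabs, n_boot=100, seed=0)
        assert st.mean == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy_value(self):
        """4 far lipids + 2 near lipids per phase, 1 peptide per phase.

        Ld: e_near = -12/2 = -6, e_far = -40/10 = -4 -> (e_n - e_f) * N_near
        / N_pep = (-2) * 2 / 1 = -4.  Lo: e_near = -16/2 = -8, e_far = -4
        -> -8.  Transfer = -4 - (-8) = +4 kJ/mol per peptide.
        """
        tabs = [_toy_table(-12.0, -40.0, -16.0, -40.0)] * 10
        st, meta = transfer_enthalpy(tabs, n_boot=100, seed=0)
        assert st.mean == pytest.approx(4.0, abs=1e-12)

    def test_antisymmetry_under_label_swap(self):
        tabs = [_toy_table(-12.0, -40.0, -16.0, -40.0)] * 10
        swapped = [_toy_table(-16.0, -40.0, -12.0, -40.0)] * 10
        a, _ = transfer_enthalpy(tabs, n_boot=100, seed=0)
        b, _ = transfer_enthalpy(swapped, n_boot=100, seed=0)
        assert a.mean == pytest.approx(-b.mean, abs=1e-12)

    def test_phase_without_peptides_flagged(self):
        t = _toy_table(-12.0, -40.0, -16.0, -40.0, n_pep_lo=0)
        with pytest.raises(ValueError, match="no\\s+peptides"):
            transfer_enthalpy([t] * 10, n_boot=100, seed=0)

    def test_end_to_end_on_synthetic_frames(self, toy_ff):
        frames = [make_energy_frame(seed=s)[0] for s in range(1, 9)]
        tabs = [decompose(fr, segment_frame(fr), toy_ff) for fr in frames]
        st, meta = transfer_enthalpy(tabs, n_boot=100, seed=1)
        assert meta["frames_used"] + meta["frames_skipped"] == 8
        assert np.isfinite(st.mean)


def test_apply_charges_roundtrip(tmp_path, stripe_system):
    (frame, _), _ = stripe_system
    ff = ForceFieldTable(pairs={("PO4", "PO4"): (1.0, 0.5)},
                         charges={"PO4": -1.0})
    out = apply_charges(frame, ff)
    assert np.all(out.charges[out.bead_types == "PO4"] == -1.0)
    ff.to_tsv(tmp_path / "pairs.tsv", tmp_path / "charges.tsv")
    back = ForceFieldTable.from_tsv(tmp_path / "pairs.tsv",
                                    tmp_path / "charges.tsv")
    assert back.pairs == ff.pairs
    assert back.charges == ff.charges
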