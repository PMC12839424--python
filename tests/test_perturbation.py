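"""Local-window RMSD, Cα neighborhoods, and the ΔD distance-change statistic."""

import numpy as np
import pytest

import varstruct as vs
from varstruct.perturbation import EmptyWindowError

from conftest import random_rigid, transformed_model


def site(i, label=""):
    return vs.SiteSpec("substitution", wt_index=i, label=label or f"X{i}X")


class TestLocalWindow:
    @pytest.mark.parametrize(
        "i,flank,n,expected",
        [
            (100, 5, 256, tuple(range(95, 106))),
            (1, 5, 256, tuple(range(1, 7))),
            (12, 5, 256, tuple(range(7, 18))),
            (256, 5, 256, tuple(range(251, 257))),
        ],
    )
    def test_window_clipping(self, i, flank, n, expected):
        model = vs.make_helix(n)
        assert vs.local_window(model, site(i), flank) == expected

    def test_insertion_window_maps_to_wt(self):
        model = vs.make_helix(20)
        cmap = vs.map_from_effects(
            [vs.ProteinEffect("inframe_insertion", 11, "", "Y")], 20, 21
        )
        spec = vs.SiteSpec("insertion", mut_index=11)
        window = vs.local_window(model, spec, 2, cmap)
        # mutant residues 9..13 minus the inserted 11 → WT 9, 10, 11, 12
        assert window == (9, 10, 11, 12)


class TestLocalRMSD:
    def test_zero_for_identical(self, helix60):
        cmap = vs.CorrespondenceMap.identity(60)
        sup = vs.superpose(helix60, helix60, cmap)
        for i in (1, 17, 42, 60):
            assert vs.local_rmsd(helix60, helix60, cmap, sup, site(i)).value == (
                pytest.approx(0.0, abs=1e-9)
            )

    def test_recovers_displacement_magnitude(self, displaced_pair):
        """Fit on the undisplaced residues, the displaced window shows the
        full 5 Å excursion."""
        wt, mut, expected = displaced_pair
        full = vs.CorrespondenceMap.identity(60)
        fit = vs.CorrespondenceMap(
            pairs=tuple((i, i) for i in range(1, 61) if not 30 <= i <= 40)
        )
        sup = vs.superpose(wt, mut, fit)
        res = vs.local_rmsd(wt, mut, full, sup, site(35))
        assert res.n_pairs == 11
        assert res.value == pytest.approx(5.0, abs=1e-6)
        assert res.value == pytest.approx(expected.local_rmsd[35], abs=1e-6)

    def test_whole_chain_window_equals_global_rmsd(self, displaced_pair):
        wt, mut, _ = displaced_pair
        cmap = vs.CorrespondenceMap.identity(60)
        sup = vs.superpose(wt, mut, cmap)
        res = vs.local_rmsd(
            wt, mut, cmap, sup, site(30), vs.MetricConfig(flank=60)
        )
        assert res.value == pytest.approx(sup.rmsd_all, abs=1e-9)

    def test_empty_window_errors(self, helix60):
        lone = vs.CorrespondenceMap(
            pairs=((50, 50), (55, 55), (60, 60)),
            wt_only=tuple(range(1, 50)) + (51, 52, 53, 54) + tuple(range(56, 60)),
            mut_only=tuple(i for i in range(1, 60) if i not in (50, 55)),
        )
        sup = vs.superpose(helix60, helix60, lone)
        with pytest.raises(EmptyWindowError):
            vs.local_rmsd(helix60, helix60, lone, sup, site(10),
                          vs.MetricConfig(flank=2))


class TestNeighbors:
    def test_straight_line_trace(self):
        coords = [(4.0 * i, 0.0, 0.0) for i in range(12)]
        model = vs.StructureModel(
            chain_id="A",
            residues=tuple(
                vs.Residue(i + 1, "A", coords[i]) for i in range(12)
            ),
        )
        assert vs.find_neighbors(model, site(6)) == (4, 5, 7, 8)

    def test_cutoff_monotonicity(self, helix60):
        for i in (5, 30, 55):
            small = set(vs.find_neighbors(helix60, site(i),
                                          vs.MetricConfig(neighbor_cutoff=8.0)))
            large = set(vs.find_neighbors(helix60, site(i),
                                          vs.MetricConfig(neighbor_cutoff=10.0)))
            assert small <= large

    def test_matches_brute_force_scan(self, helix60, displaced_pair):
        _, _, expected = displaced_pair
        for s in (30, 35, 40):
            assert vs.find_neighbors(helix60, site(s)) == expected.neighbors[s]

    def test_insertion_site_neighbors_mapped_back(self):
        wt = vs.make_helix(20)
        cmap = vs.map_from_effects(
            [vs.ProteinEffect("inframe_insertion", 11, "", "Y")], 20, 21
        )
        # mutant = WT with one extra residue spliced in at position 11
        coords = list(wt.ca_array())
        coords.insert(10, np.array([50.0, 50.0, 50.0]))  # far away: no neighbors
        mut = vs.StructureModel(
            chain_id="A",
            residues=tuple(
                vs.Residue(i + 1, "A", tuple(c)) for i, c in enumerate(coords)
            ),
        )
        spec = vs.SiteSpec("insertion", mut_index=11)
        assert vs.find_neighbors(wt, spec, mut=mut, cmap=cmap) == ()


class TestDeltaD:
    def test_zero_for_identical(self, helix60):
        cmap = vs.CorrespondenceMap.identity(60)
        s = site(30)
        neigh = vs.find_neighbors(helix60, s)
        for rec in vs.compute_delta_d(helix60, helix60, cmap, s, neigh):
            assert rec.delta_d == pytest.approx(0.0, abs=1e-12)
            assert not rec.flagged

    def test_matches_generator_oracle(self, displaced_pair):
        wt, mut, expected = displaced_pair
        cmap = vs.CorrespondenceMap.identity(60)
        for s_idx in (30, 35, 40):
            s = site(s_idx)
            neigh = vs.find_neighbors(wt, s)
            recs = vs.compute_delta_d(wt, mut, cmap, s, neigh)
            assert len(recs) == len(expected.neighbors[s_idx])
            for rec in recs:
                exp = expected.delta_d[(s_idx, rec.neighbor_wt_index)]
                assert rec.delta_d == pytest.approx(exp, abs=1e-9)
                assert rec.delta_d == pytest.approx(rec.d_mut - rec.d_wt, abs=1e-12)

    def test_invariant_under_rigid_motion_of_either_input(
        self, displaced_pair, rng
    ):
        wt, mut, _ = displaced_pair
        cmap = vs.CorrespondenceMap.identity(60)
        s = site(30)
        neigh = vs.find_neighbors(wt, s)
        base = [r.delta_d for r in vs.compute_delta_d(wt, mut, cmap, s, neigh)]
        for _ in range(3):
            R, t = random_rigid(rng)
            moved_mut = transformed_model(mut, R, t)
            got = [r.delta_d for r in vs.compute_delta_d(wt, moved_mut, cmap, s, neigh)]
            np.testing.assert_allclose(got, base, atol=1e-9)
            R2, t2 = random_rigid(rng)
            moved_wt = transformed_model(wt, R2, t2)
            got2 = [r.delta_d for r in vs.compute_delta_d(moved_wt, mut, cmap, s, neigh)]
            np.testing.assert_allclose(got2, base, atol=1e-9)

    def test_antisymmetric_under_swap(self, displaced_pair):
        wt, mut, _ = displaced_pair
        cmap = vs.CorrespondenceMap.identity(60)
        s = site(30)
        neigh = vs.find_neighbors(wt, s)
        fwd = vs.compute_delta_d(wt, mut, cmap, s, neigh)
        rev = vs.compute_delta_d(mut, wt, cmap, s, neigh)
        for a, b in zip(fwd, rev):
            assert a.delta_d == pytest.approx(-b.delta_d, abs=1e-12)

    def test_flags_follow_threshold(self, displaced_pair):
        wt, mut, expected = displaced_pair
        cmap = vs.CorrespondenceMap.identity(60)
        cfg = vs.MetricConfig(flag_threshold=3.0)
        # boundary site 30: neighbors 26-29 lie outside the displaced segment
        s = site(30)
        recs = vs.compute_delta_d(wt, mut, cmap, s, vs.find_neighbors(wt, s, cfg), cfg)
        for rec in recs:
            exp = expected.delta_d[(30, rec.neighbor_wt_index)]
            assert rec.flagged == (abs(exp) >= 3.0)
        assert any(r.flagged for r in recs)


class TestReport:
    def test_zero_perturbation_all_zero(self, helix60):
        cmap = vs.CorrespondenceMap.identity(60)
        rep = vs.perturbation_report(
            helix60, helix60, cmap, [site(10), site(30), site(50)]
        )
        assert rep.superposition.rmsd_all == pytest.approx(0.0, abs=1e-9)
        assert all(r.value == pytest.approx(0.0, abs=1e-9) for r in rep.local)
        assert not any(r.flagged for r in rep.delta_d)
        assert rep.failures == ()

    def test_row_counts(self, displaced_pair):
        wt, mut, expected = displaced_pair
        cmap = vs.CorrespondenceMap.identity(60)
        sites = [site(30), site(35), site(40)]
        rep = vs.perturbation_report(wt, mut, cmap, sites)
        assert len(rep.local) == 3
        assert len(rep.delta_d) == sum(len(expected.neighbors[s]) for s in (30, 35, 40))
        # deterministic ordering: sites then neighbors ascending
        keys = [(r.site.wt_index, r.neighbor_wt_index) for r in rep.delta_d]
        assert keys == sorted(keys)

    def test_per_site_failure_does_not_abort(self, displaced_pair):
        wt, mut, _ = displaced_pair
        cmap = vs.CorrespondenceMap(
            pairs=tuple((i, i) for i in range(1, 60)), wt_only=(60,), mut_only=(60,)
        )
        rep = vs.perturbation_report(wt, mut, cmap, [site(30), site(60, "bad")])
        assert len(rep.local) == 1
        assert rep.failures and rep.failures[0][0] == "bad"
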