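import numpy as np
import pandas as pd
import pytest

from saxsconf import (
    AtomModel,
    DomainDecomposition,
    build_restraints,
    default_decomposition,
    make_two_state_toy,
    sample_conformations,
)
from saxsconf.conformers import CA_CA_BOND, group_beads
from saxsconf.core_io import _ATOM_COLUMNS


class TestDefaultDecomposition:
    def test_three_rigid_groups(self):
        d = default_decomposition()
        assert set(d.rigid_groups) == {"CARF-dimer", "nuclease-like", "nuclease"}
        assert d.reference == "CARF-dimer"

    def test_carf_dimer_spans_both_carf_domains(self):
        d = default_decomposition()
        ivals = d.rigid_groups["CARF-dimer"]
        assert ("A", 3, 151) in ivals and ("A", 293, 422) in ivals

    def test_hinge_loop_is_a_linker_not_a_group(self):
        d = default_decomposition()
        assert ("A", 423, 428) in d.linkers
        for ivals in d.rigid_groups.values():
            for chain, a, b in ivals:
                assert not (a <= 423 <= b or a <= 428 <= b)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="two rigid groups"):
            DomainDecomposition(
                rigid_groups={"x": (("A", 1, 10),), "y": (("A", 10, 20),)}
            )


def _toy():
    return make_two_state_toy(seed=7)


class TestBuildRestraints:
    def test_ground_state_satisfies_own_restraints(self):
        toy = _toy()
        rs = build_restraints(toy.decomposition, toy.closed_model,
                              dmax=120.0, q_max=0.11)
        groups = group_beads(toy.closed_model, toy.decomposition)
        coms = {g: gb.com for g, gb in groups.items()}
        for r in rs.restraints:
            d = np.linalg.norm(coms[r.group_a] - coms[r.group_b])
            assert r.lower - 1e-9 <= d <= r.upper + 1e-9

    def test_upper_bounds_capped_at_dmax(self):
        toy = _toy()
        rs = build_restraints(toy.decomposition, toy.closed_model,
                              dmax=75.0, q_max=0.05)
        assert all(r.upper <= 75.0 + 1e-9 for r in rs.restraints)

    def test_window_half_width_is_pi_over_qmax(self):
        toy = _toy()
        rs = build_restraints(toy.decomposition, toy.closed_model,
                              dmax=500.0, q_max=0.25)
        groups = group_beads(toy.closed_model, toy.decomposition)
        coms = {g: gb.com for g, gb in groups.items()}
        half = np.pi / 0.25
        for r in rs.restraints:
            d0 = np.linalg.norm(coms[r.group_a] - coms[r.group_b])
            assert r.upper == pytest.approx(min(500.0, d0 + half))
            assert r.lower == pytest.approx(max(0.0, d0 - half))

    def test_window_mode_adds_anchor_caps(self):
        toy = _toy()
        rs = build_restraints(toy.decomposition, toy.closed_model,
                              dmax=120.0, q_max=0.11, mode="window:+-5A")
        anchors = [r for r in rs.restraints if r.group_b.startswith("anchor:")]
        assert {r.group_a for r in anchors} == {"domain2", "domain3"}
        assert all(r.upper == 5.0 for r in anchors)

    def test_dmax_below_ground_distance_errors(self):
        toy = _toy()
        with pytest.raises(ValueError, match="exceeds dmax"):
            build_restraints(toy.decomposition, toy.closed_model,
                             dmax=40.0, q_max=0.11)


class TestSampler:
    def test_n_zero_gives_empty_list(self):
        toy = _toy()
        rs = build_restraints(toy.decomposition, toy.closed_model, 120.0, 0.11)
        assert sample_conformations(toy.closed_model, toy.decomposition, rs,
                                    n=0, seed=1) == []

    def test_null_moves_reproduce_ground(self):
        toy = _toy()
        rs = build_restraints(toy.decomposition, toy.closed_model, 120.0, 0.11)
        confs = sample_conformations(toy.closed_model, toy.decomposition, rs,
                                     n=3, seed=1, max_rot=0.0, max_trans=0.0)
        groups = group_beads(toy.closed_model, toy.decomposition,
                            scheme="calpha-weighted")
        ground = np.concatenate([g.coords for g in groups.values()])
        for c in confs:
            np.testing.assert_allclose(c.coordinates, ground, atol=1e-12)

    def test_same_seed_bit_identical(self):
        toy = _toy()
        rs = build_restraints(toy.decomposition, toy.closed_model, 120.0, 0.11)
        a = sample_conformations(toy.closed_model, toy.decomposition, rs,
                                 n=5, seed=42)
        b = sample_conformations(toy.closed_model, toy.decomposition, rs,
                                 n=5, seed=42)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.coordinates, cb.coordinates)

    def test_reference_group_fixed_across_conformations(self):
        toy = _toy()
        rs = build_restraints(toy.decomposition, toy.closed_model, 120.0, 0.11)
        confs = sample_conformations(toy.closed_model, toy.decomposition, rs,
                                     n=10, seed=3)
        nref = 120  # beads in domain1
        ref0 = confs[0].coordinates[:nref]
        for c in confs[1:]:
            np.testing.assert_array_equal(c.coordinates[:nref], ref0)

    def test_transforms_reproduce_coordinates(self):
        toy = _toy()
        rs = build_restraints(toy.decomposition, toy.closed_model, 120.0, 0.11)
        confs = sample_conformations(toy.closed_model, toy.decomposition, rs,
                                     n=5, seed=9)
        groups = group_beads(toy.closed_model, toy.decomposition)
        names = list(groups)
        for c in confs:
            off = 0
            for g in names:
                n = groups[g].coords.shape[0]
                block = c.coordinates[off:off + n]
                if g in c.transforms:
                    R, t = c.transforms[g]
                    com = groups[g].coords.mean(axis=0)
                    expect = (groups[g].coords - com) @ R.T + com + t
                else:
                    expect = groups[g].coords
                np.testing.assert_allclose(block, expect, atol=1e-12)
                off += n

    def test_emitted_states_pass_brute_force_verifier(self):
        toy = _toy()
        rs = build_restraints(toy.decomposition, toy.closed_model, 120.0, 0.11)
        confs = sample_conformations(toy.closed_model, toy.decomposition, rs,
                                     n=200, seed=17, clash_dist=2.0)
        groups = group_beads(toy.closed_model, toy.decomposition)
        names = list(groups)
        sizes = [groups[g].coords.shape[0] for g in names]
        offsets = np.cumsum([0] + sizes)
        for c in confs:
            blocks = {g: c.coordinates[offsets[i]:offsets[i + 1]]
                      for i, g in enumerate(names)}
            coms = {g: b.mean(axis=0) for g, b in blocks.items()}
            for r in rs.restraints:
                if r.group_b.startswith("anchor:"):
                    d = np.linalg.norm(coms[r.group_a] - groups[r.group_a].com)
                else:
                    d = np.linalg.norm(coms[r.group_a] - coms[r.group_b])
                assert r.lower - 1e-6 <= d <= r.upper + 1e-6
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    diff = blocks[a][:, None] - blocks[b][None]
                    assert np.sqrt((diff**2).sum(-1).min()) >= 2.0 - 1e-9

    def test_window_mode_caps_displacement(self):
        toy = _toy()
        rs5 = build_restraints(toy.decomposition, toy.closed_model, 120.0, 0.11,
                               mode="window:+-5A")
        confs = sample_conformations(toy.closed_model, toy.decomposition, rs5,
                                     n=50, seed=21)
        for c in confs:
            for g, (R, t) in c.transforms.items():
                assert np.linalg.norm(t) <= 5.0 + 1e-6

    def test_unconstrained_mode_explores_beyond_5A(self):
        toy = _toy()
        rs = build_restraints(toy.decomposition, toy.closed_model, 120.0, 0.11)
        confs = sample_conformations(toy.closed_model, toy.decomposition, rs,
                                     n=100, seed=23)
        disp = [np.linalg.norm(c.transforms["domain3"][1]) for c in confs]
        assert max(disp) > 5.0

    def test_infeasible_restraints_raise_acceptance_error(self):
        toy = _toy()
        # contradictory: require domain3 anchored while pair windows are tiny
        rs = build_restraints(toy.decomposition, toy.closed_model, 120.0, 0.11)
        from saxsconf.conformers import Restraint, RestraintSet

        tight = RestraintSet(
            tuple(Restraint(r.group_a, r.group_b, 119.0, 120.0)
                  for r in rs.restraints),
            dmax=120.0,
        )
        with pytest.raises(RuntimeError, match="acceptance rate"):
            sample_conformations(toy.closed_model, toy.decomposition, tight,
                                 n=5, seed=1)


class TestLinkerContinuity:
    def test_linker_gap_limits_separation(self):
        # two 30-residue helical-ish chains joined by a 2-residue linker:
        # flanking C-alphas may not separate beyond 3.8 * 3 * stretch
        rows = []
        for r in range(1, 31):
            rows.append(("A", r, "ALA", "CA", "C", 3.8 * r, 0.0, 0.0, 10.0, False))
        for r in range(33, 63):
            rows.append(("A", r, "ALA", "CA", "C", 3.8 * r, 0.0, 0.0, 10.0, False))
        model = AtomModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS))
        decomp = DomainDecomposition(
            rigid_groups={"a": (("A", 1, 30),), "b": (("A", 33, 62),)},
            linkers=(("A", 31, 32),),
            reference="a",
        )
        rs = build_restraints(decomp, model, dmax=500.0, q_max=0.02)
        confs = sample_conformations(model, decomp, rs, n=40, seed=2,
                                     max_trans=8.0, stride=5)
        groups = group_beads(model, decomp)
        allowed = CA_CA_BOND * 3 * 1.0
        for c in confs:
            a_end = c.coordinates[29]
            b_start = c.coordinates[30]
            assert np.linalg.norm(a_end - b_start) <= allowed + 1e-9
            assert c.max_linker_gap <= allowed + 1e-9
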