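import numpy as np
import pandas as pd
import pytest

from saxsconf import (
    AtomModel,
    align_domains,
    domain_bfactor_summary,
    kabsch,
    transplant_ligand,
)
from saxsconf.compare import SuperpositionResult
from saxsconf.conformers import DomainDecomposition
from saxsconf.core_io import _ATOM_COLUMNS


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _fold(n=80, seed=0):
    """A random smooth 3-D walk standing in for a compact C-alpha trace."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    smooth = np.cumsum(0.6 * steps + 0.4 * np.roll(steps, 1, axis=0), axis=0)
    return smooth * 3.8 / np.linalg.norm(np.diff(smooth, axis=0), axis=1).mean()


class TestKabsch:
    def test_identity(self):
        P = _fold()
        res = kabsch(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rigid_motion(self):
        P = _fold(seed=1)
        R = _rotation([1, 2, 3], 1.1)
        t = np.array([4.0, -7.0, 2.5])
        Q = (P - t) @ R  # so that Q @ R.T + t = P  with rotation R.T
        res = kabsch(P, Q)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.apply(Q), P, atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_noise_rmsd_matches_expectation(self):
        rng = np.random.default_rng(2)
        P = _fold(200, seed=3)
        Q = P + rng.normal(0, 0.5, P.shape)
        res = kabsch(P, Q)
        assert res.rmsd == pytest.approx(0.5 * np.sqrt(3), rel=0.10)

    def test_rotation_always_proper(self):
        # mirrored target would otherwise induce a reflection
        P = _fold(seed=4)
        Q = P * np.array([-1.0, 1.0, 1.0])
        res = kabsch(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_inputs_rejected(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch(line, line)

    def test_rmsd_invariant_under_joint_prerotation(self):
        rng = np.random.default_rng(5)
        P = _fold(seed=6)
        Q = P + rng.normal(0, 1.0, P.shape)
        base = kabsch(P, Q).rmsd
        R = _rotation([0, 1, 1], 0.8)
        assert kabsch(P @ R.T, Q @ R.T).rmsd == pytest.approx(base, rel=1e-9)


class TestAlignDomains:
    def test_self_alignment_is_exact(self):
        A = _fold(100, seed=7)
        res = align_domains(A, A.copy())
        assert res.n_matched == 100
        assert res.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rotated_copy_with_deletion(self):
        A = _fold(100, seed=8)
        R = _rotation([1, 0, 2], 0.9)
        B = np.delete(A, slice(40, 50), axis=0) @ R.T + np.array([10.0, 0, 5])
        res = align_domains(A, B)
        assert res.n_matched == 90
        assert res.rmsd == pytest.approx(0.0, abs=1e-3)

    def test_perturbed_homolog_matches_most_residues(self):
        rng = np.random.default_rng(9)
        A = _fold(120, seed=10)
        B = (A + rng.normal(0, 0.8, A.shape)) @ _rotation([1, 1, 0], 0.5).T
        res = align_domains(A, B)
        assert res.n_matched >= 110
        assert res.rmsd < 2.0

    def test_unrelated_folds_rejected(self):
        A = _fold(60, seed=11) * 0.2  # collapsed blob, nothing matches at 4 A
        B = _fold(60, seed=12) + 500.0
        with pytest.raises(ValueError, match="non-homologous|matched"):
            align_domains(A, B, d_cut=0.05)


def _model_from_coords(coords, bfactor=20.0, resnum0=1, het=False, element="C"):
    rows = [
        ("A", resnum0 + i, "ALA", "CA", element, x, y, z, bfactor, het)
        for i, (x, y, z) in enumerate(np.asarray(coords, float))
    ]
    return AtomModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS))


class TestTransplantLigand:
    def test_identity_transform_keeps_ligand(self):
        acceptor = _model_from_coords(_fold(30, seed=13))
        donor = _model_from_coords(_fold(30, seed=14) + 30.0)
        ident = SuperpositionResult(np.eye(3), np.zeros(3), 0.0, 0)
        mask = donor.atoms["resnum"] <= 3
        combined, dmin = transplant_ligand(acceptor, donor, mask, ident)
        lig = combined.atoms[combined.atoms["het"]]
        np.testing.assert_allclose(
            lig[["x", "y", "z"]].to_numpy(),
            donor.atoms[np.asarray(mask)][["x", "y", "z"]].to_numpy(),
        )

    def test_transform_roundtrip(self):
        donor = _model_from_coords(_fold(30, seed=15))
        acceptor = _model_from_coords(_fold(30, seed=16))
        R = _rotation([2, 1, 1], 0.7)
        sup = SuperpositionResult(R, np.array([1.0, 2.0, 3.0]), 0.0, 0)
        mask = donor.atoms["resnum"] <= 5
        once, _ = transplant_ligand(acceptor, donor, mask, sup)
        lig_once = once.atoms[once.atoms["het"]]
        lig_model = AtomModel(lig_once.reset_index(drop=True))
        back, _ = transplant_ligand(acceptor, lig_model,
                                    np.ones(len(lig_once), bool), sup.inverse())
        lig_back = back.atoms[back.atoms["het"]]
        np.testing.assert_allclose(
            lig_back[["x", "y", "z"]].to_numpy(),
            donor.atoms[np.asarray(mask)][["x", "y", "z"]].to_numpy(),
            atol=1e-9,
        )

    def test_min_distance_matches_brute_force(self):
        acceptor = _model_from_coords(_fold(40, seed=17))
        donor = _model_from_coords(_fold(10, seed=18) + 15.0)
        ident = SuperpositionResult(np.eye(3), np.zeros(3), 0.0, 0)
        mask = np.ones(len(donor.atoms), bool)
        _, dmin = transplant_ligand(acceptor, donor, mask, ident)
        brute = np.min(
            np.linalg.norm(
                acceptor.coords[:, None] - donor.coords[None], axis=-1
            )
        )
        assert dmin == pytest.approx(brute, rel=1e-12)

    def test_empty_selection_rejected(self):
        m = _model_from_coords(_fold(10, seed=19))
        ident = SuperpositionResult(np.eye(3), np.zeros(3), 0.0, 0)
        with pytest.raises(ValueError, match="empty ligand"):
            transplant_ligand(m, m, np.zeros(10, bool), ident)


class TestBfactorSummary:
    decomp = DomainDecomposition(
        rigid_groups={"first": (("A", 1, 10),), "second": (("A", 11, 20),)}
    )

    def test_uniform_bfactors(self):
        m = _model_from_coords(_fold(20, seed=20), bfactor=20.0)
        s = domain_bfactor_summary(m, self.decomp)
        assert s.loc["first", "mean"] == pytest.approx(20.0)
        assert s.loc["second", "mean"] == pytest.approx(20.0)

    def test_doubled_group_stands_out(self):
        m = _model_from_coords(_fold(20, seed=21), bfactor=20.0)
        atoms = m.atoms.copy()
        atoms.loc[atoms["resnum"] > 10, "bfactor"] = 40.0
        s = domain_bfactor_summary(AtomModel(atoms), self.decomp)
        assert s["mean"].idxmax() == "second"

    def test_matches_brute_force(self):
        rng = np.random.default_rng(22)
        m = _model_from_coords(_fold(20, seed=23))
        atoms = m.atoms.copy()
        atoms["bfactor"] = rng.uniform(5, 80, len(atoms))
        model = AtomModel(atoms)
        s = domain_bfactor_summary(model, self.decomp)
        manual = atoms[atoms["resnum"] <= 10]["bfactor"]
        assert s.loc["first", "mean"] == pytest.approx(manual.mean())
        assert s.loc["first", "median"] == pytest.approx(manual.median())

    def test_empty_group_errors(self):
        m = _model_from_coords(_fold(10, seed=24))
        decomp = DomainDecomposition(rigid_groups={"ghost": (("B", 1, 5),)})
        with pytest.raises(ValueError, match="no atoms"):
            domain_bfactor_summary(m, decomp)
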