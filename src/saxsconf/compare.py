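"""Structure superposition and comparison utilities.

Least-squares (Kabsch) fitting, a sequence-independent iterative-trim
C-alpha correspondence for comparing homologous domains, ligand
transplantation between superposed structures, and per-domain
temperature-factor summaries.  The correspondence search is a deliberate
approximation of full distance-matrix alignment: it seeds pairs from the
best gapless alignment of local C-alpha distance profiles and then
alternates superposition with order-preserving nearest-neighbour re-pairing
under a distance cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core_io import AtomModel
from .conformers import DomainDecomposition

__all__ = [
    "SuperpositionResult",
    "kabsch",
    "align_domains",
    "transplant_ligand",
    "domain_bfactor_summary",
]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray      # 3x3 proper orthogonal, applied to the mobile set
    translation: np.ndarray   # A
    rmsd: float
    n_matched: int
    correspondence: tuple[tuple[int, int], ...] = ()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "SuperpositionResult":
        Rt = self.rotation.T
        return SuperpositionResult(
            Rt, -Rt @ self.translation, self.rmsd, self.n_matched, self.correspondence
        )


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of Q onto P (both (N,3), N >= 3).

    Returns the proper rotation R and translation t minimising
    ||P - (Q R^T + t)||; reflections are corrected by flipping the smallest
    singular direction.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("P and Q must be equal-shape (N, 3) arrays with N >= 3")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1e-300):
        raise ValueError("degenerate (collinear) point sets")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    diff = P - (Q @ R.T + t)
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return SuperpositionResult(R, t, rmsd, P.shape[0])


def _order_preserving_pairs(
    A: np.ndarray, B_moved: np.ndarray, d_cut: float
) -> list[tuple[int, int]]:
    """Maximum sequence-order-preserving matching within d_cut.

    LCS-style dynamic programme: maximise the number of matched pairs
    (ties broken toward smaller summed distance) subject to the
    correspondence being strictly increasing in both sequences.
    """
    D = cdist(A, B_moved)
    na, nb = D.shape
    eligible = D <= d_cut
    # score = pairs - eps * distance, so cardinality dominates
    eps = 1e-4 / max(d_cut, 1e-6)
    gain = np.where(eligible, 1.0 - eps * D, -np.inf)
    dp = np.zeros((na + 1, nb + 1))
    for i in range(1, na + 1):
        diag = dp[i - 1, :-1] + gain[i - 1]
        row = np.maximum(dp[i - 1, 1:], diag)
        dp[i, 1:] = np.maximum.accumulate(row)
        dp[i, 0] = 0.0
    pairs: list[tuple[int, int]] = []
    i, j = na, nb
    while i > 0 and j > 0:
        if eligible[i - 1, j - 1] and np.isclose(
            dp[i, j], dp[i - 1, j - 1] + gain[i - 1, j - 1]
        ):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif dp[i, j] == dp[i - 1, j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _seed_offsets(A: np.ndarray, B: np.ndarray, min_window: int = 20):
    """Candidate gapless window alignments of local C-alpha distance profiles.

    The per-residue descriptor is the vector of distances to the next
    ``w`` residues (rotation invariant); sliding B against A, the offsets
    with the smallest mean descriptor discrepancy over the overlap seed
    the correspondence search (best five are returned for restarts).
    """
    w = 8

    def profile(X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        out = np.zeros((n, w))
        for k in range(1, w + 1):
            d = np.linalg.norm(X[k:] - X[:-k], axis=1)
            out[: n - k, k - 1] = d
            out[n - k:, k - 1] = d[-1] if d.size else 0.0
        return out

    pa, pb = profile(A), profile(B)
    na, nb = A.shape[0], B.shape[0]
    scored: list[tuple[float, int]] = []
    for off in range(-(nb - min_window), na - min_window + 1):
        i0, j0 = max(0, off), max(0, -off)
        L = min(na - i0, nb - j0)
        if L < min_window:
            continue
        scored.append((float(np.mean(np.abs(pa[i0:i0 + L] - pb[j0:j0 + L]))), off))
    if not scored:
        raise ValueError("point sets too short to seed an alignment")
    scored.sort()
    seeds = []
    for _, off in scored[:5]:
        i0, j0 = max(0, off), max(0, -off)
        L = min(na - i0, nb - j0)
        seeds.append([(i0 + k, j0 + k) for k in range(L)])
    return seeds


def align_domains(
    A: np.ndarray,
    B: np.ndarray,
    d_cut: float = 4.0,
    max_iter: int = 20,
    resnums_a: np.ndarray | None = None,
    resnums_b: np.ndarray | None = None,
) -> SuperpositionResult:
    """Sequence-independent superposition of two C-alpha traces.

    Iterates Kabsch fitting on the current pairs with order-preserving
    re-pairing of each A residue to its nearest transformed B residue
    within ``d_cut`` until the pair set is stable.  Correspondence indices
    are reported as residue numbers when ``resnums_*`` are given, else as
    0-based positions.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape[0] < 20 or B.shape[0] < 20:
        raise ValueError("need at least 20 C-alpha positions per set")

    def refine(seed_pairs):
        pairs = seed_pairs
        prev = None
        for _ in range(max_iter):
            ia = [p[0] for p in pairs]
            ib = [p[1] for p in pairs]
            res = kabsch(A[ia], B[ib])
            pairs = _order_preserving_pairs(A, res.apply(B), d_cut)
            if len(pairs) < 3:
                return None, []
            if pairs == prev:
                break
            prev = pairs
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        return kabsch(A[ia], B[ib]), pairs

    best: tuple | None = None
    for seed in _seed_offsets(A, B):
        try:
            res, pairs = refine(seed)
        except ValueError:
            continue
        if res is None:
            continue
        key = (-len(pairs), res.rmsd)
        if best is None or key < best[0]:
            best = (key, res, pairs)
    if best is None or len(best[2]) < 10:
        n = 0 if best is None else len(best[2])
        raise ValueError(
            f"only {n} matched pairs within {d_cut} A: folds appear non-homologous"
        )
    _, result, pairs = best
    ia = [p[0] for p in pairs]
    ib = [p[1] for p in pairs]
    if resnums_a is not None and resnums_b is not None:
        corr = tuple((int(resnums_a[i]), int(resnums_b[j])) for i, j in pairs)
    else:
        corr = tuple((int(i), int(j)) for i, j in pairs)
    return SuperpositionResult(
        result.rotation, result.translation, result.rmsd, len(pairs), corr
    )


def transplant_ligand(
    acceptor: AtomModel,
    donor: AtomModel,
    ligand_mask: pd.Series | np.ndarray,
    transform: SuperpositionResult,
) -> tuple[AtomModel, float]:
    """Move the donor's ligand atoms by ``transform`` into the acceptor model.

    ``transform`` must map donor-protein coordinates onto the acceptor
    frame.  Returns the combined model and the minimum heavy-atom distance
    between the transplanted ligand and the acceptor (no clash filtering is
    applied; the distance lets the caller judge).
    """
    lig = donor.atoms[np.asarray(ligand_mask, bool)].copy()
    if lig.empty:
        raise ValueError("empty ligand selection")
    moved = transform.apply(lig[["x", "y", "z"]].to_numpy(float))
    lig[["x", "y", "z"]] = moved
    lig["het"] = True
    acc = acceptor.atoms[acceptor.atoms["element"] != "H"]
    dmin = float(cdist(moved, acc[["x", "y", "z"]].to_numpy(float)).min())
    combined = pd.concat([acceptor.atoms, lig], ignore_index=True)
    return AtomModel(combined, source_id=f"{acceptor.source_id}+ligand"), dmin


def domain_bfactor_summary(
    model: AtomModel,
    decomp: DomainDecomposition,
    calpha_only: bool = False,
) -> pd.DataFrame:
    """Mean/median/sd of temperature factors per rigid group."""
    prot = model.protein()
    if calpha_only:
        prot = prot[prot["atom"] == "CA"]
    rows = []
    for name, ivals in decomp.rigid_groups.items():
        mask = np.zeros(len(prot), dtype=bool)
        for chain, a, b in ivals:
            mask |= ((prot["chain"] == chain) & prot["resnum"].between(a, b)).to_numpy()
        sub = prot[mask]
        if sub.empty:
            raise ValueError(f"group {name!r} has no atoms in the model")
        bf = sub["bfactor"].to_numpy(float)
        rows.append((name, len(bf), bf.mean(), float(np.median(bf)), bf.std(ddof=1)))
    return pd.DataFrame(rows, columns=["group", "n_atoms", "mean", "median", "sd"]).set_index("group")
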