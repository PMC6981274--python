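"""Restrained rigid-body conformational sampling.

The crystal structure's domains are treated as rigid groups: the two CARF
domains move as one unit (the CARF dimer, held fixed as the frame of
reference) while the nuclease and/or nuclease-like domains are perturbed by
random rigid motions.  Proposals are accepted when they satisfy
centre-of-mass distance restraints derived from the measured P(r)
(no inter-domain distance may exceed d_max; distances stay within a window
of half-width pi/q_max — the nominal resolution of the data — around their
ground-state values), avoid inter-group C-alpha clashes, and keep the
tethering linkers geometrically plausible.  All accepted states are equally
probable: the sampler explores the feasible region uniformly by a random
walk, recording every ``stride``-th accepted state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AtomModel, select_calpha
from .debye import RESIDUE_ELECTRONS, _DEFAULT_ELECTRONS, BeadModel

__all__ = [
    "DomainDecomposition",
    "Restraint",
    "RestraintSet",
    "Conformation",
    "default_decomposition",
    "group_beads",
    "build_restraints",
    "sample_conformations",
]

CA_CA_BOND = 3.8  # A, ideal consecutive C-alpha distance


@dataclass(frozen=True)
class DomainDecomposition:
    """Rigid groups (name -> residue intervals) plus unconstrained linkers.

    ``reference`` names the group held fixed as the frame of reference
    during sampling.  Intervals are (chain, first, last), inclusive, author
    numbering.
    """

    rigid_groups: dict[str, tuple[tuple[str, int, int], ...]]
    linkers: tuple[tuple[str, int, int], ...] = ()
    reference: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for name, ivals in self.rigid_groups.items():
            for chain, a, b in ivals:
                for r in range(a, b + 1):
                    key = (chain, r)
                    if key in seen:
                        raise ValueError(f"residue {chain}/{r} in two rigid groups")
                    seen.add(key)
        for chain, a, b in self.linkers:
            for r in range(a, b + 1):
                if (chain, r) in seen:
                    raise ValueError(f"linker residue {chain}/{r} also in a rigid group")
        if self.reference and self.reference not in self.rigid_groups:
            raise ValueError(f"unknown reference group {self.reference!r}")

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self.rigid_groups)


def default_decomposition(chain: str = "A") -> DomainDecomposition:
    """Can1 decomposition: the CARF dimer (both CARF domains) as one rigid
    unit, the nuclease-like domain, and the nuclease domain.

    The hinge loop 423-428 is an unconstrained tether, so the nuclease
    rigid group starts at 429 (the loop overlaps the nominal 426-638 domain
    boundary; the tether takes precedence so it can flex).
    """
    return DomainDecomposition(
        rigid_groups={
            "CARF-dimer": ((chain, 3, 151), (chain, 293, 422)),
            "nuclease-like": ((chain, 168, 276),),
            "nuclease": ((chain, 429, 638),),
        },
        linkers=((chain, 152, 167), (chain, 277, 292), (chain, 423, 428)),
        reference="CARF-dimer",
    )


@dataclass(frozen=True)
class GroupBeads:
    """Per-group one-bead-per-residue coordinates used by the sampler."""

    name: str
    coords: np.ndarray          # (N, 3) ground-state C-alpha positions
    form_factors: np.ndarray    # (N,)
    resnums: np.ndarray         # (N,) author numbering
    chains: np.ndarray          # (N,) chain ids

    @property
    def com(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def group_beads(
    model: AtomModel,
    decomp: DomainDecomposition,
    scheme: str = "calpha-weighted",
) -> dict[str, GroupBeads]:
    """Extract C-alpha beads for every rigid group of a decomposition."""
    out: dict[str, GroupBeads] = {}
    prot = model.protein()
    ca = prot[prot["atom"] == "CA"]
    for name, ivals in decomp.rigid_groups.items():
        coords, resnums, _ = select_calpha(model, list(ivals))
        chains = []
        names = []
        for chain, a, b in ivals:
            sub = ca[(ca["chain"] == chain) & ca["resnum"].between(a, b)].sort_values("resnum")
            chains.extend([chain] * len(sub))
            names.extend(sub["resname"].tolist())
        if scheme == "calpha-uniform":
            ff = np.ones(len(coords))
        elif scheme == "calpha-weighted":
            ff = np.array([RESIDUE_ELECTRONS.get(n, _DEFAULT_ELECTRONS) for n in names], float)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        out[name] = GroupBeads(name, coords, ff, resnums, np.asarray(chains))
    return out


@dataclass(frozen=True)
class Restraint:
    group_a: str
    group_b: str    # another group, or "anchor:<group>" for a displacement cap
    lower: float
    upper: float


@dataclass(frozen=True)
class RestraintSet:
    restraints: tuple[Restraint, ...]
    provenance: str = ""
    dmax: float = float("inf")

    def __post_init__(self) -> None:
        for r in self.restraints:
            if not (0.0 <= r.lower < r.upper):
                raise ValueError(f"invalid bounds [{r.lower}, {r.upper}] for "
                                 f"{r.group_a}-{r.group_b}")
            if r.upper > self.dmax + 1e-9:
                raise ValueError("restraint upper bound exceeds dmax")


def build_restraints(
    decomp: DomainDecomposition,
    ground: AtomModel,
    dmax: float,
    q_max: float,
    mode: str = "unconstrained",
) -> RestraintSet:
    """Centre-of-mass distance windows from the measured P(r) extent.

    For every group pair at ground-state COM separation d0 the window is
    [max(0, d0 - pi/q_max), min(dmax, d0 + pi/q_max)] — pi/q_max being the
    nominal real-space resolution of the measurement.  ``window:+-5A`` and
    ``window:+-10A`` additionally cap each non-reference group's COM
    displacement from its crystallographic position (encoded as a restraint
    to a fixed anchor); ``unconstrained`` applies no displacement caps.
    """
    caps = {"unconstrained": None, "window:+-5A": 5.0, "window:+-10A": 10.0}
    if mode not in caps:
        raise ValueError(f"unknown restraint mode {mode!r}; choose from {list(caps)}")
    half = np.pi / q_max
    groups = group_beads(ground, decomp, scheme="calpha-uniform")
    names = list(groups)
    restraints: list[Restraint] = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d0 = float(np.linalg.norm(groups[a].com - groups[b].com))
            if d0 > dmax:
                raise ValueError(
                    f"ground-state COM distance {a}-{b} ({d0:.1f} A) exceeds dmax "
                    f"({dmax:.1f} A): inconsistent inputs"
                )
            restraints.append(
                Restraint(a, b, max(0.0, d0 - half), min(dmax, d0 + half))
            )
    cap = caps[mode]
    if cap is not None:
        for name in names:
            if name != decomp.reference:
                restraints.append(Restraint(name, f"anchor:{name}", 0.0, cap))
    return RestraintSet(tuple(restraints), provenance=mode, dmax=dmax)


@dataclass(frozen=True)
class Conformation:
    """A sampled rigid-body placement of the decomposition's groups.

    ``coordinates``/``form_factors`` concatenate the groups in decomposition
    order; applying ``transforms`` (rotation about the group's ground-state
    COM, then translation) to the ground-state group coordinates reproduces
    ``coordinates`` exactly.
    """

    index: int
    transforms: dict[str, tuple[np.ndarray, np.ndarray]]
    coordinates: np.ndarray
    form_factors: np.ndarray
    restraint_ok: bool
    max_linker_gap: float

    def beads(self) -> BeadModel:
        return BeadModel(self.coordinates, self.form_factors)

    def com_displacement(self, group: str, groups: dict[str, GroupBeads]) -> float:
        R, t = self.transforms[group]
        return float(np.linalg.norm(t))


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    if max_deg <= 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _random_translation(rng: np.random.Generator, max_trans: float) -> np.ndarray:
    if max_trans <= 0:
        return np.zeros(3)
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * max_trans * rng.uniform(0.0, 1.0) ** (1.0 / 3.0)


class _LinkerCheck:
    """Precomputed flanking-bead indices and allowed gap per linker."""

    def __init__(self, decomp: DomainDecomposition, groups: dict[str, GroupBeads],
                 stretch: float) -> None:
        self.entries: list[tuple[tuple[str, int], tuple[str, int], float]] = []
        index: dict[tuple[str, int], tuple[str, int]] = {}
        for name, g in groups.items():
            for k, (c, r) in enumerate(zip(g.chains, g.resnums)):
                index[(str(c), int(r))] = (name, k)
        for chain, a, b in decomp.linkers:
            before = after = None
            for r in range(a - 1, a - 30, -1):
                if (chain, r) in index:
                    before = index[(chain, r)]
                    n_missing_before = a - 1 - r
                    break
            for r in range(b + 1, b + 30):
                if (chain, r) in index:
                    after = index[(chain, r)]
                    n_missing_after = r - b - 1
                    break
            if before is None or after is None:
                continue  # linker at a chain terminus tethers nothing
            length = (b - a + 1) + n_missing_before + n_missing_after
            allowed = CA_CA_BOND * (length + 1) * stretch
            self.entries.append((before, after, allowed))

    def max_gap(self, coords: dict[str, np.ndarray]) -> float:
        worst = 0.0
        for (ga, ia), (gb, ib), _ in self.entries:
            gap = float(np.linalg.norm(coords[ga][ia] - coords[gb][ib]))
            worst = max(worst, gap)
        return worst

    def ok(self, coords: dict[str, np.ndarray]) -> bool:
        for (ga, ia), (gb, ib), allowed in self.entries:
            if np.linalg.norm(coords[ga][ia] - coords[gb][ib]) > allowed:
                return False
        return True


def _min_intergroup_dist(coords: dict[str, np.ndarray], a: str, b: str) -> float:
    diff = coords[a][:, None, :] - coords[b][None, :, :]
    return float(np.sqrt(np.min(np.sum(diff * diff, axis=-1))))


def sample_conformations(
    ground: AtomModel,
    decomp: DomainDecomposition,
    restraints: RestraintSet,
    n: int,
    seed: int,
    max_rot: float = 15.0,
    max_trans: float = 5.0,
    clash_dist: float = 3.0,
    max_linker_stretch: float = 1.0,
    stride: int = 10,
    mobile_groups: tuple[str, ...] | None = None,
    scheme: str = "calpha-weighted",
) -> list[Conformation]:
    """Uniform random-walk sampling of the restraint-feasible region.

    Each proposal perturbs every mobile group by a rotation about its COM
    (angle <= max_rot degrees) plus a translation (<= max_trans A); a
    proposal is accepted iff it satisfies all COM restraints, has no
    inter-group C-alpha pair closer than clash_dist, and keeps every linker
    gap below 3.8 A x (linker length + 1) x max_linker_stretch.  Every
    ``stride``-th accepted state is emitted until ``n`` conformations exist.
    Fully reproducible from ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    groups = group_beads(ground, decomp, scheme=scheme)
    ref = decomp.reference or next(iter(groups))
    if mobile_groups is None:
        mobile = tuple(g for g in groups if g != ref)
    else:
        mobile = tuple(mobile_groups)
        if ref in mobile:
            raise ValueError("the reference group cannot be mobile")
    linker_check = _LinkerCheck(decomp, groups, max_linker_stretch)
    coms0 = {g: groups[g].com for g in groups}
    ff_all = np.concatenate([groups[g].form_factors for g in groups])
    pair_rs = [r for r in restraints.restraints if not r.group_b.startswith("anchor:")]
    anchor_rs = [r for r in restraints.restraints if r.group_b.startswith("anchor:")]

    def apply_state(state: dict[str, tuple[np.ndarray, np.ndarray]]) -> dict[str, np.ndarray]:
        coords = {}
        for g in groups:
            if g in state:
                R, t = state[g]
                coords[g] = (groups[g].coords - coms0[g]) @ R.T + coms0[g] + t
            else:
                coords[g] = groups[g].coords
        return coords

    def valid(coords: dict[str, np.ndarray]) -> bool:
        coms = {g: coords[g].mean(axis=0) for g in groups}
        for r in pair_rs:
            d = np.linalg.norm(coms[r.group_a] - coms[r.group_b])
            if not (r.lower - 1e-9 <= d <= r.upper + 1e-9):
                return False
        for r in anchor_rs:
            if np.linalg.norm(coms[r.group_a] - coms0[r.group_a]) > r.upper + 1e-9:
                return False
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if _min_intergroup_dist(coords, a, b) < clash_dist:
                    return False
        return linker_check.ok(coords)

    state: dict[str, tuple[np.ndarray, np.ndarray]] = {
        g: (np.eye(3), np.zeros(3)) for g in mobile
    }
    out: list[Conformation] = []
    accepted = 0
    proposals = 0
    if n == 0:
        return out
    while len(out) < n:
        proposals += 1
        trial = {}
        for g in mobile:
            R, t = state[g]
            dR = _random_rotation(rng, max_rot)
            dt = _random_translation(rng, max_trans)
            trial[g] = (dR @ R, t + dt)
        coords = apply_state(trial)
        if valid(coords):
            state = trial
            accepted += 1
            if accepted % stride == 0:
                emit = apply_state(state)
                out.append(
                    Conformation(
                        index=len(out),
                        transforms={g: (state[g][0].copy(), state[g][1].copy())
                                    for g in mobile},
                        coordinates=np.concatenate([emit[g] for g in groups]),
                        form_factors=ff_all,
                        restraint_ok=True,
                        max_linker_gap=linker_check.max_gap(coords),
                    )
                )
        if proposals >= 10_000 and accepted / proposals < 0.01:
            raise RuntimeError(
                f"acceptance rate {accepted / proposals:.2%} below 1% after "
                f"{proposals} proposals; loosen max_rot/max_trans or the restraints"
            )
    return out
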