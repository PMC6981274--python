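"""Synthetic ground-truth generators for every pipeline input.

Emulates the study conditions at toy scale: a multi-domain particle with a
compact (closed) and an extended (open) state differing by a rigid hinge
translation of one terminal domain; noisy solution-scattering curves of
single states and known-weight mixtures; and triplicate single-exponential
nicking time courses.  The noise model is multiplicative Gaussian with a
relative sd growing linearly toward high q, as in buffer-subtracted SAXS;
detector artefacts and interparticle interference are deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conformers import DomainDecomposition
from .core_io import AtomModel, ScatteringProfile, _ATOM_COLUMNS
from .debye import BeadModel, debye_intensity
from .kinetics import TimeCourse

__all__ = [
    "TwoStateToy",
    "make_two_state_toy",
    "simulate_profile",
    "simulate_mixture",
    "simulate_timecourse",
]

DOMAIN_RADIUS = 15.0      # A, radius of each random bead cluster
DOMAIN_GAP = 4.0          # A, clearance between neighbouring clusters
LINKER_RESIDUES = 8       # phantom residues reserved between domains


@dataclass(frozen=True)
class TwoStateToy:
    closed: BeadModel
    open: BeadModel
    decomposition: DomainDecomposition
    closed_model: AtomModel      # same beads as one-CA-per-residue structures,
    open_model: AtomModel        # usable by the rigid-body sampler
    hinge_translation: float
    seed: int


def _beads_to_model(positions: np.ndarray, resnums: np.ndarray, label: str) -> AtomModel:
    rows = [
        ("A", int(rn), "ALA", "CA", "C", float(x), float(y), float(z), 20.0, False)
        for rn, (x, y, z) in zip(resnums, positions)
    ]
    return AtomModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS), source_id=label)


def make_two_state_toy(
    n_domains: int = 3,
    beads_per_domain: int = 120,
    hinge_translation: float = 25.0,
    seed: int = 0,
) -> TwoStateToy:
    """Closed/open pair of multi-domain bead particles with known truth.

    Domains are dense random bead clusters (uniform in spheres of radius
    15 A) packed along a line with 4 A clearance; the open state translates
    the terminal domain outward by ``hinge_translation`` along the line of
    centres.  Beads double as one-C-alpha-per-residue structures (chain A,
    sequential numbering with phantom linker residues between domains) so
    the same objects feed the sampler; the returned decomposition names the
    first domain as the fixed reference.
    """
    if n_domains < 2:
        raise ValueError("need at least 2 domains")
    rng = np.random.default_rng(seed)
    spacing = 2 * DOMAIN_RADIUS + DOMAIN_GAP
    clusters = []
    for i in range(n_domains):
        v = rng.normal(size=(beads_per_domain, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = DOMAIN_RADIUS * rng.uniform(0, 1, beads_per_domain) ** (1 / 3)
        centre = np.array([i * spacing, 0.0, 0.0])
        clusters.append(v * r[:, None] + centre)
    closed_pos = np.vstack(clusters)
    open_clusters = [c.copy() for c in clusters]
    open_clusters[-1] = open_clusters[-1] + np.array([hinge_translation, 0.0, 0.0])
    open_pos = np.vstack(open_clusters)

    groups: dict[str, tuple[tuple[str, int, int], ...]] = {}
    resnums = []
    start = 1
    for i in range(n_domains):
        end = start + beads_per_domain - 1
        groups[f"domain{i + 1}"] = (("A", start, end),)
        resnums.extend(range(start, end + 1))
        start = end + 1 + LINKER_RESIDUES
    decomp = DomainDecomposition(rigid_groups=groups, linkers=(), reference="domain1")
    resnums = np.asarray(resnums)
    ff = np.ones(closed_pos.shape[0])
    return TwoStateToy(
        closed=BeadModel(closed_pos, ff),
        open=BeadModel(open_pos, ff),
        decomposition=decomp,
        closed_model=_beads_to_model(closed_pos, resnums, "toy-closed"),
        open_model=_beads_to_model(open_pos, resnums, "toy-open"),
        hinge_translation=hinge_translation,
        seed=seed,
    )


def _apply_noise(
    q: np.ndarray, intensity: np.ndarray, noise_level: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rel = max(noise_level, 1e-9) * (1.0 + 5.0 * q / q[-1])
    sigma = np.abs(intensity) * rel
    rng = np.random.default_rng(seed)
    obs = intensity * (1.0 + rel * rng.standard_normal(q.size) * (noise_level > 0))
    return obs, sigma


def simulate_profile(
    model: BeadModel,
    q_grid: np.ndarray,
    noise_level: float = 0.01,
    seed: int = 0,
) -> ScatteringProfile:
    """Noisy Debye profile: I_obs = I (1 + eps), eps ~ N(0, rel(q)) with
    rel(q) = noise_level * (1 + 5 q/q_max); sigma is the true per-point sd."""
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    q = np.asarray(q_grid, float)
    truth = debye_intensity(model, q).intensity
    obs, sigma = _apply_noise(q, truth, noise_level, seed)
    return ScatteringProfile(q, obs, sigma, label=f"sim(seed={seed})")


def simulate_mixture(
    models: list[BeadModel],
    weights: list[float],
    q_grid: np.ndarray,
    noise_level: float = 0.01,
    seed: int = 0,
) -> ScatteringProfile:
    """Noisy profile of a known-weight mixture (noise on the weighted sum)."""
    w = np.asarray(weights, float)
    if len(models) != w.size:
        raise ValueError("one weight per model required")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    q = np.asarray(q_grid, float)
    total = np.zeros(q.size)
    for m, wi in zip(models, w):
        if wi > 0:
            total += wi * debye_intensity(m, q).intensity
        else:
            debye_intensity(m, q)  # keep structure of the computation identical
    obs, sigma = _apply_noise(q, total, noise_level, seed)
    return ScatteringProfile(q, obs, sigma, label=f"mix(seed={seed})")


def simulate_timecourse(
    k: float,
    amplitude: float = 0.95,
    times: np.ndarray | None = None,
    noise_sd: float = 0.05,
    replicates: int = 3,
    seed: int = 0,
) -> TimeCourse:
    """Triplicate (by default) nicking time courses with Gaussian noise,
    clamped to [0, 1]."""
    if k <= 0:
        raise ValueError("k must be positive")
    if times is None:
        times = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0])
    t = np.asarray(times, float)
    rng = np.random.default_rng(seed)
    truth = amplitude * (1.0 - np.exp(-k * t))
    noisy = truth[None, :] + noise_sd * rng.standard_normal((replicates, t.size))
    return TimeCourse(t, np.clip(noisy, 0.0, 1.0))
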