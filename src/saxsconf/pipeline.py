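"""End-to-end apo-state conformational analysis.

Given an experimental (apo) curve and a ground-state structure the pipeline
computes the model-free invariants, estimates d_max from the P(r) scan,
derives centre-of-mass restraints, samples a restrained rigid-body
ensemble, predicts each conformation's Debye profile and reports the chi^2
of the ground state alongside the best single-state and best two-state
fits.  Every under-specified constant (Guinier limit, Moore terms, Porod
cutoff, clash distance, chi^2 convention) is echoed into the report so two
runs can diff their assumptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .conformers import (
    DomainDecomposition,
    RestraintSet,
    build_restraints,
    default_decomposition,
    group_beads,
    sample_conformations,
)
from .core_io import AtomModel, ScatteringProfile, read_profile, read_structure
from .debye import debye_intensity
from .ensemble import best_single_state, chi2, multi_state_fit
from .invariants import (
    dimensionless_kratky,
    estimate_dmax,
    guinier_fit,
    moore_pr,
    porod_volume,
)

__all__ = ["RunConfig", "profile_report", "conformational_fit",
           "run_conformational_analysis", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    apo_profile: str
    structure: str
    complex_profile: str | None = None
    restraint_mode: str = "unconstrained"
    mobile_groups: tuple[str, ...] | None = None
    n_conformations: int = 2430
    seed: int = 1
    max_rot: float = 15.0
    max_trans: float = 5.0
    clash_dist: float = 3.0
    stride: int = 10
    qrg_limit: float = 1.3
    dmax: float | None = None          # None: estimate from the P(r) scan
    q_cut: float | None = None         # None: 8/Rg
    k_states: int = 2
    fit_constant: bool = False
    prefilter: int | None = 200
    out_dir: str = "saxsconf-out"

    def validate(self) -> None:
        for p in (self.apo_profile, self.structure, self.complex_profile):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def profile_report(
    profile: ScatteringProfile,
    qrg_limit: float = 1.3,
    dmax: float | None = None,
    q_cut: float | None = None,
) -> dict:
    """Guinier, Kratky, P(r), d_max and Porod volume for one curve."""
    g = guinier_fit(profile, qrg_limit=qrg_limit)
    x, y, ref = dimensionless_kratky(profile, g)
    if dmax is None:
        grid = np.arange(2.0 * g.rg, 5.0 * g.rg + 1e-9, 0.1 * g.rg)
        dmax, scores = estimate_dmax(profile, grid)
        dmax_scan = {"grid": grid.tolist(), "scores": scores.tolist()}
    else:
        dmax_scan = None
    pr = moore_pr(profile, dmax)
    vp = porod_volume(profile, g, q_cut=q_cut)
    return {
        "label": profile.label,
        "n_points": len(profile),
        "q_range": [float(profile.q[0]), float(profile.q[-1])],
        "guinier": {
            "rg": g.rg, "i0": g.i0, "rg_stderr": g.rg_stderr,
            "i0_stderr": g.i0_stderr, "q_window": list(g.q_window),
            "n_points": g.n_points, "fit_r2": g.fit_r2, "qrg_limit": qrg_limit,
        },
        "kratky": {
            "x": x.tolist(), "y": y.tolist(),
            "globular_reference_point": list(ref),
        },
        "dmax": float(dmax),
        "dmax_scan": dmax_scan,
        "pr": {
            "dmax": pr.dmax, "n_terms": int(pr.coefficients.size),
            "rg_real": pr.rg_real, "i0_real": pr.i0_real,
            "chi2_fit": pr.chi2_fit, "negativity": pr.negativity,
            "r": pr.r.tolist(), "p": pr.p.tolist(),
        },
        "porod": {
            "volume": vp,
            "q_cut": q_cut if q_cut is not None else min(8.0 / g.rg, float(profile.q[-1])),
            "gap_fill": "guinier",
        },
    }


def conformational_fit(
    exp: ScatteringProfile,
    ground: AtomModel,
    decomp: DomainDecomposition,
    dmax: float,
    mode: str = "unconstrained",
    n: int = 2430,
    seed: int = 1,
    mobile_groups: tuple[str, ...] | None = None,
    k_states: int = 2,
    prefilter: int | None = 200,
    fit_constant: bool = False,
    max_rot: float = 15.0,
    max_trans: float = 5.0,
    clash_dist: float = 3.0,
    stride: int = 10,
    scheme: str = "calpha-weighted",
) -> dict:
    """Restrained sampling + ensemble fit of one experimental curve.

    Returns the report fragment plus the sampled conformations (under key
    "_conformations") for callers that want the coordinates.
    """
    restraints = build_restraints(decomp, ground, dmax=dmax,
                                  q_max=float(exp.q[-1]), mode=mode)
    groups = group_beads(ground, decomp, scheme=scheme)
    ground_beads = np.concatenate([groups[g].coords for g in groups])
    ground_ff = np.concatenate([groups[g].form_factors for g in groups])
    from .debye import BeadModel
    ground_calc = debye_intensity(BeadModel(ground_beads, ground_ff), exp.q)
    ground_chi2 = chi2(exp, ground_calc, fit_constant)

    confs = sample_conformations(
        ground, decomp, restraints, n=n, seed=seed, max_rot=max_rot,
        max_trans=max_trans, clash_dist=clash_dist, stride=stride,
        mobile_groups=mobile_groups, scheme=scheme,
    )
    pool = [(c.index, debye_intensity(c.beads(), exp.q)) for c in confs]
    single = best_single_state(exp, pool, fit_constant)
    multi = multi_state_fit(exp, pool, k=k_states, prefilter=prefilter)
    mobile = tuple(mobile_groups) if mobile_groups is not None else tuple(
        g for g in decomp.rigid_groups if g != decomp.reference
    )
    displacements = {
        g: [float(np.linalg.norm(c.transforms[g][1])) for c in confs] for g in mobile
    }
    best_conf = confs[single.member_ids[0]]
    return {
        "restraints": [
            {"a": r.group_a, "b": r.group_b, "lower": r.lower, "upper": r.upper}
            for r in restraints.restraints
        ],
        "restraint_mode": mode,
        "pi_over_qmax": float(np.pi / exp.q[-1]),
        "n_conformations": len(confs),
        "sampler": {
            "seed": seed, "max_rot_deg": max_rot, "max_trans_A": max_trans,
            "clash_dist_A": clash_dist, "stride": stride,
            "mobile_groups": list(mobile), "scheme": scheme,
        },
        "ground_state_chi2": ground_chi2,
        "best_single_state": {
            "id": int(single.member_ids[0]), "chi2": single.chi2,
            "scale": single.scale,
            "displacements_A": {
                g: float(np.linalg.norm(best_conf.transforms[g][1])) for g in mobile
            },
        },
        "best_multi_state": {
            "ids": [int(i) for i in multi.member_ids],
            "weights": list(multi.weights), "chi2": multi.chi2, "k": k_states,
        },
        "displacement_summary": {
            g: {"min": min(v), "max": max(v), "mean": float(np.mean(v))}
            for g, v in displacements.items()
        },
        "chi2_convention": "reduced, N-1, analytic scale"
                           + (", fitted constant" if fit_constant else ""),
        "_conformations": confs,
    }


def run_conformational_analysis(config: RunConfig) -> dict:
    """Full run from files: invariants for each curve, then the restrained
    ensemble analysis of the apo curve.  Deterministic given the seed."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    stage = "invariants(apo)"
    try:
        apo = read_profile(config.apo_profile)
        report["apo"] = profile_report(apo, config.qrg_limit, config.dmax,
                                       config.q_cut)
        if config.complex_profile:
            stage = "invariants(complex)"
            cplx = read_profile(config.complex_profile)
            report["complex"] = profile_report(cplx, config.qrg_limit,
                                               None, config.q_cut)
        stage = "conformational-fit"
        ground = read_structure(config.structure)
        decomp = default_decomposition()
        fit = conformational_fit(
            apo, ground, decomp, dmax=report["apo"]["dmax"],
            mode=config.restraint_mode, n=config.n_conformations,
            seed=config.seed, mobile_groups=config.mobile_groups,
            k_states=config.k_states, prefilter=config.prefilter,
            fit_constant=config.fit_constant, max_rot=config.max_rot,
            max_trans=config.max_trans, clash_dist=config.clash_dist,
            stride=config.stride,
        )
        fit.pop("_conformations")
        report["conformational_fit"] = fit
    except Exception as exc:
        report["error"] = {"stage": stage, "message": str(exc)}
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
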