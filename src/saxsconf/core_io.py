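"""Readers, writers and coordinate selection for SAXS profiles and structures.

Units are fixed throughout the package: momentum transfer q in inverse
angstroms, lengths in angstroms, volumes in cubic angstroms.  Profiles
recorded in inverse nanometres must be rescaled (multiply q by 0.1) before
they enter the pipeline; no unit auto-detection is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ScatteringProfile",
    "AtomModel",
    "read_profile",
    "write_profile",
    "read_structure",
    "write_structure",
    "select_calpha",
]


@dataclass(frozen=True)
class ScatteringProfile:
    """A 1-D scattering curve I(q) on a strictly increasing q grid.

    ``sigma`` (per-point uncertainty, same units as ``intensity``) is optional:
    two-column files are accepted, but operations that need uncertainties
    raise rather than invent them.  Individual intensities may be negative
    (buffer-subtracted data); sigma must be positive where present.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if q.ndim != 1 or i.shape != q.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if q.size and q[0] <= 0:
            raise ValueError("all q must be > 0")
        dq = np.diff(q)
        if np.any(dq <= 0):
            idx = int(np.argmax(dq <= 0))
            raise ValueError(f"q must be strictly increasing; violation at index {idx + 1}")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(s <= 0):
                raise ValueError("sigma must be > 0 where present")

    @property
    def has_sigma(self) -> bool:
        return self.sigma is not None

    def require_sigma(self) -> np.ndarray:
        if self.sigma is None:
            raise ValueError(
                f"profile {self.label!r} has no uncertainty column; "
                "this operation requires sigma"
            )
        return self.sigma

    def __len__(self) -> int:
        return self.q.size

    def crop(self, q_min: float = 0.0, q_max: float = np.inf) -> "ScatteringProfile":
        m = (self.q >= q_min) & (self.q <= q_max)
        return ScatteringProfile(
            self.q[m],
            self.intensity[m],
            None if self.sigma is None else self.sigma[m],
            self.label,
        )


_ATOM_COLUMNS = [
    "chain", "resnum", "resname", "atom", "element",
    "x", "y", "z", "bfactor", "het",
]


@dataclass
class AtomModel:
    """Atomistic coordinates as a flat atom table.

    ``atoms`` is a DataFrame with columns chain, resnum (author numbering,
    integer), resname, atom, element, x, y, z, bfactor, het (bool; True for
    non-polymer records such as ligands).  (chain, resnum, atom) is unique.
    """

    atoms: pd.DataFrame
    source_id: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite atom coordinates")
        dup = self.atoms.duplicated(subset=["chain", "resnum", "atom", "het"])
        if dup.any():
            row = self.atoms[dup].iloc[0]
            raise ValueError(
                f"duplicate atom record {row.chain}/{row.resnum}/{row.atom}"
            )

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    def protein(self) -> pd.DataFrame:
        return self.atoms[~self.atoms["het"]]

    def residue_numbers(self, chain: str | None = None) -> np.ndarray:
        t = self.protein()
        if chain is not None:
            t = t[t["chain"] == chain]
        return np.unique(t["resnum"].to_numpy(int))


def read_profile(path: str | Path, dialect: str = "plain3col") -> ScatteringProfile:
    """Read a whitespace-delimited 2- or 3-column text profile (q, I[, sigma]).

    Lines starting with '#' or that do not parse as numbers are skipped, which
    tolerates the loosely standardised .dat headers in the wild; any skipped
    non-comment line is counted so callers can log the assumption.
    """
    if dialect != "plain3col":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows: list[tuple[float, ...]] = []
    for line in path.read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        try:
            vals = tuple(float(p) for p in parts[:3])
        except ValueError:
            continue
        if len(vals) >= 2:
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no numeric rows found")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    sigma = arr[:, 2] if ncol >= 3 else None
    return ScatteringProfile(arr[:, 0], arr[:, 1], sigma, label=path.stem)


def write_profile(profile: ScatteringProfile, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {profile.label}\n# q intensity" + (" sigma\n" if profile.has_sigma else "\n"))
        for i in range(len(profile)):
            cols = [f"{profile.q[i]:.8e}", f"{profile.intensity[i]:.8e}"]
            if profile.sigma is not None:
                cols.append(f"{profile.sigma[i]:.8e}")
            fh.write(" ".join(cols) + "\n")


def _structure_to_table(st: gemmi.Structure) -> pd.DataFrame:
    st.setup_entities()
    model = st[0]
    recs = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H" and res.name != "MSE"
            for atom in res:
                recs.append(
                    (
                        chain.name,
                        res.seqid.num,
                        res.name,
                        atom.name,
                        atom.element.name,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        atom.b_iso,
                        het,
                    )
                )
    return pd.DataFrame(recs, columns=_ATOM_COLUMNS)


def read_structure(path: str | Path) -> AtomModel:
    """Read a PDB or mmCIF file into an AtomModel (author residue numbering)."""
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # pragma: no cover - gemmi error text varies
        raise ValueError(f"{path}: could not parse structure ({exc})") from exc
    table = _structure_to_table(st)
    if table.empty:
        raise ValueError(f"{path}: no atoms found")
    return AtomModel(table, source_id=st.name or path.stem)


def write_structure(model: AtomModel, path: str | Path) -> None:
    """Write an AtomModel as PDB (extension .pdb) or mmCIF (.cif)."""
    st = gemmi.Structure()
    st.name = model.source_id or "model"
    md = gemmi.Model("1")
    for chain_name, chain_tab in model.atoms.groupby("chain", sort=False):
        ch = gemmi.Chain(str(chain_name))
        for (resnum, resname, het), res_tab in chain_tab.groupby(
            ["resnum", "resname", "het"], sort=False
        ):
            res = gemmi.Residue()
            res.name = str(resname)
            res.seqid = gemmi.SeqId(int(resnum), " ")
            res.het_flag = "H" if het else "A"
            for rec in res_tab.itertuples():
                at = gemmi.Atom()
                at.name = rec.atom
                at.element = gemmi.Element(rec.element)
                at.pos = gemmi.Position(rec.x, rec.y, rec.z)
                at.b_iso = float(rec.bfactor)
                res.add_atom(at)
            ch.add_residue(res)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def select_calpha(
    model: AtomModel,
    ranges: Sequence[tuple[str, int, int]],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Collect C-alpha positions for (chain, first, last) intervals, in order.

    Intervals are inclusive on both ends and use author numbering.  Residues
    absent from the model (disorder gaps) are skipped silently; the skip
    count is returned so callers can report it.

    Returns (coords (N,3), residue numbers (N,), skipped count).
    """
    ca = model.protein()
    ca = ca[ca["atom"] == "CA"]
    coords: list[np.ndarray] = []
    resnums: list[int] = []
    skipped = 0
    for chain, first, last in ranges:
        if last < first:
            raise ValueError(f"empty interval {first}-{last}")
        sub = ca[(ca["chain"] == chain) & ca["resnum"].between(first, last)]
        sub = sub.sort_values("resnum")
        present = set(sub["resnum"].to_numpy(int))
        skipped += (last - first + 1) - len(present)
        coords.append(sub[["x", "y", "z"]].to_numpy(float))
        resnums.extend(sub["resnum"].to_numpy(int))
    out = np.vstack([c for c in coords if c.size] or [np.empty((0, 3))])
    if out.shape[0] == 0:
        raise ValueError("selection matched no modelled residues")
    return out, np.asarray(resnums, dtype=int), skipped
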