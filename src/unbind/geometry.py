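"""Static-structure measurements: PDB reading, rigid superposition and
near-attack-conformation (NAC) geometry.

A methyl transfer by an SN2 mechanism needs the acceptor nitrogen close to
the donated methyl carbon (a few A) and a near-linear donor-S - C - N
arrangement.  :func:`nac_report` measures the N6-Ce distance and the
5'S-Ce-N6 angle across a set of complexes and flags SN2-compatible
geometries (defaults: distance <= 3.5 A, angle >= 150 deg).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial.transform import Rotation

__all__ = [
    "StructureModel",
    "Superposition",
    "read_structure",
    "superpose",
    "apply_superposition",
    "distance",
    "angle",
    "nac_report",
    "fetch_pdb",
]


@dataclass
class StructureModel:
    """Flat atom table of one structure (first model of a PDB file).

    Alternate locations are resolved before construction (highest
    occupancy, then alphabetic altloc id), so (chain, resid, name) keys
    are unique.  Hydrogens are retained but flagged.
    """

    atoms: pd.DataFrame
    source: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.atoms[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("non-finite coordinates")
        keys = self.atoms[["chain", "resid", "name"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValueError(f"duplicate atom key {tuple(dup)} in {self.source}")

    def coords(self, idx=None) -> np.ndarray:
        df = self.atoms if idx is None else self.atoms.loc[idx]
        return df[["x", "y", "z"]].to_numpy(dtype=float)

    def atom(self, spec: str) -> np.ndarray:
        """Coordinates of one atom.

        Accepts ``"chain:resid:name"`` (e.g. ``"A:395:OD1"``) or
        ``"resname:name"`` (e.g. ``"BA2:N6"``, unique over the structure).
        """
        parts = spec.split(":")
        df = self.atoms
        if len(parts) == 3:
            chain, resid, name = parts
            sel = df[(df["chain"] == chain) & (df["resid"] == int(resid))
                     & (df["name"] == name)]
            scope = df[(df["chain"] == chain) & (df["resid"] == int(resid))]
        elif len(parts) == 2:
            resname, name = parts
            scope = df[df["resname"] == resname]
            sel = scope[scope["name"] == name]
        else:
            raise ValueError(
                f"atom spec {spec!r}: use 'chain:resid:name' or 'resname:name'"
            )
        if len(sel) == 0:
            avail = sorted(scope["name"].unique()) if len(scope) else []
            raise KeyError(
                f"{self.source}: no atom {spec!r}; available: {avail}"
            )
        if len(sel) > 1:
            raise KeyError(f"{self.source}: atom spec {spec!r} is ambiguous")
        return sel[["x", "y", "z"]].to_numpy(dtype=float)[0]

    def select(self, specs) -> np.ndarray:
        return np.array([self.atom(s) for s in specs])


def read_structure(path, model_index: int = 0) -> StructureModel:
    """Parse a PDB file (ATOM and HETATM, waters retained).

    Altlocs resolve to the highest-occupancy conformer (alphabetic id on
    ties); hydrogens are kept and flagged via the ``is_hydrogen`` column.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models")
    model = models[model_index]

    rows = []
    for chain in model:
        for residue in chain:
            het_flag, resid, _ = residue.id
            for atom in residue:
                if atom.is_disordered():
                    variants = sorted(
                        atom.child_dict.values(),
                        key=lambda a: (-(a.get_occupancy() or 0.0),
                                       a.get_altloc()),
                    )
                    chosen = variants[0]
                else:
                    chosen = atom
                # PDB prints 3 decimals; re-round the parser's float32 so
                # coordinates equal the printed values exactly
                x, y, z = (round(float(c), 3) for c in chosen.get_coord())
                element = (chosen.element or "").strip().upper()
                rows.append({
                    "name": atom.get_id(),
                    "element": element,
                    "resname": residue.get_resname().strip(),
                    "resid": resid,
                    "chain": chain.id,
                    "x": float(x), "y": float(y), "z": float(z),
                    "occupancy": float(chosen.get_occupancy() or 1.0),
                    "is_hetero": het_flag.strip() != "",
                    "is_hydrogen": element == "H",
                })
    if not rows:
        raise ValueError(f"{path}: no atoms parsed")
    return StructureModel(pd.DataFrame(rows), path.name)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Superposition:
    """Rigid least-squares transform mapping mobile onto reference."""

    rotation: np.ndarray      # 3x3, proper orthonormal
    translation: np.ndarray   # applied after rotation
    rmsd_A: float
    n_pairs: int


def superpose(mobile_xyz: np.ndarray,
              reference_xyz: np.ndarray) -> Superposition:
    """Kabsch superposition over order-matched atom pairs.

    Requires at least three non-collinear pairs.  The returned transform
    is ``y = R x + t``; its RMSD is the residual over the paired atoms.
    """
    mob = np.asarray(mobile_xyz, dtype=float)
    ref = np.asarray(reference_xyz, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("need matching (n, 3) coordinate arrays")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atom pairs")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    if (np.linalg.matrix_rank(mob_c, tol=1e-8) < 2
            or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2):
        raise ValueError("collinear atom selection; superposition is "
                         "underdetermined")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    r = rot.as_matrix()
    t = ref.mean(axis=0) - r @ mob.mean(axis=0)
    # residual of the actually-applied transform, not the SVD estimate
    moved = mob @ r.T + t
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))
    return Superposition(r, t, rmsd, n)


def apply_superposition(sup: Superposition, xyz: np.ndarray) -> np.ndarray:
    return np.asarray(xyz, dtype=float) @ sup.rotation.T + sup.translation


# ---------------------------------------------------------------------------
# distances, angles, NAC table
# ---------------------------------------------------------------------------

def distance(a, b) -> float:
    """Euclidean distance in A."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def angle(a, b, c) -> float:
    """Angle at vertex ``b`` in degrees, in [0, 180]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("coincident points define no angle")
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def nac_report(complexes, max_distance_A: float = 3.5,
               min_angle_deg: float = 150.0) -> pd.DataFrame:
    """Near-attack geometry table across complexes.

    ``complexes`` is a list of ``(label, structure, spec)`` where ``spec``
    maps the keys ``n6`` (acceptor N), ``ce`` (methyl carbon) and ``s5``
    (donor 5'S — or 5'N in bisubstrate analogues, where the sulphur
    position is a nitrogen) to atom spec strings.  Rows with unresolvable
    atoms report the error and do not suppress the other rows.
    """
    rows = []
    for label, model, spec in complexes:
        try:
            n6 = model.atom(spec["n6"])
            ce = model.atom(spec["ce"])
            s5 = model.atom(spec["s5"])
            d = distance(n6, ce)
            ang = angle(s5, ce, n6)
            rows.append({
                "complex": label,
                "d_N6_Ce_A": d,
                "angle_S_Ce_N6_deg": ang,
                "sn2_compatible": bool(d <= max_distance_A
                                       and ang >= min_angle_deg),
                "error": "",
            })
        except (KeyError, ValueError) as exc:
            rows.append({
                "complex": label,
                "d_N6_Ce_A": np.nan,
                "angle_S_Ce_N6_deg": np.nan,
                "sn2_compatible": False,
                "error": str(exc),
            })
    return pd.DataFrame(rows)


def fetch_pdb(accession: str, outdir, *, allow_network: bool = False) -> Path:
    """Download a PDB entry by accession. Off unless explicitly enabled."""
    if not allow_network:
        raise RuntimeError(
            "network fetch disabled; pass allow_network=True or supply "
            "a local file"
        )
    import urllib.request

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{accession.lower()}.pdb"
    url = f"https://files.rcsb.org/download/{accession.upper()}.pdb"
    urllib.request.urlretrieve(url, path)
    return path
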