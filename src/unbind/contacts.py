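"""Intermolecular contacts, binding-pocket definition and bound/unbound
classification for protein-ligand trajectory ensembles.

Contacts are heavy-atom (non-hydrogen) intermolecular distances below a
cutoff (default 5 A, strict inequality).  The binding pocket is the set of
residues whose time-mean contact count reaches the 90th percentile of mean
contacts over the contacting residues.  A dissociation event is the mean
ligand-to-pocket distance exceeding 10 A, where the per-residue distance is
the minimum heavy-atom distance from the residue to any ligand heavy atom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "TrajectoryEnsemble",
    "ContactProfile",
    "PocketDefinition",
    "BoundSeries",
    "compute_contacts",
    "define_pocket",
    "ligand_pocket_distance",
    "ligand_pocket_distance_series",
    "classify_bound",
    "polar_contact_series",
    "load_ensemble",
]

ATOM_COLUMNS = ["name", "element", "resid", "resname", "segid", "is_ligand"]


@dataclass
class TrajectoryEnsemble:
    """Atom table plus per-trajectory coordinate stacks (A).

    ``atoms`` carries one row per atom: name, element, resid, resname,
    segid and a ligand flag.  ``trajectories`` is a list of arrays shaped
    ``(n_frames, n_atoms, 3)``, one per independent run.
    """

    atoms: pd.DataFrame
    trajectories: list
    frame_interval_ns: float

    def __post_init__(self) -> None:
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")
        if not self.trajectories:
            raise ValueError("need at least one trajectory")
        n_atoms = len(self.atoms)
        self.trajectories = [np.asarray(t, dtype=float) for t in self.trajectories]
        for i, t in enumerate(self.trajectories):
            if t.ndim != 3 or t.shape[1] != n_atoms or t.shape[2] != 3:
                raise ValueError(
                    f"trajectory {i}: expected (n_frames, {n_atoms}, 3), "
                    f"got {t.shape}"
                )
        lig = self.atoms["is_ligand"].to_numpy(dtype=bool)
        if not lig.any() or lig.all():
            raise ValueError("need at least one ligand and one protein atom")

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    def heavy_mask(self) -> np.ndarray:
        elem = self.atoms["element"].astype(str).str.strip().str.upper()
        return (elem != "H").to_numpy()

    def ligand_heavy_idx(self) -> np.ndarray:
        lig = self.atoms["is_ligand"].to_numpy(dtype=bool)
        return np.flatnonzero(lig & self.heavy_mask())

    def protein_heavy_idx(self) -> np.ndarray:
        lig = self.atoms["is_ligand"].to_numpy(dtype=bool)
        return np.flatnonzero(~lig & self.heavy_mask())

    def residue_keys(self) -> pd.DataFrame:
        """Distinct protein residues in atom-table order."""
        prot = self.atoms.loc[~self.atoms["is_ligand"].astype(bool)]
        keys = prot[["segid", "resid", "resname"]].drop_duplicates()
        return keys.reset_index(drop=True)

    def check_imaged(self, bond_limit_A: float = 3.0) -> None:
        """Reject trajectories with broken (PBC-split) residues.

        For every residue with more than one heavy atom, every heavy atom
        must have a neighbour within ``bond_limit_A`` in every frame of
        the first trajectory; periodic imaging artefacts violate this.
        """
        heavy = self.heavy_mask()
        groups = self.atoms.assign(_i=np.arange(len(self.atoms)))
        groups = groups[heavy]
        first = self.trajectories[0]
        for (_, _, _), sub in groups.groupby(["segid", "resid", "resname"]):
            idx = sub["_i"].to_numpy()
            if idx.size < 2:
                continue
            for frame in (first[0], first[-1]):
                d = cdist(frame[idx], frame[idx])
                np.fill_diagonal(d, np.inf)
                if d.min(axis=1).max() > bond_limit_A:
                    raise ValueError(
                        "residue appears split across the periodic box; "
                        "re-image the trajectory before analysis"
                    )


@dataclass
class ContactProfile:
    """Per-frame per-residue intermolecular contact counts.

    ``counts`` is a list (one entry per trajectory) of integer arrays
    shaped ``(n_frames, n_residues)``; ``mean_contacts`` is the grand mean
    over all frames of all trajectories.
    """

    residues: pd.DataFrame
    counts: list
    mean_contacts: np.ndarray
    contact_cutoff_A: float

    def residue_label(self, i: int) -> str:
        r = self.residues.iloc[i]
        return f"{r.resname}{r.resid}"


@dataclass(frozen=True)
class PocketDefinition:
    """Residues whose mean contact count reaches the percentile threshold."""

    residue_indices: np.ndarray
    residues: pd.DataFrame
    percentile: float
    percentile_value: float

    def labels(self) -> list:
        return [f"{r.resname}{r.resid}" for _, r in self.residues.iterrows()]


@dataclass(frozen=True)
class BoundSeries:
    """Per-frame bound/unbound classification of one trajectory."""

    bound: np.ndarray
    threshold_A: float
    criterion: str
    frame_interval_ns: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "bound", np.asarray(self.bound, dtype=bool))


def compute_contacts(ens: TrajectoryEnsemble, cutoff_A: float = 5.0,
                     ligand_idx=None, protein_idx=None) -> ContactProfile:
    """Count intermolecular heavy-atom contacts per residue per frame.

    A contact is a ligand-heavy-atom / protein-heavy-atom pair at a
    distance strictly below ``cutoff_A``.  Selections default to the
    ensemble's ligand flag; explicit index arrays must be disjoint.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff must be positive")
    lig = np.asarray(ligand_idx if ligand_idx is not None
                     else ens.ligand_heavy_idx())
    prot = np.asarray(protein_idx if protein_idx is not None
                      else ens.protein_heavy_idx())
    if lig.size == 0 or prot.size == 0:
        raise ValueError("empty ligand or protein selection")
    if np.intersect1d(lig, prot).size:
        raise ValueError("ligand and protein selections overlap")

    residues = ens.residue_keys()
    key_of = {tuple(k): i for i, k in enumerate(
        residues[["segid", "resid", "resname"]].itertuples(index=False))}
    prot_res = np.array([
        key_of[(ens.atoms["segid"].iat[a], ens.atoms["resid"].iat[a],
                ens.atoms["resname"].iat[a])]
        for a in prot
    ])

    n_res = len(residues)
    counts = []
    total = np.zeros(n_res)
    n_frames_total = 0
    for traj in ens.trajectories:
        c = np.zeros((traj.shape[0], n_res), dtype=np.int32)
        for f in range(traj.shape[0]):
            d = cdist(traj[f, lig], traj[f, prot])
            pair_lt = d < cutoff_A
            if pair_lt.any():
                np.add.at(c[f], prot_res, pair_lt.sum(axis=0))
        counts.append(c)
        total += c.sum(axis=0)
        n_frames_total += traj.shape[0]
    mean = total / n_frames_total
    return ContactProfile(residues, counts, mean, cutoff_A)


def define_pocket(profile: ContactProfile,
                  percentile: float = 90.0) -> PocketDefinition:
    """Pocket = residues whose mean contact count reaches the percentile.

    The percentile (linear interpolation) is computed over residues with a
    nonzero mean contact only, and membership uses ``>=`` so that a single
    contacting residue forms its own pocket.
    """
    mean = profile.mean_contacts
    nonzero = mean[mean > 0]
    if nonzero.size == 0:
        raise ValueError("no binding observed: all mean contacts are zero")
    value = float(np.percentile(nonzero, percentile))
    members = np.flatnonzero(mean >= value)
    return PocketDefinition(
        members, profile.residues.iloc[members].reset_index(drop=True),
        percentile, value,
    )


def _pocket_atom_indices(ens: TrajectoryEnsemble,
                         pocket: PocketDefinition) -> list:
    heavy = ens.heavy_mask()
    lig_flag = ens.atoms["is_ligand"].to_numpy(dtype=bool)
    out = []
    for _, r in pocket.residues.iterrows():
        sel = (
            (ens.atoms["segid"] == r.segid)
            & (ens.atoms["resid"] == r.resid)
            & (ens.atoms["resname"] == r.resname)
            & ~lig_flag & heavy
        )
        out.append(np.flatnonzero(sel.to_numpy()))
    return out


def ligand_pocket_distance(ens: TrajectoryEnsemble, pocket: PocketDefinition,
                           traj: int, frame: int) -> float:
    """Mean over pocket residues of the minimum heavy-atom distance from
    each residue to the ligand, in one frame."""
    return float(
        ligand_pocket_distance_series(ens, pocket, trajectories=[traj])[0][frame]
    )


def ligand_pocket_distance_series(ens: TrajectoryEnsemble,
                                  pocket: PocketDefinition,
                                  trajectories=None) -> list:
    """Per-frame mean ligand-to-pocket distance for each trajectory."""
    if len(pocket.residue_indices) == 0:
        raise ValueError("empty pocket")
    lig = ens.ligand_heavy_idx()
    res_atoms = _pocket_atom_indices(ens, pocket)
    which = range(ens.n_trajectories) if trajectories is None else trajectories
    out = []
    for ti in which:
        traj = ens.trajectories[ti]
        series = np.empty(traj.shape[0])
        for f in range(traj.shape[0]):
            lig_xyz = traj[f, lig]
            mins = [cdist(lig_xyz, traj[f, idx]).min() for idx in res_atoms]
            series[f] = np.mean(mins)
        out.append(series)
    return out


def classify_bound(distances_A, threshold_A: float = 10.0,
                   frame_interval_ns: float = 1.0,
                   criterion: str = "pocket-distance",
                   strict: bool = False) -> BoundSeries:
    """Threshold a distance series into a bound/unbound series.

    The pocket-distance rule marks a frame unbound once the distance
    surpasses the threshold (bound iff ``d <= t``).  The alternative
    adenosine-N6-to-D395-Cgamma criterion uses a strict ``d < 6`` bound
    definition; pass ``threshold_A=6, strict=True`` for it.
    """
    d = np.asarray(distances_A, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances in series")
    bound = d < threshold_A if strict else d <= threshold_A
    return BoundSeries(bound, threshold_A, criterion, frame_interval_ns)


# ---------------------------------------------------------------------------
# polar contact monitoring
# ---------------------------------------------------------------------------

def _resolve_atom_spec(ens: TrajectoryEnsemble, spec: str) -> np.ndarray:
    """Resolve 'D395:OD1/OD2' or 'AMP:N7' to atom indices.

    The residue part matches a resid (digits anywhere in the token, e.g.
    ``D395`` or ``395``) or a resname (``AMP``); slash-separated atom
    names are alternatives whose per-frame minimum distance is reported.
    """
    res_part, _, atom_part = spec.partition(":")
    if not atom_part:
        raise ValueError(f"atom spec {spec!r} must look like RES:NAME[/NAME]")
    digits = "".join(ch for ch in res_part if ch.isdigit())
    if digits:
        res_mask = ens.atoms["resid"].astype(int) == int(digits)
    else:
        res_mask = ens.atoms["resname"].astype(str) == res_part
    if not res_mask.any():
        raise ValueError(f"no residue matches {res_part!r}")
    names = atom_part.split("/")
    mask = res_mask & ens.atoms["name"].astype(str).isin(names)
    idx = np.flatnonzero(mask.to_numpy())
    if idx.size == 0:
        avail = sorted(ens.atoms.loc[res_mask, "name"].unique())
        raise ValueError(
            f"no atom named {names} in {res_part!r}; available: {avail}"
        )
    return idx


def polar_contact_series(ens: TrajectoryEnsemble, pairs,
                         cutoffs_A=None) -> pd.DataFrame:
    """Per-frame minimum distances for named atom-pair alternatives.

    ``pairs`` maps a label to a 2-tuple of atom specs, e.g.
    ``{"D395-K513": ("D395:OD1/OD2", "K513:NZ")}``.  For each frame the
    minimum distance over all listed atom alternatives of the two partners
    is reported; a ``<label>_formed`` column flags frames within the
    per-pair cutoff (default 4.0 A, the salt-bridge heavy-atom criterion).
    """
    cutoffs_A = cutoffs_A or {}
    resolved = {
        label: (_resolve_atom_spec(ens, a), _resolve_atom_spec(ens, b))
        for label, (a, b) in pairs.items()
    }
    rows = []
    for ti, traj in enumerate(ens.trajectories):
        for f in range(traj.shape[0]):
            row = {"trajectory": ti, "time_ns": f * ens.frame_interval_ns}
            for label, (ia, ib) in resolved.items():
                d = cdist(traj[f, ia], traj[f, ib]).min()
                row[label] = d
                row[f"{label}_formed"] = d <= cutoffs_A.get(label, 4.0)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file input via MDAnalysis
# ---------------------------------------------------------------------------

def load_ensemble(topology, trajectory_files, ligand_selection: str,
                  frame_interval_ns: float) -> TrajectoryEnsemble:
    """Read one or more trajectory files into a :class:`TrajectoryEnsemble`.

    Formats are whatever MDAnalysis can read against the given topology
    (multi-model PDB, XTC, DCD ...).  ``ligand_selection`` is an
    MDAnalysis selection string, e.g. ``"resname AMP"``.
    """
    import MDAnalysis as mda

    trajectories = []
    atoms_df = None
    for path in trajectory_files:
        u = mda.Universe(str(topology), str(path))
        lig = u.select_atoms(ligand_selection)
        if lig.n_atoms == 0:
            raise ValueError(f"ligand selection {ligand_selection!r} is empty")
        lig_idx = set(lig.indices)
        if atoms_df is None:
            elements = []
            for a in u.atoms:
                try:
                    elements.append(a.element)
                except Exception:
                    # fall back to the leading letter of the atom name
                    elements.append(a.name.lstrip("0123456789")[0])
            atoms_df = pd.DataFrame({
                "name": [a.name for a in u.atoms],
                "element": elements,
                "resid": [a.resid for a in u.atoms],
                "resname": [a.resname for a in u.atoms],
                "segid": [a.segid for a in u.atoms],
                "is_ligand": [a.index in lig_idx for a in u.atoms],
            })
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=float)
        trajectories.append(frames)
    return TrajectoryEnsemble(atoms_df, trajectories, frame_interval_ns)
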