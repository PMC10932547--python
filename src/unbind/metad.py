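"""Free-energy profiles from well-tempered metadynamics hill files.

The estimator is the final-bias reconstruction: the deposited Gaussians
are summed on a grid and the potential of mean force along the collective
variable is ``F = -(gamma/(gamma-1)) * V_bias`` (heights stored in HILLS
files are assumed already tempered, the common convention).  Convergence
is assessed by recomputing the profile as a function of the number of
Gaussians added; replicas are averaged pointwise after anchoring each
profile's reactant-basin minimum at zero, with the standard error of the
mean across replicas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FreeEnergyProfile",
    "parse_hills",
    "write_hills",
    "merge_walkers",
    "bias_on_grid",
    "pmf",
    "convergence_series",
    "barrier_and_dg",
    "replica_mean_sem",
    "antisym_cv",
]

KCAL_TO_KJ = 4.184
HILL_COLUMNS = ["time", "cv", "sigma", "height", "biasf"]


@dataclass
class FreeEnergyProfile:
    """1-D free-energy profile in kcal/mol, minimum shifted to zero."""

    grid: np.ndarray
    F_kcal: np.ndarray
    sem_kcal: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.F_kcal = np.asarray(self.F_kcal, dtype=float)
        if self.grid.shape != self.F_kcal.shape:
            raise ValueError("grid and F must have matching shapes")
        if not np.all(np.isfinite(self.F_kcal)):
            raise ValueError("free energy must be finite on the grid")
        self.F_kcal = self.F_kcal - self.F_kcal.min()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cv": self.grid, "F_kcal": self.F_kcal})
        if self.sem_kcal is not None:
            df["sem_kcal"] = self.sem_kcal
        return df

    def plot(self, ax=None, label=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.F_kcal, label=label)
        if self.sem_kcal is not None:
            ax.fill_between(self.grid, self.F_kcal - self.sem_kcal,
                            self.F_kcal + self.sem_kcal, alpha=0.3)
        ax.set_xlabel("collective variable")
        ax.set_ylabel("free energy (kcal/mol)")
        return ax


# ---------------------------------------------------------------------------
# HILLS I/O
# ---------------------------------------------------------------------------

def parse_hills(path) -> pd.DataFrame:
    """Read a PLUMED-style HILLS file into a hills table.

    The header line ``#! FIELDS time <cv> sigma_<cv> height biasf`` names
    the columns; ``time`` and ``height`` are required by name, the second
    field is taken as the CV centre and any ``sigma*`` field as the width.
    Heights stay in kJ/mol as read.  Non-monotone deposition times within
    one file raise a warning (walkers write in order).
    """
    path = Path(path)
    header = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "FIELDS" in line:
                    fields = line.split()
                    header = fields[fields.index("FIELDS") + 1:]
                continue
            rows.append([float(tok) for tok in line.split()])
    if header is None:
        raise ValueError(f"{path}: no '#! FIELDS' header line")

    def col(name_pred, what):
        for i, h in enumerate(header):
            if name_pred(h):
                return i
        raise ValueError(f"{path}: missing required column {what!r} "
                         f"(header: {header})")

    i_time = col(lambda h: h == "time", "time")
    i_height = col(lambda h: h == "height", "height")
    i_sigma = col(lambda h: h.startswith("sigma"), "sigma")
    # the CV is the first field that is none of the above
    named = {i_time, i_height, i_sigma}
    try:
        i_biasf = col(lambda h: h == "biasf", "biasf")
        named.add(i_biasf)
    except ValueError:
        i_biasf = None
    i_cv = next(i for i in range(len(header)) if i not in named)

    if not rows:
        return pd.DataFrame(columns=HILL_COLUMNS)
    data = np.asarray(rows, dtype=float)
    if data.shape[1] < len(header):
        raise ValueError(f"{path}: fewer data columns than header fields")
    df = pd.DataFrame({
        "time": data[:, i_time],
        "cv": data[:, i_cv],
        "sigma": data[:, i_sigma],
        "height": data[:, i_height],
        "biasf": data[:, i_biasf] if i_biasf is not None else np.inf,
    })
    if np.any(np.diff(df["time"].to_numpy()) < 0):
        warnings.warn(f"{path}: deposition times are not monotone",
                      RuntimeWarning)
    if (df["sigma"] <= 0).any() or (df["height"] < 0).any():
        raise ValueError(f"{path}: widths must be positive, heights >= 0")
    return df


def write_hills(hills: pd.DataFrame, path) -> Path:
    """Inverse of :func:`parse_hills` for the package's own dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#! FIELDS time cv sigma height biasf\n")
        for row in hills.itertuples(index=False):
            fh.write(f"{row.time:.6f} {row.cv:.9f} {row.sigma:.6f} "
                     f"{row.height:.9f} {row.biasf:.3f}\n")
    return path


def merge_walkers(walker_hills) -> pd.DataFrame:
    """Stable time-sorted merge of per-walker hills tables.

    Ties in deposition time are broken by walker index, preserving each
    walker's internal order (mergesort is stable).
    """
    if not walker_hills:
        raise ValueError("need at least one walker")
    frames = []
    for i, h in enumerate(walker_hills):
        h = h.copy()
        if "walker" not in h.columns:
            h["walker"] = i
        frames.append(h)
    merged = pd.concat(frames, ignore_index=True)
    return (merged.sort_values(["time", "walker"], kind="mergesort")
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# bias and PMF reconstruction
# ---------------------------------------------------------------------------

def bias_on_grid(hills: pd.DataFrame, grid: np.ndarray,
                 chunk: int = 2048) -> np.ndarray:
    """Sum of deposited Gaussians evaluated on a sorted grid (kJ/mol)."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted")
    v = np.zeros(grid.size)
    if len(hills) == 0:
        return v
    c = hills["cv"].to_numpy()
    s = hills["sigma"].to_numpy()
    h = hills["height"].to_numpy()
    for start in range(0, c.size, chunk):
        sl = slice(start, start + chunk)
        z = (grid[None, :] - c[sl, None]) / s[sl, None]
        v += (h[sl, None] * np.exp(-0.5 * z * z)).sum(axis=0)
    return v


def pmf(hills: pd.DataFrame, grid: np.ndarray,
        gamma: float = 35.0) -> FreeEnergyProfile:
    """Free-energy profile from the accumulated bias.

    With tempered heights the converged bias equals ``-(1-1/gamma) F``,
    so ``F = -(gamma/(gamma-1)) V`` (kJ converted to kcal, minimum at 0).
    ``gamma=inf`` gives the untempered estimator ``F = -V`` used for runs
    that were not well tempered.
    """
    if not np.isinf(gamma) and gamma <= 1:
        raise ValueError("bias factor must exceed 1 (or be inf)")
    v = bias_on_grid(hills, grid)
    factor = 1.0 if np.isinf(gamma) else gamma / (gamma - 1.0)
    f = -factor * v / KCAL_TO_KJ
    return FreeEnergyProfile(np.asarray(grid, dtype=float), f)


def convergence_series(hills: pd.DataFrame, grid: np.ndarray,
                       checkpoints, gamma: float = 35.0):
    """Profiles from the first k hills, plus max deviation from the final.

    Returns ``(profiles, deviations)`` where ``deviations[i]`` is
    ``max |F_k - F_final|`` over the grid, both profiles min-shifted.
    The final profile uses every hill regardless of the last checkpoint.
    """
    checkpoints = list(checkpoints)
    if any(b <= a for a, b in zip(checkpoints, checkpoints[1:])):
        raise ValueError("checkpoints must be strictly increasing")
    final = pmf(hills, grid, gamma)
    profiles = []
    deviations = []
    for k in checkpoints:
        prof = pmf(hills.iloc[:k], grid, gamma)
        profiles.append(prof)
        deviations.append(float(np.max(np.abs(prof.F_kcal - final.F_kcal))))
    return profiles, np.asarray(deviations)


def barrier_and_dg(profile: FreeEnergyProfile,
                   reactant_window, product_window):
    """Barrier and reaction free energy between two basins.

    ``reactant_window``/``product_window`` are (lo, hi) CV intervals each
    containing a local minimum.  The barrier is the highest point between
    the two minima relative to the reactant minimum; the reaction free
    energy is product minimum minus reactant minimum.
    """
    g, f = profile.grid, profile.F_kcal

    def window_min(win):
        lo, hi = win
        mask = (g >= lo) & (g <= hi)
        if not mask.any():
            raise ValueError(f"window {win} contains no grid points")
        idx = np.flatnonzero(mask)
        return idx[np.argmin(f[idx])]

    i_r = window_min(reactant_window)
    i_p = window_min(product_window)
    lo, hi = sorted((i_r, i_p))
    if hi - lo < 2:
        raise ValueError("no interior points between the two minima")
    interior = slice(lo + 1, hi)
    i_ts = lo + 1 + int(np.argmax(f[interior]))
    if f[i_ts] <= max(f[i_r], f[i_p]):
        raise ValueError("no interior maximum between the basins")
    barrier = float(f[i_ts] - f[i_r])
    dg_rxn = float(f[i_p] - f[i_r])
    return barrier, dg_rxn


def replica_mean_sem(profiles, grid=None,
                     reactant_window=None) -> FreeEnergyProfile:
    """Pointwise mean and SEM over replica profiles.

    Each replica is first re-anchored so that its reactant-basin minimum
    (the global minimum when no window is given) sits at zero, then the
    mean and ``sd/sqrt(n)`` are taken per grid point.  Profiles on
    different grids are linearly interpolated onto the target grid with a
    warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two replicas")
    if grid is None:
        grid = profiles[0].grid
    grid = np.asarray(grid, dtype=float)
    aligned = []
    for prof in profiles:
        f = prof.F_kcal
        g = prof.grid
        if g.shape != grid.shape or not np.allclose(g, grid):
            warnings.warn("replica grids differ; interpolating",
                          RuntimeWarning)
            f = np.interp(grid, g, f)
            g = grid
        if reactant_window is not None:
            lo, hi = reactant_window
            mask = (g >= lo) & (g <= hi)
            if not mask.any():
                raise ValueError("reactant window contains no grid points")
            f = f - f[mask].min()
        else:
            f = f - f.min()
        aligned.append(f)
    stack = np.vstack(aligned)
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    prof = FreeEnergyProfile(grid, mean)
    prof.sem_kcal = sem
    return prof


# ---------------------------------------------------------------------------
# collective variable
# ---------------------------------------------------------------------------

def antisym_cv(ce, sd, n6):
    """Antisymmetric methyl-transfer stretch xi = r(CE-SD) - r(CE-N6).

    ``CE`` is the transferring methyl carbon, ``SD`` the donor sulphur and
    ``N6`` the acceptor nitrogen.  Returns ``(xi, r_cs, r_cn)`` in the
    units of the input coordinates; both raw distances are reported
    because they are monitored alongside the biased coordinate.
    """
    ce = np.asarray(ce, dtype=float)
    sd = np.asarray(sd, dtype=float)
    n6 = np.asarray(n6, dtype=float)
    r_cs = float(np.linalg.norm(ce - sd))
    r_cn = float(np.linalg.norm(ce - n6))
    if r_cs == 0.0 or r_cn == 0.0:
        raise ValueError("coincident atoms in CV definition")
    return r_cs - r_cn, r_cs, r_cn
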