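"""Synthetic ground-truth generators for the full analysis chain.

Three generators stand in for the data a residence-time study obtains from
molecular dynamics:

* :func:`simulate_two_state` — two-state (bound/unbound) distance series
  with exponentially distributed first-dissociation times, emulating an
  ensemble of 16 independent 500 ns runs per condition;
* :func:`simulate_coordinates` — full 3-D toy coordinate frames in which a
  ligand sits inside a rigid pocket until its jump time, for end-to-end
  contacts-to-kinetics testing;
* :func:`simulate_wtmetad` — overdamped Langevin dynamics on an analytic
  1-D potential with well-tempered Gaussian deposition shared among
  multiple walkers, written as PLUMED-style HILLS files.

Every generator returns its ground truth (true rate, true jump times, the
analytic free-energy profile) so downstream estimators can be tested for
parameter recovery, and is byte-reproducible from its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import TrajectoryEnsemble

__all__ = [
    "TwoStateParams",
    "TwoStateRealisation",
    "simulate_two_state",
    "PocketSpec",
    "default_pocket_spec",
    "simulate_coordinates",
    "WTMetadParams",
    "WTMetadRun",
    "simulate_wtmetad",
    "ToyAtom",
    "make_toy_structure",
]

KB_KJ = 0.008314462618  # Boltzmann constant, kJ/(mol K)
KCAL_TO_KJ = 4.184


# ---------------------------------------------------------------------------
# two-state distance trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStateParams:
    """Parameters of the two-state bound/unbound distance generator.

    The defaults reproduce the study design the pipeline targets: sixteen
    independent 500 ns runs, frames every 0.5 ns, a bound-state
    ligand-pocket distance fluctuating around 4 A (well below the 10 A
    dissociation threshold) and an unbound plateau at 20 A.
    """

    koff_true_per_ns: float = 1.0 / 150.0
    t_max_ns: float = 500.0
    dt_ns: float = 0.5
    n_traj: int = 16
    bound_distance_mean_A: float = 4.0
    bound_distance_sd_A: float = 0.8
    unbound_distance_mean_A: float = 20.0
    unbound_distance_sd_A: float = 1.5
    rebinding_rate_per_ns: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.koff_true_per_ns <= 0:
            raise ValueError("koff_true must be positive")
        if self.dt_ns <= 0 or self.t_max_ns < self.dt_ns:
            raise ValueError("need 0 < dt <= t_max")
        if self.n_traj < 1:
            raise ValueError("need at least one trajectory")
        if self.unbound_distance_mean_A <= 10.0:
            raise ValueError("unbound mean must exceed the 10 A threshold")
        if self.bound_distance_mean_A + 3 * self.bound_distance_sd_A >= 10.0:
            raise ValueError("bound distances must stay clear of 10 A "
                             "(mean + 3 sd < 10)")
        if self.rebinding_rate_per_ns < 0:
            raise ValueError("rebinding rate cannot be negative")


@dataclass
class TwoStateRealisation:
    """Distance series plus the ground truth that generated them."""

    params: TwoStateParams
    time_ns: np.ndarray                  # shared frame-time grid
    distances_A: np.ndarray              # (n_traj, n_frames)
    true_times_ns: np.ndarray            # drawn Exp times (may exceed t_max)
    censored: np.ndarray                 # True where the jump falls beyond t_max

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: trajectory_id, time_ns, distance_A."""
        n_traj, n_frames = self.distances_A.shape
        return pd.DataFrame({
            "trajectory_id": np.repeat(np.arange(n_traj), n_frames),
            "time_ns": np.tile(self.time_ns, n_traj),
            "distance_A": self.distances_A.ravel(),
        })

    def manifest(self) -> dict:
        return {
            "koff_true_per_ns": self.params.koff_true_per_ns,
            "tau_true_ns": 1.0 / self.params.koff_true_per_ns,
            "seed": self.params.seed,
            "n_traj": self.params.n_traj,
            "t_max_ns": self.params.t_max_ns,
            "dt_ns": self.params.dt_ns,
            "true_times_ns": self.true_times_ns.tolist(),
            "censored": self.censored.tolist(),
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "distances.csv", index=False)
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2))


def simulate_two_state(params: TwoStateParams) -> TwoStateRealisation:
    """Draw per-trajectory jump times T ~ Exp(koff) and emit distances.

    Frames at times ``i*dt < T`` fluctuate (Gaussian, clipped at 0) about
    the bound mean; frames at or after T about the unbound mean.  The
    unbound state is absorbing unless a rebinding rate is given, in which
    case the ligand re-enters after an Exp(k_rebind) dwell and a fresh
    dissociation time is drawn (first-passage analysis should then use the
    first crossing only).
    """
    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.t_max_ns / params.dt_ns))
    # frames record the state at the END of each interval (dt, 2dt, ...),
    # so an arbitrarily fast rate leaves every recorded frame unbound
    t = np.arange(1, n_frames + 1) * params.dt_ns

    true_times = rng.exponential(1.0 / params.koff_true_per_ns,
                                 size=params.n_traj)
    censored = true_times > params.t_max_ns

    bound_state = t[None, :] < true_times[:, None]
    if params.rebinding_rate_per_ns > 0:
        bound_state = bound_state.copy()
        for i in range(params.n_traj):
            clock = true_times[i]
            while clock < params.t_max_ns:
                clock += rng.exponential(1.0 / params.rebinding_rate_per_ns)
                if clock >= params.t_max_ns:
                    break
                t_off = clock + rng.exponential(1.0 / params.koff_true_per_ns)
                bound_state[i] |= (t >= clock) & (t < t_off)
                clock = t_off

    noise = rng.standard_normal((params.n_traj, n_frames))
    d = np.where(
        bound_state,
        params.bound_distance_mean_A + params.bound_distance_sd_A * noise,
        params.unbound_distance_mean_A + params.unbound_distance_sd_A * noise,
    )
    np.clip(d, 0.0, None, out=d)
    return TwoStateRealisation(params, t, d, true_times, censored)


# ---------------------------------------------------------------------------
# toy coordinate ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PocketSpec:
    """Rigid toy pocket: residue atoms and ligand atoms with base positions.

    ``residues`` maps (segid, resid, resname) to a list of
    (atom_name, element, xyz); ``ligand_atoms`` is a list of the same
    triples for the ligand residue.
    """

    residues: tuple
    ligand_atoms: tuple
    ligand_resname: str = "LIG"

    def __post_init__(self) -> None:
        if not self.residues or not self.ligand_atoms:
            raise ValueError("pocket spec needs >=1 residue and >=1 ligand atom")
        for _, atoms in self.residues:
            if not atoms:
                raise ValueError("each pocket residue needs >=1 atom")


def default_pocket_spec() -> PocketSpec:
    """Three-residue pocket cradling a two-atom ligand at ~3-4 A."""
    return PocketSpec(
        residues=(
            (("PROT", 395, "ASP"), [("CG", "C", (3.5, 0.0, 0.0)),
                                    ("OD1", "O", (4.2, 1.0, 0.0))]),
            (("PROT", 513, "LYS"), [("NZ", "N", (-3.5, 0.5, 0.0))]),
            (("PROT", 406, "TYR"), [("OH", "O", (0.0, 3.8, 0.5))]),
        ),
        ligand_atoms=(("N6", "N", (0.0, 0.0, 0.0)),
                      ("C2", "C", (1.2, 0.3, 0.2))),
        ligand_resname="AMP",
    )


def simulate_coordinates(params: TwoStateParams,
                         pocket: PocketSpec | None = None
                         ) -> tuple[TrajectoryEnsemble, TwoStateRealisation]:
    """Full 3-D toy frames realising the two-state process.

    While bound, ligand atoms jitter (sd 0.3 A) about base positions
    within contact range of the pocket; from the jump frame onward the
    whole ligand is displaced by 15 A (> 12 A), so contacts vanish.
    Pocket atoms jitter rigidly with sd 0.1 A.  Returns the ensemble and
    the underlying two-state realisation (ground truth).
    """
    pocket = pocket or default_pocket_spec()
    real = simulate_two_state(params)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))

    rows = []
    base = []
    for (segid, resid, resname), atoms in pocket.residues:
        for name, elem, xyz in atoms:
            rows.append((name, elem, resid, resname, segid, False))
            base.append(xyz)
    for name, elem, xyz in pocket.ligand_atoms:
        rows.append((name, elem, 1, pocket.ligand_resname, "LIG", True))
        base.append(xyz)
    atoms_df = pd.DataFrame(
        rows, columns=["name", "element", "resid", "resname", "segid",
                       "is_ligand"])
    base = np.asarray(base, dtype=float)
    n_lig = len(pocket.ligand_atoms)
    escape = np.array([15.0, 0.0, 0.0])

    n_frames = real.time_ns.size
    trajectories = []
    for i in range(params.n_traj):
        bound = real.time_ns < real.true_times_ns[i]
        frames = np.tile(base, (n_frames, 1, 1))
        frames[:, :-n_lig or None, :] += 0.1 * rng.standard_normal(
            (n_frames, base.shape[0] - n_lig, 3))
        lig_jitter = 0.3 * rng.standard_normal((n_frames, n_lig, 3))
        frames[:, -n_lig:, :] += lig_jitter
        frames[~bound, -n_lig:, :] += escape
        trajectories.append(frames)
    ens = TrajectoryEnsemble(atoms_df, trajectories, params.dt_ns)
    return ens, real


# ---------------------------------------------------------------------------
# well-tempered metadynamics on an analytic potential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WTMetadParams:
    """Well-tempered multiple-walker metadynamics on a 1-D double well.

    The deposition protocol defaults match the production metadynamics
    setup the package targets: bias factor 35, a new Gaussian every
    0.2 ps with initial height 0.3 kJ/mol and width 0.05 (CV units),
    24 walkers sharing hill history every 1 ps, 250 ps per walker.
    The potential is the quartic double well
    ``V(x) = B * ((x/a)^2 - 1)^2`` with barrier ``B`` (kcal/mol) at x=0
    and minima at +-a.
    """

    barrier_kcal: float = 4.0
    minima_position: float = 1.0
    bias_factor: float = 35.0
    initial_height_kj: float = 0.3
    width: float = 0.05
    stride_ps: float = 0.2
    n_walkers: int = 24
    t_per_walker_ps: float = 250.0
    share_interval_ps: float = 1.0
    temperature_K: float = 300.0
    dt_ps: float = 0.004
    diffusion: float = 0.1       # CV^2 / ps, sets the Langevin mobility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if self.initial_height_kj <= 0 or self.width <= 0 or self.stride_ps <= 0:
            raise ValueError("height, width and stride must be positive")
        if self.dt_ps <= 0 or self.dt_ps > self.stride_ps:
            raise ValueError("need 0 < dt <= stride")
        if self.n_walkers < 1 or self.t_per_walker_ps <= 0:
            raise ValueError("need >=1 walker with positive run length")

    @property
    def steps_per_walker(self) -> int:
        return int(round(self.t_per_walker_ps / self.dt_ps))


@dataclass
class WTMetadRun:
    """Hills per walker plus the analytic reference free-energy profile."""

    params: WTMetadParams
    hills: list                       # one DataFrame per walker
    grid: np.ndarray                  # CV grid used for deposition
    reference_F_kcal: np.ndarray      # analytic PMF, min-shifted

    def merged_hills(self) -> pd.DataFrame:
        frames = [h.assign(walker=i) for i, h in enumerate(self.hills)]
        return (pd.concat(frames, ignore_index=True)
                .sort_values(["time", "walker"], kind="mergesort")
                .reset_index(drop=True))

    def write_hills(self, outdir) -> list:
        """One PLUMED-style HILLS file per walker; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, h in enumerate(self.hills):
            path = outdir / f"HILLS.{i}"
            with open(path, "w") as fh:
                fh.write("#! FIELDS time cv sigma height biasf\n")
                for row in h.itertuples(index=False):
                    fh.write(f"{row.time:.6f} {row.cv:.9f} {row.sigma:.6f} "
                             f"{row.height:.9f} {row.biasf:.3f}\n")
            paths.append(path)
        return paths


def _double_well(params: WTMetadParams):
    a = params.minima_position
    b_kj = params.barrier_kcal * KCAL_TO_KJ

    def v(x):
        return b_kj * ((x / a) ** 2 - 1.0) ** 2

    def dv(x):
        return b_kj * 4.0 * x / a ** 2 * ((x / a) ** 2 - 1.0)

    return v, dv


def simulate_wtmetad(params: WTMetadParams) -> WTMetadRun:
    """Overdamped Langevin walkers with well-tempered hill deposition.

    Euler-Maruyama integration of ``dx = -beta D (V' + Vbias') dt +
    sqrt(2 D dt) dW`` on the analytic double well.  Every ``stride_ps``
    each walker deposits a Gaussian whose height is scaled by
    ``exp(-Vbias(x)/(kB T (gamma - 1)))`` against the bias it currently
    sees; hills enter the shared history at ``share_interval_ps``, walkers
    always see their own hills immediately.  A warning is raised if the
    deterministic drift ever moves a walker by more than the Gaussian
    width in a single step (a sign the step size is too coarse).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    v, dv = _double_well(p)

    half_range = p.minima_position * 1.8
    grid = np.linspace(-half_range, half_range, 1601)
    dx = grid[1] - grid[0]

    beta = 1.0 / (KB_KJ * p.temperature_K)
    kt_delta = KB_KJ * p.temperature_K * (p.bias_factor - 1.0)

    n_steps = p.steps_per_walker
    deposit_every = max(1, int(round(p.stride_ps / p.dt_ps)))
    share_every = max(1, int(round(p.share_interval_ps / p.dt_ps)))

    # per-walker view of the bias (shared history + own fresh hills)
    vbias = np.zeros((p.n_walkers, grid.size))
    dvbias = np.zeros_like(vbias)
    pending_v = np.zeros(grid.size)
    pending_dv = np.zeros(grid.size)
    shared_v = np.zeros(grid.size)
    shared_dv = np.zeros(grid.size)

    x = rng.choice([-p.minima_position, p.minima_position], size=p.n_walkers)
    x = x + 0.05 * rng.standard_normal(p.n_walkers)
    hills = [[] for _ in range(p.n_walkers)]
    noise_amp = np.sqrt(2.0 * p.diffusion * p.dt_ps)
    drift_warned = False

    def interp_rows(table, pos):
        f = np.clip((pos - grid[0]) / dx, 0, grid.size - 1 - 1e-9)
        i0 = f.astype(int)
        w = f - i0
        rows = np.arange(p.n_walkers)
        return table[rows, i0] * (1 - w) + table[rows, i0 + 1] * w

    for step in range(n_steps):
        force = dv(x) + interp_rows(dvbias, x)
        drift = -beta * p.diffusion * force * p.dt_ps
        if not drift_warned and np.any(np.abs(drift) > p.width):
            warnings.warn(
                "Langevin drift exceeds the hill width in one step; "
                "reduce dt_ps for a converged integration", RuntimeWarning)
            drift_warned = True
        x = x + drift + noise_amp * rng.standard_normal(p.n_walkers)
        np.clip(x, grid[0], grid[-1], out=x)

        if (step + 1) % deposit_every == 0:
            t_ps = (step + 1) * p.dt_ps
            vb_here = interp_rows(vbias, x)
            heights = p.initial_height_kj * np.exp(-vb_here / kt_delta)
            for w_i in range(p.n_walkers):
                h = float(heights[w_i])
                c = float(x[w_i])
                hills[w_i].append((t_ps, c, p.width, h, p.bias_factor))
                g = h * np.exp(-0.5 * ((grid - c) / p.width) ** 2)
                dg = g * (-(grid - c) / p.width ** 2)
                pending_v += g
                pending_dv += dg
                vbias[w_i] += g
                dvbias[w_i] += dg

        if (step + 1) % share_every == 0:
            shared_v += pending_v
            shared_dv += pending_dv
            pending_v[:] = 0.0
            pending_dv[:] = 0.0
            vbias[:] = shared_v
            dvbias[:] = shared_dv

    hill_frames = [
        pd.DataFrame(h, columns=["time", "cv", "sigma", "height", "biasf"])
        for h in hills
    ]
    ref = v(grid) / KCAL_TO_KJ
    ref = ref - ref.min()
    return WTMetadRun(p, hill_frames, grid, ref)


# ---------------------------------------------------------------------------
# toy PDB structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyAtom:
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    xyz: tuple
    occupancy: float = 1.0
    altloc: str = " "
    hetero: bool = False


def make_toy_structure(atoms, path) -> Path:
    """Write a minimal PDB from a list of :class:`ToyAtom`.

    Coordinates are rounded to the PDB's 3-decimal precision before
    writing so that a write-read round trip through the structure reader
    is exact.  Duplicate (chain, resid, atom name, altloc) keys are
    rejected.
    """
    seen = set()
    for a in atoms:
        key = (a.chain, a.resid, a.name, a.altloc)
        if key in seen:
            raise ValueError(f"duplicate atom identifier {key}")
        seen.add(key)

    path = Path(path)
    lines = []
    for serial, a in enumerate(atoms, start=1):
        x, y, z = (round(c, 3) for c in a.xyz)
        record = "HETATM" if a.hetero else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{serial:>5d} {name:<4s}{a.altloc}{a.resname:>3s} "
            f"{a.chain}{a.resid:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
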