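"""Dissociation kinetics from trajectory ensembles.

The central object is :class:`DissociationKinetics`, a model built from
per-trajectory first-dissociation records.  Its :meth:`~DissociationKinetics.fit`
returns a :class:`KineticResults` carrying the fitted mean lifetime ``tau``,
its combinatorial block-averaged uncertainty, and unit conversions to
``koff``, ``Kd``, mean lifetime in seconds and the Eyring activation free
energy.

The estimator mirrors the protocol used for ligand-residence analysis of
independent equal-length MD runs:

* the survival curve is the empirical fraction of still-bound trajectories,
  with never-dissociating runs counted as bound through the common horizon
  (right-censoring at a fixed horizon makes the naive estimator exact);
* a single exponential ``S(t) = exp(-t/tau)`` (model ``"A"``) or
  ``S(t) = A*exp(-t/tau)`` (model ``"B"``) is least-squares fitted to that
  curve;
* the uncertainty comes from enumerating every half-sized block of the
  ensemble — all C(n, n/2) subsets, 12 870 for n = 16 — fitting each block,
  and reporting the mean and standard deviation of the block estimates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "DissociationRecord",
    "SurvivalCurve",
    "KineticFit",
    "RateEstimate",
    "DissociationKinetics",
    "KineticResults",
    "extract_dissociation_times",
    "survival_curve",
    "default_fit_grid",
    "fit_exponential",
    "block_average_fit",
    "koff_from_tau",
    "kd_from_koff",
    "lifetime_from_koff",
    "eyring_barrier",
    "eyring_rate",
]

# Physical constants (SI except R, which is kept in kcal/(mol K) because
# activation free energies are reported in kcal/mol).
R_KCAL = 1.98720425e-3  # gas constant, kcal/(mol K)
KB_J = 1.380649e-23     # Boltzmann constant, J/K
H_J = 6.62607015e-34    # Planck constant, J s

DEFAULT_KON = 1e9       # diffusion-limited association rate, 1/(M s)
DEFAULT_TEMPERATURE = 300.0  # ambient, K


# ---------------------------------------------------------------------------
# records and survival curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DissociationRecord:
    """First dissociation of one trajectory.

    ``time_ns`` is NaN when the trajectory never dissociates within its
    sampled horizon; the event time is then only known to exceed
    ``censor_time_ns``.
    """

    trajectory_id: str
    time_ns: float
    censored: bool
    censor_time_ns: float

    def __post_init__(self) -> None:
        if self.censor_time_ns <= 0:
            raise ValueError("censor_time_ns must be positive")
        if self.censored:
            if not math.isnan(self.time_ns):
                raise ValueError("censored record must carry NaN time")
        else:
            if math.isnan(self.time_ns):
                raise ValueError("uncensored record needs a finite time")
            if not 0 <= self.time_ns <= self.censor_time_ns:
                raise ValueError(
                    f"time {self.time_ns} outside [0, {self.censor_time_ns}]"
                )


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical fraction of bound trajectories on a time grid (ns)."""

    time_ns: np.ndarray
    fraction_bound: np.ndarray
    n_trajectories: int

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ns, dtype=float)
        s = np.asarray(self.fraction_bound, dtype=float)
        object.__setattr__(self, "time_ns", t)
        object.__setattr__(self, "fraction_bound", s)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("time grid and fractions must be matching 1-D arrays")
        if np.any(np.diff(t) < 0):
            raise ValueError("time grid must be sorted")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("fraction bound must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ns": self.time_ns, "fraction_bound": self.fraction_bound}
        )


def extract_dissociation_times(bound_series, frame_interval_ns=None,
                               trajectory_ids=None):
    """First-crossing dissociation times from per-trajectory bound series.

    Parameters
    ----------
    bound_series
        Sequence of per-frame boolean arrays (``True`` = bound), or of
        objects with ``bound`` and ``frame_interval_ns`` attributes (the
        contacts module's ``BoundSeries``).
    frame_interval_ns
        Frame spacing in ns; required for plain boolean arrays.

    The event time is the time of the first unbound frame; a trajectory
    that never leaves the bound state is censored at its full length.
    Once a trajectory has dissociated it stays dissociated — re-entries
    are deliberately not credited.
    """
    records = []
    for i, series in enumerate(bound_series):
        if hasattr(series, "bound"):
            bound = np.asarray(series.bound, dtype=bool)
            dt = series.frame_interval_ns
        else:
            bound = np.asarray(series, dtype=bool)
            dt = frame_interval_ns
        if dt is None or dt <= 0:
            raise ValueError("frame_interval_ns must be positive")
        if bound.size == 0:
            raise ValueError(f"trajectory {i}: empty bound series")
        tid = trajectory_ids[i] if trajectory_ids is not None else str(i)
        horizon = bound.size * dt
        unbound = np.flatnonzero(~bound)
        if unbound.size == 0:
            records.append(DissociationRecord(tid, float("nan"), True, horizon))
        else:
            records.append(
                DissociationRecord(tid, float(unbound[0] * dt), False, horizon)
            )
    return records


def survival_curve(records: Sequence[DissociationRecord],
                   grid: np.ndarray | None = None) -> SurvivalCurve:
    """Fraction of bound trajectories over time.

    ``S(t)`` counts records whose dissociation time exceeds ``t``; censored
    records count as bound through their censor time.  The default grid is
    0, the sorted distinct event times, and the common horizon — the
    coarsest grid on which the empirical step function is fully resolved.
    """
    if not records:
        raise ValueError("need at least one record")
    horizon = min(r.censor_time_ns for r in records)
    times = np.array([r.time_ns for r in records])
    censored = np.array([r.censored for r in records])
    if grid is None:
        events = np.unique(times[~censored])
        grid = np.unique(np.concatenate([[0.0], events, [horizon]]))
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.size and grid.max() > horizon + 1e-9:
            raise ValueError(
                f"grid extends to {grid.max()} ns beyond the common horizon "
                f"{horizon} ns; survival is undefined there"
            )
    # censored trajectories survive every grid point at or below the horizon
    surv = np.where(censored[:, None], True, times[:, None] > grid[None, :])
    s = surv.mean(axis=0)
    return SurvivalCurve(grid, s, len(records))


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------

def default_fit_grid(horizon_ns: float, n_points: int = 256) -> np.ndarray:
    """Uniform time grid for survival fitting.

    Fits target the fraction-bound curve sampled uniformly in time (as a
    per-frame bound fraction is); fitting on the event-time grid instead
    would over-weight the event-dense early decay and bias the lifetime
    low under censoring.
    """
    return np.linspace(0.0, horizon_ns, n_points)


@dataclass(frozen=True)
class KineticFit:
    """Single least-squares exponential fit of a survival curve."""

    model: str                 # "A" (A fixed at 1) or "B" (A free)
    tau_ns: float
    pre_exponential: float
    residual: float            # sum of squared residuals
    n_points: int

    def __post_init__(self) -> None:
        if self.tau_ns <= 0:
            raise ValueError("tau must be positive")


class AllCensoredError(RuntimeError):
    """No dissociation events: the lifetime is only bounded from below."""


def _tau_initial(t: np.ndarray, s: np.ndarray) -> float:
    """Deterministic start: first time S drops below 1/e, else horizon/2."""
    below = np.flatnonzero(s < math.exp(-1))
    if below.size and t[below[0]] > 0:
        return float(t[below[0]])
    return float(max(t[-1] / 2.0, np.max(t[t > 0], initial=1.0) / 2.0))


def _sse_model_a(tau: float, t: np.ndarray, s: np.ndarray) -> float:
    r = s - np.exp(-t / tau)
    return float(r @ r)


def _fit_tau_model_a(t: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """1-D bounded least squares for S(t)=exp(-t/tau); returns (tau, sse)."""
    horizon = float(t[-1]) if t[-1] > 0 else 1.0
    lo, hi = horizon * 1e-4, horizon * 1e4
    res = minimize_scalar(
        _sse_model_a, bounds=(lo, hi), args=(t, s), method="bounded",
        options={"xatol": lo * 1e-6},
    )
    return float(res.x), float(res.fun)


def fit_exponential(curve: SurvivalCurve, model: str = "A") -> KineticFit:
    """Fit ``exp(-t/tau)`` (model A) or ``A*exp(-t/tau)`` (model B).

    The fit target is the empirical fraction-bound step function on the
    curve's own grid.  A pre-exponential near 1 under model B indicates
    that the single exponential describes the decay well.
    """
    t = curve.time_ns
    s = curve.fraction_bound
    if np.all(s >= 1.0):
        raise AllCensoredError(
            "no dissociations within the horizon; tau >> horizon, fit impossible"
        )
    if np.unique(t[s < 1]).size < 3 and model == "B":
        raise ValueError("model B needs >= 3 distinct times with S < 1")
    if model == "A":
        tau, sse = _fit_tau_model_a(t, s)
        return KineticFit("A", tau, 1.0, sse, t.size)
    if model != "B":
        raise ValueError(f"unknown model {model!r}; use 'A' or 'B'")

    tau0 = _tau_initial(t, s)

    def resid(p):
        a, tau = p
        return a * np.exp(-t / tau) - s

    sol = least_squares(
        resid, x0=[1.0, tau0],
        bounds=([1e-9, t[-1] * 1e-4], [10.0, t[-1] * 1e4]),
    )
    a, tau = sol.x
    return KineticFit("B", float(tau), float(a), float(2 * sol.cost), t.size)


@dataclass(frozen=True)
class BlockAverage:
    """Combinatorial block-averaged lifetime estimate."""

    tau_mean_ns: float
    tau_sd_ns: float
    n_subsets: int
    n_skipped: int         # subsets without a single dissociation
    block_size: int
    model: str
    tau_values: np.ndarray = field(repr=False)


def _subset_survival(times: np.ndarray, censored: np.ndarray,
                     grid: np.ndarray, idx: np.ndarray):
    sub_t = times[idx]
    sub_c = censored[idx]
    surv = np.where(sub_c[:, None], True, sub_t[:, None] > grid[None, :])
    return surv.mean(axis=0)


def block_average_fit(records: Sequence[DissociationRecord],
                      block_size: int | None = None,
                      model: str = "A",
                      grid: np.ndarray | None = None) -> BlockAverage:
    """Enumerate all C(n, block) blocks, fit each, average the lifetimes.

    With the default half-sized blocks and n = 16 this enumerates all
    16-choose-8 = 12 870 combinations; the mean of the block fits is the
    reported lifetime and their standard deviation its error.  Blocks in
    which no trajectory dissociates cannot be fitted and are skipped (and
    counted).  The companion single fit on all n trajectories — "without
    block averaging" — is available via :func:`fit_exponential`.
    """
    n = len(records)
    if block_size is None:
        if n % 2:
            raise ValueError("default half-blocks need an even ensemble size")
        block_size = n // 2
    if not 0 < block_size <= n:
        raise ValueError("block size must be in (0, n]")
    times = np.array([r.time_ns for r in records])
    censored = np.array([r.censored for r in records])
    horizon = min(r.censor_time_ns for r in records)
    if grid is None:
        grid = default_fit_grid(horizon)

    taus = []
    skipped = 0
    total = 0
    for combo in itertools.combinations(range(n), block_size):
        total += 1
        idx = np.asarray(combo)
        if censored[idx].all():
            skipped += 1
            continue
        s = _subset_survival(times, censored, grid, idx)
        if model == "A":
            tau, _ = _fit_tau_model_a(grid, s)
        else:
            tau = fit_exponential(
                SurvivalCurve(grid, s, block_size), model=model
            ).tau_ns
        taus.append(tau)
    if not taus:
        raise AllCensoredError("every block was fully censored; no fit possible")
    taus = np.asarray(taus)
    sd = float(taus.std(ddof=1)) if taus.size > 1 else 0.0
    return BlockAverage(float(taus.mean()), sd, total, skipped,
                        block_size, model, taus)


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def koff_from_tau(tau_ns: float) -> float:
    """Dissociation rate in 1/s from a mean lifetime in ns."""
    if tau_ns <= 0:
        raise ValueError("tau must be positive")
    return 1.0 / (tau_ns * 1e-9)


def kd_from_koff(koff: float, kon: float = DEFAULT_KON) -> float:
    """Equilibrium dissociation constant Kd = koff/kon in M."""
    if koff <= 0 or kon <= 0:
        raise ValueError("rates must be positive")
    return koff / kon


def lifetime_from_koff(koff: float) -> float:
    """Mean bound lifetime 1/koff in seconds."""
    if koff <= 0:
        raise ValueError("koff must be positive")
    return 1.0 / koff


def eyring_barrier(rate: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Activation free energy (kcal/mol) implied by a rate constant.

    Transition-state theory with transmission coefficient 1:
    ``dG = R T ln(kB T / (h k))``.
    """
    if rate <= 0 or temperature <= 0:
        raise ValueError("rate and temperature must be positive")
    return R_KCAL * temperature * math.log(KB_J * temperature / (H_J * rate))


def eyring_rate(dg_kcal: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`eyring_barrier`: rate in 1/s from a barrier."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return KB_J * temperature / H_J * math.exp(-dg_kcal / (R_KCAL * temperature))


@dataclass(frozen=True)
class RateEstimate:
    """Lifetime with all derived kinetic and thermodynamic quantities."""

    tau_ns: float
    tau_sd_ns: float
    koff_per_s: float
    kon_per_M_s: float
    kd_M: float
    mean_lifetime_s: float
    dg_barrier_kcal: float
    temperature_K: float

    @classmethod
    def from_tau(cls, tau_ns: float, tau_sd_ns: float = 0.0,
                 kon: float = DEFAULT_KON,
                 temperature: float = DEFAULT_TEMPERATURE) -> "RateEstimate":
        koff = koff_from_tau(tau_ns)
        return cls(
            tau_ns=tau_ns,
            tau_sd_ns=tau_sd_ns,
            koff_per_s=koff,
            kon_per_M_s=kon,
            kd_M=kd_from_koff(koff, kon),
            mean_lifetime_s=lifetime_from_koff(koff),
            dg_barrier_kcal=eyring_barrier(koff, temperature),
            temperature_K=temperature,
        )

    def to_dict(self) -> dict:
        return {
            "tau_ns": self.tau_ns,
            "tau_sd_ns": self.tau_sd_ns,
            "koff_per_s": self.koff_per_s,
            "kon_per_M_s": self.kon_per_M_s,
            "kd_M": self.kd_M,
            "kd_mM": self.kd_M * 1e3,
            "mean_lifetime_s": self.mean_lifetime_s,
            "mean_lifetime_min": self.mean_lifetime_s / 60.0,
            "dg_barrier_kcal_per_mol": self.dg_barrier_kcal,
            "temperature_K": self.temperature_K,
        }


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class DissociationKinetics:
    """Exponential dissociation model for an ensemble of independent runs.

    Parameters
    ----------
    records
        One :class:`DissociationRecord` per trajectory.

    Examples
    --------
    >>> recs = [DissociationRecord(str(i), 50.0 * (i + 1), False, 500.0)
    ...         for i in range(4)]
    >>> res = DissociationKinetics(recs).fit(model="A", block_size=2)
    >>> res.tau_ns > 0
    True
    """

    def __init__(self, records: Sequence[DissociationRecord]):
        if not records:
            raise ValueError("need at least one dissociation record")
        self.records = list(records)
        self.n_trajectories = len(records)
        self.horizon_ns = min(r.censor_time_ns for r in records)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DissociationKinetics":
        """Build from a table with columns trajectory_id, time_ns, censored
        and optionally censor_time_ns (defaults to the max observed time)."""
        if "censor_time_ns" in df.columns:
            horizon = df["censor_time_ns"]
        else:
            horizon = pd.Series(
                float(df["time_ns"].max()), index=df.index
            )
        records = [
            DissociationRecord(
                str(row.trajectory_id),
                float("nan") if row.censored else float(row.time_ns),
                bool(row.censored),
                float(h),
            )
            for (_, row), h in zip(df.iterrows(), horizon)
        ]
        return cls(records)

    @classmethod
    def from_bound_series(cls, bound_series, frame_interval_ns=None,
                          trajectory_ids=None) -> "DissociationKinetics":
        return cls(extract_dissociation_times(
            bound_series, frame_interval_ns, trajectory_ids))

    def survival(self, grid: np.ndarray | None = None) -> SurvivalCurve:
        return survival_curve(self.records, grid)

    def fit(self, model: str = "A", block: bool = True,
            block_size: int | None = None,
            grid: np.ndarray | None = None) -> "KineticResults":
        """Fit the exponential; with ``block=True`` also enumerate all
        half-sized (or ``block_size``-sized) blocks for the uncertainty.

        Fitting uses a uniform time grid over the common horizon (see
        :func:`default_fit_grid`) unless an explicit grid is given.
        """
        if grid is None:
            grid = default_fit_grid(self.horizon_ns)
        full = fit_exponential(self.survival(grid), model=model)
        blocks = None
        if block:
            blocks = block_average_fit(self.records, block_size, model, grid)
        return KineticResults(self, full, blocks)


class KineticResults:
    """Fit results: lifetime, block-averaged uncertainty, conversions."""

    def __init__(self, model: DissociationKinetics, full_fit: KineticFit,
                 blocks: BlockAverage | None):
        self.model = model
        self.full_fit = full_fit
        self.blocks = blocks

    @property
    def tau_ns(self) -> float:
        """Reported lifetime: block-averaged mean when available."""
        return self.blocks.tau_mean_ns if self.blocks else self.full_fit.tau_ns

    @property
    def tau_sd_ns(self) -> float:
        return self.blocks.tau_sd_ns if self.blocks else float("nan")

    @property
    def pre_exponential(self) -> float:
        return self.full_fit.pre_exponential

    def convert(self, kon: float = DEFAULT_KON,
                temperature: float = DEFAULT_TEMPERATURE) -> RateEstimate:
        return RateEstimate.from_tau(self.tau_ns, self.tau_sd_ns,
                                     kon, temperature)

    def summary(self, kon: float = DEFAULT_KON,
                temperature: float = DEFAULT_TEMPERATURE) -> str:
        n_cens = sum(r.censored for r in self.model.records)
        est = self.convert(kon, temperature)
        lines = [
            "Dissociation kinetics (single-exponential survival fit)",
            "=" * 58,
            f"trajectories          {self.model.n_trajectories:>12d}"
            f"   (censored: {n_cens})",
            f"horizon               {self.model.horizon_ns:>12.1f} ns",
            f"model                 {self.full_fit.model:>12s}",
            f"tau (all runs)        {self.full_fit.tau_ns:>12.4g} ns",
            f"pre-exponential A     {self.full_fit.pre_exponential:>12.4g}",
        ]
        if self.blocks:
            b = self.blocks
            lines += [
                f"block size            {b.block_size:>12d}"
                f"   ({b.n_subsets} subsets, {b.n_skipped} skipped)",
                f"tau (block mean)      {b.tau_mean_ns:>12.4g} ns",
                f"tau SD                {b.tau_sd_ns:>12.4g} ns",
            ]
        lines += [
            "-" * 58,
            f"koff                  {est.koff_per_s:>12.4g} 1/s",
            f"Kd (kon={kon:.3g}/M/s) {est.kd_M * 1e3:>11.4g} mM",
            f"mean lifetime         {est.mean_lifetime_s:>12.4g} s",
            f"Eyring dG' (T={temperature:.0f} K) {est.dg_barrier_kcal:>9.4g}"
            " kcal/mol",
        ]
        return "\n".join(lines)

    def to_dict(self, kon: float = DEFAULT_KON,
                temperature: float = DEFAULT_TEMPERATURE) -> dict:
        out = {
            "model": self.full_fit.model,
            "n_trajectories": self.model.n_trajectories,
            "n_censored": int(sum(r.censored for r in self.model.records)),
            "horizon_ns": self.model.horizon_ns,
            "tau_all_ns": self.full_fit.tau_ns,
            "pre_exponential": self.full_fit.pre_exponential,
        }
        if self.blocks:
            out.update(
                block_size=self.blocks.block_size,
                n_subsets=self.blocks.n_subsets,
                n_subsets_skipped=self.blocks.n_skipped,
                tau_block_mean_ns=self.blocks.tau_mean_ns,
                tau_block_sd_ns=self.blocks.tau_sd_ns,
            )
        out["conversions"] = self.convert(kon, temperature).to_dict()
        return out

    def plot_survival(self, ax=None):
        """Step plot of the empirical survival with the fitted exponential."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.model.survival()
        ax.step(curve.time_ns, curve.fraction_bound, where="post",
                label="ensemble")
        tt = np.linspace(0, curve.time_ns[-1], 200)
        ax.plot(tt, self.full_fit.pre_exponential * np.exp(-tt / self.tau_ns),
                "--", label=f"fit tau={self.tau_ns:.3g} ns")
        ax.set_xlabel("time (ns)")
        ax.set_ylabel("fraction bound")
        ax.set_ylim(0, 1.05)
        ax.legend()
        return ax
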