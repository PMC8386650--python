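"""Well-tempered multiple-walker metadynamics on 1D toy potentials.

A desk-scale enhanced-sampling engine: overdamped (position) Langevin
dynamics on an analytic potential, with history-dependent Gaussian bias
deposited along the collective variable (CV).  In the well-tempered variant
each deposited hill is scaled by exp(-V_bias/((gamma-1) kB T)), so hill
heights decay where the bias has already accumulated and the bias converges
to -(1 - 1/gamma) F.  Several walkers explore the same landscape and share
their bias, exchanging newly deposited hills at a fixed synchronisation
stride.

The free-energy profile is reconstructed from the deposited hills with the
standard rescaled-bias estimator F(s) = -(gamma/(gamma-1)) V_bias(s), shifted
so the global minimum is zero.  For 1D overdamped Langevin dynamics the free
energy along the CV equals the potential itself, which provides an exact
oracle for validating the whole chain.

Default bias parameters follow common practice for ligand-binding CVs:
0.1 kcal/mol hills of 0.1 Angstrom width every 4 ps, bias factor 10, a
kappa = 100 kcal/mol/A^2 harmonic wall at 12 A, six walkers syncing every
20 ps, at 300 K.  Units: kcal/mol, Angstrom, ps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "KB_KCAL_MOL_K",
    "MetadParams",
    "ToyPotential",
    "HillsRecord",
    "FreeEnergyProfile",
    "run_langevin_metadynamics",
    "reconstruct_fes",
    "convergence_series",
    "find_wells_and_barriers",
    "write_hills",
    "read_hills",
    "write_fes",
    "read_fes",
]

KB_KCAL_MOL_K = 0.0019872041  # Boltzmann constant, kcal/mol/K


@dataclass(frozen=True)
class MetadParams:
    """Well-tempered multiple-walker bias parameters (kcal/mol, Angstrom, ps)."""

    hill_height: float = 0.1
    hill_sigma: float = 0.1
    deposition_stride: float = 4.0
    bias_factor: float = 10.0
    wall_kappa: float = 100.0
    wall_position: float = 12.0
    n_walkers: int = 6
    walker_sync_stride: float = 20.0
    temperature: float = 300.0

    def __post_init__(self):
        if self.bias_factor <= 1:
            raise ValueError("well-tempered bias factor must be > 1")
        if self.deposition_stride <= 0 or self.walker_sync_stride <= 0:
            raise ValueError("strides must be > 0")
        if self.hill_height < 0 or self.hill_sigma <= 0:
            raise ValueError("hill height must be >= 0 and sigma > 0")
        if self.n_walkers < 1:
            raise ValueError("need at least one walker")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kt(self) -> float:
        return KB_KCAL_MOL_K * self.temperature


@dataclass(frozen=True)
class ToyPotential:
    """Analytic 1D potential with Langevin integration parameters.

    ``friction`` is the drag coefficient zeta in kcal*ps/mol/A^2 (diffusion
    coefficient D = kB*T/zeta); ``timestep`` in ps.  Factories below cover the
    harmonic, double-well, flat and tabulated forms.
    """

    form: str
    parameters: dict = field(default_factory=dict)
    temperature: float = 300.0
    friction: float = 5.0
    timestep: float = 0.01

    def __post_init__(self):
        if self.temperature <= 0 or self.friction <= 0 or self.timestep <= 0:
            raise ValueError("temperature, friction and timestep must be > 0")
        if self.form == "double_well" and self.parameters.get("barrier", 0.0) < 0:
            raise ValueError("barrier must be >= 0")

    @classmethod
    def harmonic(cls, k: float = 2.0, center: float = 0.0, **kwargs) -> "ToyPotential":
        return cls(form="harmonic", parameters={"k": k, "center": center}, **kwargs)

    @classmethod
    def flat(cls, **kwargs) -> "ToyPotential":
        return cls(form="flat", parameters={}, **kwargs)

    @classmethod
    def double_well(
        cls,
        barrier: float = 1.3,
        half_separation: float = 1.0,
        center: float = 0.0,
        tilt: float = 0.0,
        **kwargs,
    ) -> "ToyPotential":
        """Quartic double well U = barrier*((s-c)^2 - a^2)^2 / a^4 + tilt*(s-c).

        Minima near c +/- a separated by a barrier of the given height
        (kcal/mol) at s = c when tilt = 0.
        """
        return cls(
            form="double_well",
            parameters={
                "barrier": barrier,
                "half_separation": half_separation,
                "center": center,
                "tilt": tilt,
            },
            **kwargs,
        )

    @classmethod
    def tabulated(cls, grid, energy, **kwargs) -> "ToyPotential":
        grid = np.asarray(grid, dtype=float)
        energy = np.asarray(energy, dtype=float)
        if grid.size != energy.size or grid.size < 2:
            raise ValueError("tabulated potential needs matching grid/energy arrays")
        return cls(form="tabulated", parameters={"grid": grid, "energy": energy}, **kwargs)

    def energy(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        p = self.parameters
        if self.form == "harmonic":
            return 0.5 * p["k"] * (s - p["center"]) ** 2
        if self.form == "flat":
            return np.zeros_like(s)
        if self.form == "double_well":
            a = p["half_separation"]
            u = s - p["center"]
            return p["barrier"] * (u**2 - a**2) ** 2 / a**4 + p["tilt"] * u
        if self.form == "tabulated":
            return np.interp(s, p["grid"], p["energy"])
        raise ValueError(f"unknown potential form {self.form!r}")

    def force(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        p = self.parameters
        if self.form == "harmonic":
            return -p["k"] * (s - p["center"])
        if self.form == "flat":
            return np.zeros_like(s)
        if self.form == "double_well":
            a = p["half_separation"]
            u = s - p["center"]
            return -(4.0 * p["barrier"] * u * (u**2 - a**2) / a**4 + p["tilt"])
        if self.form == "tabulated":
            g, e = p["grid"], p["energy"]
            de = np.gradient(e, g)
            return -np.interp(s, g, de)
        raise ValueError(f"unknown potential form {self.form!r}")


@dataclass(frozen=True)
class HillsRecord:
    """Deposited Gaussians: times (ps), centers/sigmas (A), heights (kcal/mol).

    ``height`` stores the *deposited* (well-tempered scaled) heights, each in
    (0, hill_height]; ``walker`` identifies the depositing replica.
    """

    time: np.ndarray
    center: np.ndarray
    sigma: np.ndarray
    height: np.ndarray
    walker: np.ndarray
    bias_factor: float
    cv_label: str = "cv1"

    def __post_init__(self):
        arrays = {
            name: np.asarray(getattr(self, name), dtype=(int if name == "walker" else float))
            for name in ("time", "center", "sigma", "height", "walker")
        }
        n = arrays["time"].size
        if any(a.size != n for a in arrays.values()):
            raise ValueError("hill arrays must share one length")
        for name, a in arrays.items():
            object.__setattr__(self, name, a)
        for w in np.unique(arrays["walker"]):
            tw = arrays["time"][arrays["walker"] == w]
            if np.any(np.diff(tw) < 0):
                raise ValueError(f"hill times must be non-decreasing per walker (walker {w})")

    def __len__(self) -> int:
        return int(self.time.size)

    def sorted_by_time(self) -> "HillsRecord":
        order = np.argsort(self.time, kind="stable")
        return HillsRecord(
            time=self.time[order],
            center=self.center[order],
            sigma=self.sigma[order],
            height=self.height[order],
            walker=self.walker[order],
            bias_factor=self.bias_factor,
            cv_label=self.cv_label,
        )


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Free energy (kcal/mol) on a CV grid (A); global minimum pinned at 0."""

    grid: np.ndarray
    free_energy: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        f = np.asarray(self.free_energy, dtype=float)
        if g.size != f.size:
            raise ValueError("grid and free energy must match")
        if not np.all(np.isfinite(f)):
            raise ValueError("free energy must be finite on the grid")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "free_energy", f)


def _wall_force(x, kappa, pos):
    """One-sided harmonic walls applied symmetrically at +/- pos."""
    f = np.zeros_like(x)
    over = x > pos
    under = x < -pos
    f[over] = -2.0 * kappa * (x[over] - pos)
    f[under] = -2.0 * kappa * (x[under] + pos)
    return f


def run_langevin_metadynamics(
    potential: ToyPotential,
    params: MetadParams,
    n_steps: int,
    seed: int = 0,
    x0=None,
    traj_stride: int = 10,
    grid_range: Optional[tuple] = None,
):
    """Run well-tempered multiple-walker metadynamics; return (trajectory, hills).

    Euler-Maruyama overdamped Langevin on U + V_bias + V_wall.  Every
    ``deposition_stride`` each walker deposits a Gaussian whose height is
    hill_height * exp(-V_bias/((gamma-1) kB T)) evaluated with the bias that
    walker currently sees; hills enter the shared bias at every
    ``walker_sync_stride`` (a walker always sees its own un-synced hills).
    With ``hill_height = 0`` this is plain Langevin sampling.

    The timestep is checked against the stiffest curvature of U plus the
    wall: dt must satisfy dt * max|U''| / friction <= 0.5, else ValueError.
    Returns ``trajectory`` of shape (n_saved, n_walkers) and a
    :class:`HillsRecord` (empty when hill_height is 0).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    dt = potential.timestep
    zeta = potential.friction
    kt = params.kt
    gamma = params.bias_factor

    if grid_range is None:
        grid_range = (-params.wall_position - 3.0, params.wall_position + 3.0)
    dg = params.hill_sigma / 5.0
    grid = np.arange(grid_range[0], grid_range[1] + dg, dg)

    # documented stability check for the explicit Euler step, probing only the
    # thermally reachable region (U - min U <= 15 kcal/mol): curvature in
    # regions the dynamics cannot visit is irrelevant
    probe = grid[(grid > grid_range[0] + dg) & (grid < grid_range[1] - dg)]
    u_probe = potential.energy(probe)
    reachable = u_probe - u_probe.min() <= 15.0
    curvature = np.gradient(-potential.force(probe), probe)[reachable]
    k_max = float(np.nanmax(np.abs(curvature)))
    if np.any(np.abs(probe[reachable]) >= params.wall_position):
        k_max += 2.0 * params.wall_kappa
    if dt * k_max / zeta > 0.5:
        raise ValueError(
            f"timestep {dt} ps unstable for potential stiffness "
            f"(max curvature ~{k_max:.1f} kcal/mol/A^2, friction {zeta}); "
            f"require dt*k/friction <= 0.5"
        )

    rng = np.random.default_rng(seed)
    nw = params.n_walkers
    if x0 is None:
        x = grid[np.argmin(potential.energy(grid))] + 0.05 * rng.standard_normal(nw)
    else:
        x = np.broadcast_to(np.asarray(x0, dtype=float), (nw,)).copy()

    steps_per_dep = max(1, int(round(params.deposition_stride / dt)))
    steps_per_sync = max(1, int(round(params.walker_sync_stride / dt)))
    sig2 = params.hill_sigma**2
    noise_scale = math.sqrt(2.0 * kt * dt / zeta)
    mobility_dt = dt / zeta

    v_grid = np.zeros_like(grid)       # shared bias potential
    f_grid = np.zeros_like(grid)       # shared bias force (-dV/ds)
    pend_c: list = []                  # pending hill centers, each (nw,)
    pend_h: list = []

    h_time, h_center, h_height, h_walker = [], [], [], []
    n_saved = n_steps // traj_stride + 1
    traj = np.empty((n_saved, nw))
    traj[0] = x
    save_i = 1

    depositing = params.hill_height > 0
    for step in range(1, n_steps + 1):
        f = potential.force(x) + _wall_force(x, params.wall_kappa, params.wall_position)
        if depositing:
            f = f + np.interp(x, grid, f_grid)
            for c, h in zip(pend_c, pend_h):
                d = x - c
                f = f + h * d / sig2 * np.exp(-0.5 * d * d / sig2)
        x = x + mobility_dt * f + noise_scale * rng.standard_normal(nw)

        if depositing and step % steps_per_dep == 0:
            v_seen = np.interp(x, grid, v_grid)
            for c, h in zip(pend_c, pend_h):
                d = x - c
                v_seen = v_seen + h * np.exp(-0.5 * d * d / sig2)
            h_dep = params.hill_height * np.exp(-v_seen / ((gamma - 1.0) * kt))
            t_now = step * dt
            h_time.extend([t_now] * nw)
            h_center.extend(x.tolist())
            h_height.extend(h_dep.tolist())
            h_walker.extend(range(nw))
            pend_c.append(x.copy())
            pend_h.append(h_dep.copy())

        if depositing and step % steps_per_sync == 0 and pend_c:
            for c, h in zip(pend_c, pend_h):
                for ci, hi in zip(c, h):
                    d = grid - ci
                    g = np.exp(-0.5 * d * d / sig2)
                    v_grid += hi * g
                    f_grid += hi * d / sig2 * g
            pend_c.clear()
            pend_h.clear()

        if step % traj_stride == 0:
            traj[save_i] = x
            save_i += 1

    n = len(h_time)
    hills = HillsRecord(
        time=np.asarray(h_time),
        center=np.asarray(h_center),
        sigma=np.full(n, params.hill_sigma),
        height=np.asarray(h_height),
        walker=np.asarray(h_walker, dtype=int),
        bias_factor=gamma,
    )
    return traj[:save_i], hills


def _bias_on_grid(grid, centers, sigmas, heights, chunk=2000):
    v = np.zeros_like(grid)
    for i in range(0, centers.size, chunk):
        c = centers[i : i + chunk, None]
        s = sigmas[i : i + chunk, None]
        h = heights[i : i + chunk, None]
        v += np.sum(h * np.exp(-0.5 * ((grid[None, :] - c) / s) ** 2), axis=0)
    return v


def reconstruct_fes(hills: HillsRecord, grid) -> FreeEnergyProfile:
    """Free energy from deposited hills: F = -(gamma/(gamma-1)) V_bias, min 0.

    Permutation-invariant in hill order (a plain Gaussian sum).
    """
    if len(hills) == 0:
        raise ValueError("no hills deposited; cannot reconstruct a profile")
    grid = np.asarray(grid, dtype=float)
    gamma = hills.bias_factor
    v = _bias_on_grid(grid, hills.center, hills.sigma, hills.height)
    fes = -(gamma / (gamma - 1.0)) * v
    return FreeEnergyProfile(grid=grid, free_energy=fes - fes.min())


def convergence_series(hills: HillsRecord, block: int, grid) -> list:
    """Profiles from the first k*block hills (deposition-time order), k = 1, ...

    The final element always uses all hills, so it equals
    ``reconstruct_fes(hills, grid)``.  Used to monitor convergence the way
    production metadynamics is monitored by replotting the profile every N
    deposited Gaussians.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    if len(hills) == 0:
        raise ValueError("no hills deposited")
    h = hills.sorted_by_time()
    grid = np.asarray(grid, dtype=float)
    gamma = h.bias_factor
    boundaries = list(range(block, len(h) + 1, block))
    if not boundaries or boundaries[-1] != len(h):
        boundaries.append(len(h))
    profiles = []
    v = np.zeros_like(grid)
    start = 0
    for b in boundaries:
        v = v + _bias_on_grid(grid, h.center[start:b], h.sigma[start:b], h.height[start:b])
        start = b
        fes = -(gamma / (gamma - 1.0)) * v
        profiles.append(FreeEnergyProfile(grid=grid, free_energy=fes - fes.min()))
    return profiles


def find_wells_and_barriers(fes: FreeEnergyProfile, prominence: float = 0.5):
    """Locate free-energy wells and the barriers between them.

    Wells are local minima with at least ``prominence`` kcal/mol of
    prominence (grid endpoints count when the profile rises away from them).
    Returns ``(wells, barriers)``: wells as a list of (location, depth) sorted
    by location, and barriers as a DataFrame where entry (i, j) is
    max F on the path from well i to well j minus F(well i).
    """
    f = fes.free_energy
    idx, _ = find_peaks(-f, prominence=prominence)
    # include boundary minima the peak finder cannot see
    for edge, inner in ((0, 1), (f.size - 1, f.size - 2)):
        if f[inner] > f[edge] and np.max(f) - f[edge] >= prominence:
            idx = np.append(idx, edge)
    idx = np.sort(np.unique(idx))
    wells = [(float(fes.grid[i]), float(f[i])) for i in idx]
    n = len(wells)
    barriers = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            lo, hi = sorted((idx[a], idx[b]))
            barriers[a, b] = float(np.max(f[lo : hi + 1]) - f[idx[a]])
    labels = [w[0] for w in wells]
    return wells, pd.DataFrame(barriers, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# I/O: HILLS-dialect text files and FES tables
# ---------------------------------------------------------------------------

def write_hills(path, hills: HillsRecord) -> None:
    """Write a whitespace-separated HILLS-dialect file.

    Header ``#! FIELDS time <cv> sigma_<cv> height biasf walker`` followed by
    one line per deposited Gaussian.
    """
    cv = hills.cv_label
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#! FIELDS time {cv} sigma_{cv} height biasf walker\n")
        for i in range(len(hills)):
            fh.write(
                f"{hills.time[i]:.6f} {hills.center[i]:.9f} {hills.sigma[i]:.9f} "
                f"{hills.height[i]:.9e} {hills.bias_factor:.6f} {int(hills.walker[i])}\n"
            )


def read_hills(path) -> HillsRecord:
    """Read a HILLS-dialect file written by :func:`write_hills`.

    Files without a walker column are accepted (all hills assigned walker 0).
    """
    cv_label = "cv1"
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "FIELDS" in line:
                    fields = line.split()
                    if "time" in fields:
                        cv_label = fields[fields.index("time") + 1]
                continue
            rows.append([float(v) for v in line.split()])
    if not rows:
        raise ValueError(f"no hills found in {path}")
    data = np.asarray(rows)
    has_walker = data.shape[1] >= 6
    return HillsRecord(
        time=data[:, 0],
        center=data[:, 1],
        sigma=data[:, 2],
        height=data[:, 3],
        walker=data[:, 5].astype(int) if has_walker else np.zeros(data.shape[0], dtype=int),
        bias_factor=float(data[0, 4]),
        cv_label=cv_label,
    )


def write_fes(path, fes: FreeEnergyProfile) -> None:
    """FES as a two-column CSV: cv_A, F_kcal_mol."""
    pd.DataFrame({"cv_A": fes.grid, "F_kcal_mol": fes.free_energy}).to_csv(path, index=False)


def read_fes(path) -> FreeEnergyProfile:
    df = pd.read_csv(path)
    return FreeEnergyProfile(
        grid=df["cv_A"].to_numpy(float), free_energy=df["F_kcal_mol"].to_numpy(float)
    )
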