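"""Analytic model potentials and overdamped Langevin dynamics on a 1D CV.

The collective variable (CV) here is a 1D displacement coordinate standing
in for the ligand RMSD from its docked pose: non-negative, with a bound
state at small values (a Gaussian well) and a repulsive half-harmonic wall
capping the unbound region.  Energies are expressed in units of kT at the
simulation temperature; the integrator is the overdamped (inertialess)
Euler--Maruyama scheme, which is sufficient because only the statistics of
the CV matter at this scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PotentialSpec",
    "DynParams",
    "Trajectory",
    "potential_energy",
    "potential_force",
    "step_langevin",
    "run_langevin",
    "rmsd",
    "write_colvar",
    "read_colvar",
]

_FORMS = ("gaussian_well", "double_well", "harmonic")


@dataclass(frozen=True)
class PotentialSpec:
    """A 1D model potential for the displacement CV.

    Parameters
    ----------
    form:
        One of ``gaussian_well`` (attractive Gaussian well plus an outer
        half-harmonic wall), ``double_well`` (two Gaussian wells plus wall)
        or ``harmonic``.
    depth:
        Well depth in kT (ignored for ``harmonic``).
    width:
        Gaussian well width (CV units); for ``harmonic`` this is
        reinterpreted so the spring constant is ``1/width**2`` kT per CV^2.
    wall_position:
        Onset of the half-harmonic repulsive wall (CV units).
    wall_stiffness:
        Wall spring constant, kT per CV^2.
    centers:
        Well center(s).  One value for ``gaussian_well``/``harmonic``, two
        for ``double_well``.
    """

    form: str = "gaussian_well"
    depth: float = 5.0
    width: float = 0.5
    wall_position: float = 3.0
    wall_stiffness: float = 50.0
    centers: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown potential form {self.form!r}; expected one of {_FORMS}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.wall_stiffness < 0:
            raise ValueError("wall_stiffness must be >= 0")
        if self.wall_position <= 0:
            raise ValueError("wall_position must be > 0")
        n_expected = 2 if self.form == "double_well" else 1
        if len(self.centers) != n_expected:
            raise ValueError(f"{self.form} requires {n_expected} center(s), got {len(self.centers)}")


@dataclass(frozen=True)
class DynParams:
    """Overdamped Langevin integration parameters (kT energy units)."""

    dt: float = 1e-3
    friction: float = 1.0
    kT: float = 1.0
    n_steps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")
        if self.kT <= 0:
            raise ValueError("kT must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class Trajectory:
    """Time series of the CV: strictly increasing times, equal lengths."""

    times: np.ndarray
    cv_values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cv_values = np.asarray(self.cv_values, dtype=float)
        if self.times.shape != self.cv_values.shape:
            raise ValueError("times and cv_values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def potential_energy(spec: PotentialSpec, s: float | np.ndarray) -> float | np.ndarray:
    """Evaluate U(s) in kT.

    For ``gaussian_well``: U(s) = -depth * exp(-(s-c)^2 / (2 width^2)) plus
    a half-harmonic wall ``0.5 * wall_stiffness * (s - wall_position)^2``
    for s beyond the wall.  ``double_well`` sums two such wells;
    ``harmonic`` is ``0.5 * k * (s - c)^2`` with ``k = 1/width^2``.
    """
    s = np.asarray(s, dtype=float)
    if spec.form == "harmonic":
        k = 1.0 / spec.width**2
        u = 0.5 * k * (s - spec.centers[0]) ** 2
    else:
        u = np.zeros_like(s)
        for c in spec.centers:
            u = u - spec.depth * np.exp(-((s - c) ** 2) / (2.0 * spec.width**2))
        excess = np.maximum(s - spec.wall_position, 0.0)
        u = u + 0.5 * spec.wall_stiffness * excess**2
    return float(u) if u.ndim == 0 else u


def potential_force(spec: PotentialSpec, s: float | np.ndarray) -> float | np.ndarray:
    """Analytic force F(s) = -dU/ds in kT per CV unit."""
    s = np.asarray(s, dtype=float)
    if spec.form == "harmonic":
        k = 1.0 / spec.width**2
        f = -k * (s - spec.centers[0])
    else:
        f = np.zeros_like(s)
        for c in spec.centers:
            # dU/ds of the well term is depth*(s-c)/width^2 * exp(...)
            f = f - spec.depth * (s - c) / spec.width**2 * np.exp(
                -((s - c) ** 2) / (2.0 * spec.width**2)
            )
        excess = np.maximum(s - spec.wall_position, 0.0)
        f = f - spec.wall_stiffness * excess
    return float(f) if f.ndim == 0 else f


def step_langevin(s: float, total_force: float, params: DynParams, noise: float) -> float:
    """One overdamped Euler--Maruyama update.

    s' = s + F*dt/friction + sqrt(2*kT*dt/friction) * noise,
    with ``noise`` a standard-normal draw.  Deterministic given its inputs.
    """
    if not (math.isfinite(total_force) and math.isfinite(noise) and math.isfinite(s)):
        raise ValueError("non-finite state, force or noise in Langevin step")
    drift = total_force * params.dt / params.friction
    amplitude = math.sqrt(2.0 * params.kT * params.dt / params.friction)
    return s + drift + amplitude * noise


def run_langevin(
    spec: PotentialSpec,
    params: DynParams,
    s0: float = 0.0,
    sample_stride: int = 1,
    reflect_at_zero: bool = True,
) -> Trajectory:
    """Propagate an unbiased trajectory; reflecting boundary at s=0 keeps the
    CV on the RMSD-like non-negative half-line."""
    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal(params.n_steps)
    s = float(s0)
    out_t, out_s = [0.0], [s]
    for i in range(params.n_steps):
        f = potential_force(spec, s)
        s = step_langevin(s, f, params, noise[i])
        if reflect_at_zero and s < 0.0:
            s = -s
        if (i + 1) % sample_stride == 0:
            out_t.append((i + 1) * params.dt)
            out_s.append(s)
    return Trajectory(np.array(out_t), np.array(out_s))


def rmsd(frame: np.ndarray, reference: np.ndarray) -> float:
    """Root mean squared displacement between two coordinate sets.

    No rotational/translational superposition is applied: this is the plain
    per-atom displacement RMSD, sqrt(mean_i |x_i - y_i|^2).  Coordinate sets
    must have identical shapes (n_atoms, n_dims) or (n_atoms,).
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape or frame.size == 0:
        raise ValueError(f"coordinate shapes differ or empty: {frame.shape} vs {reference.shape}")
    d = frame - reference
    if d.ndim == 1:
        d = d[:, None]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=-1))))


def write_colvar(traj: Trajectory, path) -> None:
    """Write a COLVAR-like two-column file with a '#! FIELDS time cv' header."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS time cv\n")
        for t, s in zip(traj.times, traj.cv_values):
            fh.write(f"{t:.9g} {s:.9g}\n")


def read_colvar(path) -> Trajectory:
    times, cvs = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#! FIELDS"):
            raise ValueError(f"{path}: missing '#! FIELDS' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            times.append(float(parts[0]))
            cvs.append(float(parts[1]))
    return Trajectory(np.array(times), np.array(cvs))
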