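"""Synthetic virtual-screen generator.

Builds a library of toy "ligands" whose pose stability is controlled by a
latent Gaussian-well depth — binders drawn from a deeper-well population
than non-binders — runs the full CTMD pipeline (well-tempered metadynamics
replicas on each ligand's potential, c(t) scoring) and returns a labeled
score table.  This emulates, at desk scale, a screening dataset of docked
poses with experimentally known binder/non-binder labels: the latent depth
plays the role of the (unknown) binding stability the method must recover.

Defaults describe a screen of 5 binders (depth 8 +/- 1 kT) against 27
non-binders (depth 2 +/- 1 kT), scored by 3 independent replicas of
5e5 steps with a hill deposited every 500 steps (1000 hills/replica).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ._kernels import wt_metad_gaussian_well
from .ct import Grid
from .enrichment import BINDER, NONBINDER, ScreenTable
from .metad import GAS_CONSTANT_KJ_PER_MOL_K, HillList, ThermoParams, deposit_hill, write_hills
from .scoring import LigandScore, ReplicaSet, ctmd_score
from .toy_dynamics import DynParams, PotentialSpec

__all__ = [
    "LigandSpec",
    "MetadParams",
    "gen_library",
    "run_wt_metad",
    "simulate_screen",
    "fast_hills_fixture",
    "default_grid",
]

#: default well-tempered hill height, kT: 1.2 kJ/mol at 300 K
DEFAULT_W0_KT = 1.2 / (GAS_CONSTANT_KJ_PER_MOL_K * 300.0)


@dataclass(frozen=True)
class MetadParams:
    """Hill deposition parameters (internal kT units).

    w0: initial hill height; sigma: hill width in CV units; pace: dynamics
    steps between depositions.
    """

    w0: float = DEFAULT_W0_KT
    sigma: float = 0.02
    pace: int = 500

    def __post_init__(self) -> None:
        if self.w0 < 0 or self.sigma <= 0 or self.pace < 1:
            raise ValueError("invalid metadynamics parameters")


@dataclass(frozen=True)
class LigandSpec:
    """One synthetic ligand: its label and latent well depth (kT)."""

    ligand_id: str
    true_label: str
    well_depth: float
    seed_base: int

    def __post_init__(self) -> None:
        if self.well_depth < 0:
            raise ValueError("well_depth must be >= 0")
        if self.true_label not in (BINDER, NONBINDER):
            raise ValueError(f"unknown label {self.true_label!r}")


def gen_library(
    n_binders: int = 5,
    n_nonbinders: int = 27,
    depth_binder_mean: float = 8.0,
    depth_nonbinder_mean: float = 2.0,
    depth_sd: float = 1.0,
    seed: int = 0,
) -> list[LigandSpec]:
    """Draw a ligand library with latent well depths.

    Depths come from normal distributions truncated at zero (a well depth
    cannot be negative); ``depth_sd = 0`` degenerates to exact means.
    Deterministic given ``seed``; per-ligand seed bases are drawn from the
    same stream so replica noise is independent across ligands.
    """
    if n_binders < 0 or n_nonbinders < 0:
        raise ValueError("counts must be >= 0")
    if depth_binder_mean < 0 or depth_nonbinder_mean < 0:
        raise ValueError("depth means must be >= 0")
    if depth_sd < 0:
        raise ValueError("depth_sd must be >= 0")
    rng = np.random.default_rng(seed)

    def draw(mean: float, n: int) -> np.ndarray:
        if depth_sd == 0:
            return np.full(n, mean)
        a = (0.0 - mean) / depth_sd  # truncate at zero
        return truncnorm.rvs(a, np.inf, loc=mean, scale=depth_sd, size=n, random_state=rng)

    specs: list[LigandSpec] = []
    for label, mean, n, prefix in (
        (BINDER, depth_binder_mean, n_binders, "B"),
        (NONBINDER, depth_nonbinder_mean, n_nonbinders, "N"),
    ):
        depths = draw(mean, n)
        for i in range(n):
            seed_base = int(rng.integers(0, 2**30))
            specs.append(LigandSpec(f"{prefix}{i + 1:03d}", label, float(depths[i]), seed_base))
    return specs


def default_grid(potential: PotentialSpec, metad: MetadParams, n_points: int = 1000) -> Grid:
    """Quadrature grid covering the accessible CV range: from the reflecting
    boundary at zero out past the wall (biased wall excursions reach ~0.6
    past the onset once the well region is filled, plus 3 hill sigmas)."""
    return Grid(0.0, potential.wall_position + 0.75 + 3.0 * metad.sigma, n_points)


def run_wt_metad(
    potential: PotentialSpec,
    dyn: DynParams,
    metad: MetadParams,
    thermo: ThermoParams,
    s0: float = 0.0,
    bias_grid_pad: float = 1.0,
) -> HillList:
    """One well-tempered metadynamics replica; returns the deposited hills.

    Only ``gaussian_well`` potentials are supported in the compiled path.
    """
    if potential.form != "gaussian_well":
        raise ValueError("the metadynamics simulator supports gaussian_well potentials")
    rng = np.random.default_rng(dyn.seed)
    noise = rng.standard_normal(dyn.n_steps)
    centers, heights, _ = wt_metad_gaussian_well(
        noise,
        dyn.dt,
        dyn.friction,
        dyn.kT,
        metad.pace,
        metad.w0,
        metad.sigma,
        thermo.gamma,
        potential.depth,
        potential.width,
        potential.centers[0],
        potential.wall_position,
        potential.wall_stiffness,
        s0,
        0.0,
        potential.wall_position + bias_grid_pad,
    )
    times = (np.arange(len(centers)) + 1) * metad.pace * dyn.dt
    sigmas = np.full(len(centers), metad.sigma)
    return HillList.from_arrays(times, centers, sigmas, heights, thermo)


def simulate_screen(
    library: list[LigandSpec],
    dyn: DynParams | None = None,
    metad: MetadParams | None = None,
    n_replicas: int = 3,
    grid: Grid | None = None,
    thermo: ThermoParams | None = None,
    out_dir: str | os.PathLike | None = None,
    potential_width: float = 0.5,
    wall_position: float = 3.0,
    wall_stiffness: float = 50.0,
) -> pd.DataFrame:
    """Run the full CTMD pipeline on a synthetic library.

    For each ligand, ``n_replicas`` independent well-tempered metadynamics
    runs are propagated on a Gaussian well of that ligand's latent depth
    (replica seeds = seed_base + replica index), the terminal c(t) of each
    replica is computed, and the CTMD score is their minimum.  If
    ``out_dir`` is given, one PLUMED-format HILLS file per replica is
    written under ``out_dir/<ligand_id>/HILLS.<replica>``.

    Returns a screen table (ligand_id, score, label) plus columns
    ``well_depth`` and per-replica terminal c(t) values.
    """
    if not library:
        raise ValueError("empty ligand library")
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    dyn = dyn if dyn is not None else DynParams(dt=1e-3, friction=1.0, kT=1.0, n_steps=500_000)
    metad = metad if metad is not None else MetadParams()
    thermo = thermo if thermo is not None else ThermoParams()
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        if not os.access(out_dir, os.W_OK):
            raise OSError(f"output directory not writable: {out_dir}")

    rows = []
    for lig in library:
        potential = PotentialSpec(
            form="gaussian_well",
            depth=lig.well_depth,
            width=potential_width,
            wall_position=wall_position,
            wall_stiffness=wall_stiffness,
        )
        g = grid if grid is not None else default_grid(potential, metad)
        replicas = []
        for r in range(n_replicas):
            rep_dyn = DynParams(dyn.dt, dyn.friction, dyn.kT, dyn.n_steps, lig.seed_base + r)
            hills = run_wt_metad(potential, rep_dyn, metad, thermo)
            replicas.append(hills)
            if out_dir is not None:
                lig_dir = os.path.join(out_dir, lig.ligand_id)
                os.makedirs(lig_dir, exist_ok=True)
                write_hills(hills, os.path.join(lig_dir, f"HILLS.{r}"))
        score: LigandScore = ctmd_score(ReplicaSet(lig.ligand_id, replicas), g, thermo)
        row = {
            "ligand_id": lig.ligand_id,
            "score": score.score,
            "label": lig.true_label,
            "well_depth": lig.well_depth,
        }
        for r, term in enumerate(score.per_replica_terminal_ct):
            row[f"ct_terminal_{r}"] = term
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        df.to_csv(os.path.join(out_dir, "screen.csv"), index=False)
    return df


def fast_hills_fixture(
    profile: str,
    n_hills: int,
    seed: int = 0,
    w0: float = DEFAULT_W0_KT,
    sigma: float = 0.05,
    thermo: ThermoParams | None = None,
    s_range: tuple[float, float] = (0.2, 2.8),
) -> HillList:
    """Hill lists mimicking the two pose-stability regimes, with no dynamics.

    ``stuck``: centers jitter narrowly around one point, piling tempered
    bias locally (high terminal c(t)).  ``escaping``: centers drift across
    the CV range, spreading the same hill budget thinly (lower terminal
    c(t)).  Heights follow the well-tempered rule exactly.  Fast enough for
    unit tests; deterministic given seed.
    """
    if profile not in ("stuck", "escaping"):
        raise ValueError(f"unknown profile {profile!r}")
    if n_hills < 0:
        raise ValueError("n_hills must be >= 0")
    thermo = thermo if thermo is not None else ThermoParams()
    rng = np.random.default_rng(seed)
    lo, hi = s_range
    if profile == "stuck":
        anchor = 0.5 * (lo + hi)
        centers = anchor + 0.5 * sigma * rng.standard_normal(n_hills)
    else:
        drift = np.linspace(lo, hi, n_hills) if n_hills else np.empty(0)
        centers = drift + 0.5 * sigma * rng.standard_normal(n_hills)
    centers = np.clip(centers, 0.0, None)

    hills = HillList([], thermo)
    for k in range(n_hills):
        hills = deposit_hill(hills, float(centers[k]), float(k + 1), w0, sigma, thermo)
    return hills
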