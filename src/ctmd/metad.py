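"""Well-tempered metadynamics bias construction and PLUMED HILLS file I/O.

The time-dependent bias V(s, t) is represented discretely as a list of
deposited Gaussian hills.  Under the well-tempered scheme each new hill is
scaled down by exp(-V(s,t)/((gamma-1) kT)) where gamma > 1 is the bias
factor, so the bias converges instead of growing without bound.

Internally all energies are in kT; HILLS files follow the PLUMED
convention of kJ/mol and are converted at the file boundary using the
temperature stored in :class:`ThermoParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAS_CONSTANT_KJ_PER_MOL_K",
    "Hill",
    "HillList",
    "ThermoParams",
    "HillsParseError",
    "wt_hill_height",
    "deposit_hill",
    "bias_value",
    "bias_force",
    "read_hills",
    "write_hills",
]

#: molar gas constant R in kJ/(mol K); kT at 300 K is 2.494 kJ/mol
GAS_CONSTANT_KJ_PER_MOL_K = 0.008314462618153241


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic context: inverse temperature beta (1/kT, internal units),
    well-tempered bias factor gamma, and the absolute temperature in kelvin
    used only for kJ/mol <-> kT conversion at file boundaries."""

    beta: float = 1.0
    gamma: float = 10.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.gamma <= 1:
            raise ValueError("gamma must be > 1 (well-tempered bias factor)")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kT_kj_per_mol(self) -> float:
        return GAS_CONSTANT_KJ_PER_MOL_K * self.temperature


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: height * exp(-(s-center)^2 / (2 sigma^2))."""

    time: float
    center: float
    sigma: float
    height: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.height < 0:
            raise ValueError("height must be >= 0")
        if self.time < 0:
            raise ValueError("time must be >= 0")


class HillList:
    """Time-ordered sequence of hills: the discrete representation of V(s,t).

    Supports vectorized bias evaluation; construction checks that times are
    non-decreasing.
    """

    def __init__(self, hills: list[Hill] | None = None, thermo: ThermoParams | None = None):
        hills = list(hills) if hills else []
        for a, b in zip(hills, hills[1:]):
            if b.time < a.time:
                raise ValueError("hill times must be non-decreasing")
        self.hills = hills
        self.thermo = thermo if thermo is not None else ThermoParams()

    def __len__(self) -> int:
        return len(self.hills)

    def __iter__(self):
        return iter(self.hills)

    def __getitem__(self, i):
        return self.hills[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([h.time for h in self.hills], dtype=float)

    @property
    def centers(self) -> np.ndarray:
        return np.array([h.center for h in self.hills], dtype=float)

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([h.sigma for h in self.hills], dtype=float)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h.height for h in self.hills], dtype=float)

    @classmethod
    def from_arrays(
        cls,
        times: np.ndarray,
        centers: np.ndarray,
        sigmas: np.ndarray,
        heights: np.ndarray,
        thermo: ThermoParams | None = None,
    ) -> "HillList":
        hills = [
            Hill(float(t), float(c), float(s), float(h))
            for t, c, s, h in zip(times, centers, sigmas, heights)
        ]
        return cls(hills, thermo)


def wt_hill_height(w0: float, current_bias_at_center: float, thermo: ThermoParams) -> float:
    """Well-tempered hill height: w = w0 * exp(-V / ((gamma - 1) kT)).

    ``current_bias_at_center`` is V(s,t) (kT) already accumulated at the
    deposition point; the height decays toward zero as bias builds up, and
    equals w0 when no bias is present.
    """
    if w0 < 0:
        raise ValueError("w0 must be >= 0")
    if current_bias_at_center < 0:
        raise ValueError("bias must be >= 0")
    kT = 1.0 / thermo.beta
    return w0 * math.exp(-current_bias_at_center / ((thermo.gamma - 1.0) * kT))


def deposit_hill(
    hills: HillList,
    s_now: float,
    t_now: float,
    w0: float,
    sigma: float,
    thermo: ThermoParams | None = None,
) -> HillList:
    """Append one well-tempered hill at the current CV value.

    The height is computed from the bias accumulated *before* this
    deposition, evaluated at ``s_now``.  Returns a new HillList.
    """
    thermo = thermo if thermo is not None else hills.thermo
    if hills.hills and t_now < hills.hills[-1].time:
        raise ValueError(
            f"out-of-order deposition: t={t_now} before last hill time {hills.hills[-1].time}"
        )
    v_here = bias_value(hills, s_now, t_now)
    h = wt_hill_height(w0, v_here, thermo)
    return HillList(hills.hills + [Hill(t_now, s_now, sigma, h)], thermo)


def bias_value(hills: HillList, s: float | np.ndarray, t: float = np.inf) -> float | np.ndarray:
    """V(s, t): sum of all Gaussian hills deposited at or before time t."""
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    v = np.zeros_like(s_arr)
    if len(hills):
        times = hills.times
        keep = times <= t
        if keep.any():
            c = hills.centers[keep]
            sg = hills.sigmas[keep]
            h = hills.heights[keep]
            # (n_points, n_hills) Gaussian matrix; fine at desk scale
            d = s_arr[:, None] - c[None, :]
            v = (h[None, :] * np.exp(-(d * d) / (2.0 * sg[None, :] ** 2))).sum(axis=1)
    return float(v[0]) if np.isscalar(s) or np.asarray(s).ndim == 0 else v


def bias_force(hills: HillList, s: float | np.ndarray, t: float = np.inf) -> float | np.ndarray:
    """-dV/ds of the accumulated bias at time t (kT per CV unit)."""
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    f = np.zeros_like(s_arr)
    if len(hills):
        keep = hills.times <= t
        if keep.any():
            c = hills.centers[keep]
            sg = hills.sigmas[keep]
            h = hills.heights[keep]
            d = s_arr[:, None] - c[None, :]
            f = (h[None, :] * d / sg[None, :] ** 2 * np.exp(-(d * d) / (2.0 * sg[None, :] ** 2))).sum(axis=1)
    return float(f[0]) if np.isscalar(s) or np.asarray(s).ndim == 0 else f


class HillsParseError(ValueError):
    """Raised for malformed HILLS files; message carries the line number."""


_HILLS_FIELDS = ["time", "cv", "sigma_cv", "height", "biasf"]


def write_hills(hills: HillList, path, cv_name: str = "cv") -> None:
    """Write a single-CV PLUMED-dialect HILLS file.

    Columns: ``time cv sigma_cv height biasf``; height is converted from
    internal kT to kJ/mol using the ThermoParams temperature, and the bias
    factor gamma is written in the last column.
    """
    kT_kj = hills.thermo.kT_kj_per_mol
    gamma = hills.thermo.gamma
    with open(path, "w") as fh:
        fh.write(f"#! FIELDS time {cv_name} sigma_{cv_name} height biasf\n")
        for h in hills:
            fh.write(
                f"{h.time:.10g} {h.center:.10g} {h.sigma:.10g} "
                f"{h.height * kT_kj:.10g} {gamma:.10g}\n"
            )


def read_hills(path, thermo: ThermoParams | None = None) -> HillList:
    """Read a PLUMED-dialect single-CV HILLS file into a HillList (kT units).

    The header must declare ``time <cv> sigma_<cv> height biasf``.  Heights
    (kJ/mol in the file) are converted to kT at ``thermo.temperature``.  If
    ``thermo`` is omitted, gamma is taken from the file's biasf column and
    T = 300 K is assumed.  A biasf column inconsistent with ``thermo.gamma``
    raises a parse error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#! FIELDS "):
            raise HillsParseError(f"{path}:1: missing '#! FIELDS' header")
        fields = header.split()[2:]
        if len(fields) != 5 or fields[0] != "time" or fields[3] != "height" or fields[4] != "biasf":
            raise HillsParseError(
                f"{path}:1: expected fields 'time <cv> sigma_<cv> height biasf', got {fields}"
            )
        cv_name = fields[1]
        if fields[2] != f"sigma_{cv_name}":
            raise HillsParseError(f"{path}:1: sigma field {fields[2]!r} does not match CV {cv_name!r}")

        rows = []
        file_gamma = None
        last_t = -math.inf
        for lineno, line in enumerate(fh, start=2):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 5:
                raise HillsParseError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            try:
                t, c, sg, h_kj, biasf = (float(x) for x in parts)
            except ValueError as exc:
                raise HillsParseError(f"{path}:{lineno}: non-numeric token ({exc})") from None
            if t < last_t:
                raise HillsParseError(f"{path}:{lineno}: non-monotone time {t} after {last_t}")
            last_t = t
            if file_gamma is None:
                file_gamma = biasf
            elif not math.isclose(biasf, file_gamma, rel_tol=1e-9):
                raise HillsParseError(f"{path}:{lineno}: inconsistent biasf column")
            rows.append((t, c, sg, h_kj))

        if thermo is None:
            gamma = file_gamma if file_gamma is not None else 10.0
            thermo = ThermoParams(beta=1.0, gamma=gamma, temperature=300.0)
        elif file_gamma is not None and not math.isclose(file_gamma, thermo.gamma, rel_tol=1e-6):
            raise HillsParseError(
                f"{path}: biasf column {file_gamma} disagrees with requested gamma {thermo.gamma}"
            )
        kT_kj = thermo.kT_kj_per_mol
        hills = [Hill(t, c, sg, h_kj / kT_kj) for t, c, sg, h_kj in rows]
        return HillList(hills, thermo)
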