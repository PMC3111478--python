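"""Mean-squared displacement and Einstein-relation diffusion coefficients.

MSD curves are averaged over molecules and over replica time origins (a new
origin every ``origin_stride`` ps, 50 ps by default); the diffusion
coefficient follows from an ordinary least-squares fit of msd(τ) over a lag
window via D = slope / (2·N_dim).  Lateral (2-D) variants project the
displacement on a coordinate plane.  Standard errors per species come from
the spread over copies of the same molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import D_A2_PER_PS_TO_1E5_CM2_PER_S
from .model import Topology, Trajectory

__all__ = [
    "MSDSeries",
    "DiffusionFit",
    "molecule_com_trajectory",
    "compute_msd",
    "fit_diffusion",
    "species_report",
]

AXIS_PLANES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


@dataclass
class MSDSeries:
    lags: np.ndarray  # ps, uniform grid starting at 0
    msd: np.ndarray  # Å²
    n_origins: np.ndarray  # replica origins averaged per lag
    n_dim: int

    def __post_init__(self) -> None:
        if self.msd[0] != 0.0:
            raise ValueError("msd(0) must be 0")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")


@dataclass
class DiffusionFit:
    D: float  # Å²/ps
    window: tuple[float, float]  # ps
    slope_se: float  # Å²/ps
    intercept: float  # Å²
    n_dim: int

    @property
    def D_se(self) -> float:
        return self.slope_se / (2 * self.n_dim)

    @property
    def D_1e5_cm2_s(self) -> float:
        """D in the conventional 10⁻⁵ cm²/s reporting unit."""
        return self.D * D_A2_PER_PS_TO_1E5_CM2_PER_S


def molecule_com_trajectory(traj: Trajectory, topology: Topology,
                            molecules=None) -> np.ndarray:
    """Center-of-mass paths (n_frames, n_molecules, 3) from unwrapped coords."""
    if molecules is None:
        molecules = list(range(topology.n_molecules))
    xyz = traj.unwrapped
    out = np.empty((traj.n_frames, len(molecules), 3))
    for j, m in enumerate(molecules):
        mol = topology.molecules[m]
        w = topology.masses[mol.atom_ids]
        out[:, j, :] = (
            xyz[:, mol.atom_ids, :] * w[None, :, None]
        ).sum(axis=1) / w.sum()
    return out


def msd_from_paths(paths: np.ndarray, dt: float, origin_stride: float = 50.0,
                   axes=(0, 1, 2), max_lag: float | None = None) -> MSDSeries:
    """Replica-averaged MSD of (n_frames, n_paths, 3) trajectories.

    Origins are placed at 0, stride, 2·stride, … ; each origin contributes
    displacements at every lag that fits in the remaining trajectory.
    """
    n_frames = paths.shape[0]
    # A 50 ps stride over 4 ps frames is not a whole number of frames; the
    # stride is rounded to the nearest frame count (minimum 1) rather than
    # rejected, since the conventional settings themselves do not divide.
    stride_frames = max(1, int(round(origin_stride / dt)))
    if max_lag is None:
        n_lags = n_frames
    else:
        n_lags = int(round(max_lag / dt)) + 1
        if n_lags > n_frames:
            raise ValueError(
                f"max lag {max_lag} ps exceeds trajectory length "
                f"{(n_frames - 1) * dt} ps"
            )
    axes = list(axes)
    p = np.ascontiguousarray(paths[:, :, axes])
    origins = np.arange(0, n_frames, stride_frames)
    msd = np.zeros(n_lags)
    n_origins = np.zeros(n_lags, dtype=np.int64)
    for lag in range(1, n_lags):
        o = origins[origins + lag < n_frames]
        if o.size == 0:
            break
        d = p[o + lag] - p[o]
        msd[lag] = np.mean(np.sum(d * d, axis=-1))
        n_origins[lag] = o.size
    n_origins[0] = origins.size
    return MSDSeries(
        lags=np.arange(n_lags) * dt, msd=msd, n_origins=n_origins,
        n_dim=len(axes),
    )


def compute_msd(traj: Trajectory, topology: Topology, molecules=None,
                origin_stride: float = 50.0, axes=(0, 1, 2),
                max_lag: float | None = None,
                use_com: bool = True) -> MSDSeries:
    """Replica-averaged MSD of molecule displacements.

    ``use_com=True`` (default) tracks the molecular center of mass;
    ``use_com=False`` averages the squared displacement over the atoms of
    each molecule instead.
    """
    if molecules is not None and len(molecules) == 0:
        raise ValueError("empty molecule selection")
    if use_com:
        paths = molecule_com_trajectory(traj, topology, molecules)
    else:
        if molecules is None:
            molecules = list(range(topology.n_molecules))
        ids = np.concatenate(
            [topology.molecules[m].atom_ids for m in molecules]
        )
        paths = traj.unwrapped[:, ids, :]
    return msd_from_paths(paths, traj.dt, origin_stride, axes, max_lag)


def fit_diffusion(msd: MSDSeries, window=(100.0, 2000.0)) -> DiffusionFit:
    """OLS fit of msd(τ) over the lag window; D = slope / (2·N_dim)."""
    lo, hi = window
    mask = (msd.lags >= lo) & (msd.lags <= hi) & (msd.n_origins > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"fit window [{lo}, {hi}] ps contains {int(mask.sum())} points; "
            "at least 3 required"
        )
    res = stats.linregress(msd.lags[mask], msd.msd[mask])
    return DiffusionFit(
        D=res.slope / (2 * msd.n_dim),
        window=(lo, hi),
        slope_se=res.stderr,
        intercept=res.intercept,
        n_dim=msd.n_dim,
    )


def species_report(traj: Trajectory, topology: Topology,
                   window=(100.0, 2000.0), origin_stride: float = 50.0,
                   max_lag: float | None = None,
                   kinds=("metabolite", "ion", "protein")) -> pd.DataFrame:
    """Per-species diffusion table with copy-based standard errors.

    For each species, D is fitted per copy and averaged; SE is the sample SD
    over copies divided by √n (absent for species represented once).
    Lateral D values are 2-D fits on the xy, xz and yz coordinate planes,
    averaged over copies, with their mean in ``D_lateral_mean``.
    """
    groups: dict[str, list[int]] = {}
    for i, mol in enumerate(topology.molecules):
        if mol.kind in kinds:
            groups.setdefault(mol.species, []).append(i)
    if not groups:
        raise ValueError("no molecules of the requested kinds")

    if max_lag is None:
        max_lag = min(window[1] * 1.25, (traj.n_frames - 1) * traj.dt)
    rows = []
    for species, mols in sorted(groups.items()):
        paths = molecule_com_trajectory(traj, topology, mols)
        D_copies = []
        lateral = {k: [] for k in AXIS_PLANES}
        for j in range(len(mols)):
            single = paths[:, j : j + 1, :]
            m3 = msd_from_paths(single, traj.dt, origin_stride,
                                max_lag=max_lag)
            D_copies.append(fit_diffusion(m3, window).D)
            for plane, ax in AXIS_PLANES.items():
                m2 = msd_from_paths(single, traj.dt, origin_stride, axes=ax,
                                    max_lag=max_lag)
                lateral[plane].append(fit_diffusion(m2, window).D)
        D_copies = np.asarray(D_copies)
        n = len(mols)
        se = float(D_copies.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        row = {
            "species": species,
            "n_copies": n,
            "D_A2_per_ps": float(D_copies.mean()),
            "D_se": se,
            "D_1e5_cm2_s": float(D_copies.mean()) * D_A2_PER_PS_TO_1E5_CM2_PER_S,
        }
        for plane in AXIS_PLANES:
            row[f"D_lateral_{plane}"] = float(np.mean(lateral[plane]))
        row["D_lateral_mean"] = float(
            np.mean([row[f"D_lateral_{p}"] for p in AXIS_PLANES])
        )
        rows.append(row)
    return pd.DataFrame(rows)


def windowed_diffusion(traj: Trajectory, topology: Topology, molecules,
                       block_length: float, window=(100.0, 2000.0),
                       origin_stride: float = 50.0) -> pd.DataFrame:
    """Diffusion re-fitted on successive sub-trajectories of given length (ps).

    Useful for checking the stationarity of D along a long trajectory.
    """
    block_frames = int(round(block_length / traj.dt))
    if block_frames < 3:
        raise ValueError("block length too short")
    paths = molecule_com_trajectory(traj, topology, molecules)
    rows = []
    for start in range(0, traj.n_frames - block_frames + 1, block_frames):
        sub = paths[start : start + block_frames]
        msd = msd_from_paths(sub, traj.dt, origin_stride)
        fit = fit_diffusion(msd, window)
        rows.append({
            "t_start_ps": start * traj.dt,
            "t_end_ps": (start + block_frames - 1) * traj.dt,
            "D_A2_per_ps": fit.D,
        })
    return pd.DataFrame(rows)
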