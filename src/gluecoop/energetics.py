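"""Pairwise nonbonded interaction energies between components of a complex.

The interaction energy (IntE) between two atom groups is the sum over all
inter-group atom pairs of an electrostatic and a Lennard-Jones 12-6 term:

    E_elec(r) = 332.0636 * q_i * q_j / (eps(r) * r)
    E_vdw(r)  = eps_ij * [ (rmin_ij / r)^12 - 2 (rmin_ij / r)^6 ]

with CHARMM-style combining (eps_ij geometric, rmin_ij = rmin_half_i +
rmin_half_j).  The default screening is the distance-dependent dielectric
eps(r) = 2r, making the Coulomb term decay as r^-2 — a common implicit
compensation for missing solvent; a constant eps = 2 mode is available for
sensitivity checks.  Only inter-component pairs (A-L, L-B, A-B) are ever
evaluated, so bonded 1-2/1-3/1-4 exclusions never arise.

Energies over a conformational ensemble are reported as mean +/- sample
standard deviation across frames, and can be decomposed residue-by-residue
on the partner protein (the "glueability" footprint): per-frame residue
contributions are an exact partition of the group total.

Also provided: Shrake-Rupley solvent-accessible surface area and the
nonpolar solvation estimate G_np = gamma * SASA with gamma = 0.0072
kcal/(mol A^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .constants import COULOMB_CONSTANT, DEFAULT_PROBE_RADIUS, NONPOLAR_GAMMA

__all__ = [
    "AtomRecord",
    "ParameterizedComplex",
    "Ensemble",
    "PairEnergies",
    "InteractionEnergyReport",
    "DielectricMode",
    "pair_nonbonded_energy",
    "group_interaction_energy",
    "residue_level_profile",
    "trajectory_statistics",
    "sasa",
    "nonpolar_solvation",
]

COMPONENTS = ("A", "L", "B")
PAIRS = ("AL", "LB", "AB")

DielectricMode = Literal["2r", "const2"]


@dataclass(frozen=True)
class AtomRecord:
    """One parameterized atom: identity, coordinates and nonbonded parameters."""

    atom_id: int
    atom_name: str
    residue_index: int
    residue_name: str
    component_label: str
    coordinates: tuple[float, float, float]
    partial_charge: float
    lj_epsilon: float
    lj_rmin_half: float
    mass: float
    vdw_radius_for_sasa: float = 1.7

    def __post_init__(self):
        if self.component_label not in COMPONENTS:
            raise ValueError(
                f"component_label must be one of {COMPONENTS}, got "
                f"{self.component_label!r}"
            )
        if not all(math.isfinite(c) for c in self.coordinates):
            raise ValueError(f"atom {self.atom_id}: non-finite coordinates")
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.atom_id}: lj_epsilon must be >= 0")
        if self.lj_epsilon > 0 and self.lj_rmin_half <= 0:
            raise ValueError(
                f"atom {self.atom_id}: lj_rmin_half must be > 0 when lj_epsilon > 0"
            )


class ParameterizedComplex:
    """An ordered collection of atoms partitioned into components A, L, B.

    Parameters are stored as flat numpy arrays for vectorized energy
    evaluation; :attr:`atoms` retains the per-atom records.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        if not atoms:
            raise ValueError("complex must contain at least one atom")
        self.atoms = list(atoms)
        self.coordinates = np.array([a.coordinates for a in self.atoms], dtype=float)
        self.charges = np.array([a.partial_charge for a in self.atoms])
        self.lj_epsilon = np.array([a.lj_epsilon for a in self.atoms])
        self.lj_rmin_half = np.array([a.lj_rmin_half for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms])
        self.sasa_radii = np.array([a.vdw_radius_for_sasa for a in self.atoms])
        self.component_index: dict[str, np.ndarray] = {
            c: np.array([i for i, a in enumerate(self.atoms) if a.component_label == c],
                        dtype=int)
            for c in COMPONENTS
        }

    def __len__(self) -> int:
        return len(self.atoms)

    def group(self, label: str) -> np.ndarray:
        """Atom indices of one component (A, L or B)."""
        if label not in COMPONENTS:
            raise ValueError(f"unknown component {label!r}")
        return self.component_index[label]

    def residues_of(self, label: str) -> list[tuple[int, str]]:
        """Ordered unique (residue_index, residue_name) of one component."""
        seen: dict[int, str] = {}
        for i in self.group(label):
            a = self.atoms[i]
            seen.setdefault(a.residue_index, a.residue_name)
        return sorted(seen.items())

    def component_mass(self, label: str) -> float:
        return float(self.masses[self.group(label)].sum())


class Ensemble:
    """A reference complex plus frames of alternative coordinates.

    Every frame must carry the same atom count and ordering as the reference
    complex; frame 0 need not equal the reference coordinates.
    """

    def __init__(self, complex_: ParameterizedComplex, frames: np.ndarray):
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3 or frames.shape[1:] != (len(complex_), 3):
            raise ValueError(
                f"frames must have shape (n_frames, {len(complex_)}, 3), "
                f"got {frames.shape}"
            )
        if not np.all(np.isfinite(frames)):
            raise ValueError("frames contain non-finite coordinates")
        self.complex = complex_
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @classmethod
    def single_frame(cls, complex_: ParameterizedComplex) -> "Ensemble":
        return cls(complex_, complex_.coordinates[None])


@dataclass(frozen=True)
class PairEnergies:
    """Electrostatic and van der Waals energy of one atom pair, kcal/mol."""

    elec: float
    vdw: float

    @property
    def total(self) -> float:
        return self.elec + self.vdw


@dataclass(frozen=True)
class TrajectoryStats:
    """Mean and sample (n-1) standard deviation of a per-frame series."""

    mean: float
    sample_std: float
    n_frames: int

    @property
    def std_error(self) -> float:
        """Standard error of the mean (0 for a single frame)."""
        if self.n_frames < 2:
            return 0.0
        return self.sample_std / math.sqrt(self.n_frames)


@dataclass(frozen=True)
class InteractionEnergyReport:
    """Ensemble IntE between two components, with optional residue table.

    ``per_frame`` columns: elec, vdw, total (kcal/mol, one row per frame).
    ``residue_table`` (when requested) columns: residue_index, residue_name,
    elec_mean, elec_std, vdw_mean, vdw_std, total_mean, total_std.
    """

    pair: str
    per_frame: pd.DataFrame
    elec: TrajectoryStats
    vdw: TrajectoryStats
    total: TrajectoryStats
    residue_table: pd.DataFrame | None = None


def _dielectric_denominator(r: np.ndarray, mode: DielectricMode) -> np.ndarray:
    """eps(r) * r for the Coulomb denominator."""
    if mode == "2r":
        return 2.0 * r * r
    if mode == "const2":
        return 2.0 * r
    raise ValueError(f"unknown dielectric mode {mode!r}; use '2r' or 'const2'")


def pair_nonbonded_energy(
    atom_i: AtomRecord,
    atom_j: AtomRecord,
    dielectric: DielectricMode = "2r",
    r: float | None = None,
) -> PairEnergies:
    """Nonbonded energy of a single atom pair at distance ``r``.

    If ``r`` is omitted it is taken from the atoms' coordinates.  Raises for
    overlapping atoms (r = 0).
    """
    if r is None:
        d = np.subtract(atom_i.coordinates, atom_j.coordinates)
        r = float(np.sqrt(np.dot(d, d)))
    if r <= 0:
        raise ValueError("atoms overlap (r = 0); pair energy undefined")
    elec = COULOMB_CONSTANT * atom_i.partial_charge * atom_j.partial_charge / (
        float(_dielectric_denominator(np.array(r), dielectric))
    )
    eps_ij = math.sqrt(atom_i.lj_epsilon * atom_j.lj_epsilon)
    if eps_ij > 0:
        rmin_ij = atom_i.lj_rmin_half + atom_j.lj_rmin_half
        q = (rmin_ij / r) ** 6
        vdw = eps_ij * (q * q - 2.0 * q)
    else:
        vdw = 0.0
    return PairEnergies(elec=elec, vdw=vdw)


def _group_energy_arrays(
    coords: np.ndarray,
    complex_: ParameterizedComplex,
    idx_x: np.ndarray,
    idx_y: np.ndarray,
    dielectric: DielectricMode,
    cutoff: float | None,
):
    """Per-pair elec/vdw matrices between two index sets (vectorized)."""
    diff = coords[idx_x][:, None, :] - coords[idx_y][None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    if np.any(r <= 0):
        raise ValueError("overlapping atoms between groups (r = 0)")
    qq = np.outer(complex_.charges[idx_x], complex_.charges[idx_y])
    elec = COULOMB_CONSTANT * qq / _dielectric_denominator(r, dielectric)
    eps = np.sqrt(np.outer(complex_.lj_epsilon[idx_x], complex_.lj_epsilon[idx_y]))
    rmin = complex_.lj_rmin_half[idx_x][:, None] + complex_.lj_rmin_half[idx_y][None, :]
    with np.errstate(divide="ignore"):
        q6 = np.where(eps > 0, (rmin / r) ** 6, 0.0)
    vdw = eps * (q6 * q6 - 2.0 * q6)
    if cutoff is not None:
        mask = r <= cutoff
        elec = elec * mask
        vdw = vdw * mask
    return elec, vdw


def _pair_groups(complex_: ParameterizedComplex, pair: str) -> tuple[np.ndarray, np.ndarray]:
    if pair not in PAIRS:
        raise ValueError(f"pair must be one of {PAIRS}, got {pair!r}")
    gx, gy = complex_.group(pair[0]), complex_.group(pair[1])
    if len(gx) == 0 or len(gy) == 0:
        raise ValueError(f"pair {pair}: component {pair[0] if len(gx)==0 else pair[1]} is empty")
    return gx, gy


def group_interaction_energy(
    frame: np.ndarray,
    complex_: ParameterizedComplex,
    pair: str,
    dielectric: DielectricMode = "2r",
    cutoff: float | None = None,
) -> tuple[float, float, float]:
    """(elec, vdw, total) between two components for one coordinate frame.

    Sums every inter-group atom pair; no distance cutoff unless given.
    """
    idx_x, idx_y = _pair_groups(complex_, pair)
    elec, vdw = _group_energy_arrays(
        np.asarray(frame, dtype=float), complex_, idx_x, idx_y, dielectric, cutoff
    )
    e, v = float(elec.sum()), float(vdw.sum())
    return e, v, e + v


def trajectory_statistics(series: Iterable[float]) -> TrajectoryStats:
    """Mean and sample standard deviation (n-1; zero when n = 1) of a series."""
    values = np.asarray(list(series), dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    if values.size == 1:
        return TrajectoryStats(mean=float(values[0]), sample_std=0.0, n_frames=1)
    return TrajectoryStats(
        mean=float(values.mean()),
        sample_std=float(values.std(ddof=1)),
        n_frames=int(values.size),
    )


def ensemble_interaction_energy(
    ensemble: Ensemble,
    pair: str,
    dielectric: DielectricMode = "2r",
    cutoff: float | None = None,
    with_residue_profile: bool = False,
    partner: str | None = None,
) -> InteractionEnergyReport:
    """IntE between two components averaged over an ensemble.

    With ``with_residue_profile`` the energy is additionally decomposed over
    the residues of ``partner`` (default: the second component of the pair).
    """
    cx = ensemble.complex
    idx_x, idx_y = _pair_groups(cx, pair)
    rows = []
    residue_frames: dict[tuple[int, str], list[np.ndarray]] = {}
    if with_residue_profile:
        partner = partner or pair[1]
        if partner not in pair:
            raise ValueError(f"partner {partner!r} is not part of pair {pair!r}")
        part_idx = idx_x if partner == pair[0] else idx_y
        axis = 0 if partner == pair[0] else 1
        res_ids = np.array([cx.atoms[i].residue_index for i in part_idx])
        residues = cx.residues_of(partner)
    per_res_elec, per_res_vdw = [], []
    for frame in ensemble.frames:
        elec, vdw = _group_energy_arrays(frame, cx, idx_x, idx_y, dielectric, cutoff)
        rows.append((elec.sum(), vdw.sum()))
        if with_residue_profile:
            e_atom = elec.sum(axis=1 - axis)
            v_atom = vdw.sum(axis=1 - axis)
            per_res_elec.append(
                [e_atom[res_ids == ri].sum() for ri, _ in residues]
            )
            per_res_vdw.append(
                [v_atom[res_ids == ri].sum() for ri, _ in residues]
            )
    per_frame = pd.DataFrame(rows, columns=["elec", "vdw"])
    per_frame["total"] = per_frame["elec"] + per_frame["vdw"]

    residue_table = None
    if with_residue_profile:
        e_arr = np.array(per_res_elec)
        v_arr = np.array(per_res_vdw)
        t_arr = e_arr + v_arr
        ddof = 1 if ensemble.n_frames > 1 else 0
        residue_table = pd.DataFrame(
            {
                "residue_index": [ri for ri, _ in residues],
                "residue_name": [rn for _, rn in residues],
                "elec_mean": e_arr.mean(axis=0),
                "elec_std": e_arr.std(axis=0, ddof=ddof),
                "vdw_mean": v_arr.mean(axis=0),
                "vdw_std": v_arr.std(axis=0, ddof=ddof),
                "total_mean": t_arr.mean(axis=0),
                "total_std": t_arr.std(axis=0, ddof=ddof),
            }
        )
    return InteractionEnergyReport(
        pair=pair,
        per_frame=per_frame,
        elec=trajectory_statistics(per_frame["elec"]),
        vdw=trajectory_statistics(per_frame["vdw"]),
        total=trajectory_statistics(per_frame["total"]),
        residue_table=residue_table,
    )


def residue_level_profile(
    ensemble: Ensemble,
    ligand_group: str,
    partner_group: str,
    dielectric: DielectricMode = "2r",
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Per-residue footprint of the partner's interaction with the ligand.

    For every residue of ``partner_group``: mean +/- sample std over frames
    of its summed IntE with ``ligand_group``.  Per-frame residue
    contributions sum exactly to the per-frame group total.
    """
    pair = "".join(sorted((ligand_group, partner_group),
                          key=lambda c: COMPONENTS.index(c)))
    report = ensemble_interaction_energy(
        ensemble, pair, dielectric=dielectric, cutoff=cutoff,
        with_residue_profile=True, partner=partner_group,
    )
    return report.residue_table


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Coordinates re-expressed in a molecule-fixed principal-axes frame.

    Centering on the centroid and aligning to the (sign-fixed, right-handed)
    principal axes makes the sphere-point lattice co-rotate with the
    molecule, so the computed SASA is invariant under rigid-body transforms
    of the input.
    """
    centered = coords - coords.mean(axis=0)
    if len(coords) < 2:
        return centered
    cov = centered.T @ centered
    _w, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # largest variance first
    # fix each axis sign by its largest-magnitude component
    for k in range(3):
        j = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return centered @ vecs


def _sphere_points(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(
    complex_: ParameterizedComplex,
    group: str | Sequence[int] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = 960,
    coordinates: np.ndarray | None = None,
) -> float:
    """Shrake-Rupley solvent-accessible surface area, Angstrom^2.

    Test points are placed on each atom's solvent-expanded sphere
    (radius + probe) and counted as accessible unless strictly inside
    another atom's expanded sphere.  Exactly coincident identical atoms are
    de-duplicated (the shared surface is counted once).  ``group`` restricts
    the reported area to a component or an index set, while all atoms still
    occlude.
    """
    if n_sphere_points < 100:
        raise ValueError("n_sphere_points must be >= 100 for a meaningful area")
    coords = complex_.coordinates if coordinates is None else np.asarray(coordinates, float)
    coords = _canonical_frame(coords)
    radii = complex_.sasa_radii
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = [complex_.atoms[i].atom_id for i in np.nonzero(~(radii > 0))[0]]
        raise ValueError(f"missing/invalid SASA radius for atoms {bad}")
    expanded = radii + probe_radius
    n = len(complex_)
    if group is None:
        report = np.arange(n)
    elif isinstance(group, str):
        report = complex_.group(group)
    else:
        report = np.asarray(group, dtype=int)

    # De-duplicate exactly coincident identical atoms: later copy gets 0 area
    # and is removed from the occluder set.
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        same = (
            (np.linalg.norm(coords - coords[i], axis=1) < 1e-9)
            & (np.abs(expanded - expanded[i]) < 1e-9)
        )
        same[: i + 1] = False
        keep[same] = False

    unit = _sphere_points(n_sphere_points)
    total = 0.0
    occluders = np.nonzero(keep)[0]
    for i in report:
        if not keep[i]:
            continue
        pts = coords[i] + expanded[i] * unit
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in occluders:
            if j == i:
                continue
            dij = np.linalg.norm(coords[j] - coords[i])
            if dij >= expanded[i] + expanded[j]:
                continue
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= expanded[j] - 1e-12
        total += accessible.sum() / n_sphere_points * 4.0 * math.pi * expanded[i] ** 2
    return float(total)


def nonpolar_solvation(sasa_value: float, gamma: float = NONPOLAR_GAMMA) -> float:
    """Nonpolar solvation free energy G_np = gamma * SASA, kcal/mol."""
    if sasa_value < 0:
        raise ValueError("SASA must be nonnegative")
    return gamma * sasa_value
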