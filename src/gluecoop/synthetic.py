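"""Synthetic fixtures: binding scenarios and toy bead complexes.

Everything downstream (equilibrium solving, energy decomposition, the
cooperativity-effect screen) is exercisable on data generated here, with
ground truth known by construction:

* ``random_binding_scenario`` draws five dissociation constants and derives
  the sixth from thermodynamic cycle closure, so closure is exact to
  rounding; an optional alpha_1 target plants a known cooperativity.
* ``make_toy_ternary_system`` builds a three-cluster bead complex (chains
  A / L / B) with random charges and Lennard-Jones parameters, optionally a
  planted salt-bridge pair across a chosen interface, and records
  ground-truth pair energies computed by an independent scalar loop (plain
  ``math``, no shared code with the vectorized engine).
* ``plant_cooperativity_scenario`` derives ternary and dual ensembles from
  one toy system, tightening (or loosening) inter-component contacts by a
  stated factor, and returns the closed-form expected interaction-energy
  changes.

All generators are pure functions of their integer seed.

Default study conditions: dissociation constants log-uniform in
1e-9..1e-4 M (the nanomolar-to-hundred-micromolar range typical of
glue-mediated ternary systems), component totals around 1e-6 M (recruitment
assay scale), bead ensembles of 50 frames with 0.1 A coordinate noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_CONSTANT
from .energetics import AtomRecord, Ensemble, ParameterizedComplex
from .equilibrium import Totals
from .thermo import BindingConstants, RateConstants

__all__ = [
    "ScenarioSpec",
    "ToyComplexSpec",
    "GroundTruthEnergies",
    "random_binding_scenario",
    "make_toy_ternary_system",
    "sample_ensemble",
    "plant_cooperativity_scenario",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a random thermodynamically consistent binding scenario."""

    seed: int
    kd_lo: float = 1e-9
    kd_hi: float = 1e-4
    alpha1_target: float | None = None
    total_lo: float = 5e-7
    total_hi: float = 2e-6
    on_rate_lo: float = 1e5
    on_rate_hi: float = 1e7

    def __post_init__(self):
        for lo, hi, name in [
            (self.kd_lo, self.kd_hi, "kd"),
            (self.total_lo, self.total_hi, "total"),
            (self.on_rate_lo, self.on_rate_hi, "on_rate"),
        ]:
            if not (0 < lo < hi):
                raise ValueError(f"{name} bounds must satisfy 0 < lo < hi")
        if self.alpha1_target is not None and self.alpha1_target <= 0:
            raise ValueError("alpha1_target must be positive")


def _log_uniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size))


def random_binding_scenario(
    spec: ScenarioSpec,
) -> tuple[RateConstants, BindingConstants, Totals]:
    """A closure-exact scenario: five Kd's drawn, the sixth derived.

    kd_A_L, kd_L_B, kd_A_B and kd_AL_B are drawn log-uniform (kd_AL_B is
    instead set to kd_L_B / alpha1_target when a target is given); kd_LB_A
    and kd_AB_L follow from cycle closure, making all three path products
    identical up to rounding.  On-rates are drawn log-uniform and off-rates
    set to Kd * on-rate, so kds_from_rates reproduces the constants.
    """
    rng = np.random.default_rng(spec.seed)
    kd_a_l, kd_l_b, kd_a_b = _log_uniform(rng, spec.kd_lo, spec.kd_hi, 3)
    if spec.alpha1_target is None:
        kd_al_b = float(_log_uniform(rng, spec.kd_lo, spec.kd_hi))
    else:
        kd_al_b = kd_l_b / spec.alpha1_target
        if not (spec.kd_lo / 1e6 <= kd_al_b <= spec.kd_hi * 1e6):
            raise ValueError(
                f"alpha1 target {spec.alpha1_target} puts kd_AL_B={kd_al_b:g} M "
                "far outside the scenario bounds"
            )
    product = kd_a_l * kd_al_b  # [A][L][B]/[ALB] along the AL path
    constants = BindingConstants(
        kd_A_L=float(kd_a_l),
        kd_L_B=float(kd_l_b),
        kd_A_B=float(kd_a_b),
        kd_AL_B=float(kd_al_b),
        kd_LB_A=float(product / kd_l_b),
        kd_AB_L=float(product / kd_a_b),
    )
    ons = _log_uniform(rng, spec.on_rate_lo, spec.on_rate_hi, 6)
    kds = [constants.kd_A_L, constants.kd_L_B, constants.kd_A_B,
           constants.kd_AL_B, constants.kd_LB_A, constants.kd_AB_L]
    offs = [kd * on for kd, on in zip(kds, ons)]
    rates = RateConstants(
        v1_on=ons[0], v1_off=offs[0],
        u1_on=ons[1], u1_off=offs[1],
        r1_on=ons[2], r1_off=offs[2],
        v2_on=ons[3], v2_off=offs[3],
        u2_on=ons[4], u2_off=offs[4],
        r2_on=ons[5], r2_off=offs[5],
    )
    totals = Totals(*(float(v) for v in _log_uniform(rng, spec.total_lo, spec.total_hi, 3)))
    return rates, constants, totals


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of a toy three-cluster bead complex.

    Beads of A sit around the origin, L at ``interface_gap`` along +x, B a
    further gap beyond, so each inter-component interface has a controlled
    separation.  ``salt_bridge`` optionally plants a +1/-1 charge pair at a
    fixed distance across one interface ("AL", "LB" or "AB").
    """

    seed: int
    n_atoms_A: int = 20
    n_atoms_L: int = 8
    n_atoms_B: int = 20
    cluster_radius: float = 2.0
    interface_gap: float = 10.0
    charge_scale: float = 0.2
    lj_eps_range: tuple[float, float] = (0.05, 0.2)
    lj_rmin_half_range: tuple[float, float] = (1.0, 1.5)
    salt_bridge: str | None = None
    salt_bridge_distance: float = 6.0
    n_residues_A: int = 5
    n_residues_B: int = 5

    def __post_init__(self):
        if min(self.n_atoms_A, self.n_atoms_L, self.n_atoms_B) < 1:
            raise ValueError("atom counts must be >= 1")
        if self.salt_bridge is not None and self.salt_bridge not in ("AL", "LB", "AB"):
            raise ValueError("salt_bridge must be one of 'AL', 'LB', 'AB'")


@dataclass(frozen=True)
class GroundTruthEnergies:
    """Independently computed pair energies of a toy complex (kcal/mol)."""

    pair_totals: dict  # pair -> (elec, vdw)
    per_residue: dict  # (pair, partner) -> {residue_index: (elec, vdw)}


def _scalar_pair_energy(qi, qj, epsi, epsj, rhi, rhj, r, dielectric="2r"):
    """Reference scalar nonbonded energy; deliberately independent of the
    vectorized engine (pure ``math``)."""
    if dielectric == "2r":
        elec = COULOMB_CONSTANT * qi * qj / (2.0 * r * r)
    else:
        elec = COULOMB_CONSTANT * qi * qj / (2.0 * r)
    eps = math.sqrt(epsi * epsj)
    if eps > 0:
        rmin = rhi + rhj
        s6 = (rmin / r) ** 6
        vdw = eps * (s6 * s6 - 2.0 * s6)
    else:
        vdw = 0.0
    return elec, vdw


def reference_group_energies(
    complex_: ParameterizedComplex,
    coordinates: np.ndarray | None = None,
    dielectric: str = "2r",
) -> GroundTruthEnergies:
    """Brute-force O(N^2) scalar-loop energies for every component pair.

    This is the oracle the vectorized engine is validated against; it shares
    no code with :mod:`gluecoop.energetics`.
    """
    coords = complex_.coordinates if coordinates is None else np.asarray(coordinates)
    pair_totals = {}
    per_residue = {}
    for pair in ("AL", "LB", "AB"):
        gi = complex_.group(pair[0])
        gj = complex_.group(pair[1])
        tot_e = tot_v = 0.0
        res_i: dict[int, list] = {}
        res_j: dict[int, list] = {}
        for i in gi:
            ai = complex_.atoms[i]
            for j in gj:
                aj = complex_.atoms[j]
                dx = coords[i][0] - coords[j][0]
                dy = coords[i][1] - coords[j][1]
                dz = coords[i][2] - coords[j][2]
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                e, v = _scalar_pair_energy(
                    ai.partial_charge, aj.partial_charge,
                    ai.lj_epsilon, aj.lj_epsilon,
                    ai.lj_rmin_half, aj.lj_rmin_half, r, dielectric,
                )
                tot_e += e
                tot_v += v
                acc_i = res_i.setdefault(ai.residue_index, [0.0, 0.0])
                acc_i[0] += e
                acc_i[1] += v
                acc_j = res_j.setdefault(aj.residue_index, [0.0, 0.0])
                acc_j[0] += e
                acc_j[1] += v
        pair_totals[pair] = (tot_e, tot_v)
        per_residue[(pair, pair[0])] = {k: tuple(v) for k, v in res_i.items()}
        per_residue[(pair, pair[1])] = {k: tuple(v) for k, v in res_j.items()}
    return GroundTruthEnergies(pair_totals=pair_totals, per_residue=per_residue)


def _place_cluster(rng, n, center, radius, min_sep=0.5, max_attempts=100):
    """Random beads in a ball, rejecting overlaps closer than ``min_sep``."""
    pts = []
    for _ in range(n):
        for _attempt in range(max_attempts):
            u = rng.normal(size=3)
            u *= radius * rng.random() ** (1 / 3) / np.linalg.norm(u)
            p = np.asarray(center) + u
            if all(np.linalg.norm(p - q) >= min_sep for q in pts):
                pts.append(p)
                break
        else:
            raise RuntimeError("could not place non-overlapping beads")
    return np.array(pts)


def make_toy_ternary_system(
    spec: ToyComplexSpec,
) -> tuple[ParameterizedComplex, GroundTruthEnergies]:
    """Deterministic toy bead complex plus its ground-truth energies."""
    rng = np.random.default_rng(spec.seed)
    gap = spec.interface_gap
    centers = {"A": np.zeros(3), "L": np.array([gap, 0.0, 0.0]),
               "B": np.array([2.0 * gap, 0.0, 0.0])}
    counts = {"A": spec.n_atoms_A, "L": spec.n_atoms_L, "B": spec.n_atoms_B}
    n_res = {"A": min(spec.n_residues_A, spec.n_atoms_A), "L": 1,
             "B": min(spec.n_residues_B, spec.n_atoms_B)}

    atoms = []
    serial = 1
    res_offset = 0
    index_of: dict[str, list[int]] = {c: [] for c in "ALB"}
    for comp in ("A", "L", "B"):
        coords = _place_cluster(rng, counts[comp], centers[comp], spec.cluster_radius)
        charges = rng.uniform(-spec.charge_scale, spec.charge_scale, counts[comp])
        charges -= charges.mean()  # keep each component neutral overall
        eps = rng.uniform(*spec.lj_eps_range, counts[comp])
        rmh = rng.uniform(*spec.lj_rmin_half_range, counts[comp])
        for k in range(counts[comp]):
            res_idx = res_offset + 1 + (k * n_res[comp]) // counts[comp]
            atoms.append(
                AtomRecord(
                    atom_id=serial,
                    atom_name=f"{comp}{k + 1}",
                    residue_index=res_idx,
                    residue_name="BEA",
                    component_label=comp,
                    coordinates=tuple(coords[k]),
                    partial_charge=float(charges[k]),
                    lj_epsilon=float(eps[k]),
                    lj_rmin_half=float(rmh[k]),
                    mass=12.011,
                    vdw_radius_for_sasa=1.7,
                )
            )
            index_of[comp].append(serial - 1)
            serial += 1
        res_offset += n_res[comp]

    if spec.salt_bridge is not None:
        ci, cj = spec.salt_bridge[0], spec.salt_bridge[1]
        # move one bead of each partner to the interface midline, +1/-1 charge
        i = index_of[ci][0]
        j = index_of[cj][0]
        mid = 0.5 * (centers[ci] + centers[cj])
        half = 0.5 * spec.salt_bridge_distance
        direction = centers[cj] - centers[ci]
        direction = direction / np.linalg.norm(direction)
        atoms[i] = _replace_atom(atoms[i], coordinates=tuple(mid - half * direction),
                                 partial_charge=1.0)
        atoms[j] = _replace_atom(atoms[j], coordinates=tuple(mid + half * direction),
                                 partial_charge=-1.0)

    cx = ParameterizedComplex(atoms)
    return cx, reference_group_energies(cx)


def _replace_atom(atom: AtomRecord, **changes) -> AtomRecord:
    from dataclasses import replace

    return replace(atom, **changes)


def sample_ensemble(
    complex_: ParameterizedComplex,
    n_frames: int,
    sigma: float,
    seed: int,
    base_coordinates: np.ndarray | None = None,
) -> Ensemble:
    """Frames = reference coordinates + i.i.d. Gaussian noise of scale sigma (A)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    base = complex_.coordinates if base_coordinates is None else np.asarray(base_coordinates)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(n_frames,) + base.shape) if sigma > 0 else 0.0
    frames = np.broadcast_to(base, (n_frames,) + base.shape) + noise
    return Ensemble(complex_, np.array(frames, dtype=float))


@dataclass(frozen=True)
class PlantedCEScenario:
    """Ternary + dual ensembles with analytically known energy changes."""

    complex: ParameterizedComplex
    ternary: Ensemble
    dual_AL: Ensemble
    dual_LB: Ensemble
    dual_AB: Ensemble
    expected_delta_AL: float
    expected_delta_LB: float
    expected_delta_AB: float

    @property
    def expected_ce_no_ab(self) -> float:
        return self.expected_delta_AL + self.expected_delta_LB

    @property
    def expected_ce_full(self) -> float:
        return self.expected_ce_no_ab + self.expected_delta_AB


def _shift_component(complex_, coords, comp, factor, anchor_comp):
    """Scale the gap between two component centroids by ``factor``.

    Moves every atom of ``comp`` along the centroid-centroid axis so the
    separation becomes factor * original.
    """
    out = coords.copy()
    gi = complex_.group(anchor_comp)
    gj = complex_.group(comp)
    ci = coords[gi].mean(axis=0)
    cj = coords[gj].mean(axis=0)
    out[gj] += (factor - 1.0) * (cj - ci)
    return out


def plant_cooperativity_scenario(
    spec: ToyComplexSpec,
    lb_factor: float = 0.8,
    ab_factor: float = 1.0,
    n_frames: int = 1,
    sigma: float = 0.0,
) -> PlantedCEScenario:
    """Build matched dual/ternary ensembles with a planted energy change.

    Dual complexes keep the reference geometry of their two components; in
    the ternary frames the L-B centroid gap is scaled by ``lb_factor``
    (< 1 tightens the interface -> more favorable IntE_LB when attractive)
    and the A-B gap by ``ab_factor`` applied on top (!= 1 models e.g. a
    protein-protein salt bridge broken on ternary formation).  Expected
    interaction-energy changes are computed with the scalar reference loop
    on the noise-free geometries.
    """
    if lb_factor <= 0 or ab_factor <= 0:
        raise ValueError("contact factors must be positive")
    cx, _ = make_toy_ternary_system(spec)
    ref = cx.coordinates

    # Ternary geometry: move B toward/away from L, then adjust A-B if asked.
    tern = _shift_component(cx, ref, "B", lb_factor, anchor_comp="L")
    if ab_factor != 1.0:
        # scale the A-B centroid gap by moving A, preserving the L-B gap
        ga, gb = cx.group("A"), cx.group("B")
        ca, cb = tern[ga].mean(axis=0), tern[gb].mean(axis=0)
        tern = tern.copy()
        tern[ga] += (ab_factor - 1.0) * (ca - cb)

    base_truth_ref = reference_group_energies(cx, ref)
    base_truth_tern = reference_group_energies(cx, tern)

    def _pair_total(truth, pair):
        e, v = truth.pair_totals[pair]
        return e + v

    expected_delta_al = _pair_total(base_truth_tern, "AL") - _pair_total(base_truth_ref, "AL")
    expected_delta_lb = _pair_total(base_truth_tern, "LB") - _pair_total(base_truth_ref, "LB")
    expected_delta_ab = _pair_total(base_truth_tern, "AB") - _pair_total(base_truth_ref, "AB")

    seed = spec.seed
    ternary = sample_ensemble(cx, n_frames, sigma, seed + 1, base_coordinates=tern)
    dual_al = sample_ensemble(cx, n_frames, sigma, seed + 2, base_coordinates=ref)
    dual_lb = sample_ensemble(cx, n_frames, sigma, seed + 3, base_coordinates=ref)
    dual_ab = sample_ensemble(cx, n_frames, sigma, seed + 4, base_coordinates=ref)
    return PlantedCEScenario(
        complex=cx,
        ternary=ternary,
        dual_AL=dual_al,
        dual_LB=dual_lb,
        dual_AB=dual_ab,
        expected_delta_AL=expected_delta_al,
        expected_delta_LB=expected_delta_lb,
        expected_delta_AB=expected_delta_ab,
    )
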