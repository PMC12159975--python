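"""Readers and writers: PDB structures, parameter tables, group maps, scenarios.

Structures come in as (multi-model) PDB parsed with Biopython; nonbonded
parameters as a CSV keyed either by (residue_name, atom_name) or by atom
serial; and the component assignment (A / L / B) as a JSON or TOML group
map of the form

    {"A": {"chains": ["A"]}, "L": {"chains": ["L"]},
     "B": {"residues": [[120, 180]]}}

Binding scenarios (the six dissociation constants plus optional totals and
temperature) travel as flat JSON/TOML key-value files or as CSV rows with
columns kd_A_L ... kd_AB_L, temperature_K.
"""

from __future__ import annotations

import json
import math
import tomllib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .constants import DEFAULT_TEMPERATURE
from .energetics import AtomRecord, Ensemble, ParameterizedComplex
from .thermo import BindingConstants

__all__ = [
    "load_complex",
    "write_complex_pdb",
    "write_parameter_csv",
    "read_group_map",
    "read_scenario",
    "write_scenario",
    "read_scenario_table",
]

PARAM_COLUMNS = [
    "residue_name", "atom_name", "charge_e", "lj_epsilon_kcal",
    "lj_rmin_half_A", "mass_amu", "vdw_radius_A",
]


class MissingParameterError(ValueError):
    """Atoms without force-field parameters, listed as (residue, atom) pairs."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            "no parameters for atoms: "
            + ", ".join(f"{res}/{atom}" for res, atom in self.missing)
        )


def _load_mapping_file(path) -> dict:
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return json.load(fh)


def read_group_map(path) -> dict[str, dict]:
    """Component -> selection mapping (chains and/or residue index ranges)."""
    raw = _load_mapping_file(path)
    out = {}
    for comp in ("A", "L", "B"):
        if comp not in raw:
            raise ValueError(f"group map missing component {comp!r}")
        sel = raw[comp]
        if not isinstance(sel, dict) or not ({"chains", "residues"} & sel.keys()):
            raise ValueError(
                f"group map entry for {comp!r} must specify 'chains' and/or 'residues'"
            )
        out[comp] = sel
    return out


def _component_of(chain_id: str, residue_index: int, group_map: dict) -> str | None:
    hits = []
    for comp, sel in group_map.items():
        if chain_id in sel.get("chains", []):
            hits.append(comp)
            continue
        for lo, hi in sel.get("residues", []):
            if lo <= residue_index <= hi:
                hits.append(comp)
                break
    if len(hits) > 1:
        raise ValueError(
            f"chain {chain_id!r} residue {residue_index} assigned to multiple "
            f"components: {hits}"
        )
    return hits[0] if hits else None


def load_complex(
    structure_file,
    parameter_table,
    group_map,
    strict: bool = True,
):
    """Parameterized complex (or ensemble) from PDB + parameter CSV + group map.

    Returns a :class:`ParameterizedComplex` for a single-model PDB and an
    :class:`Ensemble` for a multi-model PDB.  ``parameter_table`` may be a
    path or a DataFrame with columns ``residue_name, atom_name, charge_e,
    lj_epsilon_kcal, lj_rmin_half_A, mass_amu, vdw_radius_A`` (use
    residue_name ``"*"`` rows or an ``atom_serial`` column for per-serial
    keys).  In strict mode unparameterized atoms raise
    :class:`MissingParameterError`; otherwise they are dropped with a
    warning.
    """
    if isinstance(parameter_table, (str, Path)):
        # round_trip parsing: the default converter can be an ulp off
        params = pd.read_csv(parameter_table, float_precision="round_trip")
    else:
        params = parameter_table.copy()
    if isinstance(group_map, (str, Path)):
        group_map = read_group_map(group_map)

    by_serial = {}
    if "atom_serial" in params.columns:
        by_serial = {
            int(row.atom_serial): row for row in params.itertuples()
            if not pd.isna(row.atom_serial)
        }
    by_key = {
        (str(row.residue_name), str(row.atom_name)): row
        for row in params.itertuples()
    }

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("complex", str(structure_file))
    models = list(structure)
    if not models:
        raise ValueError(f"no models in {structure_file}")

    atoms = []
    missing = []
    seen_chains = set()
    for chain in models[0]:
        seen_chains.add(chain.id)
        for residue in chain:
            res_index = residue.id[1]
            comp = _component_of(chain.id, res_index, group_map)
            if comp is None:
                raise ValueError(
                    f"group map does not cover chain {chain.id!r} residue "
                    f"{res_index} ({residue.resname.strip()})"
                )
            for atom in residue:
                serial = atom.serial_number
                row = by_serial.get(serial) or by_key.get(
                    (residue.resname.strip(), atom.get_name())
                )
                if row is None:
                    missing.append((f"{residue.resname.strip()}{res_index}", atom.get_name()))
                    continue
                atoms.append(
                    AtomRecord(
                        atom_id=serial,
                        atom_name=atom.get_name(),
                        residue_index=res_index,
                        residue_name=residue.resname.strip(),
                        component_label=comp,
                        coordinates=tuple(float(x) for x in atom.coord),
                        partial_charge=float(row.charge_e),
                        lj_epsilon=float(row.lj_epsilon_kcal),
                        lj_rmin_half=float(row.lj_rmin_half_A),
                        mass=float(row.mass_amu),
                        vdw_radius_for_sasa=float(row.vdw_radius_A),
                    )
                )
    if missing:
        if strict:
            raise MissingParameterError(missing)
        warnings.warn(
            f"dropped {len(missing)} unparameterized atoms", stacklevel=2
        )
    if not atoms:
        raise ValueError("no parameterized atoms loaded")
    cx = ParameterizedComplex(atoms)

    if len(models) == 1:
        return cx
    frames = []
    for model in models:
        model_atoms = [a for c in model for r in c for a in r]
        coords = []
        kept_serials = {a.atom_id for a in cx.atoms}
        for atom in model_atoms:
            if atom.serial_number in kept_serials:
                coords.append([float(x) for x in atom.coord])
        if len(coords) != len(cx):
            raise ValueError(
                f"model has {len(coords)} parameterized atoms, expected {len(cx)}"
            )
        frames.append(coords)
    return Ensemble(cx, np.array(frames))


def write_complex_pdb(path, complex_: ParameterizedComplex, frames=None, header=None):
    """Write a complex (optionally multi-frame) as a standard PDB file.

    Components map to chain IDs A/L/B; atoms are emitted as fixed-width ATOM
    records, one MODEL block per frame.
    """
    if frames is None:
        frames = complex_.coordinates[None]
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    lines = []
    if header:
        for text in header.splitlines():
            lines.append(f"REMARK   1 {text}")
    multi = frames.shape[0] > 1
    for m, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for atom, (x, y, z) in zip(complex_.atoms, frame):
            name = atom.atom_name[:4]
            lines.append(
                f"ATOM  {atom.atom_id:5d} {name:^4s} {atom.residue_name[:3]:>3s} "
                f"{atom.component_label}{atom.residue_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{'C':>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_parameter_csv(path, complex_: ParameterizedComplex):
    """Per-serial parameter table matching :func:`load_complex`'s schema."""
    rows = [
        {
            "atom_serial": a.atom_id,
            "residue_name": a.residue_name,
            "atom_name": a.atom_name,
            "charge_e": a.partial_charge,
            "lj_epsilon_kcal": a.lj_epsilon,
            "lj_rmin_half_A": a.lj_rmin_half,
            "mass_amu": a.mass,
            "vdw_radius_A": a.vdw_radius_for_sasa,
        }
        for a in complex_.atoms
    ]
    # %.17g keeps the round trip lossless for float64 parameters
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


SCENARIO_KD_KEYS = ["kd_A_L", "kd_L_B", "kd_A_B", "kd_AL_B", "kd_LB_A", "kd_AB_L"]


def read_scenario(path) -> tuple[BindingConstants, float]:
    """One binding scenario (six Kd's + temperature) from JSON/TOML."""
    raw = _load_mapping_file(path)
    missing = [k for k in SCENARIO_KD_KEYS if k not in raw]
    if missing:
        raise ValueError(f"scenario file missing keys: {missing}")
    constants = BindingConstants(**{k: float(raw[k]) for k in SCENARIO_KD_KEYS})
    temperature = float(raw.get("temperature_K", DEFAULT_TEMPERATURE))
    return constants, temperature


def write_scenario(path, constants: BindingConstants,
                   temperature: float = DEFAULT_TEMPERATURE, extra=None):
    payload = {k: getattr(constants, k) for k in SCENARIO_KD_KEYS}
    payload["temperature_K"] = temperature
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_scenario_table(path) -> list[tuple[BindingConstants, float]]:
    """Scenarios from a CSV with one row per scenario."""
    df = pd.read_csv(path)
    missing = [k for k in SCENARIO_KD_KEYS if k not in df.columns]
    if missing:
        raise ValueError(f"scenario CSV missing columns: {missing}")
    out = []
    for row in df.itertuples():
        constants = BindingConstants(
            **{k: float(getattr(row, k)) for k in SCENARIO_KD_KEYS}
        )
        temp = float(getattr(row, "temperature_K", DEFAULT_TEMPERATURE))
        if math.isnan(temp):
            temp = DEFAULT_TEMPERATURE
        out.append((constants, temp))
    return out
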