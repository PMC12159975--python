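"""Cooperativity-effect (CE) estimator and ligand-library ranking.

The CE approximates the cooperativity free energy of a glue ligand by the
change in ensemble-averaged pairwise interaction energies on going from the
dual complexes to the ternary complex:

    CE = dIntE_AL + dIntE_LB + dIntE_AB,
    dIntE_XY = <IntE_XY>_ternary - <IntE_XY>_dual

A more negative CE means the ternary assembly gains more nonbonded
stabilization than the dual complexes provide, i.e. stronger glue-like
character.  The protein-protein term dIntE_AB converges slowly in practice,
so the default screening variant drops it (``ce_no_ab``); the full variant
is computed whenever a dual A-B ensemble is supplied.  Mass-normalized
values (kcal/mol per amu) crudely account for the entropic cost of larger
ligands and are reported alongside, never instead of, the raw values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from .energetics import DielectricMode, Ensemble, ensemble_interaction_energy

__all__ = ["CEInput", "CEScreenRecord", "ce_estimate", "mass_normalize",
           "relative_ce", "rank_candidates"]


@dataclass(frozen=True)
class CEInput:
    """Ensembles needed to estimate the CE of one ligand.

    The ternary ensemble must contain all three components; each dual
    ensemble is an ensemble of the full parameterized system in which only
    the named pair is considered bound (the estimator evaluates just that
    pair's interaction).  ``dual_AB`` is optional; without it only the
    no-AB CE variant is available.
    """

    ligand_id: str
    molecular_mass: float
    ternary: Ensemble
    dual_AL: Ensemble
    dual_LB: Ensemble
    dual_AB: Ensemble | None = None

    def __post_init__(self):
        if not (math.isfinite(self.molecular_mass) and self.molecular_mass > 0):
            raise ValueError(f"molecular_mass must be positive, got {self.molecular_mass!r}")
        n_lig = len(self.ternary.complex.group("L"))
        for name in ("dual_AL", "dual_LB"):
            ens = getattr(self, name)
            if ens is None:
                raise ValueError(f"{name} ensemble is required")
            if len(ens.complex.group("L")) != n_lig:
                raise ValueError(
                    f"{name}: ligand atom count {len(ens.complex.group('L'))} "
                    f"differs from ternary ({n_lig})"
                )


@dataclass(frozen=True)
class CEScreenRecord:
    """Per-ligand screening record: IntE terms, CE variants, normalizations."""

    ligand_id: str
    mass: float
    inte_AL_ternary: float
    inte_AL_ternary_std: float
    inte_LB_ternary: float
    inte_LB_ternary_std: float
    inte_AB_ternary: float | None
    inte_AB_ternary_std: float | None
    delta_inte_AL: float
    delta_inte_LB: float
    delta_inte_AB: float | None
    ce_no_ab: float
    ce_full: float | None
    ce_no_ab_stderr: float
    ce_full_stderr: float | None
    inte_norm: float = float("nan")
    ce_norm: float = float("nan")
    relative_ce_value: float | None = None
    rank: int | None = None

    @property
    def inte_ligand_total(self) -> float:
        """Ternary ligand IntE with both proteins (AL + LB), the default
        screening IntE axis; the AL-only axis is available as
        ``inte_AL_ternary``."""
        return self.inte_AL_ternary + self.inte_LB_ternary

    def active_ce(self, variant: str = "no_ab") -> float:
        if variant == "no_ab":
            return self.ce_no_ab
        if variant == "full":
            if self.ce_full is None:
                raise ValueError(
                    f"{self.ligand_id}: full CE unavailable (no dual AB ensemble)"
                )
            return self.ce_full
        raise ValueError(f"unknown CE variant {variant!r}")


def ce_estimate(
    inp: CEInput,
    dielectric: DielectricMode = "2r",
    cutoff: float | None = None,
) -> CEScreenRecord:
    """The interaction-energy based cooperativity estimate for one ligand.

    Ensemble means are compared (ternary minus dual), matching the
    statistical-average semantics of the underlying ensembles; uncertainties
    are root-sum-square standard errors of the two means.
    """
    tern_al = ensemble_interaction_energy(inp.ternary, "AL", dielectric, cutoff)
    tern_lb = ensemble_interaction_energy(inp.ternary, "LB", dielectric, cutoff)
    dual_al = ensemble_interaction_energy(inp.dual_AL, "AL", dielectric, cutoff)
    dual_lb = ensemble_interaction_energy(inp.dual_LB, "LB", dielectric, cutoff)

    delta_al = tern_al.total.mean - dual_al.total.mean
    delta_lb = tern_lb.total.mean - dual_lb.total.mean
    var_no_ab = (
        tern_al.total.std_error ** 2 + dual_al.total.std_error ** 2
        + tern_lb.total.std_error ** 2 + dual_lb.total.std_error ** 2
    )
    ce_no_ab = delta_al + delta_lb

    delta_ab = ce_full = ce_full_err = None
    inte_ab = inte_ab_std = None
    if inp.dual_AB is not None:
        tern_ab = ensemble_interaction_energy(inp.ternary, "AB", dielectric, cutoff)
        dual_ab = ensemble_interaction_energy(inp.dual_AB, "AB", dielectric, cutoff)
        delta_ab = tern_ab.total.mean - dual_ab.total.mean
        ce_full = ce_no_ab + delta_ab
        ce_full_err = math.sqrt(
            var_no_ab + tern_ab.total.std_error ** 2 + dual_ab.total.std_error ** 2
        )
        inte_ab = tern_ab.total.mean
        inte_ab_std = tern_ab.total.sample_std

    return CEScreenRecord(
        ligand_id=inp.ligand_id,
        mass=inp.molecular_mass,
        inte_AL_ternary=tern_al.total.mean,
        inte_AL_ternary_std=tern_al.total.sample_std,
        inte_LB_ternary=tern_lb.total.mean,
        inte_LB_ternary_std=tern_lb.total.sample_std,
        inte_AB_ternary=inte_ab,
        inte_AB_ternary_std=inte_ab_std,
        delta_inte_AL=delta_al,
        delta_inte_LB=delta_lb,
        delta_inte_AB=delta_ab,
        ce_no_ab=ce_no_ab,
        ce_full=ce_full,
        ce_no_ab_stderr=math.sqrt(var_no_ab),
        ce_full_stderr=ce_full_err,
    )


def mass_normalize(record: CEScreenRecord, variant: str = "no_ab") -> CEScreenRecord:
    """Fill in mass-normalized IntE and CE (kcal/mol per amu)."""
    if record.mass <= 0:
        raise ValueError(f"{record.ligand_id}: mass must be positive")
    return replace(
        record,
        inte_norm=record.inte_ligand_total / record.mass,
        ce_norm=record.active_ce(variant) / record.mass,
    )


def relative_ce(
    record: CEScreenRecord, reference: CEScreenRecord, variant: str = "no_ab"
) -> float:
    """CE of a ligand minus CE of the reference ligand (antisymmetric)."""
    for rec in (record, reference):
        if variant == "full" and rec.ce_full is None:
            raise ValueError(
                f"{rec.ligand_id}: full CE unavailable; cannot compare variants"
            )
    return record.active_ce(variant) - reference.active_ce(variant)


def rank_candidates(
    records: list[CEScreenRecord],
    reference_id: str,
    variant: str = "no_ab",
    normalized: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Deterministic ranking of a ligand library against a reference.

    Ordering key: (CE, ternary ligand IntE, ligand_id) ascending — more
    negative is better, id breaks ties.  The summary counts records strictly
    better than the reference on BOTH axes, in the requested mode.
    """
    ids = [r.ligand_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ligand ids: {dupes}")
    if reference_id not in ids:
        raise ValueError(f"reference ligand {reference_id!r} not among records")

    def axes(r: CEScreenRecord) -> tuple[float, float]:
        ce = r.active_ce(variant)
        inte = r.inte_ligand_total
        if normalized:
            ce, inte = ce / r.mass, inte / r.mass
        return ce, inte

    decorated = sorted(records, key=lambda r: (*axes(r), r.ligand_id))
    decorated = [replace(r, rank=i + 1,
                         relative_ce_value=r.active_ce(variant)
                         - next(x for x in records
                                if x.ligand_id == reference_id).active_ce(variant))
                 for i, r in enumerate(decorated)]
    ref = next(r for r in decorated if r.ligand_id == reference_id)
    ref_ce, ref_inte = axes(ref)
    better = sum(
        1 for r in decorated
        if r.ligand_id != reference_id and axes(r)[0] < ref_ce and axes(r)[1] < ref_inte
    )
    table = pd.DataFrame(
        [
            {
                "rank": r.rank,
                "ligand_id": r.ligand_id,
                "mass_amu": r.mass,
                "inte_AL_ternary": r.inte_AL_ternary,
                "inte_LB_ternary": r.inte_LB_ternary,
                "inte_ligand_total": r.inte_ligand_total,
                "delta_inte_AL": r.delta_inte_AL,
                "delta_inte_LB": r.delta_inte_LB,
                "delta_inte_AB": r.delta_inte_AB,
                "ce_no_ab": r.ce_no_ab,
                "ce_full": r.ce_full,
                "ce_stderr": r.ce_no_ab_stderr if variant == "no_ab" else r.ce_full_stderr,
                "inte_norm": r.inte_ligand_total / r.mass,
                "ce_norm": r.active_ce(variant) / r.mass,
                "relative_ce": r.relative_ce_value,
            }
            for r in decorated
        ]
    )
    summary = {
        "reference_id": reference_id,
        "variant": variant,
        "normalized": normalized,
        "n_records": len(records),
        "n_better_than_reference": better,
        "inte_axis": "AL+LB (ternary ligand total)",
    }
    return table, summary
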