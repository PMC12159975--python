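"""Closed-form thermodynamics of ternary-complex cooperativity.

A molecular glue ternary complex ALB (protein A, ligand L, protein B) can
assemble along three paths, each a dual complex followed by recruitment of
the third component:

    A + L -> AL,  AL + B -> ALB      (dissociation constants kd_A_L, kd_AL_B)
    L + B -> LB,  LB + A -> ALB      (kd_L_B, kd_LB_A)
    A + B -> AB,  AB + L -> ALB      (kd_A_B, kd_AB_L)

Thermodynamic cycle closure requires the three products

    kd_A_L * kd_AL_B = kd_L_B * kd_LB_A = kd_A_B * kd_AB_L

to coincide (each equals [A][L][B]/[ALB] at equilibrium).  Cooperativity is
the free-energy gain of a binary association when the third component is
already present:

    dG_coop,1 = dG_AL_B - dG_L_B = dG_ALB - dG_A_L - dG_L_B
    dG_coop,2 = dG_ALB - dG_A_L - dG_A_B
    dG_coop,3 = dG_ALB - dG_L_B - dG_A_B

with the dimensionless alphas defined through dG_coop,X = -RT ln(alpha_X),
so alpha > 1 (dG_coop < 0) means positive cooperativity: the glue makes the
second association tighter.  alpha_1 equals the binary-over-ternary-step
ratio kd_L_B / kd_AL_B.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

from .constants import DEFAULT_TEMPERATURE, R_KCAL

__all__ = [
    "RateConstants",
    "BindingConstants",
    "FreeEnergySet",
    "CooperativityResult",
    "CycleClosureError",
    "CycleClosureWarning",
    "kds_from_rates",
    "dg_from_kd",
    "kd_from_dg",
    "cooperativity",
    "cooperativity_from_free_energies",
    "relative_cooperativity",
]

#: Relative closure tolerance that raises an error.
STRICT_CLOSURE_RTOL = 1e-6
#: Relative closure tolerance that only warns.
LENIENT_CLOSURE_RTOL = 1e-2


class CycleClosureError(ValueError):
    """Thermodynamic cycle closure violated beyond the strict tolerance."""


class CycleClosureWarning(UserWarning):
    """Thermodynamic cycle closure violated beyond the lenient tolerance."""


def _check_positive_finite(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
            raise ValueError(
                f"{type(obj).__name__}.{name} must be strictly positive and "
                f"finite, got {value!r}"
            )


@dataclass(frozen=True)
class RateConstants:
    """On/off rate constants of the six reversible association steps.

    On-rates in 1/(M * time), off-rates in 1/time; any consistent time unit.
    Prefixes: v = path via AL, u = path via LB, r = path via AB; suffix 1 for
    the dual step, 2 for the ternary (second) step.
    """

    v1_on: float
    v1_off: float
    u1_on: float
    u1_off: float
    r1_on: float
    r1_off: float
    v2_on: float
    v2_off: float
    u2_on: float
    u2_off: float
    r2_on: float
    r2_off: float

    def __post_init__(self):
        _check_positive_finite(self, [f.name for f in fields(self)])


@dataclass(frozen=True)
class BindingConstants:
    """The six dissociation constants (molar) of the three assembly paths.

    Parameters
    ----------
    strict_closure
        If True, a cycle-closure violation beyond ``STRICT_CLOSURE_RTOL``
        raises :class:`CycleClosureError`; otherwise violations beyond
        ``LENIENT_CLOSURE_RTOL`` only emit :class:`CycleClosureWarning`.
    """

    kd_A_L: float
    kd_L_B: float
    kd_A_B: float
    kd_AL_B: float
    kd_LB_A: float
    kd_AB_L: float
    strict_closure: bool = field(default=False, compare=False)

    _KD_FIELDS = ("kd_A_L", "kd_L_B", "kd_A_B", "kd_AL_B", "kd_LB_A", "kd_AB_L")

    def __post_init__(self):
        _check_positive_finite(self, self._KD_FIELDS)
        residual = self.closure_residual()
        if self.strict_closure and residual > STRICT_CLOSURE_RTOL:
            raise CycleClosureError(
                "cycle closure violated: path products "
                f"{self.closure_products()} (relative spread {residual:.3e})"
            )
        if not self.strict_closure and residual > LENIENT_CLOSURE_RTOL:
            warnings.warn(
                "cycle closure violated: path products "
                f"{self.closure_products()} (relative spread {residual:.3e})",
                CycleClosureWarning,
                stacklevel=2,
            )

    def closure_products(self) -> tuple[float, float, float]:
        """The three path products, each nominally [A][L][B]/[ALB]."""
        return (
            self.kd_A_L * self.kd_AL_B,
            self.kd_L_B * self.kd_LB_A,
            self.kd_A_B * self.kd_AB_L,
        )

    def closure_residual(self) -> float:
        """Relative spread of the three path products: (max-min)/min."""
        products = self.closure_products()
        return (max(products) - min(products)) / min(products)

    def ternary_formation_product(self) -> float:
        """[A][L][B]/[ALB] as the geometric mean of the three path products.

        Equal to each individual product when closure is exact; the geometric
        mean keeps lenient (noisy) constant sets path-symmetric.
        """
        p1, p2, p3 = self.closure_products()
        return math.exp((math.log(p1) + math.log(p2) + math.log(p3)) / 3.0)

    def to_free_energies(self, temperature: float = DEFAULT_TEMPERATURE) -> "FreeEnergySet":
        """Convert each Kd to a standard binding free energy (RT ln Kd)."""
        dgs = {
            "dg" + name[2:]: dg_from_kd(getattr(self, name), temperature)
            for name in self._KD_FIELDS
        }
        dg_alb = R_KCAL * temperature * math.log(self.ternary_formation_product())
        return FreeEnergySet(dg_ALB=dg_alb, temperature=temperature, **dgs)


@dataclass(frozen=True)
class FreeEnergySet:
    """Standard binding free energies (kcal/mol) of all assembly steps.

    ``dg_ALB`` is the overall ternary formation free energy from the three
    isolated components; path independence requires it to equal each of
    dg_A_L + dg_AL_B, dg_L_B + dg_LB_A and dg_A_B + dg_AB_L.
    """

    dg_A_L: float
    dg_L_B: float
    dg_A_B: float
    dg_AL_B: float
    dg_LB_A: float
    dg_AB_L: float
    dg_ALB: float
    temperature: float = DEFAULT_TEMPERATURE

    #: Absolute path-independence tolerance, kcal/mol.
    PATH_TOL = 1e-2

    def __post_init__(self):
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        for f in fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                raise ValueError(f"FreeEnergySet.{f.name} must be finite")
        sums = self.path_sums()
        if max(sums) - min(sums) > self.PATH_TOL or abs(
            self.dg_ALB - sum(sums) / 3.0
        ) > self.PATH_TOL:
            raise ValueError(
                f"path independence violated: path sums {sums} vs dg_ALB={self.dg_ALB}"
            )

    def path_sums(self) -> tuple[float, float, float]:
        """Ternary formation free energy along each of the three paths."""
        return (
            self.dg_A_L + self.dg_AL_B,
            self.dg_L_B + self.dg_LB_A,
            self.dg_A_B + self.dg_AB_L,
        )


@dataclass(frozen=True)
class CooperativityResult:
    """The three cooperativity measures at a stated temperature.

    ``classification`` follows the sign of dG_coop,1: "positive" when
    dG_coop,1 < 0 (alpha_1 > 1), "none" when zero, "negative" otherwise.
    """

    alpha1: float
    alpha2: float
    alpha3: float
    dg_coop1: float
    dg_coop2: float
    dg_coop3: float
    temperature: float

    @property
    def classification(self) -> str:
        if self.dg_coop1 < 0:
            return "positive"
        if self.dg_coop1 == 0:
            return "none"
        return "negative"

    @property
    def alphas(self) -> tuple[float, float, float]:
        return (self.alpha1, self.alpha2, self.alpha3)

    @property
    def dg_coops(self) -> tuple[float, float, float]:
        return (self.dg_coop1, self.dg_coop2, self.dg_coop3)

    def as_dict(self) -> dict:
        return {
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "alpha3": self.alpha3,
            "dg_coop1_kcal_mol": self.dg_coop1,
            "dg_coop2_kcal_mol": self.dg_coop2,
            "dg_coop3_kcal_mol": self.dg_coop3,
            "temperature_K": self.temperature,
            "classification": self.classification,
        }


def kds_from_rates(rates: RateConstants, strict_closure: bool = False) -> BindingConstants:
    """Dissociation constants as off-rate / on-rate for each of the six steps.

    Cycle closure is not guaranteed for arbitrary rate sets; the returned
    :class:`BindingConstants` carries the closure residual as a diagnostic
    (``closure_residual()``), and warns or errors per ``strict_closure``.
    """
    return BindingConstants(
        kd_A_L=rates.v1_off / rates.v1_on,
        kd_L_B=rates.u1_off / rates.u1_on,
        kd_A_B=rates.r1_off / rates.r1_on,
        kd_AL_B=rates.v2_off / rates.v2_on,
        kd_LB_A=rates.u2_off / rates.u2_on,
        kd_AB_L=rates.r2_off / rates.r2_on,
        strict_closure=strict_closure,
    )


def dg_from_kd(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Standard binding free energy RT ln(Kd), kcal/mol, Kd in molar (1 M state)."""
    if not (math.isfinite(kd) and kd > 0):
        raise ValueError(f"kd must be strictly positive and finite, got {kd!r}")
    if not (math.isfinite(temperature) and temperature > 0):
        raise ValueError(f"temperature must be positive, got {temperature!r}")
    return R_KCAL * temperature * math.log(kd)


def kd_from_dg(dg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`dg_from_kd`: Kd = exp(dG / RT), molar."""
    if not math.isfinite(dg):
        raise ValueError(f"dg must be finite, got {dg!r}")
    if not (math.isfinite(temperature) and temperature > 0):
        raise ValueError(f"temperature must be positive, got {temperature!r}")
    return math.exp(dg / (R_KCAL * temperature))


def cooperativity(
    constants: BindingConstants, temperature: float = DEFAULT_TEMPERATURE
) -> CooperativityResult:
    """All three cooperativity measures from a set of dissociation constants.

    dG_coop,1 is evaluated as dg_AL_B - dg_L_B (exactly zero for a fully
    symmetric constant set); dG_coop,2/3 reference the protein-protein edge
    kd_A_B.  Each alpha is exp(-dG_coop / RT), so the identity
    dG_coop,X = -RT ln(alpha_X) holds to machine precision by construction.
    """
    rt = R_KCAL * temperature
    dg = constants.to_free_energies(temperature)
    dg_coop1 = dg.dg_AL_B - dg.dg_L_B
    dg_coop2 = dg.dg_ALB - dg.dg_A_L - dg.dg_A_B
    dg_coop3 = dg.dg_ALB - dg.dg_L_B - dg.dg_A_B
    return CooperativityResult(
        alpha1=math.exp(-dg_coop1 / rt),
        alpha2=math.exp(-dg_coop2 / rt),
        alpha3=math.exp(-dg_coop3 / rt),
        dg_coop1=dg_coop1,
        dg_coop2=dg_coop2,
        dg_coop3=dg_coop3,
        temperature=temperature,
    )


def cooperativity_from_free_energies(fes: FreeEnergySet) -> CooperativityResult:
    """Cooperativity from binding free energies (path-independent route)."""
    rt = R_KCAL * fes.temperature
    dg_coop1 = fes.dg_ALB - fes.dg_A_L - fes.dg_L_B
    dg_coop2 = fes.dg_ALB - fes.dg_A_L - fes.dg_A_B
    dg_coop3 = fes.dg_ALB - fes.dg_L_B - fes.dg_A_B
    return CooperativityResult(
        alpha1=math.exp(-dg_coop1 / rt),
        alpha2=math.exp(-dg_coop2 / rt),
        alpha3=math.exp(-dg_coop3 / rt),
        dg_coop1=dg_coop1,
        dg_coop2=dg_coop2,
        dg_coop3=dg_coop3,
        temperature=fes.temperature,
    )


def relative_cooperativity(fes_lig: FreeEnergySet, fes_ref: FreeEnergySet) -> float:
    """Relative cooperativity ddG_coop,1 (kcal/mol) of a ligand vs a reference.

    (dg_ALB - dg_A_L - dg_L_B)_ligand - (dg_ALB - dg_A_L - dg_L_B)_reference;
    antisymmetric in its arguments.  Both sets must share a temperature.
    """
    if fes_lig.temperature != fes_ref.temperature:
        raise ValueError(
            f"temperature mismatch: {fes_lig.temperature} K vs {fes_ref.temperature} K"
        )
    coop_lig = fes_lig.dg_ALB - fes_lig.dg_A_L - fes_lig.dg_L_B
    coop_ref = fes_ref.dg_ALB - fes_ref.dg_A_L - fes_ref.dg_L_B
    return coop_lig - coop_ref
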