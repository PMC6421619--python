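"""Parameter sets for the cartilage-regeneration model.

Two containers are provided: :class:`DimensionalParams` (laboratory units —
mm, hours, g/mm^3, cells/mm^3, moles/mm^3) and :class:`DimensionlessParams`,
the canonical input to the solver. The model is non-dimensionalised on the
matrix-production time scale ``mmax / (p80 * Ctotal_max0)`` (about 11 days
for the default values) and the defect thickness ``d``, so a unit of
dimensionless time corresponds to roughly 11 days of healing.

The tabulated dimensionless defaults are the authoritative simulation inputs.
A handful of them are not exactly recoverable from the dimensional table via
the scaling formulas (the sources round or adjust); those discrepancies are
surfaced by :func:`nondimensional_discrepancies` rather than silently
reconciled.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields
from typing import Any

__all__ = [
    "ValidationError",
    "DimensionalParams",
    "DimensionlessParams",
    "nondimensionalize",
    "matrix_timescale_hours",
    "default_dimensional",
    "default_dimensionless",
    "nondimensional_discrepancies",
    "DIMENSIONAL_UNITS",
    "DIMENSIONLESS_DESCRIPTIONS",
]


class ValidationError(ValueError):
    """A parameter set violates a model invariant; names the offending field."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional model parameters.

    Units follow the conventions of the source estimates: lengths in mm,
    time in hours, cell densities in cells/mm^3, matrix densities in g/mm^3,
    nutrient in moles/mm^3 and growth-factor concentrations in g/mm^3.
    """

    d: float            # defect thickness (mm)
    DS0: float          # stem-cell diffusion constant, 2*m1*DS ((mm^2/h)(g/mm^3))
    DC0: float          # chondrocyte diffusion constant ((mm^2/h)(g/mm^3))
    Dn: float           # nutrient diffusivity (mm^2/h)
    Dm: float           # matrix diffusivity (mm^2/h)
    Dg: float           # FGF-1 diffusivity (mm^2/h)
    Db: float           # BMP-2 diffusivity (mm^2/h)
    p10: float          # stem-cell proliferation constant, 2*m2*p1 (g/mm^3/h)
    p2: float           # stem-cell differentiation rate (1/h)
    p3: float           # stem-cell death rate (1/h)
    p40: float          # chondrocyte proliferation constant (g/mm^3/h)
    p400: float         # chondrocyte proliferation rate from FGF-1 (1/h)
    p5: float           # chondrocyte death rate (1/h)
    p6: float           # nutrient uptake by stem cells (moles/(cell h))
    p7: float           # nutrient uptake by chondrocytes (moles/(cell h))
    p80: float          # matrix production constant ((g/mm^3)/((cells/mm^3) h))
    p81: float          # matrix degradation constant, per matrix density (1/((cells/mm^3) h))
    p800: float         # FGF-1 direct matrix-deposition pre-factor (0-1)
    p9: float           # FGF-1 production constant ((g/mm^3)/((cells/mm^3) h))
    p11: float          # FGF-1 degradation rate (1/h)
    p12: float          # BMP-2 production constant ((g/mm^3)/((cells/mm^3) h))
    p13: float          # BMP-2 degradation rate (1/h)
    gamma: float        # FGF-1 boundary flux coefficient (mm/h)
    chi: float          # BMP-2 boundary flux coefficient (mm/h)
    Ctotal_max0: float  # maximum total cell density (cells/mm^3)
    CS_max0: float      # maximum stem-cell density (cells/mm^3)
    CC_max0: float      # maximum chondrocyte density (cells/mm^3)
    mmax: float         # maximum matrix density (g/mm^3)
    m1: float           # diffusivity reference matrix density (g/mm^3)
    m2: float           # proliferation reference matrix density (g/mm^3)
    m3: float           # initial matrix density (g/mm^3)
    N0: float           # boundary/initial nutrient concentration (moles/mm^3)
    n0: float           # Michaelis-Menten nutrient constant (moles/mm^3)
    n1: float           # critical nutrient concentration (moles/mm^3)
    g0: float           # FGF-1 reference concentration (g/mm^3)
    b0: float           # BMP-2 reference concentration (g/mm^3)
    g_init: float       # initial FGF-1 concentration (g/mm^3)
    b_init: float       # initial BMP-2 concentration (g/mm^3)
    alpha: float        # differentiation-threshold reduction factor (1/(g/mm^3))
    CS0_max: float      # maximum differentiation threshold density (cells/mm^3)
    CS0_min: float      # minimum differentiation threshold density (cells/mm^3)
    CS_init: float      # implanted stem-cell peak density (cells/mm^3)
    CC_init: float      # initial chondrocyte density (cells/mm^3)
    skip_validation: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.skip_validation:
            self.validate()

    def validate(self) -> None:
        may_be_zero = {"p800", "g_init", "b_init", "CC_init", "skip_validation"}
        for f in fields(self):
            if f.name in may_be_zero:
                continue
            v = getattr(self, f.name)
            _require(math.isfinite(v) and v > 0,
                     f"DimensionalParams.{f.name} must be strictly positive, got {v!r}")
        for name in ("p800", "g_init", "b_init", "CC_init"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0,
                     f"DimensionalParams.{name} must be nonnegative, got {v!r}")
        _require(self.p800 <= 1.0, f"DimensionalParams.p800 must lie in [0, 1], got {self.p800!r}")
        _require(self.CS0_min <= self.CS0_max,
                 f"DimensionalParams.CS0_min ({self.CS0_min!r}) must not exceed CS0_max ({self.CS0_max!r})")
        _require(self.n1 < self.n0 < self.N0,
                 f"DimensionalParams nutrient ordering violated: need n1 < n0 < N0, "
                 f"got n1={self.n1!r}, n0={self.n0!r}, N0={self.N0!r}")
        _require(self.m3 < self.m1 < self.mmax and self.m3 < self.m2 < self.mmax,
                 f"DimensionalParams matrix ordering violated: need m3 < m1, m2 < mmax, "
                 f"got m1={self.m1!r}, m2={self.m2!r}, m3={self.m3!r}, mmax={self.mmax!r}")

    def replace(self, **changes: float) -> "DimensionalParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "skip_validation"}


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless model parameters — the canonical solver input.

    Overbar quantities of the scaled system: cell densities are measured in
    units of the maximum total cell density, matrix in units of its maximum
    density, nutrient in units of the boundary reservoir concentration, each
    growth factor in units of its reference concentration, length in defect
    thicknesses and time in matrix-production time scales.
    """

    DS0: float      # stem-cell diffusion constant
    DC0: float      # chondrocyte diffusion constant
    Dn: float       # nutrient diffusivity
    Dm: float       # matrix diffusivity
    Dg: float       # FGF-1 diffusivity
    Db: float       # BMP-2 diffusivity
    p10: float      # stem-cell proliferation constant
    p2: float       # stem-cell differentiation rate
    p3: float       # stem-cell death rate
    p40: float      # chondrocyte proliferation constant
    p400: float     # chondrocyte proliferation rate from FGF-1
    p5: float       # chondrocyte death rate
    p6: float       # nutrient uptake by stem cells
    p7: float       # nutrient uptake by chondrocytes
    p81: float      # matrix degradation constant
    p800: float     # FGF-1 direct matrix-deposition pre-factor (0-1)
    p9: float       # FGF-1 production constant
    p11: float      # FGF-1 degradation rate
    p12: float      # BMP-2 production constant
    p13: float      # BMP-2 degradation rate
    n0: float       # Michaelis-Menten nutrient constant
    n1: float       # critical nutrient concentration
    CS0_max: float  # maximum differentiation threshold density
    CS0_min: float  # minimum differentiation threshold density
    alpha: float    # threshold reduction factor (per BMP-2 unit)
    CS_max0: float  # maximum stem-cell density fraction
    CC_max0: float  # maximum chondrocyte density fraction
    m1: float       # diffusivity reference matrix density
    m2: float       # proliferation reference matrix density
    m3: float       # initial matrix density
    g_init: float   # initial FGF-1 concentration
    b_init: float   # initial BMP-2 concentration
    gamma: float    # FGF-1 boundary flux coefficient
    chi: float      # BMP-2 boundary flux coefficient
    CS_init: float  # implanted stem-cell peak density
    CC_init: float  # initial chondrocyte density
    skip_validation: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.skip_validation:
            self.validate()

    def validate(self) -> None:
        # rate constants may be zero: switching a process off is a valid
        # model reduction (the growth-factor toggles rely on it)
        may_be_zero = {"DS0", "DC0", "Dn", "Dm", "Dg", "Db", "p10", "p40", "p400",
                       "p2", "p3", "p5", "p6", "p7", "p800", "p9", "p11", "p12",
                       "p13", "p81", "m3", "g_init", "b_init", "CC_init", "CS_init",
                       "gamma", "chi", "skip_validation"}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "skip_validation":
                continue
            _require(math.isfinite(v),
                     f"DimensionlessParams.{f.name} must be finite, got {v!r}")
            if f.name in may_be_zero:
                _require(v >= 0, f"DimensionlessParams.{f.name} must be nonnegative, got {v!r}")
            else:
                _require(v > 0, f"DimensionlessParams.{f.name} must be strictly positive, got {v!r}")
        _require(self.p800 <= 1.0,
                 f"DimensionlessParams.p800 must lie in [0, 1], got {self.p800!r}")
        _require(abs(self.CS_max0 + self.CC_max0 - 1.0) <= 1e-12,
                 f"DimensionlessParams.CS_max0 + CC_max0 must equal 1 (cell fractions of the "
                 f"total maximum density), got {self.CS_max0 + self.CC_max0!r}")
        _require(self.CS0_min <= self.CS0_max < 1.0,
                 f"DimensionlessParams threshold ordering violated: need CS0_min <= CS0_max < 1, "
                 f"got CS0_min={self.CS0_min!r}, CS0_max={self.CS0_max!r}")
        _require(self.n1 < self.n0,
                 f"DimensionlessParams nutrient ordering violated: need 0 < n1 < n0, "
                 f"got n1={self.n1!r}, n0={self.n0!r}")

    def replace(self, **changes: Any) -> "DimensionlessParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "skip_validation"}

    @classmethod
    def from_dict(cls, d: dict[str, float], *, skip_validation: bool = False) -> "DimensionlessParams":
        known = {f.name for f in fields(cls)} - {"skip_validation"}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown DimensionlessParams keys: {sorted(unknown)}")
        missing = known - set(d)
        if missing:
            raise ValidationError(f"missing DimensionlessParams keys: {sorted(missing)}")
        return cls(skip_validation=skip_validation, **{k: float(v) for k, v in d.items()})


def matrix_timescale_hours(p: DimensionalParams) -> float:
    """Characteristic matrix-production time scale, in hours.

    One unit of dimensionless time corresponds to ``mmax / (p80 * Ctotal_max0)``
    hours — about 267 h (11 days) for the default parameter set.
    """
    return p.mmax / (p.p80 * p.Ctotal_max0)


def nondimensionalize(p: DimensionalParams) -> DimensionlessParams:
    """Convert a dimensional parameter set to its dimensionless counterpart.

    Scales rates by the matrix-production time scale, lengths by the defect
    thickness, cell densities by ``Ctotal_max0``, matrix by ``mmax``, nutrient
    by ``N0`` and each growth factor by its reference concentration.
    """
    p.validate()
    T = matrix_timescale_hours(p)       # hours per dimensionless time unit
    d2 = p.d ** 2
    rate = p.p80 * p.Ctotal_max0        # = mmax / T
    return DimensionlessParams(
        # cell diffusion constants D(m) = D0 * m/(m^2 + m1^2) carry a 1/density
        # unit, so the matrix scale cancels: D0bar = D0 / (rate * d^2)
        DS0=p.DS0 / (rate * d2),
        DC0=p.DC0 / (rate * d2),
        # constant diffusivities scale as D * T / d^2
        Dn=p.Dn * T / d2,
        Dm=p.Dm * T / d2,
        Dg=p.Dg * T / d2,
        Db=p.Db * T / d2,
        p10=p.p10 / rate,
        p2=p.p2 * T,
        p3=p.p3 * T,
        p40=p.p40 / rate,
        p400=p.p400 * T,
        p5=p.p5 * T,
        p6=p.p6 * p.mmax / (p.p80 * p.N0),
        p7=p.p7 * p.mmax / (p.p80 * p.N0),
        p81=p.p81 * p.mmax / p.p80,
        p800=p.p800,
        p9=p.p9 * p.mmax / (p.p80 * p.g0),
        p11=p.p11 * T,
        p12=p.p12 * p.mmax / (p.p80 * p.b0),
        p13=p.p13 * T,
        n0=p.n0 / p.N0,
        n1=p.n1 / p.N0,
        CS0_max=p.CS0_max / p.Ctotal_max0,
        CS0_min=p.CS0_min / p.Ctotal_max0,
        alpha=p.alpha * p.b0,
        CS_max0=p.CS_max0 / p.Ctotal_max0,
        CC_max0=p.CC_max0 / p.Ctotal_max0,
        m1=p.m1 / p.mmax,
        m2=p.m2 / p.mmax,
        m3=p.m3 / p.mmax,
        g_init=p.g_init / p.g0,
        b_init=p.b_init / p.b0,
        gamma=p.gamma * T / p.d,
        chi=p.chi * T / p.d,
        CS_init=p.CS_init / p.Ctotal_max0,
        CC_init=p.CC_init / p.Ctotal_max0,
    )


def default_dimensional() -> DimensionalParams:
    """Tabulated dimensional estimates.

    Ranged entries are fixed once: the boundary nutrient reservoir N0 at the
    top of its reported range (9.5e-11 moles/mm^3, giving a Michaelis constant
    of 0.24 in nutrient units), the stem-cell diffusion constant at the top of
    its range (stem-cell fronts move visibly faster than chondrocyte fronts),
    the FGF-1 direct matrix-deposition pre-factor at 0 (its main effect is
    routed through chondrocyte proliferation), and the cell-capacity split at
    60% stem cells / 40% chondrocytes of the total maximum density. The
    differentiation-threshold densities follow the simulated values (0.35 and
    0.315 of the maximum total density).
    """
    Ctot = 1e6
    return DimensionalParams(
        d=2.0,
        DS0=7.2e-8, DC0=7.2e-9,
        Dn=4.6, Dm=2.5e-5, Dg=2e-3, Db=2e-3,
        p10=4e-6, p2=3.75e-3, p3=3.75e-3,
        p40=4e-9, p400=2e-4, p5=3.75e-3,
        p6=1.5e-14, p7=1.5e-14,
        # p81 carries a per-(g/mm^3) unit relative to p80 (the degradation
        # term is p80 - p81*m): p80/mmax makes synthesis stop exactly at mmax
        p80=3.75e-13, p81=3.75e-9, p800=0.0,
        p9=1e-17, p11=5.8e-2, p12=1e-17, p13=5.8e-2,
        gamma=1e-2, chi=1e-2,
        Ctotal_max0=Ctot, CS_max0=0.6 * Ctot, CC_max0=0.4 * Ctot,
        mmax=1e-4, m1=1e-5, m2=1e-5, m3=1e-8,
        N0=9.5e-11, n0=2.3e-11, n1=9.5e-12,
        g0=1e-10, b0=1e-10, g_init=1e-12, b_init=1e-12,
        alpha=1e10,
        CS0_max=0.35 * Ctot, CS0_min=0.315 * Ctot,
        CS_init=2.5e5, CC_init=1e2,
    )


def default_dimensionless() -> DimensionlessParams:
    """Tabulated dimensionless defaults — the parameter set used for all
    reported simulations.

    Values are the published table entries, not recomputations from the
    dimensional set (a few entries differ between the two routes; see
    :func:`nondimensional_discrepancies`). The initial chondrocyte density is
    1e-4, consistent with the simulation narrative (the tabulated "1e4" is a
    typesetting slip: cell fractions cannot exceed 1). Ranged entries are
    fixed at: stem-cell diffusion constant 1e-2 (top of range), nutrient
    diffusivity 3e2 (top of range, matching the dimensional estimate), matrix
    diffusivity 1.67e-3 (the value the dimensional estimates imply, inside
    the reported 1e-3..1e-2 range), and zero direct FGF-1 matrix deposition.
    """
    return DimensionlessParams(
        DS0=1e-2, DC0=1e-3,
        Dn=3e2, Dm=1.67e-3, Dg=1.14, Db=1.14,
        p10=12.0, p2=1.0, p3=1.0,
        p40=0.012, p400=0.012, p5=1.0,
        p6=1e4, p7=1e4,
        p81=1.0, p800=0.0,
        p9=26.67, p11=15.4, p12=26.67, p13=15.4,
        n0=0.24, n1=0.1,
        CS0_max=0.35, CS0_min=0.315, alpha=100.0,
        CS_max0=0.6, CC_max0=0.4,
        m1=0.1, m2=0.1, m3=1e-4,
        g_init=1e-2, b_init=1e-2,
        gamma=1.0, chi=1.0,
        CS_init=0.25, CC_init=1e-4,
    )


def nondimensional_discrepancies(
    p_dim: DimensionalParams | None = None,
    p_ndim: DimensionlessParams | None = None,
    rtol: float = 1e-2,
) -> dict[str, tuple[float, float]]:
    """Fields where non-dimensionalising ``p_dim`` disagrees with ``p_ndim``.

    Returns ``{field: (computed, tabulated)}`` for every field whose relative
    difference exceeds ``rtol``. With the default parameter sets this exposes
    the handful of tabulated dimensionless entries (e.g. the proliferation
    constants and growth-factor diffusivities) that cannot be reproduced from
    the dimensional estimates through the scaling formulas; the tabulated
    values remain authoritative for simulation.
    """
    if p_dim is None:
        p_dim = default_dimensional()
    if p_ndim is None:
        p_ndim = default_dimensionless()
    computed = nondimensionalize(p_dim).to_dict()
    tabulated = p_ndim.to_dict()
    out: dict[str, tuple[float, float]] = {}
    for k, c in computed.items():
        t = tabulated[k]
        scale = max(abs(c), abs(t))
        if scale > 0 and abs(c - t) / scale > rtol:
            out[k] = (c, t)
    return out


#: Units for each DimensionalParams field (parameter-provenance table).
DIMENSIONAL_UNITS: dict[str, str] = {
    "d": "mm",
    "DS0": "(mm^2/h)(g/mm^3)",
    "DC0": "(mm^2/h)(g/mm^3)",
    "Dn": "mm^2/h",
    "Dm": "mm^2/h",
    "Dg": "mm^2/h",
    "Db": "mm^2/h",
    "p10": "(g/mm^3)/h",
    "p2": "1/h",
    "p3": "1/h",
    "p40": "(g/mm^3)/h",
    "p400": "1/h",
    "p5": "1/h",
    "p6": "moles/(cell h)",
    "p7": "moles/(cell h)",
    "p80": "(g/mm^3)/((cells/mm^3) h)",
    "p81": "1/((cells/mm^3) h)",
    "p800": "dimensionless (0-1)",
    "p9": "(g/mm^3)/((cells/mm^3) h)",
    "p11": "1/h",
    "p12": "(g/mm^3)/((cells/mm^3) h)",
    "p13": "1/h",
    "gamma": "mm/h",
    "chi": "mm/h",
    "Ctotal_max0": "cells/mm^3",
    "CS_max0": "cells/mm^3",
    "CC_max0": "cells/mm^3",
    "mmax": "g/mm^3",
    "m1": "g/mm^3",
    "m2": "g/mm^3",
    "m3": "g/mm^3",
    "N0": "moles/mm^3",
    "n0": "moles/mm^3",
    "n1": "moles/mm^3",
    "g0": "g/mm^3",
    "b0": "g/mm^3",
    "g_init": "g/mm^3",
    "b_init": "g/mm^3",
    "alpha": "1/(g/mm^3)",
    "CS0_max": "cells/mm^3",
    "CS0_min": "cells/mm^3",
    "CS_init": "cells/mm^3",
    "CC_init": "cells/mm^3",
}

#: Short description of each DimensionlessParams field.
DIMENSIONLESS_DESCRIPTIONS: dict[str, str] = {
    "DS0": "stem-cell diffusion constant",
    "DC0": "chondrocyte diffusion constant",
    "Dn": "nutrient diffusivity",
    "Dm": "matrix diffusivity",
    "Dg": "FGF-1 diffusivity",
    "Db": "BMP-2 diffusivity",
    "p10": "stem-cell proliferation constant",
    "p2": "stem-cell differentiation rate",
    "p3": "stem-cell death rate",
    "p40": "chondrocyte proliferation constant",
    "p400": "chondrocyte proliferation rate from FGF-1",
    "p5": "chondrocyte death rate",
    "p6": "nutrient uptake constant (stem cells)",
    "p7": "nutrient uptake constant (chondrocytes)",
    "p81": "matrix degradation constant",
    "p800": "FGF-1 direct matrix-deposition pre-factor",
    "p9": "FGF-1 production constant",
    "p11": "FGF-1 degradation rate",
    "p12": "BMP-2 production constant",
    "p13": "BMP-2 degradation rate",
    "n0": "Michaelis-Menten nutrient constant",
    "n1": "critical nutrient concentration",
    "CS0_max": "maximum differentiation-threshold density",
    "CS0_min": "minimum differentiation-threshold density",
    "alpha": "threshold reduction factor",
    "CS_max0": "maximum stem-cell density fraction",
    "CC_max0": "maximum chondrocyte density fraction",
    "m1": "diffusivity reference matrix density",
    "m2": "proliferation reference matrix density",
    "m3": "initial matrix density",
    "g_init": "initial FGF-1 concentration",
    "b_init": "initial BMP-2 concentration",
    "gamma": "FGF-1 boundary flux coefficient",
    "chi": "BMP-2 boundary flux coefficient",
    "CS_init": "implanted stem-cell peak density",
    "CC_init": "initial chondrocyte density",
}
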