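"""Equilibrium in vitro mass-balance model for ionizable organics.

Distributes a nominal medium concentration among the compartments of a
well-plate test system — headspace air, well plastic, medium lipid, medium
protein (serum albumin), bulk water and cells — and returns the freely
dissolved fraction f_free, i.e. the share of chemical actually available
for cellular uptake. At equilibrium the mass fraction of compartment i is

    frac_i = D_i * V_i / sum_j D_j * V_j

with water as the reference phase (D_water = 1); plastic enters through an
area-based sorption coefficient (K_plastic-w in L/m² times exposed area).

Ionization is handled Henderson-Hasselbalch style: the neutral fraction
f_N = 1 / (1 + 10^(pH - pKa)) partitions with the neutral-form coefficients
while the ionic form is penalized (octanol-like phases: 10^-3.5; albumin:
a smaller, specific-binding offset; air: ions are non-volatile). The
regression constants of the phase sub-models live in
:class:`~txqivive.config.MassBalanceConfig` so they can be recalibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MassBalanceConfig

__all__ = [
    "PhysChem",
    "AssaySetup",
    "MassBalanceResult",
    "PFOA",
    "HEPG2_96WELL",
    "neutral_fraction",
    "distribution_ratios",
    "distribute",
    "apply_free_fraction",
]

COMPARTMENTS = ("air", "plastic", "medium_lipid", "medium_protein", "water", "cells")


@dataclass
class PhysChem:
    """Physical-chemical properties of the test chemical."""

    name: str
    mw: float                 # g/mol
    melting_point: float      # °C
    pka: float | None         # monoprotic acid; None = non-ionizable
    log_kow_n: float          # neutral octanol-water partition ratio
    log_kaw_n: float          # neutral air-water partition ratio
    solubility: float         # mg/L

    def __post_init__(self) -> None:
        if self.mw <= 0 or self.solubility <= 0:
            raise ValueError("MW and solubility must be positive")


@dataclass
class AssaySetup:
    """In vitro test-system geometry and composition."""

    well_format: str = "96-well"
    medium_volume: float = 2.0e-4          # L per well
    headspace_volume: float = 1.6e-4       # L per well
    plastic_area: float = 1.1e-4           # m² exposed to medium
    serum_fraction: float = 0.10           # FBS volume fraction of medium
    serum_lipid_fraction: float = 0.0021   # lipid volume fraction of serum
    serum_protein_fraction: float = 0.059  # protein volume fraction of serum
    cell_number: float = 4.0e4             # cells per well
    cell_volume: float = 2.43e-12          # L per cell
    cell_lipid_fraction: float = 0.02
    cell_protein_fraction: float = 0.20
    ph: float = 7.4
    temperature: float = 310.15            # K

    def __post_init__(self) -> None:
        for name in (
            "medium_volume", "headspace_volume", "plastic_area",
            "serum_fraction", "serum_lipid_fraction",
            "serum_protein_fraction", "cell_number", "cell_volume",
            "cell_lipid_fraction", "cell_protein_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "serum_fraction", "serum_lipid_fraction",
            "serum_protein_fraction", "cell_lipid_fraction",
            "cell_protein_fraction",
        ):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} is a fraction and must be <= 1")
        if not 0 <= self.ph <= 14:
            raise ValueError("pH must lie in [0, 14]")


@dataclass
class MassBalanceResult:
    """Equilibrium mass fractions and the freely dissolved outcome."""

    fractions: dict                     # compartment -> mass fraction
    f_free: float                       # = water fraction
    nominal: np.ndarray                 # µM, as supplied
    free: np.ndarray                    # µM, full precision
    free_rounded: np.ndarray            # µM, reporting precision
    ratios: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nominal_uM": self.nominal,
                "free_uM": self.free,
                "free_uM_rounded": self.free_rounded,
            }
        )


# EPI-Suite-style property set for perfluorooctanoic acid
PFOA = PhysChem(
    name="PFOA",
    mw=414.07,
    melting_point=54.3,
    pka=2.8,
    log_kow_n=6.30,
    log_kaw_n=-2.10,
    solubility=9500.0,
)

# 96-well HepG2 screening assay parameterization (ToxCast-style)
HEPG2_96WELL = AssaySetup()


def neutral_fraction(pka: float | None, ph: float) -> float:
    """Neutral fraction of a monoprotic acid at the given pH."""
    if pka is None:
        return 1.0
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def distribution_ratios(
    chem: PhysChem,
    ph: float = 7.4,
    temperature: float = 310.15,
    config: MassBalanceConfig | None = None,
) -> dict[str, float]:
    """Effective (ionization-corrected) partition ratios vs water.

    Returns D_OW, D_AW, D_lipid_w, D_protein_w, D_cell components and the
    plastic sorption coefficient K_plastic_w (L/m²). The ionic form
    partitions into octanol-like phases ``ion_logkow_offset`` log units
    below the neutral form and is non-volatile; albumin binds the ion with
    its own, smaller offset (perfluoroalkyl acid anions bind albumin
    specifically).
    """
    cfg = config or MassBalanceConfig()
    f_n = neutral_fraction(chem.pka, ph)
    kow_n = 10.0 ** chem.log_kow_n
    kaw_n = 10.0 ** chem.log_kaw_n
    ion_penalty = 10.0 ** cfg.ion_logkow_offset
    d_ow = f_n * kow_n + (1.0 - f_n) * kow_n * ion_penalty
    d_aw = f_n * kaw_n
    d_lipid = d_ow
    k_prot_neutral = 10.0 ** (
        cfg.protein_slope * chem.log_kow_n + cfg.protein_intercept
    )
    d_protein = f_n * k_prot_neutral + (1.0 - f_n) * k_prot_neutral * (
        10.0 ** cfg.ion_albumin_offset
    )
    k_plastic = 10.0 ** (
        cfg.plastic_slope * chem.log_kow_n + cfg.plastic_intercept
    )
    return {
        "D_OW": d_ow,
        "D_AW": d_aw,
        "D_lipid_w": d_lipid,
        "D_protein_w": d_protein,
        "K_plastic_w": k_plastic,   # L/m², area-normalized
        "f_neutral": f_n,
    }


def _subcooled_solubility(chem: PhysChem, temperature: float) -> float:
    """Subcooled-liquid solubility cap (mg/L) via the melting-point
    correction exp(6.79 * (1 - Tm/T)) for solids."""
    tm = chem.melting_point + 273.15
    if tm <= temperature:
        return chem.solubility
    return chem.solubility * np.exp(6.79 * (1.0 - tm / temperature))


def distribute(
    nominal_conc: float | np.ndarray,
    chem: PhysChem,
    setup: AssaySetup | None = None,
    config: MassBalanceConfig | None = None,
) -> MassBalanceResult:
    """Partition nominal medium concentration(s) (µM) over the test system.

    The free fraction is concentration-independent in the linear
    (below-solubility) regime; nominal concentrations above the
    melting-point-corrected solubility are capped with a warning.
    """
    cfg = config or MassBalanceConfig()
    setup = setup or HEPG2_96WELL
    nominal = np.atleast_1d(np.asarray(nominal_conc, dtype=float))
    if (nominal < 0).any():
        raise ValueError("nominal concentrations must be non-negative")

    ratios = distribution_ratios(chem, setup.ph, setup.temperature, cfg)
    serum_vol = setup.medium_volume * setup.serum_fraction
    v_lipid = serum_vol * setup.serum_lipid_fraction
    v_protein = serum_vol * setup.serum_protein_fraction
    v_water = setup.medium_volume - v_lipid - v_protein
    v_cells = setup.cell_number * setup.cell_volume
    d_cell = (
        setup.cell_lipid_fraction * ratios["D_lipid_w"]
        + setup.cell_protein_fraction * ratios["D_protein_w"]
    )

    capacity = {
        "air": ratios["D_AW"] * setup.headspace_volume,
        "plastic": ratios["K_plastic_w"] * setup.plastic_area,
        "medium_lipid": ratios["D_lipid_w"] * v_lipid,
        "medium_protein": ratios["D_protein_w"] * v_protein,
        "water": 1.0 * v_water,
        "cells": d_cell * v_cells,
    }
    total = sum(capacity.values())
    if total <= 0:
        raise ValueError("all compartment capacities are zero")
    fractions = {k: v / total for k, v in capacity.items()}
    f_free = fractions["water"]

    sol_um = _subcooled_solubility(chem, setup.temperature) / chem.mw * 1000.0
    capped = np.minimum(nominal, sol_um)
    if (capped < nominal).any():
        import warnings

        warnings.warn(
            "nominal concentration exceeds (subcooled) solubility; capped",
            stacklevel=2,
        )
    free = apply_free_fraction(capped, f_free, decimals=None)
    free_rounded = apply_free_fraction(capped, f_free, decimals=cfg.report_decimals)
    return MassBalanceResult(
        fractions=fractions,
        f_free=f_free,
        nominal=nominal,
        free=free,
        free_rounded=free_rounded,
        ratios=ratios,
    )


def apply_free_fraction(
    nominal: float | np.ndarray,
    f_free: float,
    decimals: int | None = None,
) -> np.ndarray:
    """Elementwise free concentration = nominal × f_free (µM); ``decimals``
    applies the reporting precision (full precision when None)."""
    if not 0 < f_free <= 1:
        raise ValueError("f_free must lie in (0, 1]")
    nominal = np.atleast_1d(np.asarray(nominal, dtype=float))
    if (nominal < 0).any():
        raise ValueError("nominal concentrations must be non-negative")
    free = nominal * f_free
    if decimals is not None:
        free = np.round(free, decimals)
    return free
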