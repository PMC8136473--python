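"""Asbestos-body burden: densities per cm³ and conversion to AB per g dry lung.

The field's standard burden unit is AB per gram of dry lung tissue
(g_dw⁻¹).  A count N_c in a probed formalin-fixed paraffin-embedded tissue
volume V_c converts as

    N_gdw = (N_c / V_c) × D_dw / (V_s × O_c × R_wv)

with V_s the fixed→embedded volumetric shrinkage factor (2.3), R_wv the wet
weight per unit fixed-tissue volume (0.916 g/cm³), D_dw the wet-to-dry mass
ratio (≈ 10, measured per sample by drying), and O_c an orientation
correction needed only when counting on thin 2D sections — for a full 3D
tomographic count O_c is exactly 1.  (The classical formula is sometimes
typeset with D_dw folded into a single fraction; the form above is the one
consistent dimensionally and with published burden tables.)

The European Respiratory Society threshold of 10³ AB/g_dw marks a high
level of occupational asbestos exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConversionFactors",
    "BurdenResult",
    "ERS_THRESHOLD_GDW",
    "count_density",
    "orientation_correction",
    "convert_to_gdw",
    "compute_ddw",
    "classify_exposure",
    "summarize_burden",
]

#: European Respiratory Society marker of high occupational exposure (AB/g_dw)
ERS_THRESHOLD_GDW = 1e3


@dataclass(frozen=True)
class ConversionFactors:
    """Stereological factors of the burden conversion.

    v_s : volumetric shrinkage, formalin-fixed → paraffin-embedded (2.3).
    r_wv : wet weight to fixed-tissue volume ratio, g/cm³ (0.916).
    d_dw : wet-to-dry weight conversion factor (≈ 10).
    o_c : orientation correction, ≥ 1; exactly 1 for 3D volume counts.
    """

    v_s: float = 2.3
    r_wv: float = 0.916
    d_dw: float = 10.0
    o_c: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v_s", "r_wv", "d_dw", "o_c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.o_c < 1.0:
            raise ValueError("o_c must be >= 1 (no correction can inflate a 3D count)")


@dataclass
class BurdenResult:
    """Replicate densities with summary statistics and the converted burden."""

    densities_cm3: tuple[float, ...]
    mean_cm3: float
    sd_cm3: float | None  # None for a single replicate
    n_replicates: int
    n_gdw: float | None = None
    exceeds_ers: bool | None = None

    def to_dict(self) -> dict:
        return {
            "densities_per_cm3": list(self.densities_cm3),
            "mean_per_cm3": self.mean_cm3,
            "sd_per_cm3": self.sd_cm3,
            "n_replicates": self.n_replicates,
            "n_gdw": self.n_gdw,
            "exceeds_ers": self.exceeds_ers,
        }


def count_density(counts: Sequence[float], volumes_cm3: Sequence[float]) -> BurdenResult:
    """Per-replicate densities N_c/V_c with mean and sample SD (n−1).

    ``counts`` and ``volumes_cm3`` are parallel per-replicate lists; three
    replicate volumes per sample is the typical design, and the spread
    between them reflects the heterogeneity of AB deposition in the lung.
    """
    counts = list(counts)
    volumes = list(volumes_cm3)
    if not counts:
        raise ValueError("need at least one replicate")
    if len(counts) != len(volumes):
        raise ValueError(f"{len(counts)} counts but {len(volumes)} volumes")
    if any(v <= 0 for v in volumes):
        raise ValueError("every probed volume must be positive")
    dens = tuple(c / v for c, v in zip(counts, volumes))
    mean = float(np.mean(dens))
    sd = float(np.std(dens, ddof=1)) if len(dens) > 1 else None
    return BurdenResult(
        densities_cm3=dens, mean_cm3=mean, sd_cm3=sd, n_replicates=len(dens)
    )


def orientation_correction(mean_length_um: float, section_thickness_um: float = math.inf) -> float:
    """Orientation correction factor O_c for section-based counting.

    A fibre of length L uniformly oriented in space intersects a section of
    thickness T with probability proportional to T + L·E|cosθ|, and
    E|cosθ| = 1/2 for orientations uniform on the sphere; a naive per-section
    density therefore overcounts by O_c = 1 + L/(2T).  For a true 3D volume
    (T → ∞) the factor is exactly 1, independent of fibre length.
    """
    if mean_length_um < 0:
        raise ValueError("mean length must be non-negative")
    if math.isinf(section_thickness_um):
        return 1.0
    if section_thickness_um <= 0:
        raise ValueError("section thickness must be positive (or infinite)")
    return 1.0 + mean_length_um / (2.0 * section_thickness_um)


def convert_to_gdw(density_cm3: float, factors: ConversionFactors | None = None) -> float:
    """Convert a volumetric density (AB/cm³) to AB per gram of dry tissue."""
    if density_cm3 < 0:
        raise ValueError("density must be non-negative")
    f = factors or ConversionFactors()
    return density_cm3 * f.d_dw / (f.v_s * f.o_c * f.r_wv)


def compute_ddw(wet_mass_g: float, dry_mass_g: float) -> float:
    """Wet-to-dry conversion factor D_dw = wet mass / dry mass."""
    if dry_mass_g <= 0:
        raise ValueError("dry mass must be positive")
    if wet_mass_g < dry_mass_g:
        raise ValueError("wet mass cannot be below dry mass")
    return wet_mass_g / dry_mass_g


def classify_exposure(n_gdw: float, threshold: float = ERS_THRESHOLD_GDW) -> bool:
    """True when the burden exceeds the high-occupational-exposure marker."""
    if n_gdw < 0:
        raise ValueError("burden must be non-negative")
    return n_gdw > threshold


def summarize_burden(
    counts: Sequence[float],
    volumes_cm3: Sequence[float],
    factors: ConversionFactors | None = None,
) -> BurdenResult:
    """count_density → convert_to_gdw → ERS flag, in one call."""
    result = count_density(counts, volumes_cm3)
    result.n_gdw = convert_to_gdw(result.mean_cm3, factors)
    result.exceeds_ers = classify_exposure(result.n_gdw)
    return result
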