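"""Mixed-layer depth, stratification index and upper-mixed-layer averages.

CTD-style casts are coarse (bottle depths at 10-25 m spacing), so all
between-depth values come from linear interpolation and upper-mixed-layer
averages are plain unweighted means over the sampled depths inside the
layer.

Mixed-layer depth follows the density-threshold rule: the shallowest
depth at which a >= 0.05 kg m^-3 density increase over the 5 m above is
first observed.  A cast with no such crossing is, by convention, mixed
down to its deepest sampled depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Profile",
    "UmlSummary",
    "mixed_layer_depth",
    "stratification_index",
    "uml_average",
    "summarize_cast",
]

DEFAULT_MLD_THRESHOLD = 0.05  # kg m^-3
DEFAULT_MLD_SPAN = 5.0  # m
DEFAULT_SI_REFERENCE_DEPTH = 75.0  # m
SURFACE_MAX_DEPTH = 5.0  # m; shallowest sample must be at or above this


@dataclass
class Profile:
    """Depth-indexed cast: temperature, density (sigma-t acceptable) and
    optional per-depth extra variables (e.g. bacterial abundance)."""

    depth_m: np.ndarray
    temperature_C: np.ndarray
    density_kg_m3: np.ndarray
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.density_kg_m3 = np.asarray(self.density_kg_m3, dtype=float)
        if self.depth_m.size < 2:
            raise ValueError("a cast needs at least 2 depth levels")
        if np.any(self.depth_m < 0):
            raise ValueError("depths must be non-negative")
        if np.any(np.diff(self.depth_m) <= 0):
            raise ValueError("depth grid must be strictly increasing")
        for name, arr in list(self.extras.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.size != self.depth_m.size:
                raise ValueError(f"extra variable {name!r} length mismatch")
            self.extras[name] = arr
        for arr in (self.temperature_C, self.density_kg_m3):
            if arr.size != self.depth_m.size:
                raise ValueError("temperature/density length mismatch with depth")

    def variable(self, name: str) -> np.ndarray:
        if name == "temperature":
            return self.temperature_C
        if name == "density":
            return self.density_kg_m3
        if name in self.extras:
            return self.extras[name]
        raise KeyError(f"no variable {name!r} in cast")


@dataclass
class UmlSummary:
    mld_m: float
    stratification_index_C_m: float
    uml_means: dict[str, float]


def mixed_layer_depth(
    profile: Profile,
    threshold: float = DEFAULT_MLD_THRESHOLD,
    span: float = DEFAULT_MLD_SPAN,
) -> float:
    """Shallowest depth z with density(z) - density(z - span) >= threshold.

    Density at z - span is linearly interpolated; candidate z values are
    the sampled depths at least ``span`` below the shallowest sample.
    Returns the deepest sampled depth when no crossing exists.
    """
    z = profile.depth_m
    rho = profile.density_kg_m3
    ok = np.isfinite(rho)
    z, rho = z[ok], rho[ok]
    if z.size < 2:
        raise ValueError("unusable cast: fewer than two density levels")
    if z[-1] - z[0] < span:
        raise ValueError(f"cast spans less than {span} m of density data")
    candidates = z[z >= z[0] + span]
    rho_above = np.interp(candidates - span, z, rho)
    rho_at = np.interp(candidates, z, rho)
    crossing = rho_at - rho_above >= threshold
    if crossing.any():
        return float(candidates[np.argmax(crossing)])
    return float(z[-1])


def stratification_index(
    profile: Profile, reference_depth: float = DEFAULT_SI_REFERENCE_DEPTH
) -> float:
    """(T_surface - T_reference) / reference_depth, in deg C per metre.

    Surface temperature is the shallowest sample, which must lie within
    the top 5 m; winter inversions give negative values.
    """
    z = profile.depth_m
    T = profile.temperature_C
    if z[0] > SURFACE_MAX_DEPTH:
        raise ValueError(
            f"no surface sample: shallowest depth {z[0]:g} m > {SURFACE_MAX_DEPTH} m"
        )
    if z[-1] < reference_depth:
        raise ValueError(
            f"cast too shallow for stratification index: {z[-1]:g} m < {reference_depth} m"
        )
    t_ref = float(np.interp(reference_depth, z, T))
    return (float(T[0]) - t_ref) / reference_depth


def uml_average(profile: Profile, mld: float, variable: str) -> float:
    """Unweighted mean of a cast variable over sampled depths <= mld."""
    if mld <= 0:
        raise ValueError("mixed-layer depth must be positive")
    values = profile.variable(variable)
    sel = (profile.depth_m <= mld) & np.isfinite(values)
    if not sel.any():
        raise ValueError(f"no sampled depth within the mixed layer (mld={mld:g} m)")
    return float(values[sel].mean())


def summarize_cast(
    profile: Profile,
    variables: list[str] | None = None,
    threshold: float = DEFAULT_MLD_THRESHOLD,
    span: float = DEFAULT_MLD_SPAN,
    reference_depth: float = DEFAULT_SI_REFERENCE_DEPTH,
) -> UmlSummary:
    """Derive mld, stratification index and UML means in one pass."""
    mld = mixed_layer_depth(profile, threshold=threshold, span=span)
    si = stratification_index(profile, reference_depth=reference_depth)
    if variables is None:
        variables = ["temperature", "density", *profile.extras.keys()]
    means = {v: uml_average(profile, mld, v) for v in variables}
    return UmlSummary(mld_m=mld, stratification_index_C_m=si, uml_means=means)
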