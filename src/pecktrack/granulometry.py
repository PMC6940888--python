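"""Feed-particle granulometry from sieve analysis.

Feed particle size is characterised by the geometric mean diameter (GMD) and
geometric standard deviation (GSD) of the mass retained on a stack of sieves
with descending apertures, the standard feed-science summary (log-normal in
spirit): with mass W_i retained in the class of mean diameter d_i,

    GMD = 10 ** (sum W_i log10 d_i / sum W_i)
    GSD = 10 ** sqrt(sum W_i (log10 d_i - log10 GMD)^2 / sum W_i)

The class mean diameter is the geometric mean of the two adjacent sieve
apertures; the pan class pairs the finest aperture with a configurable floor
(default 38 um), and the topmost sieve pairs its aperture with sqrt(2) times
itself (the usual sieve-ratio convention), also configurable.  GMD is
invariant to the logarithm base; GSD is defined as 10**(log10 sd) so a
single-class stack gives GSD exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SieveStack", "gmd_gsd", "gmd_gsd_from_classes"]

SQRT2 = math.sqrt(2.0)


@dataclass
class SieveStack:
    """Sieve apertures (um, strictly descending), retained masses (g), pan mass."""

    apertures_um: np.ndarray
    masses_g: np.ndarray
    pan_mass_g: float = 0.0
    pan_floor_um: float = 38.0
    top_factor: float = SQRT2

    def __post_init__(self) -> None:
        self.apertures_um = np.asarray(self.apertures_um, float)
        self.masses_g = np.asarray(self.masses_g, float)
        if self.apertures_um.ndim != 1 or self.apertures_um.size == 0:
            raise ValueError("need at least one sieve")
        if self.apertures_um.shape != self.masses_g.shape:
            raise ValueError("one retained mass per sieve required")
        if not np.all(np.diff(self.apertures_um) < 0):
            raise ValueError("apertures must be strictly descending")
        if np.any(self.apertures_um <= 0):
            raise ValueError("apertures must be positive")
        if np.any(self.masses_g < 0) or self.pan_mass_g < 0:
            raise ValueError("masses must be nonnegative")
        if self.masses_g.sum() + self.pan_mass_g <= 0:
            raise ValueError("total mass must be positive")
        if self.top_factor <= 1.0:
            raise ValueError("top_factor must exceed 1")

    def class_diameters_um(self) -> np.ndarray:
        """Geometric-mean class diameters, sieves top to bottom then pan."""
        a = self.apertures_um
        upper = np.concatenate([[a[0] * self.top_factor], a[:-1]])
        d = np.sqrt(upper * a)
        if self.pan_mass_g > 0:
            if self.pan_floor_um <= 0:
                raise ValueError(
                    "pan holds mass but pan_floor_um is not positive: class "
                    "diameter undefined"
                )
            d = np.append(d, math.sqrt(a[-1] * self.pan_floor_um))
        return d

    def class_masses_g(self) -> np.ndarray:
        m = self.masses_g
        if self.pan_mass_g > 0:
            m = np.append(m, self.pan_mass_g)
        return m

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SieveStack":
        """Two-column CSV (aperture_um, mass_g); aperture 0 denotes the pan."""
        df = pd.read_csv(path)
        cols = [c.strip() for c in df.columns]
        df.columns = cols
        ap = df["aperture_um"].to_numpy(float)
        ms = df["mass_g"].to_numpy(float)
        pan = float(ms[ap == 0].sum())
        keep = ap > 0
        order = np.argsort(-ap[keep])
        return cls(ap[keep][order], ms[keep][order], pan_mass_g=pan, **kwargs)


def gmd_gsd_from_classes(diameters_um, masses) -> tuple[float, float]:
    """GMD (um) and GSD from explicit class mean diameters and mass weights."""
    d = np.asarray(diameters_um, float)
    w = np.asarray(masses, float)
    occupied = w > 0
    if not occupied.any():
        raise ValueError("no occupied size class")
    if np.any(d[occupied] <= 0):
        raise ValueError("occupied class with nonpositive diameter")
    d, w = d[occupied], w[occupied]
    logs = np.log10(d)
    mean_log = float(np.sum(w * logs) / np.sum(w))
    var_log = float(np.sum(w * (logs - mean_log) ** 2) / np.sum(w))
    return 10.0**mean_log, 10.0 ** math.sqrt(var_log)


def gmd_gsd(stack: SieveStack) -> tuple[float, float]:
    """Geometric mean diameter (um) and geometric standard deviation of a
    sieve stack.  Doubling every mass leaves both unchanged; GSD >= 1 always,
    with equality for a single occupied class."""
    return gmd_gsd_from_classes(stack.class_diameters_um(), stack.class_masses_g())
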