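"""Parameter containers for the vascular tumour growth model.

The model is dimensionless throughout: tumour cell density ``p`` is measured
in units of ``K_delta * V0`` (the cell-per-vessel ratio at half-maximal
occlusion times the vascular carrying capacity), vessel density ``v`` in
units of ``V0``, oxygen ``s`` in units of the blood oxygen level ``s_b``,
time in units of the inverse maximal proliferation rate ``1/beta`` and space
in units of ``sqrt(D_p/beta)``.  Hence the tumour-cell motility is 1 and all
other diffusivities are relative to it.

Two parameterisations of the oxygen kinetics coexist:

* the *full* model carries ``ds`` (background consumption), ``sigmap``
  (tumour consumption) and the vascular exchange coefficient ``hs``;
* the *reduced* (quasi-steady oxygen) model only needs the groupings
  ``ds_tilde = ds/hs`` and ``sigmap_tilde = sigmap/hs``.

``Params`` stores both groups; the reduced values may be given directly
(as in the spatially homogeneous phase-plane studies) or derived from the
full-model values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional


__all__ = ["Params", "ScalingAnchors", "DoseSchedule"]


@dataclass
class Params:
    """Dimensionless model constants.

    Parameters
    ----------
    eta0 : float
        Maximum vessel proliferation rate (logistic growth rate of ``v``).
    dp : float
        Tumour apoptosis rate.
    delta : float
        Maximum vessel occlusion rate; the per-vessel occlusion rate is
        half-maximal (``delta/2``) when ``p/v == 1`` in dimensionless units.
    sbeta : float
        Oxygen level of half-maximal tumour proliferation.
    ds_tilde, sigmap_tilde : float, optional
        Reduced-model oxygen groupings (background and tumour consumption
        relative to vascular exchange).  Derived from ``ds/hs`` and
        ``sigmap/hs`` when not given explicitly.
    ds, sigmap, hs, Ds : float, optional
        Full-model oxygen kinetics: background decay, tumour consumption,
        vascular exchange coefficient and oxygen diffusivity.
    Dv : float
        Vessel (endothelial cell) diffusivity relative to tumour cells.
    Dc, hc, dc, Kc, k : float
        Drug transport and kinetics: tissue diffusivity, vascular exchange,
        tissue decay, concentration of half-maximal kill, and plasma decay
        rate.
    """

    eta0: float
    dp: float
    delta: float
    sbeta: float
    ds_tilde: Optional[float] = None
    sigmap_tilde: Optional[float] = None
    ds: Optional[float] = None
    sigmap: Optional[float] = None
    hs: Optional[float] = None
    Ds: Optional[float] = None
    Dv: float = 1.0
    Dc: float = 0.0
    hc: float = 0.0
    dc: float = 0.0
    Kc: float = 0.05
    k: float = 0.9

    def __post_init__(self) -> None:
        for name in ("eta0", "dp", "delta", "sbeta", "Dv", "Dc", "hc",
                     "dc", "Kc", "k"):
            val = getattr(self, name)
            if val < 0:
                raise ValueError(f"{name} must be nonnegative, got {val}")
        for name in ("ds_tilde", "sigmap_tilde", "ds", "sigmap", "hs", "Ds"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValueError(f"{name} must be nonnegative, got {val}")
        if self.Dv <= 0:
            raise ValueError("Dv must be positive")

    @property
    def ds_t(self) -> float:
        """Reduced-model background oxygen consumption ``ds/hs``."""
        if self.ds_tilde is not None:
            return self.ds_tilde
        if self.ds is not None and self.hs:
            return self.ds / self.hs
        raise ValueError("neither ds_tilde nor (ds, hs) is set")

    @property
    def sigmap_t(self) -> float:
        """Reduced-model tumour oxygen consumption ``sigmap/hs``."""
        if self.sigmap_tilde is not None:
            return self.sigmap_tilde
        if self.sigmap is not None and self.hs:
            return self.sigmap / self.hs
        raise ValueError("neither sigmap_tilde nor (sigmap, hs) is set")

    @property
    def coexistence_possible(self) -> bool:
        """Existence condition for a positive steady state: the apoptosis
        rate must be below the maximal proliferation rate ``1/(1+sbeta)``."""
        return self.dp < 1.0 / (1.0 + self.sbeta)

    def with_(self, **kwargs) -> "Params":
        """Copy with fields replaced."""
        return replace(self, **kwargs)


@dataclass
class ScalingAnchors:
    """Dimensional anchors for converting model units to cm and days.

    The nondimensionalisation absorbs the dimensional scales (beta, V0,
    K_delta, s_b, D_p), which are not independently known here; the defaults
    are derived from printed figure annotations (82.15 space units = 0.29 cm
    and 100 time units = about 145 days) and are flagged as such.
    """

    days_per_time_unit: float = 1.45
    cm_per_space_unit: float = 3.53e-3
    provenance: dict = field(default_factory=lambda: {
        "days_per_time_unit": "caption-derived",
        "cm_per_space_unit": "caption-derived",
    })

    def __post_init__(self) -> None:
        if self.days_per_time_unit <= 0 or self.cm_per_space_unit <= 0:
            raise ValueError("scaling anchors must be positive")

    def speed_cm_per_day(self, speed_dimensionless: float) -> float:
        return speed_dimensionless * self.cm_per_space_unit / self.days_per_time_unit

    def length_cm(self, x_dimensionless: float) -> float:
        return x_dimensionless * self.cm_per_space_unit

    def time_days(self, t_dimensionless: float) -> float:
        return t_dimensionless * self.days_per_time_unit


@dataclass
class DoseSchedule:
    """Plasma drug input: none, a single bolus, or periodic boluses.

    After each injection the plasma concentration decays exponentially at
    rate ``k`` (one-compartment pharmacokinetics).  For a periodic schedule
    the concentration regains ``c_init`` at each injection; this presumes
    the half-life ``ln 2 / k`` is short compared with the inter-bolus period
    ``T_per`` (a warning is issued otherwise).
    """

    mode: str = "none"
    c_init: float = 1.0
    k: float = 0.9
    T_per: float = 10.0
    n_boluses: int = 4
    t_start: float = 200.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "single", "periodic"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.c_init < 0:
            raise ValueError("c_init must be nonnegative")
        if self.mode != "none" and self.k <= 0:
            raise ValueError("plasma decay rate k must be positive")
        if self.mode == "periodic":
            if self.T_per <= 0 or self.n_boluses < 1:
                raise ValueError("periodic schedule needs T_per > 0 and "
                                 "n_boluses >= 1")
            half_life = math.log(2.0) / self.k
            if half_life > 0.5 * self.T_per:
                warnings.warn(
                    f"drug half-life {half_life:.3g} is not small compared "
                    f"with the bolus period {self.T_per:.3g}; residual drug "
                    "will accumulate between boluses", stacklevel=2)

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.k if self.k > 0 else math.inf

    def bolus_times(self) -> list[float]:
        """Injection times (discontinuities of the plasma concentration)."""
        if self.mode == "single":
            return [self.t_start]
        if self.mode == "periodic":
            return [self.t_start + j * self.T_per for j in range(self.n_boluses)]
        return []

    def concentration(self, t):
        """Plasma concentration c_b(t); vectorised over ``t``.

        Right-continuous at bolus times (the concentration jumps to
        ``c_init`` at each injection).
        """
        import numpy as np

        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be nonnegative")
        out = np.zeros_like(t)
        if self.mode == "none":
            return out if out.ndim else float(out)
        tau = t - self.t_start
        active = tau >= 0
        if self.mode == "single":
            out[active] = self.c_init * np.exp(-self.k * tau[active])
        else:
            # modulo T_per while boluses remain, exponential tail afterwards
            j = np.minimum(np.floor_divide(tau, self.T_per),
                           self.n_boluses - 1)
            out[active] = self.c_init * np.exp(
                -self.k * (tau[active] - j[active] * self.T_per))
        return out if out.ndim else float(out)
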