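"""Single-shell dielectric model and the Clausius-Mossotti factor.

A cell is modelled as a conducting cytoplasmic sphere wrapped in a thin,
poorly conducting membrane shell, suspended in a low-conductivity aqueous
medium.  The real part of the Clausius-Mossotti (CM) factor,

    Re[CM](w) = Re[(e*_p - e*_m) / (e*_p + 2 e*_m)],   e* = e - j s / w,

sets the sign and magnitude of the time-averaged DEP force: positive values
mean attraction toward high-field regions (pDEP), negative values repulsion
toward low-field regions (nDEP).  The crossover frequency f_co is the root
of Re[CM].  Re[CM] is bounded in [-0.5, 1] for any passive material pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["ShellModel", "re_cm_single_shell", "crossover_frequency", "EPS0"]

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m


@dataclass(frozen=True)
class ShellModel:
    """Single-shell cell parameters.

    Defaults approximate an MCF-7 breast-cancer cell (19 um diameter) in a
    sucrose/glucose DEP buffer of ~60 uS/cm conductivity: thin insulating
    membrane over a conductive cytoplasm.  All parameters must be positive
    and the membrane must be thin relative to the cell radius.
    """

    r_cell: float = 9.5e-6          # m
    membrane_thickness: float = 7e-9  # m
    eps_mem: float = 7.0            # relative permittivity of membrane
    eps_cyto: float = 60.0          # relative permittivity of cytoplasm
    eps_medium: float = 78.0        # relative permittivity of medium
    sigma_mem: float = 1e-7         # S/m
    sigma_cyto: float = 0.5         # S/m
    sigma_medium: float = 6e-3      # S/m (~60 uS/cm)
    eta: float = 1.0e-3             # medium viscosity, Pa*s

    def __post_init__(self) -> None:
        for name in (
            "r_cell",
            "membrane_thickness",
            "eps_mem",
            "eps_cyto",
            "eps_medium",
            "sigma_cyto",
            "sigma_medium",
            "eta",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_mem < 0:
            raise ValueError("sigma_mem must be non-negative")
        if self.membrane_thickness >= 0.2 * self.r_cell:
            raise ValueError("membrane_thickness must be small relative to r_cell")

    @property
    def membrane_capacitance(self) -> float:
        """Specific membrane capacitance C_mem = eps0*eps_mem/d (F/m^2)."""
        return EPS0 * self.eps_mem / self.membrane_thickness


def _complex_eps(eps_rel: float, sigma: float, omega: np.ndarray) -> np.ndarray:
    return eps_rel * EPS0 - 1j * sigma / omega


def re_cm_single_shell(model: ShellModel, f) -> float | np.ndarray:
    """Real part of the CM factor of a single-shell sphere at frequency ``f`` (Hz).

    The shelled sphere is collapsed to an equivalent homogeneous particle with

        e*_p = e*_mem * (a^3 + 2 K) / (a^3 - K),
        K = (e*_cyto - e*_mem) / (e*_cyto + 2 e*_mem),
        a = r_cell / (r_cell - d_mem),

    which is then inserted into the CM expression against the medium.
    Raises ``ValueError`` for non-positive frequencies.
    """
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any(f_arr <= 0):
        raise ValueError("frequency must be positive")
    omega = 2 * np.pi * f_arr
    e_mem = _complex_eps(model.eps_mem, model.sigma_mem, omega)
    e_cyto = _complex_eps(model.eps_cyto, model.sigma_cyto, omega)
    e_med = _complex_eps(model.eps_medium, model.sigma_medium, omega)
    a = model.r_cell / (model.r_cell - model.membrane_thickness)
    k = (e_cyto - e_mem) / (e_cyto + 2 * e_mem)
    e_p = e_mem * (a**3 + 2 * k) / (a**3 - k)
    cm = (e_p - e_med) / (e_p + 2 * e_med)
    out = cm.real
    return out if np.ndim(f) else float(out[0])


def crossover_frequency(
    model: ShellModel, f_lo: float = 1e3, f_hi: float = 1e7
) -> float:
    """First zero of Re[CM] in ``[f_lo, f_hi]`` by bracketed root finding.

    Scans a dense log-spaced grid for the first sign change and refines it
    with Brent's method.  Raises ``ValueError`` when no sign change exists in
    the window (e.g. the medium is more polarizable at every frequency).
    """
    grid = np.logspace(np.log10(f_lo), np.log10(f_hi), 2000)
    vals = re_cm_single_shell(model, grid)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError("Re[CM] has no zero crossing in the given window")
    i = sign_change[0]
    return brentq(lambda f: re_cm_single_shell(model, f), grid[i], grid[i + 1])
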