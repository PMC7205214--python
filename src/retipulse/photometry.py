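"""Beer-Lambert photometry: transmittance, absorbance and nominal path length.

Green-channel fundus intensity is treated as a transmittance-like signal at
the hemoglobin isosbestic point (~550 nm), where oxy- and deoxyhemoglobin
absorb equally.  Absorbance A = -ln T is proportional to the product of the
extinction coefficient, hemoglobin concentration, and the optical path length
through the blood column, so changes in A track changes in vessel blood
volume over the cardiac cycle.

The path length returned here is *nominal*: the conversion chain assumes a
single wavelength, a uniform absorber, and (for reflectance imaging) a double
pass through the vessel.  It has not been calibrated against real vessel
dimensions; values are meaningful only relatively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "PhotometryConstants",
    "transmittance_to_absorbance",
    "absorbance_to_path_length",
]


@dataclass(frozen=True)
class PhotometryConstants:
    """Physical constants for the absorbance -> path-length conversion.

    Attributes
    ----------
    epsilon : float
        Hemoglobin extinction coefficient at the isosbestic wavelength,
        L/mmol/cm. Default 12 (550 nm, oxy == deoxy).
    hb_conc_g_per_l : float
        Hemoglobin mass concentration in whole blood, g/L. Default 150.
    hb_molar_mass_g_per_mol : float
        Hemoglobin molar mass, g/mol. Default 64,500.
    reflectance_double_pass : bool
        If True (default), light is assumed reflected back through the same
        vessel, doubling the optical path; the inferred single-pass length is
        therefore halved.
    nominal_units : bool
        Flag carried through to outputs signalling that path lengths are
        nominal (uncalibrated) micrometers.
    """

    epsilon: float = 12.0
    hb_conc_g_per_l: float = 150.0
    hb_molar_mass_g_per_mol: float = 64_500.0
    reflectance_double_pass: bool = True
    nominal_units: bool = True

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")
        if self.hb_conc_g_per_l <= 0:
            raise ConfigurationError("hb_conc_g_per_l must be > 0")
        if self.hb_molar_mass_g_per_mol <= 0:
            raise ConfigurationError("hb_molar_mass_g_per_mol must be > 0")

    @property
    def hb_conc_mmol_per_l(self) -> float:
        """Molar hemoglobin concentration, mmol/L."""
        return 1000.0 * self.hb_conc_g_per_l / self.hb_molar_mass_g_per_mol


def transmittance_to_absorbance(T):
    """Absorbance A = -ln(T) for transmittance ``T`` in (0, 1].

    Accepts scalars or arrays; raises :class:`DomainError` outside (0, 1].
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0) or np.any(T > 1):
        raise DomainError("transmittance must lie in (0, 1]")
    A = -np.log(T)
    return A if A.ndim else float(A)


def absorbance_to_path_length(A, constants: PhotometryConstants | None = None):
    """Nominal optical path length (micrometers) from absorbance.

    d_cm = A / (epsilon * c_mmol); halved when ``reflectance_double_pass``
    (the absorbance was accumulated over two passes through the vessel).
    """
    if constants is None:
        constants = PhotometryConstants()
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise DomainError("absorbance must be >= 0")
    d_cm = A / (constants.epsilon * constants.hb_conc_mmol_per_l)
    if constants.reflectance_double_pass:
        d_cm = d_cm / 2.0
    d_um = d_cm * 1e4
    return d_um if d_um.ndim else float(d_um)
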