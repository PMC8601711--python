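"""Ultrasonic deterrent sound field: spherical spreading plus ISO 9613-1
atmospheric absorption.

The deterrent speakers are modelled as isotropic point sources specified by
their level at the 1 m reference distance. Predicted level at range d is

    L(d) = L_1m - 20 log10(d / 1 m) - alpha * (d - 1 m)

with the pure-tone absorption coefficient alpha (dB/m) from the ISO 9613-1
closed-form expressions (classical plus oxygen and nitrogen relaxation
terms). Absorption is accumulated from the reference distance outward so the
1 m level is reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SoundFieldParams",
    "atmospheric_absorption",
    "spl_at_distance",
    "coverage_map",
]

_T0 = 293.15       # K, ISO reference temperature
_T01 = 273.16      # K, triple point
_PR = 101.325      # kPa, reference pressure


def atmospheric_absorption(frequency_khz: float, temperature_c: float = 14.0,
                           relative_humidity: float = 90.0,
                           pressure_kpa: float = 101.325) -> float:
    """Pure-tone atmospheric absorption coefficient in dB per metre.

    Implements the ISO 9613-1 closed-form model: classical (viscous/thermal)
    absorption plus the oxygen and nitrogen vibrational relaxation terms,
    each with its humidity- and pressure-dependent relaxation frequency.
    Inputs outside the standard's stated validity ranges raise ``ValueError``
    naming the violated bound.
    """
    if not 0 < frequency_khz:
        raise ValueError("frequency must be positive (kHz)")
    if not -20.0 <= temperature_c <= 50.0:
        raise ValueError("temperature outside the model's -20..50 degC range")
    if not 0.0 <= relative_humidity <= 100.0:
        raise ValueError("relative humidity must be within 0..100%")
    if not 0.0 < pressure_kpa <= 200.0:
        raise ValueError("pressure must be in (0, 200] kPa")

    f = float(frequency_khz) * 1e3
    T = temperature_c + 273.15
    pa = pressure_kpa

    # molar concentration of water vapour (%), from saturation pressure
    psat_over_pr = 10.0 ** (-6.8346 * (_T01 / T) ** 1.261 + 4.6151)
    h = relative_humidity * psat_over_pr * (_PR / pa)

    # relaxation frequencies of oxygen and nitrogen (Hz)
    fr_o = (pa / _PR) * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
    fr_n = (pa / _PR) * (T / _T0) ** -0.5 * (
        9.0 + 280.0 * h * np.exp(-4.170 * ((T / _T0) ** (-1.0 / 3.0) - 1.0)))

    classical = 1.84e-11 * (_PR / pa) * (T / _T0) ** 0.5
    relax = (T / _T0) ** -2.5 * (
        0.01275 * np.exp(-2239.1 / T) * fr_o / (fr_o ** 2 + f ** 2)
        + 0.1068 * np.exp(-3352.0 / T) * fr_n / (fr_n ** 2 + f ** 2))
    return float(8.686 * f ** 2 * (classical + relax))


@dataclass
class SoundFieldParams:
    """Source level, tone frequency and atmospheric state of the deterrent.

    Defaults are the deployed speakers: 98 dB SPL at 1 m at the 50 kHz
    frequency of maximum energy, in a 14 degC, 90% RH, 101.325 kPa
    atmosphere. ``source_position_mm`` is in the rig's world frame; the
    speakers stood ~15 m behind the camera baseline (negative y).
    """

    source_level_db: float = 98.0
    frequency_khz: float = 50.0
    temperature_c: float = 14.0
    relative_humidity: float = 90.0
    pressure_kpa: float = 101.325
    source_position_mm: np.ndarray = field(
        default_factory=lambda: np.array([2000.0, -15000.0, 1000.0]))

    def __post_init__(self) -> None:
        if self.frequency_khz <= 0:
            raise ValueError("frequency must be positive")
        if not 0 <= self.relative_humidity <= 100:
            raise ValueError("relative humidity must be within 0..100%")
        if self.pressure_kpa <= 0:
            raise ValueError("pressure must be positive")
        self.source_position_mm = np.asarray(self.source_position_mm, dtype=float)

    @property
    def absorption_db_per_m(self) -> float:
        return atmospheric_absorption(self.frequency_khz, self.temperature_c,
                                      self.relative_humidity, self.pressure_kpa)


def spl_at_distance(params: SoundFieldParams, distance_m):
    """Predicted SPL (dB re 20 uPa) at ``distance_m`` metres from the source.

    Valid from the 1 m reference distance outward; smaller distances raise
    ``ValueError``. Accepts scalars or arrays.
    """
    d = np.asarray(distance_m, dtype=float)
    if np.any(d < 1.0):
        raise ValueError("model is defined from the 1 m reference distance outward")
    alpha = params.absorption_db_per_m
    L = params.source_level_db - 20.0 * np.log10(d) - alpha * (d - 1.0)
    return float(L) if np.isscalar(distance_m) else L


def spl_at_position(params: SoundFieldParams, position_mm: np.ndarray,
                    second_source_mm: np.ndarray | None = None):
    """SPL at world position(s), using the nearest source when two are given.

    Incoherent summation over sources is deliberately not modelled; with the
    two deployed speakers side by side the nearest-source level is within
    ~3 dB of any summation and keeps the field monotone along rays.
    """
    pos = np.atleast_2d(np.asarray(position_mm, dtype=float))
    d = np.linalg.norm(pos - params.source_position_mm, axis=1) / 1000.0
    if second_source_mm is not None:
        d2 = np.linalg.norm(pos - np.asarray(second_source_mm, float), axis=1) / 1000.0
        d = np.minimum(d, d2)
    d = np.maximum(d, 1.0)
    out = spl_at_distance(params, d)
    return float(out[0]) if np.asarray(position_mm).ndim == 1 else out


def coverage_map(params: SoundFieldParams, x_mm: np.ndarray, y_mm: np.ndarray,
                 z_mm: float = 1000.0,
                 second_source_mm: np.ndarray | None = None) -> np.ndarray:
    """SPL grid over a horizontal slice of the scene volume at height z.

    Returns an array of shape (len(y), len(x)) of dB SPL values, clipped at
    the 1 m reference distance around each source.
    """
    X, Y = np.meshgrid(np.asarray(x_mm, float), np.asarray(y_mm, float))
    pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, float(z_mm))])
    vals = spl_at_position(params, pts, second_source_mm=second_source_mm)
    return np.asarray(vals).reshape(X.shape)
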