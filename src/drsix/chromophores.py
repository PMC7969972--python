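"""Tissue chromophores: map physiological parameters to optical coefficients.

The forward model describes skin-like tissue with five physiological
parameters: blood volume fraction (BVF), reduced scattering coefficient at
630 nm (``mus630``), scattering power-law exponent (B), melanin concentration
(Mel, mg/ml) and hemoglobin oxygen saturation (SO2).  They enter the optics
through two wavelength-resolved coefficients:

* reduced scattering  ``mus'(lam) = mus630 * (lam/630)**(-B)``  [cm^-1]
* absorption          ``mua(lam) = BVF * (SO2*mua_oxy + (1-SO2)*mua_deoxy)
  + Mel * mel_ext``   [cm^-1]

where ``mua_oxy``/``mua_deoxy`` are effective whole-blood absorption spectra
and ``mel_ext`` is melanin absorption per unit concentration, all tabulated in
a packaged chromophore table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "TissueParams",
    "ChromophoreTable",
    "PARAM_NAMES",
    "PARAM_RANGES",
    "WAVELENGTH_BAND",
    "REFERENCE_WAVELENGTH",
    "musp_at",
    "mua_at",
]

#: Parameter names in canonical column order.
PARAM_NAMES = ("bvf", "mus630", "b", "mel", "so2")

#: Physiological study ranges (skin tissue): fractions for bvf/so2,
#: cm^-1 for mus630, dimensionless exponent b, mg/ml for mel.
PARAM_RANGES = {
    "bvf": (0.01, 0.05),
    "mus630": (10.0, 30.0),
    "b": (1.3, 2.5),
    "mel": (0.0, 2.0),
    "so2": (0.60, 1.00),
}

#: Supported wavelength band, nm.
WAVELENGTH_BAND = (410.0, 650.0)

#: Reference wavelength for the scattering power law, nm.
REFERENCE_WAVELENGTH = 630.0

_FIXTURE_NAME = "chromophores_synthetic.tsv"


@dataclass(frozen=True)
class TissueParams:
    """One point in physiological parameter space.

    Attributes
    ----------
    bvf : float
        Blood volume fraction (dimensionless, e.g. 0.01--0.05).
    mus630 : float
        Reduced scattering coefficient at 630 nm, cm^-1.
    b : float
        Scattering power-law exponent (dimensionless).
    mel : float
        Melanin concentration, mg/ml.
    so2 : float
        Hemoglobin oxygen saturation (dimensionless fraction).
    """

    bvf: float
    mus630: float
    b: float
    mel: float
    so2: float

    def __post_init__(self):
        vals = [self.bvf, self.mus630, self.b, self.mel, self.so2]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite tissue parameters: {vals}")
        if self.bvf < 0 or self.mel < 0 or self.so2 < 0 or self.mus630 < 0:
            raise ValueError(f"negative tissue parameters: {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "TissueParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise ValueError(f"expected 5 parameters, got shape {arr.shape}")
        return cls(*arr)

    @classmethod
    def midrange(cls) -> "TissueParams":
        return cls(*(0.5 * (lo + hi) for lo, hi in PARAM_RANGES.values()))


class ChromophoreTable:
    """Wavelength-resolved chromophore absorption table.

    Columns: effective whole-blood absorption for fully oxygenated and fully
    deoxygenated blood (cm^-1), and melanin absorption per unit concentration
    (cm^-1 per mg/ml), on a strictly ascending nm grid covering at least
    410--650 nm.  Lookups interpolate linearly between grid nodes.
    """

    def __init__(self, wavelengths, mua_oxy, mua_deoxy, mel_ext):
        w = np.asarray(wavelengths, dtype=float)
        oxy = np.asarray(mua_oxy, dtype=float)
        deoxy = np.asarray(mua_deoxy, dtype=float)
        mel = np.asarray(mel_ext, dtype=float)
        if not (w.shape == oxy.shape == deoxy.shape == mel.shape) or w.ndim != 1:
            raise ValueError("all chromophore series must share one 1-d grid")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if np.any(oxy <= 0) or np.any(deoxy <= 0) or np.any(mel <= 0):
            raise ValueError("chromophore coefficients must be positive")
        self.wavelengths = w
        self.mua_oxy = oxy
        self.mua_deoxy = deoxy
        self.mel_ext = mel

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "ChromophoreTable":
        df = pd.read_csv(path, sep="\t")
        required = ["wavelength_nm", "mua_oxy_cm1", "mua_deoxy_cm1",
                    "mel_ext_cm1_per_mg_ml"]
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"chromophore file missing columns: {sorted(missing)}")
        return cls(df["wavelength_nm"], df["mua_oxy_cm1"], df["mua_deoxy_cm1"],
                   df["mel_ext_cm1_per_mg_ml"])

    @classmethod
    def default(cls) -> "ChromophoreTable":
        """The packaged fixture table (see ``drsix/data``)."""
        ref = importlib.resources.files("drsix") / "data" / _FIXTURE_NAME
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "wavelength_nm": self.wavelengths,
            "mua_oxy_cm1": self.mua_oxy,
            "mua_deoxy_cm1": self.mua_deoxy,
            "mel_ext_cm1_per_mg_ml": self.mel_ext,
        }).to_csv(path, sep="\t", index=False, float_format="%.6g")

    # -- interpolation -------------------------------------------------------

    def _check_range(self, lam):
        lam = np.asarray(lam, dtype=float)
        if np.any(lam < self.wavelengths[0]) or np.any(lam > self.wavelengths[-1]):
            raise ValueError(
                f"wavelength outside table coverage "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm")
        return lam

    def oxy(self, lam):
        lam = self._check_range(lam)
        return np.interp(lam, self.wavelengths, self.mua_oxy)

    def deoxy(self, lam):
        lam = self._check_range(lam)
        return np.interp(lam, self.wavelengths, self.mua_deoxy)

    def melanin(self, lam):
        lam = self._check_range(lam)
        return np.interp(lam, self.wavelengths, self.mel_ext)


def musp_at(params: TissueParams, lam):
    """Reduced scattering coefficient at wavelength ``lam`` (nm), cm^-1.

    Power law anchored at 630 nm: ``mus630 * (lam/630)**(-b)``.
    """
    lam = np.asarray(lam, dtype=float)
    lo, hi = WAVELENGTH_BAND
    if np.any(lam < lo) or np.any(lam > hi):
        raise ValueError(f"wavelength outside supported band [{lo}, {hi}] nm")
    out = params.mus630 * (lam / REFERENCE_WAVELENGTH) ** (-params.b)
    return float(out) if out.ndim == 0 else out


def mua_at(params: TissueParams, lam, table: ChromophoreTable):
    """Absorption coefficient at wavelength ``lam`` (nm), cm^-1."""
    blood = params.so2 * table.oxy(lam) + (1.0 - params.so2) * table.deoxy(lam)
    out = params.bvf * blood + params.mel * table.melanin(lam)
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


def coefficient_curves(param_table: pd.DataFrame, lam, table: ChromophoreTable):
    """Vectorized (mua, musp) for a table of parameter rows.

    Parameters
    ----------
    param_table : DataFrame with the five ``PARAM_NAMES`` columns (N rows).
    lam : array of wavelengths, nm (M,).
    table : ChromophoreTable.

    Returns
    -------
    (mua, musp) : two (N, M) arrays, cm^-1.
    """
    lam = np.asarray(lam, dtype=float)
    oxy = table.oxy(lam)[None, :]
    deoxy = table.deoxy(lam)[None, :]
    mel = table.melanin(lam)[None, :]
    bvf = param_table["bvf"].to_numpy()[:, None]
    so2 = param_table["so2"].to_numpy()[:, None]
    melc = param_table["mel"].to_numpy()[:, None]
    mus630 = param_table["mus630"].to_numpy()[:, None]
    b = param_table["b"].to_numpy()[:, None]
    mua = bvf * (so2 * oxy + (1.0 - so2) * deoxy) + melc * mel
    musp = mus630 * (lam[None, :] / REFERENCE_WAVELENGTH) ** (-b)
    return mua, musp
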