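"""MCLUT inverse model: constrained nonlinear least-squares spectral fitting.

The baseline extractor fits the five physiological parameters to a measured
six-channel reflectance by minimising the sum of squared differences between
the measurement and an LUT-derived model spectrum, subject to the
physiological box bounds.

Two model modes:

* ``point_sample`` (default, the classical inverse model): the model
  reflectance is the LUT forward value evaluated *at the six channel-center
  wavelengths only*.  This ignores the broad channel bandwidths and is the
  source of the inverse model's large errors on band-averaged data.
* ``weighted``: the model is the full 100-wavelength forward spectrum passed
  through the channel responsivity, i.e. the same operator that produced the
  data.  Provided to quantify the band-averaging mismatch.

The optimiser is multi-start bound-constrained local minimisation (L-BFGS-B
with numerical gradients from a mid-range start plus seeded random in-bounds
starts, best result polished with bounded Nelder--Mead).  The bilinear LUT
makes the objective piecewise-smooth; the multi-start guards against the
multi-modality of a 6-point objective.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .chromophores import (PARAM_NAMES, PARAM_RANGES, REFERENCE_WAVELENGTH,
                           ChromophoreTable, TissueParams)
from .mc import LUT
from .synth import (CHANNEL_CENTERS, ChannelResponsivity, Spectrum,
                    make_responsivity, wavelength_grid)

__all__ = ["FitResult", "fit_spectrum", "fit_batch", "N_EXTRA_STARTS"]

#: Additional seeded random in-bounds starts beyond the mid-range start.
N_EXTRA_STARTS = 4


@dataclass
class FitResult:
    params: TissueParams
    residual: float
    n_iterations: int
    converged: bool
    elapsed: float


class _Objective:
    """Precomputed chromophore coefficients -> fast residual evaluation."""

    def __init__(self, lut: LUT, table: ChromophoreTable, mode: str,
                 resp: ChannelResponsivity | None):
        self.lut = lut
        self.mode = mode
        if mode == "point_sample":
            lam = np.asarray(CHANNEL_CENTERS)
        elif mode == "weighted":
            self.resp = resp or make_responsivity()
            lam = self.resp.grid
        else:
            raise ValueError(f"unknown fit mode {mode!r}")
        self.oxy = table.oxy(lam)
        self.deoxy = table.deoxy(lam)
        self.mel = table.melanin(lam)
        self.loglam = np.log(lam / REFERENCE_WAVELENGTH)

    def model(self, x):
        bvf, mus630, b, mel, so2 = x
        mua = bvf * (so2 * self.oxy + (1 - so2) * self.deoxy) + mel * self.mel
        musp = mus630 * np.exp(-b * self.loglam)
        # clip: numerical-gradient probes may step epsilon past the grid edge
        r = self.lut.query(mua, musp, clip=True)
        if self.mode == "weighted":
            r = self.resp.weights @ r
        return r

    def __call__(self, x, measured):
        d = self.model(x) - measured
        return float(d @ d)


def _bounds():
    return [PARAM_RANGES[n] for n in PARAM_NAMES]


def fit_spectrum(measured, lut: LUT, table: ChromophoreTable = None,
                 bounds=None, init: TissueParams = None,
                 mode: str = "point_sample", resp=None, seed=0,
                 n_starts=1 + N_EXTRA_STARTS) -> FitResult:
    """Fit tissue parameters to one six-channel spectrum.

    ``measured`` may be a ``Spectrum`` or a length-6 array on the channel
    centers.  Never raises on non-convergence (``converged`` flags it);
    non-finite measurements raise a data error.
    """
    t0 = time.time()
    table = table or ChromophoreTable.default()
    vals = measured.values if isinstance(measured, Spectrum) else np.asarray(
        measured, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("measured spectrum contains non-finite values")
    bounds = bounds or _bounds()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    obj = _Objective(lut, table, mode, resp)
    x0 = (init.as_array() if init is not None else 0.5 * (lo + hi))
    init_res = obj(x0, vals)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF17)))
    starts = [x0] + [lo + (hi - lo) * rng.random(5)
                     for _ in range(max(0, n_starts - 1))]
    best_x, best_f, n_it, ok = x0, init_res, 0, False
    for s in starts:
        try:
            r = minimize(obj, s, args=(vals,), method="L-BFGS-B",
                         bounds=bounds, options={"ftol": 1e-14,
                                                 "gtol": 1e-12})
        except Exception:
            continue
        n_it += r.nit
        ok = ok or bool(r.success)
        if r.fun < best_f:
            best_x, best_f = r.x, r.fun
    # derivative-free polish: cleans up the kinks of the bilinear surface
    r = minimize(obj, best_x, args=(vals,), method="Nelder-Mead",
                 bounds=bounds, options={"xatol": 1e-12, "fatol": 1e-16,
                                         "maxiter": 2000})
    n_it += r.nit
    if r.fun < best_f:
        best_x, best_f = r.x, r.fun
        ok = ok or bool(r.success)
    best_x = np.clip(best_x, lo, hi)
    return FitResult(TissueParams.from_array(best_x), float(best_f),
                     int(n_it), bool(ok), time.time() - t0)


def fit_batch(spectra, lut: LUT, table: ChromophoreTable = None,
              bounds=None, mode: str = "point_sample", resp=None, seed=0):
    """Fit each row of an (N, 6) matrix independently.

    Returns ``(DataFrame, elapsed_seconds)``; rows with non-finite data are
    flagged ``failed`` instead of aborting the batch.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim == 1:
        spectra = spectra[None, :]
    if len(spectra) < 1:
        raise ValueError("empty batch")
    table = table or ChromophoreTable.default()
    t0 = time.time()
    rows = []
    for i, row in enumerate(spectra):
        if not np.all(np.isfinite(row)):
            rows.append({**{n: np.nan for n in PARAM_NAMES},
                         "residual": np.nan, "converged": False,
                         "failed": True, "seconds": 0.0})
            continue
        fr = fit_spectrum(row, lut, table, bounds=bounds, mode=mode,
                          resp=resp, seed=seed + i)
        rows.append({**{n: getattr(fr.params, n) for n in PARAM_NAMES},
                     "residual": fr.residual, "converged": fr.converged,
                     "failed": False, "seconds": fr.elapsed})
    return pd.DataFrame(rows), time.time() - t0
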