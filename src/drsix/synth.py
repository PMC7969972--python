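"""Synthetic six-channel diffuse reflectance data generation.

Pipeline: a 100-wavelength (410--650 nm) reflectance spectrum is produced for
each tissue-parameter combination by querying the Monte Carlo lookup table at
(mua(lam), mus'(lam)); multiplicative Gaussian noise mimics measurement noise;
the spectrum is then reduced to the six channels of a low-cost multispectral
sensor (centers 450, 500, 550, 570, 600, 650 nm) by a Gaussian-responsivity
weighted average (40 nm FWHM per channel).

The study design is a full factorial over 10 linearly spaced levels of each of
the five physiological parameters (100,000 spectra), randomised into a 10,000
row training split and a 30,000-row test split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromophores import (PARAM_NAMES, PARAM_RANGES, ChromophoreTable,
                           coefficient_curves)
from .mc import LUT

__all__ = ["Spectrum", "ChannelResponsivity", "SimulatedDataset",
           "wavelength_grid", "forward_spectrum", "forward_spectra",
           "add_noise", "make_responsivity", "downsample", "generate_dataset",
           "CHANNEL_CENTERS", "CHANNEL_FWHM", "N_WAVELENGTHS"]

#: Six sensor channel centers, nm.
CHANNEL_CENTERS = (450.0, 500.0, 550.0, 570.0, 600.0, 650.0)

#: Default per-channel Gaussian bandwidth (FWHM), nm.
CHANNEL_FWHM = 40.0

#: Number of wavelengths in the full-resolution grid.
N_WAVELENGTHS = 100

#: Study split sizes at the full 10-level design.
TRAIN_SIZE = 10_000
TEST_SIZE = 30_000
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


def wavelength_grid(n=N_WAVELENGTHS):
    """``n`` evenly spaced wavelengths over 410--650 nm."""
    return np.linspace(410.0, 650.0, n)


@dataclass
class Spectrum:
    """A reflectance spectrum on an ascending wavelength grid."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")


class ChannelResponsivity:
    """Gaussian channel responsivities as a weights matrix (n_channels x n_grid).

    Each row is a Gaussian centred on the channel wavelength, truncated to the
    grid and renormalised to sum to one, so down-sampling is a convex weighted
    average.
    """

    def __init__(self, centers, fwhm, grid, weights):
        self.centers = np.asarray(centers, dtype=float)
        self.fwhm = float(fwhm)
        self.grid = np.asarray(grid, dtype=float)
        self.weights = np.asarray(weights, dtype=float)
        if self.weights.shape != (self.centers.size, self.grid.size):
            raise ValueError("weights shape must be (n_channels, n_grid)")


def make_responsivity(centers=CHANNEL_CENTERS, fwhm=CHANNEL_FWHM,
                      grid=None) -> ChannelResponsivity:
    """Build Gaussian channel responsivities on the wavelength grid."""
    grid = wavelength_grid() if grid is None else np.asarray(grid, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if np.any(centers < grid[0]) or np.any(centers > grid[-1]):
        raise ValueError("channel centers must lie inside the grid span")
    sigma = fwhm / FWHM_TO_SIGMA
    w = np.exp(-0.5 * ((grid[None, :] - centers[:, None]) / sigma) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    return ChannelResponsivity(centers, fwhm, grid, w)


def forward_spectra(param_table: pd.DataFrame, lut: LUT,
                    table: ChromophoreTable, grid=None) -> np.ndarray:
    """Vectorised forward model: (N, n_grid) reflectance matrix.

    Raises a range error listing offending parameter rows if any (mua, mus')
    pair falls outside the LUT axes (nothing is clamped silently).
    """
    grid = wavelength_grid() if grid is None else np.asarray(grid, dtype=float)
    mua, musp = coefficient_curves(param_table, grid, table)
    bad = ((mua < lut.mua_axis[0]) | (mua > lut.mua_axis[-1])
           | (musp < lut.musp_axis[0]) | (musp > lut.musp_axis[-1]))
    if bad.any():
        rows = np.unique(np.nonzero(bad)[0])
        raise ValueError(
            f"{rows.size} parameter combinations give optical coefficients "
            f"outside the LUT grid (first rows: {rows[:5].tolist()}); "
            f"mua range [{mua.min():.3g}, {mua.max():.3g}], "
            f"musp range [{musp.min():.3g}, {musp.max():.3g}]")
    return lut.query(mua, musp)


def forward_spectrum(params, lut: LUT, table: ChromophoreTable,
                     grid=None) -> Spectrum:
    """Forward-model one spectrum from one TissueParams."""
    grid = wavelength_grid() if grid is None else np.asarray(grid, dtype=float)
    df = pd.DataFrame([{n: getattr(params, n) for n in PARAM_NAMES}])
    vals = forward_spectra(df, lut, table, grid)[0]
    return Spectrum(grid, vals)


def add_noise(spec: Spectrum, sigma_rel, seed=0) -> Spectrum:
    """Multiplicative Gaussian noise, floored at zero (physical reflectance)."""
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be non-negative")
    rng = np.random.default_rng(seed)
    noisy = spec.values * (1.0 + sigma_rel * rng.standard_normal(
        spec.values.shape))
    return Spectrum(spec.wavelengths, np.maximum(noisy, 0.0))


def downsample(spec: Spectrum, resp: ChannelResponsivity) -> Spectrum:
    """Weighted-average reduction of a full spectrum to the sensor channels."""
    if spec.values.shape[-1] != resp.grid.size or not np.allclose(
            spec.wavelengths, resp.grid):
        raise ValueError("spectrum grid does not match responsivity grid")
    return Spectrum(resp.centers.copy(), resp.weights @ spec.values)


@dataclass
class SimulatedDataset:
    """Full factorial simulated study dataset.

    ``params`` is an (N, 5) DataFrame with the canonical parameter columns plus
    a ``split`` column in {"train", "test", "unused"}; ``spectra100`` and
    ``spectra6`` are the aligned reflectance matrices.
    """

    params: pd.DataFrame
    spectra100: np.ndarray
    spectra6: np.ndarray
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def levels(self):
        return {n: np.unique(self.params[n].to_numpy()) for n in PARAM_NAMES}

    def split_index(self, name):
        return np.nonzero((self.params["split"] == name).to_numpy())[0]

    @property
    def train_X(self):
        return self.spectra6[self.split_index("train")]

    @property
    def test_X(self):
        return self.spectra6[self.split_index("test")]

    def train_y(self, name):
        return self.params[name].to_numpy()[self.split_index("train")]

    def test_y(self, name):
        return self.params[name].to_numpy()[self.split_index("test")]

    @property
    def truth_test(self) -> pd.DataFrame:
        return self.params.iloc[self.split_index("test")][list(PARAM_NAMES)]

    # -- persistence ---------------------------------------------------------

    def to_files(self, prefix):
        """Write ``<prefix>.tsv`` (params + 6 channels + split),
        ``<prefix>_spectra100.tsv`` and ``<prefix>.json`` metadata sidecar."""
        six = pd.DataFrame(
            self.spectra6,
            columns=[f"r{int(c)}" for c in self.meta["channel_centers"]])
        pd.concat([self.params.reset_index(drop=True), six], axis=1).to_csv(
            f"{prefix}.tsv", sep="\t", index=False)
        np.savetxt(f"{prefix}_spectra100.tsv", self.spectra100,
                   delimiter="\t", fmt="%.8g")
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"seed": self.seed, **self.meta}, fh, indent=1)

    @classmethod
    def from_files(cls, prefix):
        df = pd.read_csv(f"{prefix}.tsv", sep="\t")
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        six_cols = [c for c in df.columns if c.startswith("r") and
                    c[1:].isdigit()]
        spectra100 = np.loadtxt(f"{prefix}_spectra100.tsv", delimiter="\t")
        return cls(df[list(PARAM_NAMES) + ["split"]],
                   spectra100, df[six_cols].to_numpy(),
                   meta.pop("seed"), meta)


def parameter_grid(levels=10) -> pd.DataFrame:
    """Full factorial of ``levels`` linearly spaced values per parameter."""
    axes = [np.linspace(lo, hi, levels) for lo, hi in PARAM_RANGES.values()]
    mesh = np.meshgrid(*axes, indexing="ij")
    return pd.DataFrame({n: m.ravel() for n, m in zip(PARAM_NAMES, mesh)})


def generate_dataset(lut: LUT, table: ChromophoreTable = None,
                     resp: ChannelResponsivity = None, sigma_rel=0.01,
                     seed=0, levels=10, train_size=None,
                     test_size=None) -> SimulatedDataset:
    """Generate the full factorial study dataset, deterministically.

    At the default 10 levels this yields 100,000 spectra with a randomised
    disjoint 10,000-row train / 30,000-row test split; reduced designs scale
    the split sizes proportionally (recorded in metadata).
    """
    table = table or ChromophoreTable.default()
    resp = resp or make_responsivity()
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be non-negative")
    params = parameter_grid(levels)
    n = len(params)
    scale = n / 100_000
    train_size = int(round(TRAIN_SIZE * scale)) if train_size is None else train_size
    test_size = int(round(TEST_SIZE * scale)) if test_size is None else test_size
    if train_size + test_size > n:
        raise ValueError("train + test larger than the design")
    grid = resp.grid
    clean = forward_spectra(params, lut, table, grid)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD5)))
    noisy = clean * (1.0 + sigma_rel * rng.standard_normal(clean.shape))
    np.maximum(noisy, 0.0, out=noisy)
    spectra6 = noisy @ resp.weights.T
    # randomised split: train subset is a seeded subsample of the train pool
    perm = rng.permutation(n)
    split = np.full(n, "unused", dtype=object)
    split[perm[:train_size]] = "train"
    split[perm[n - test_size:]] = "test"
    params = params.assign(split=split)
    meta = {
        "levels": levels, "sigma_rel": sigma_rel,
        "channel_centers": list(resp.centers), "fwhm": resp.fwhm,
        "n": n, "train_size": train_size, "test_size": test_size,
        "lut_mode": lut.meta.get("mode"),
    }
    return SimulatedDataset(params, noisy, spectra6, seed, meta)
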