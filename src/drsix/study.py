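"""End-to-end study object: simulate, fit all extractors, evaluate.

``ExtractionStudy`` is the model-level entry point: it is constructed from a
simulated dataset plus the LUT that generated it (or built from a config via
:meth:`ExtractionStudy.from_config`), and its :meth:`fit` trains the requested
ML families, runs the MCLUT inverse on (a subsample of) the test split, and
returns a :class:`StudyResults` holding the accuracy tables, crosstalk
matrices, win rates and pairwise comparisons, with a ``summary()`` table.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from . import evaluate as ev
from .chromophores import PARAM_NAMES, ChromophoreTable
from .inverse import fit_batch
from .mc import LUT, MCConfig, ProbeGeometry, build_lut
from .ml import FAMILIES, ExtractorSet, ModelFamilySpec, predict, train
from .synth import SimulatedDataset, generate_dataset, make_responsivity

__all__ = ["ExtractionStudy", "StudyResults"]


class ExtractionStudy:
    """Benchmark of parameter extractors on one simulated dataset."""

    def __init__(self, dataset: SimulatedDataset, lut: LUT,
                 table: ChromophoreTable = None):
        self.dataset = dataset
        self.lut = lut
        self.table = table or ChromophoreTable.default()

    @classmethod
    def from_config(cls, config: dict) -> "ExtractionStudy":
        """Build LUT + dataset from a nested config dict (see CLI docs)."""
        seed = int(config.get("seed", 0))
        mc_cfg = MCConfig(**{"seed": seed, **config.get("mc", {})})
        geom = ProbeGeometry(**config.get("geometry", {}))
        lut = build_lut(geom=geom, cfg=mc_cfg,
                        mode=config.get("lut_mode", "scaled"))
        table = (ChromophoreTable.from_tsv(config["chromophores"])
                 if "chromophores" in config else ChromophoreTable.default())
        ds_cfg = config.get("dataset", {})
        resp = make_responsivity(fwhm=ds_cfg.get("fwhm", 40.0))
        dataset = generate_dataset(
            lut, table, resp, sigma_rel=ds_cfg.get("sigma_rel", 0.01),
            seed=seed, levels=ds_cfg.get("levels", 10))
        return cls(dataset, lut, table)

    def fit(self, families=FAMILIES, include_mclut=True, mclut_rows=None,
            mclut_mode="point_sample", seed=0, n_boot=1000,
            compare=True) -> "StudyResults":
        """Train/run all extractors and evaluate on the test split.

        ``mclut_rows`` caps the number of test rows fitted by the iterative
        inverse model (it is orders of magnitude slower than the trained
        models); metrics for it are computed on that seeded subsample, and
        pairwise comparisons are restricted to the common rows.
        """
        ds = self.dataset
        truth = ds.truth_test.reset_index(drop=True)
        n_test = len(truth)
        predictions = {}
        extractor_sets = {}
        train_seconds = {}
        for fam in families:
            t0 = time.time()
            es = train(ModelFamilySpec(fam, seed=seed), ds)
            train_seconds[fam] = time.time() - t0
            extractor_sets[fam] = es
            predictions[fam] = predict(es, ds.test_X).reset_index(drop=True)
        sub_idx = np.arange(n_test)
        if include_mclut:
            if mclut_rows is not None and mclut_rows < n_test:
                rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5B)))
                sub_idx = np.sort(rng.choice(n_test, mclut_rows, replace=False))
            fitted, _ = fit_batch(ds.test_X[sub_idx], self.lut, self.table,
                                  mode=mclut_mode, seed=seed)
            predictions["mclut"] = fitted[list(PARAM_NAMES)].reset_index(
                drop=True)
        return StudyResults(self, truth, predictions, sub_idx,
                            extractor_sets, seed=seed, n_boot=n_boot,
                            compare=compare, train_seconds=train_seconds)


class StudyResults:
    """Fitted-study results: accuracy tables, diagnostics, summary."""

    def __init__(self, study, truth, predictions, mclut_idx, extractor_sets,
                 seed=0, n_boot=1000, compare=True, train_seconds=None):
        self.study = study
        self.truth = truth
        self.predictions = predictions
        self.mclut_idx = mclut_idx
        self.extractor_sets = extractor_sets
        self.seed = seed
        self.train_seconds = train_seconds or {}
        self._build_tables(n_boot, compare)

    def _rows_for(self, model):
        return self.mclut_idx if model == "mclut" else np.arange(
            len(self.truth))

    def _build_tables(self, n_boot, compare):
        models = list(self.predictions)
        mae_t, mape_t, sd_t = {}, {}, {}
        excl = {}
        xt = {}
        for m in models:
            pred = self.predictions[m]
            tr = self.truth.iloc[self._rows_for(m)].reset_index(drop=True)
            mae_t[m] = {p: ev.mae(pred[p], tr[p]) for p in PARAM_NAMES}
            pairs = {p: ev.mape(pred[p], tr[p], return_excluded=True)
                     for p in PARAM_NAMES}
            mape_t[m] = {p: v[0] for p, v in pairs.items()}
            excl[m] = {p: v[1] for p, v in pairs.items()}
            sd_t[m] = {p: float(np.std(np.abs(pred[p].to_numpy()
                                              - tr[p].to_numpy())))
                       for p in PARAM_NAMES}
            xt[m] = ev.crosstalk(tr[list(PARAM_NAMES)], pred[list(PARAM_NAMES)])
        self.mae_table = pd.DataFrame(mae_t).T[list(PARAM_NAMES)]
        self.mape_table = pd.DataFrame(mape_t).T[list(PARAM_NAMES)]
        self.error_sd_table = pd.DataFrame(sd_t).T[list(PARAM_NAMES)]
        self.mape_excluded = excl
        self.crosstalk_tables = xt
        # head-to-head DL vs MCLUT win rates on the common rows
        self.winrates = {}
        if "dl" in self.predictions and "mclut" in self.predictions:
            idx = self.mclut_idx
            tr = self.truth.iloc[idx].reset_index(drop=True)
            dl = self.predictions["dl"].iloc[idx].reset_index(drop=True)
            mc = self.predictions["mclut"]
            for p in PARAM_NAMES:
                e_mc = np.abs(mc[p].to_numpy() - tr[p].to_numpy())
                e_dl = np.abs(dl[p].to_numpy() - tr[p].to_numpy())
                self.winrates[p] = ev.winrate_by_level(e_mc, e_dl,
                                                       tr[p].to_numpy())
        self.comparisons = None
        if compare and len(models) > 1:
            idx = self.mclut_idx if "mclut" in models else np.arange(
                len(self.truth))
            tr = self.truth.iloc[idx].reset_index(drop=True)
            abs_err = {}
            for m in models:
                pred = self.predictions[m]
                pr = pred if m == "mclut" else pred.iloc[idx].reset_index(
                    drop=True)
                abs_err[m] = {p: np.abs(pr[p].to_numpy() - tr[p].to_numpy())
                              for p in PARAM_NAMES}
            self.comparisons = ev.compare_models(abs_err, n_boot=n_boot,
                                                 seed=self.seed)

    def report(self, timings=None) -> ev.EvalReport:
        return ev.EvalReport(
            mae_table=self.mae_table, mape_table=self.mape_table,
            mape_excluded=self.mape_excluded,
            error_sd_table=self.error_sd_table,
            crosstalk_tables=self.crosstalk_tables, winrates=self.winrates,
            comparisons=self.comparisons, timings=timings,
            meta={"seed": self.seed,
                  "n_test": int(len(self.truth)),
                  "n_mclut_rows": int(len(self.mclut_idx)),
                  "dataset": self.study.dataset.meta})

    def max_offdiag_crosstalk(self, model="dl") -> float:
        return ev.max_offdiagonal(self.crosstalk_tables[model])

    def summary(self) -> str:
        lines = ["Six-channel DRS parameter extraction study",
                 "=" * 44,
                 f"test rows: {len(self.truth)}  "
                 f"(inverse-model subsample: {len(self.mclut_idx)})",
                 "", "Mean absolute percent error (%):",
                 self.mape_table.round(2).to_string(),
                 "", "Mean absolute error (parameter units):",
                 self.mae_table.round(4).to_string()]
        if "dl" in self.crosstalk_tables:
            lines += ["", "max |off-diagonal| truth-vs-extracted Pearson r "
                          f"(dl): {self.max_offdiag_crosstalk('dl'):.3f}"]
        return "\n".join(lines)

    def plot_mae(self, ax=None):
        """Bar plot of MAE per model and parameter (optional matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        self.mae_table.T.plot.bar(ax=ax, rot=0)
        ax.set_ylabel("mean absolute error")
        ax.set_xlabel("parameter")
        return ax
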