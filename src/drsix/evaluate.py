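"""Evaluation metrics for parameter-extraction benchmarking.

Accuracy is summarised by mean absolute error, MAE = mean(|pred - truth|)
(parameter units), and mean absolute percent error,
MAPE = mean(100 |pred - truth| / truth), with zero-truth rows excluded from
the percent-error mean (the ratio is undefined there; the exclusion count is
reported).  Cross-parameter identifiability ("crosstalk") is the Pearson
correlation between each true parameter and every other extracted parameter.
Model pairs are compared by seeded paired bootstrap confidence intervals on
their MAE difference, and head-to-head win rates are tabulated per true
parameter level.  A wall-clock benchmark mirrors a repeated random-batch
timing protocol.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .chromophores import PARAM_NAMES

__all__ = ["mae", "mape", "crosstalk", "winrate_by_level", "compare_models",
           "runtime_bench", "EvalReport"]


def _check(pred, truth):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length and non-empty")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(truth))):
        raise ValueError("non-finite values in pred/truth")
    return pred, truth


def mae(pred, truth) -> float:
    """Mean absolute error in parameter units."""
    pred, truth = _check(pred, truth)
    return float(np.mean(np.abs(pred - truth)))


def mape(pred, truth, return_excluded=False):
    """Mean absolute percent error; zero-truth rows are excluded.

    With ``return_excluded`` also returns the number of excluded rows.
    """
    pred, truth = _check(pred, truth)
    keep = truth != 0.0
    excluded = int(np.sum(~keep))
    if not keep.any():
        raise ValueError("all rows have zero truth; MAPE undefined")
    val = float(np.mean(100.0 * np.abs(pred[keep] - truth[keep])
                        / truth[keep]))
    return (val, excluded) if return_excluded else val


def crosstalk(truth, pred, names=PARAM_NAMES) -> pd.DataFrame:
    """5x5 Pearson matrix: entry (i, j) correlates true parameter i with
    extracted parameter j.  Zero-variance columns yield NaN, not an error."""
    truth = pd.DataFrame(np.asarray(truth, dtype=float), columns=list(names))
    pred = pd.DataFrame(np.asarray(pred, dtype=float), columns=list(names))
    if len(truth) < 3:
        raise ValueError("need at least 3 rows for correlation")
    out = np.full((len(names), len(names)), np.nan)
    for i, ti in enumerate(names):
        for j, pj in enumerate(names):
            t = truth[ti].to_numpy()
            p = pred[pj].to_numpy()
            if np.std(t) == 0 or np.std(p) == 0:
                continue
            out[i, j] = stats.pearsonr(t, p).statistic
    return pd.DataFrame(out, index=list(names), columns=list(names))


def max_offdiagonal(ct: pd.DataFrame) -> float:
    m = ct.to_numpy().copy()
    np.fill_diagonal(m, np.nan)
    return float(np.nanmax(np.abs(m)))


def winrate_by_level(err_a, err_b, truth_level) -> pd.DataFrame:
    """Per truth level: fraction of rows where ``err_b < err_a`` (ties count
    as not-better), plus error-difference quantiles for distribution plots."""
    err_a, err_b = _check(err_a, err_b)
    truth_level = np.asarray(truth_level, dtype=float)
    if truth_level.shape != err_a.shape:
        raise ValueError("truth_level misaligned with errors")
    rows = []
    for lv in np.unique(truth_level):
        m = truth_level == lv
        diff = err_a[m] - err_b[m]
        rows.append({
            "level": lv, "n": int(m.sum()),
            "win_fraction": float(np.mean(diff > 0)),
            "diff_q25": float(np.quantile(diff, 0.25)),
            "diff_median": float(np.median(diff)),
            "diff_q75": float(np.quantile(diff, 0.75)),
        })
    return pd.DataFrame(rows)


def compare_models(abs_errors: dict, n_boot=1000, seed=0,
                   alpha=0.05) -> pd.DataFrame:
    """Paired bootstrap CIs on MAE differences for every model pair.

    ``abs_errors`` maps model name -> {param: (N,) absolute errors}; rows must
    be aligned across models (same test rows).  Returns one row per
    (model_a, model_b, param) with the mean difference (b - a) and a
    percentile CI from resampling rows with replacement.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    models = list(abs_errors)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB0)))
    rows = []
    for ia, a in enumerate(models):
        for b in models[ia:]:
            for p in abs_errors[a]:
                ea = np.asarray(abs_errors[a][p], dtype=float)
                eb = np.asarray(abs_errors[b][p], dtype=float)
                if ea.shape != eb.shape:
                    raise ValueError(
                        f"misaligned error rows for {a} vs {b} on {p}")
                d = eb - ea
                n = d.size
                idx = rng.integers(0, n, size=(n_boot, n))
                boots = d[idx].mean(axis=1)
                lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
                rows.append({
                    "model_a": a, "model_b": b, "param": p,
                    "mean_diff": float(d.mean()),
                    "ci_lo": float(lo), "ci_hi": float(hi),
                    "frac_above_zero": float(np.mean(boots > 0)),
                })
    return pd.DataFrame(rows)


def runtime_bench(extract, dataset_X, batch_sizes=(1, 10, 50, 100),
                  trials=50, seed=0) -> pd.DataFrame:
    """Mean wall time of ``extract(batch)`` over seeded random batches.

    Hardware-dependent by nature: recorded for trend inspection, never a
    pass/fail quantity.
    """
    X = np.asarray(dataset_X, dtype=float)
    if max(batch_sizes) > len(X):
        raise ValueError("batch size exceeds dataset size")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7B)))
    rows = []
    for bs in batch_sizes:
        times = []
        for _ in range(trials):
            idx = rng.choice(len(X), size=bs, replace=False)
            batch = X[idx]
            t0 = time.perf_counter()
            extract(batch)
            times.append(time.perf_counter() - t0)
        rows.append({"batch_size": bs, "mean_seconds": float(np.mean(times)),
                     "sd_seconds": float(np.std(times)), "trials": trials})
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Per-model accuracy tables plus crosstalk, win rates and comparisons."""

    mae_table: pd.DataFrame        # rows: model; columns: parameter
    mape_table: pd.DataFrame
    mape_excluded: dict            # model -> {param: excluded row count}
    error_sd_table: pd.DataFrame
    crosstalk_tables: dict         # model -> 5x5 DataFrame
    winrates: dict                 # param -> winrate_by_level DataFrame
    comparisons: pd.DataFrame | None = None
    timings: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def to_json(self, path=None):
        blob = {
            "mae": self.mae_table.to_dict(),
            "mape": self.mape_table.to_dict(),
            "mape_excluded": self.mape_excluded,
            "error_sd": self.error_sd_table.to_dict(),
            "crosstalk": {k: v.to_dict() for k, v in
                          self.crosstalk_tables.items()},
            "winrates": {k: v.to_dict(orient="list")
                         for k, v in self.winrates.items()},
            "comparisons": (None if self.comparisons is None
                            else self.comparisons.to_dict(orient="list")),
            "timings": (None if self.timings is None
                        else self.timings.to_dict(orient="list")),
            "meta": self.meta,
        }
        if path is None:
            return json.dumps(blob)
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=1)

    @classmethod
    def from_json(cls, path_or_str):
        try:
            blob = json.loads(path_or_str)
        except (ValueError, TypeError):
            with open(path_or_str) as fh:
                blob = json.load(fh)
        return cls(
            mae_table=pd.DataFrame(blob["mae"]),
            mape_table=pd.DataFrame(blob["mape"]),
            mape_excluded=blob["mape_excluded"],
            error_sd_table=pd.DataFrame(blob["error_sd"]),
            crosstalk_tables={k: pd.DataFrame(v)
                              for k, v in blob["crosstalk"].items()},
            winrates={k: pd.DataFrame(v) for k, v in blob["winrates"].items()},
            comparisons=(None if blob["comparisons"] is None
                         else pd.DataFrame(blob["comparisons"])),
            timings=(None if blob["timings"] is None
                     else pd.DataFrame(blob["timings"])),
            meta=blob["meta"],
        )
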