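"""Machine-learning extractors: four regression families, one regressor per
physiological parameter, trained on six-channel reflectance features.

Families mirror the common defaults of general-purpose AutoML frameworks:

* ``dl``  -- feed-forward network, two hidden layers of 200 rectifier units,
  10 training epochs, stochastic gradient optimisation with an adaptive
  per-weight step rule (Adam); features and targets standardised on the
  training split.
* ``rf``  -- random forest, 50 trees, maximum depth 20.
* ``gbm`` -- histogram gradient boosting, 50 trees, depth 5, 20 bins.
* ``glm`` -- Gaussian identity-link least squares (ordinary linear
  regression) on standardised features.

Tree families see raw features (scale-invariant splits).  Predictions are raw
model outputs, deliberately not clipped to the physiological bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .chromophores import PARAM_NAMES
from .synth import SimulatedDataset

__all__ = ["ModelFamilySpec", "ExtractorSet", "train", "predict", "FAMILIES"]

FAMILIES = ("dl", "rf", "gbm", "glm")

_DEFAULT_HYPERPARAMS = {
    "dl": {"hidden_layer_sizes": (200, 200), "activation": "relu",
           "epochs": 10, "batch_size": 32, "learning_rate_init": 0.001},
    "rf": {"n_trees": 50, "max_depth": 20, "n_bins": 20},
    "gbm": {"n_trees": 50, "max_depth": 5, "n_bins": 20, "learning_rate": 0.1},
    "glm": {},
}


@dataclass(frozen=True)
class ModelFamilySpec:
    """A model family plus its hyperparameters and seed."""

    family: str
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"expected one of {FAMILIES}")
        merged = {**_DEFAULT_HYPERPARAMS[self.family], **self.hyperparams}
        object.__setattr__(self, "hyperparams", merged)

    def build(self, seed):
        hp = self.hyperparams
        if self.family == "dl":
            mlp = MLPRegressor(
                hidden_layer_sizes=tuple(hp["hidden_layer_sizes"]),
                activation=hp["activation"], solver="adam",
                batch_size=hp["batch_size"],
                learning_rate_init=hp["learning_rate_init"],
                max_iter=hp["epochs"], shuffle=True, random_state=seed,
                tol=0.0, n_iter_no_change=hp["epochs"] + 1)
            return TransformedTargetRegressor(
                regressor=make_pipeline(StandardScaler(), mlp),
                transformer=StandardScaler())
        if self.family == "rf":
            # n_bins is recorded for parity with histogram-based forests but
            # this backend uses exact splits
            return RandomForestRegressor(
                n_estimators=hp["n_trees"], max_depth=hp["max_depth"],
                random_state=seed, n_jobs=1)
        if self.family == "gbm":
            return HistGradientBoostingRegressor(
                max_iter=hp["n_trees"], max_depth=hp["max_depth"],
                max_bins=hp["n_bins"], learning_rate=hp["learning_rate"],
                early_stopping=False, random_state=seed)
        return make_pipeline(StandardScaler(), LinearRegression())


@dataclass
class ExtractorSet:
    """Five trained regressors (one per parameter) of one family."""

    spec: ModelFamilySpec
    regressors: dict
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.regressors) != set(PARAM_NAMES):
            raise ValueError("need exactly one regressor per parameter")

    def save(self, path):
        joblib.dump({"spec": asdict(self.spec), "regressors": self.regressors,
                     "metadata": self.metadata}, path)

    @classmethod
    def load(cls, path):
        blob = joblib.load(path)
        return cls(ModelFamilySpec(**blob["spec"]), blob["regressors"],
                   blob["metadata"])


def train(spec: ModelFamilySpec, dataset: SimulatedDataset,
          X=None, y=None) -> ExtractorSet:
    """Train one family on the dataset's training split.

    ``X``/``y`` (a feature matrix and a {param: target} dict) may be passed to
    bypass the dataset split, e.g. for synthetic-target checks.
    """
    if X is None:
        X = dataset.train_X
        y = {n: dataset.train_y(n) for n in PARAM_NAMES}
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training split")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training features")
    seeds = np.random.SeedSequence((spec.seed, 0x3A)).generate_state(
        len(PARAM_NAMES))
    regressors = {}
    loss_traces = {}
    for name, sub in zip(PARAM_NAMES, seeds):
        model = spec.build(int(sub % (2 ** 31)))
        with warnings.catch_warnings():
            # the fixed 10-epoch budget intentionally stops Adam early
            warnings.filterwarnings("ignore", category=ConvergenceWarning)
            model.fit(X, y[name])
        regressors[name] = model
        inner = getattr(model, "regressor_", None)
        if inner is not None and hasattr(inner[-1], "loss_curve_"):
            loss_traces[name] = list(map(float, inner[-1].loss_curve_))
    meta = {"n_rows": int(X.shape[0]), "seed": spec.seed,
            "loss_traces": loss_traces}
    return ExtractorSet(spec, regressors, meta)


def predict(extractors: ExtractorSet, spectra6) -> pd.DataFrame:
    """Predict all five parameters for an (N, 6) feature matrix."""
    X = np.asarray(spectra6, dtype=float)
    if X.ndim != 2 or X.shape[1] != 6:
        raise ValueError(f"expected (N, 6) features, got {X.shape}")
    return pd.DataFrame({n: extractors.regressors[n].predict(X)
                         for n in PARAM_NAMES})
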