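"""The representation x regressor QSAR model grid.

Each model is a function f mapping a compound (SMILES) to a predicted
activity label, built by combining one molecular representation (circular
fingerprints, descriptor vectors, or a trainable graph encoder) with one
regression technique (random forest, k-nearest neighbours, or a multilayer
perceptron). Hyperparameters are optimised on an inner validation split of
the training data only; test compounds never reach the objective.

``QSARRegressor`` is the sklearn-style front door; ``OracleModel`` is a
pass-through model returning true labels, used as the degenerate upper bound
in pair-level evaluation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.utils.validation import check_is_fitted

from .features import ECFPFeaturizer, GINFeaturizer, PDVFeaturizer
from .gin import GINModel, GraphEncoderConfig, mol_graph, train_gin, train_gin_features
from .hpo import HPOPlan, default_plan, inner_split, run_hpo
from .nn import Sequential, TrainConfig, predict_mlp, train_mlp

REPRESENTATIONS = ("ecfp", "pdv", "gin")
REGRESSORS = ("rf", "knn", "mlp")

#: Grid of neural-encoder settings is deliberately small at desk scale; the
#: encoder architecture itself is configured, not searched.
DEFAULT_GIN_CONFIG = GraphEncoderConfig(n_conv_layers=2, hidden_dim=64)


class NoTrainingDataError(ValueError):
    pass


class _NumpyMLPRegressor(BaseEstimator, RegressorMixin):
    """Feed-forward regressor (ReLU + batch-norm hidden layers, AdamW, MSE)."""

    def __init__(
        self,
        hidden=(128, 64),
        batch_size: int = 64,
        lr: float = 1e-3,
        lr_decay: float = 1.0,
        weight_decay: float = 0.0,
        dropout: float = 0.0,
        epochs: int = 500,
        seed: int = 0,
    ):
        self.hidden = hidden
        self.batch_size = batch_size
        self.lr = lr
        self.lr_decay = lr_decay
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.epochs = epochs
        self.seed = seed

    def fit(self, X, y):
        cfg = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            lr_decay=self.lr_decay,
            weight_decay=self.weight_decay,
            dropout=self.dropout,
            hidden=tuple(self.hidden),
            seed=self.seed,
        )
        self.net_, self.losses_ = train_mlp(np.asarray(X), np.asarray(y), cfg)
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        return predict_mlp(self.net_, np.asarray(X))


def _make_base_regressor(regressor: str, params: dict, seed: int, epochs: int, binary_features: bool):
    if regressor == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if regressor == "knn":
        metric = params.pop("metric", "jaccard" if binary_features else "euclidean")
        return KNeighborsRegressor(metric=metric, **params)
    if regressor == "mlp":
        return _NumpyMLPRegressor(epochs=epochs, seed=seed, **params)
    raise ValueError(f"unknown regressor {regressor!r}")


class QSARRegressor(BaseEstimator, RegressorMixin):
    """One representation x regressor QSAR model with inner HPO.

    Parameters
    ----------
    representation : {'ecfp', 'pdv', 'gin'}
    regressor : {'rf', 'knn', 'mlp'}
    hpo : HPOPlan or None
        Search plan; None uses the shipped default grid for the regressor
        (random sampling for rf/knn, TPE for mlp) with ``n_trials`` trials.
    n_trials : int
        Trial budget when ``hpo`` is None.
    epochs : int
        Epoch budget for neural components (the printed default is 500; desk
        runs use less).
    random_state : int
        Seeds featurisation-independent randomness: the inner split, HPO
        sampling, and network initialisation.

    After ``fit``: ``featurizer_``, ``model_``, ``best_params_``,
    ``hpo_trials_``, ``inner_split_``, and for the graph representation
    ``encoder_``. ``predict`` is deterministic once fitted.
    """

    def __init__(
        self,
        representation: str = "ecfp",
        regressor: str = "rf",
        hpo: HPOPlan | None = None,
        n_trials: int = 8,
        epochs: int = 500,
        gin_config: GraphEncoderConfig = DEFAULT_GIN_CONFIG,
        gin_train_config: TrainConfig | None = None,
        random_state: int = 0,
    ):
        self.representation = representation
        self.regressor = regressor
        self.hpo = hpo
        self.n_trials = n_trials
        self.epochs = epochs
        self.gin_config = gin_config
        self.gin_train_config = gin_train_config
        self.random_state = random_state

    # -- featurisation ---------------------------------------------------

    def _make_featurizer(self):
        if self.representation == "ecfp":
            return ECFPFeaturizer()
        if self.representation == "pdv":
            return PDVFeaturizer()
        if self.representation == "gin":
            return None  # built after encoder training
        raise ValueError(f"unknown representation {self.representation!r}")

    def _gin_train_config(self) -> TrainConfig:
        if self.gin_train_config is not None:
            cfg = self.gin_train_config
            return TrainConfig(
                epochs=self.epochs,
                batch_size=cfg.batch_size,
                lr=cfg.lr,
                lr_decay=cfg.lr_decay,
                weight_decay=cfg.weight_decay,
                dropout=cfg.dropout,
                hidden=cfg.hidden,
                seed=self.random_state,
            )
        return TrainConfig(epochs=self.epochs, batch_size=64, lr=1e-3, seed=self.random_state)

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y):
        smiles = list(X)
        y = np.asarray(y, dtype=float)
        if len(smiles) < 2:
            raise NoTrainingDataError("need at least two training compounds")
        if not np.all(np.isfinite(y)):
            raise ValueError("labels must be finite")
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.regressor not in REGRESSORS:
            raise ValueError(f"unknown regressor {self.regressor!r}")

        rng = np.random.default_rng(self.random_state)
        plan = self.hpo if self.hpo is not None else default_plan(
            self.regressor if self.regressor in ("rf", "knn", "mlp") else "rf",
            n_trials=self.n_trials,
        )
        tr_idx, val_idx = inner_split(len(smiles), plan.val_fraction, rng)
        self.inner_split_ = (tr_idx, val_idx)
        # instrumentation: exactly the compounds whose labels the HPO
        # objective may see (all drawn from the training call)
        self.hpo_objective_smiles_ = {smiles[i] for i in np.concatenate([tr_idx, val_idx])}

        if self.representation == "gin" and self.regressor == "mlp":
            return self._fit_gin_mlp(smiles, y, plan, rng, tr_idx, val_idx)

        if self.representation == "gin":
            self.encoder_ = self._fit_encoder(smiles, y)
            featurizer = GINFeaturizer(self.encoder_)
        else:
            featurizer = self._make_featurizer()

        smiles_tr = [smiles[i] for i in tr_idx]
        smiles_val = [smiles[i] for i in val_idx]
        inner_featurizer = clone(featurizer) if not isinstance(featurizer, GINFeaturizer) else featurizer
        inner_featurizer.fit(smiles_tr)
        binary = self.representation == "ecfp"
        cast = (lambda a: a.astype(bool)) if binary and self.regressor == "knn" else (lambda a: a)
        self._cast_ = cast
        x_tr = cast(inner_featurizer.transform(smiles_tr))
        x_val = cast(inner_featurizer.transform(smiles_val))

        def objective(params: dict) -> float:
            model = _make_base_regressor(self.regressor, dict(params), self.random_state, self.epochs, binary)
            model.fit(x_tr, y[tr_idx])
            pred = model.predict(x_val)
            return float(np.abs(pred - y[val_idx]).mean())

        self.best_params_, self.hpo_trials_ = run_hpo(objective, plan, rng)

        featurizer.fit(smiles)
        x_all = cast(featurizer.transform(smiles))
        self.model_ = _make_base_regressor(
            self.regressor, dict(self.best_params_), self.random_state, self.epochs, binary
        )
        self.model_.fit(x_all, y)
        self.featurizer_ = featurizer
        self._mode_ = "tabular"
        return self

    def _fit_encoder(self, smiles, y):
        graphs = [mol_graph(s) for s in smiles]
        encoder, self.encoder_losses_ = train_gin_features(
            graphs, y, self.gin_config, self._gin_train_config()
        )
        return encoder

    def _fit_gin_mlp(self, smiles, y, plan, rng, tr_idx, val_idx):
        """End-to-end graph encoder + MLP projection head."""
        graphs = [mol_graph(s) for s in smiles]
        g_tr = [graphs[i] for i in tr_idx]
        g_val = [graphs[i] for i in val_idx]

        def train_with(params: dict, gs, ys):
            cfg = TrainConfig(
                epochs=self.epochs,
                batch_size=params.get("batch_size", 64),
                lr=params.get("lr", 1e-3),
                lr_decay=params.get("lr_decay", 1.0),
                weight_decay=params.get("weight_decay", 0.0),
                dropout=params.get("dropout", 0.0),
                hidden=tuple(params.get("hidden", (64,))),
                seed=self.random_state,
            )
            encoder, head, losses = train_gin(gs, ys, self.gin_config, cfg, head="mlp")
            return GINModel(encoder, head), losses

        def objective(params: dict) -> float:
            model, _ = train_with(params, g_tr, y[tr_idx])
            pred = model.predict(g_val)
            return float(np.abs(pred - y[val_idx]).mean())

        self.best_params_, self.hpo_trials_ = run_hpo(objective, plan, rng)
        model, self.encoder_losses_ = train_with(self.best_params_, graphs, y)
        model.encoder.frozen = True
        self.model_ = model
        self.encoder_ = model.encoder
        self.featurizer_ = None
        self._mode_ = "gin_mlp"
        return self

    # -- prediction ------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        smiles = list(X)
        if self._mode_ == "gin_mlp":
            return self.model_.predict([mol_graph(s) for s in smiles])
        x = self._cast_(self.featurizer_.transform(smiles))
        return np.asarray(self.model_.predict(x), dtype=float)

    @property
    def model_tag(self) -> str:
        return f"{self.representation.upper()}-{self.regressor.upper()}"


class OracleModel(BaseEstimator, RegressorMixin):
    """Pass-through model returning the true training labels.

    Plugs into the same interface as the QSAR models and provides the
    degenerate optimum of pair-level evaluation (zero error everywhere)."""

    def fit(self, X, y):
        self.labels_ = dict(zip(list(X), np.asarray(y, dtype=float)))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "labels_")
        try:
            return np.array([self.labels_[s] for s in X], dtype=float)
        except KeyError as exc:
            raise KeyError(f"oracle has no label for compound {exc.args[0]!r}") from exc


def train_qsar_model(
    smiles,
    labels,
    representation: str,
    regressor: str,
    hpo: HPOPlan | None = None,
    n_trials: int = 8,
    epochs: int = 500,
    random_state: int = 0,
) -> QSARRegressor:
    """Functional wrapper: fit one representation x regressor model."""
    model = QSARRegressor(
        representation=representation,
        regressor=regressor,
        hpo=hpo,
        n_trials=n_trials,
        epochs=epochs,
        random_state=random_state,
    )
    return model.fit(smiles, labels)
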