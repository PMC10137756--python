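"""The dual-branch time-dependent survival network and its training loop.

The hazard is modelled as h(t|x) = h0(t) exp g(t, x).  Categorical
covariates pass through column embedding and a transformer encoder; the
encoder outputs for the N feature tokens are flattened, concatenated with
the continuous covariates and the (standardised) evaluation time, and fed
to a residual dense block ending in a scalar head g(t, x).

Training minimises the time-dependent Cox partial likelihood in risk-set
relative form: each observed event i contributes

    log sum_{j in R~_i} exp(g(t_i, x_j) - g(t_i, x_i)),

where R~_i contains i itself plus controls sampled uniformly (with
replacement) from the risk set {j : t_j >= t_i}.  Because the j = i summand
is exp(0) = 1, every term — and hence the loss — is non-negative, and the
objective is invariant to adding a constant to g (the baseline hazard
absorbs it).  Validation loss for model selection uses full risk sets and
is deterministic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np

from ._autodiff import Adam, Tensor, concat, logsumexp, relu
from .data import (SurvivalDataset, apply_preprocessor, fit_preprocessor,
                   stratified_kfold)
from .breslow import breslow_fit, median_survival_time, predict_survival
from .embedding import ColumnEmbeddingTable, EncoderConfig, encoder_forward, \
    init_encoder_params
from .metrics import c_index as _c_index, mae_uncensored
from .schema import FeatureSchema

__all__ = [
    "TrainingConfig",
    "TTSurvNetwork",
    "LinearRiskNetwork",
    "forward_risk",
    "partial_likelihood_loss",
    "train",
    "linear_baseline",
    "TTSurvModel",
    "LinearCoxModel",
    "SurvivalResults",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings; ``batch_size`` counts event terms per step."""

    learning_rate: float = 2e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 30
    sampled_controls: int = 16
    weight_decay: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience, self.sampled_controls) <= 0:
            raise ValueError("all training settings must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def _dense_block_params(n_in: int, width: int,
                        rng: np.random.Generator) -> dict[str, Tensor]:
    def lin(a: int, b: int) -> Tensor:
        return Tensor(rng.normal(0, 1.0 / np.sqrt(a), (a, b)), requires_grad=True)

    return {
        "W1": lin(n_in, width), "b1": Tensor(np.zeros(width), requires_grad=True),
        "W2": lin(width, width), "b2": Tensor(np.zeros(width), requires_grad=True),
        "P": lin(n_in, width), "bp": Tensor(np.zeros(width), requires_grad=True),
        "Wh": lin(width, 1), "bh": Tensor(np.zeros(1), requires_grad=True),
    }


class TTSurvNetwork:
    """Transformer branch + residual dense block realising g(t, x)."""

    def __init__(self, schema: FeatureSchema,
                 encoder: EncoderConfig | None = None,
                 hidden: int = 32, seed: int = 0):
        self.schema = schema
        self.encoder_config = encoder or EncoderConfig()
        self.hidden = hidden
        rng = np.random.default_rng(seed)
        self.table = ColumnEmbeddingTable(
            schema.cardinalities, self.encoder_config.d_embed,
            self.encoder_config.n_special_tokens, rng)
        self.encoder_params = init_encoder_params(self.encoder_config, rng)
        n_cat = len(schema.cardinalities)
        self.feature_dim = n_cat * self.encoder_config.d_embed + len(schema.continuous)
        self.dense = _dense_block_params(self.feature_dim + 1, hidden, rng)
        # time standardisation constants; set from training event times
        self.t_loc = 0.0
        self.t_scale = 1.0

    # -- parameters -----------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps = self.table.parameters()
        for layer in self.encoder_params:
            ps.extend(layer.values())
        ps.extend(self.dense.values())
        return ps

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {"table.per_level": self.table.per_level.data,
             "table.column_id": self.table.column_id.data,
             "table.special": self.table.special.data,
             "t_loc": np.array(self.t_loc), "t_scale": np.array(self.t_scale)}
        for i, layer in enumerate(self.encoder_params):
            for k, v in layer.items():
                d[f"enc{i}.{k}"] = v.data
        for k, v in self.dense.items():
            d[f"dense.{k}"] = v.data
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        self.table.per_level.data = np.array(d["table.per_level"])
        self.table.column_id.data = np.array(d["table.column_id"])
        self.table.special.data = np.array(d["table.special"])
        self.t_loc = float(d["t_loc"])
        self.t_scale = float(d["t_scale"])
        for i, layer in enumerate(self.encoder_params):
            for k in layer:
                layer[k].data = np.array(d[f"enc{i}.{k}"])
        for k in self.dense:
            self.dense[k].data = np.array(d[f"dense.{k}"])

    def set_time_scaling(self, event_times: np.ndarray) -> None:
        if len(event_times) == 0:
            return
        self.t_loc = float(np.mean(event_times))
        sd = float(np.std(event_times))
        self.t_scale = sd if sd > 0 else 1.0

    def _scale_t(self, t) -> np.ndarray:
        return (np.asarray(t, dtype=np.float64) - self.t_loc) / self.t_scale

    # -- forward --------------------------------------------------------------
    def subject_features(self, data: SurvivalDataset) -> Tensor:
        """Per-subject feature vector: flattened encoder tokens + continuous."""
        tokens = self.table.embed(data.x_cat, with_special=True)
        enc = encoder_forward(tokens, self.encoder_config, self.encoder_params)
        n_cat = self.table.n_features
        enc = enc.slice_axis(1, 0, n_cat)  # special tokens excluded from pooling
        flat = enc.reshape(data.n, n_cat * self.encoder_config.d_embed)
        if data.x_cont.shape[1]:
            flat = concat([flat, Tensor(data.x_cont)], axis=1)
        return flat

    def head(self, z: Tensor, t_scaled: np.ndarray) -> Tensor:
        """Residual dense block + scalar head on concat(z, t_scaled)."""
        x = concat([z, Tensor(np.asarray(t_scaled).reshape(-1, 1))], axis=1)
        p = self.dense
        h1 = relu(x @ p["W1"] + p["b1"])
        h2 = relu(h1 @ p["W2"] + p["b2"])
        out = h2 + (x @ p["P"] + p["bp"])  # skip from block input
        g = out @ p["Wh"] + p["bh"]
        return g.reshape(g.shape[0])

    def risk_tensor(self, data: SurvivalDataset, subject_idx: np.ndarray,
                    times: np.ndarray) -> Tensor:
        """g(times[r], x_{subject_idx[r]}) for parallel index arrays (autodiff)."""
        uniq, pos = np.unique(subject_idx, return_inverse=True)
        z = self.subject_features(data.subset(uniq))
        return self.head(z.gather_rows(pos), self._scale_t(times))

    def risk_matrix(self, times: np.ndarray, data: SurvivalDataset,
                    chunk: int = 32) -> np.ndarray:
        """g on the (k times) x (n subjects) grid, numpy forward only.

        The categorical/continuous feature vector z does not depend on t, so
        it is computed once per subject; only the dense block is re-run per
        evaluation time (chunked to bound memory).
        """
        times = np.atleast_1d(np.asarray(times, dtype=np.float64))
        z = self.subject_features(data).data  # (n, F)
        p = {k: v.data for k, v in self.dense.items()}
        F = z.shape[1]
        A1 = z @ p["W1"][:F] + p["b1"]       # time column added per chunk
        S1 = z @ p["P"][:F] + p["bp"]
        ts = self._scale_t(times)
        out = np.empty((len(times), data.n))
        for s in range(0, len(times), chunk):
            tc = ts[s:s + chunk, None, None]  # (c, 1, 1)
            h1 = np.maximum(A1[None] + tc * p["W1"][F], 0.0)
            h2 = np.maximum(h1 @ p["W2"] + p["b2"], 0.0)
            blk = h2 + S1[None] + tc * p["P"][F]
            out[s:s + chunk] = (blk @ p["Wh"])[..., 0] + p["bh"][0]
        return out


class LinearRiskNetwork:
    """Time-free linear risk g(x) = beta' [x_cont, x_cat codes].

    The sanity baseline: same loss machinery as the transformer model, but a
    linear predictor with no time input (a Cox proportional-hazards risk).
    """

    def __init__(self, schema: FeatureSchema, seed: int = 0, **_ignored):
        self.schema = schema
        n_in = len(schema.continuous) + len(schema.cardinalities)
        rng = np.random.default_rng(seed)
        self.beta = Tensor(rng.normal(0, 0.01, (n_in, 1)), requires_grad=True)
        self.t_loc, self.t_scale = 0.0, 1.0

    def parameters(self) -> list[Tensor]:
        return [self.beta]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {"beta": self.beta.data,
                "t_loc": np.array(self.t_loc), "t_scale": np.array(self.t_scale)}

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        self.beta.data = np.array(d["beta"])
        self.t_loc, self.t_scale = float(d["t_loc"]), float(d["t_scale"])

    def set_time_scaling(self, event_times: np.ndarray) -> None:
        pass  # time never enters the linear predictor

    @property
    def coefficients(self) -> np.ndarray:
        return self.beta.data[:, 0].copy()

    def design(self, data: SurvivalDataset) -> np.ndarray:
        return np.column_stack([data.x_cont, data.x_cat.astype(np.float64)])

    def risk_tensor(self, data: SurvivalDataset, subject_idx: np.ndarray,
                    times: np.ndarray) -> Tensor:
        X = Tensor(self.design(data)[subject_idx])
        g = X @ self.beta
        return g.reshape(g.shape[0])

    def risk_matrix(self, times, data: SurvivalDataset) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=np.float64))
        g = self.design(data) @ self.beta.data[:, 0]
        return np.broadcast_to(g, (len(times), data.n)).copy()


# ---------------------------------------------------------------------------
# loss and training
# ---------------------------------------------------------------------------

def forward_risk(model, t, x_cont, x_cat) -> np.ndarray:
    """Evaluate g(t, x) for one or more (t, x) pairs."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    x_cont = np.asarray(x_cont, dtype=np.float64).reshape(len(t), -1)
    x_cat = np.asarray(x_cat, dtype=np.int64).reshape(len(t), -1)
    if not (np.isfinite(t).all() and np.isfinite(x_cont).all()):
        raise ValueError("non-finite input to forward_risk")
    data = SurvivalDataset(model.schema, x_cont, x_cat, np.ones(len(t)),
                           np.zeros(len(t), dtype=int),
                           np.arange(len(t)))
    idx = np.arange(len(t))
    return model.risk_tensor(data, idx, t).data


def _pair_loss(model, data: SurvivalDataset, event_idx: np.ndarray,
               controls: np.ndarray) -> Tensor:
    """Mean over events of log sum_j exp(g_j - g_i) on sampled risk sets."""
    B, s = controls.shape
    subjects = np.column_stack([event_idx, controls])          # (B, 1+s)
    times = np.repeat(data.t[event_idx], 1 + s)
    g = model.risk_tensor(data, subjects.ravel(), times).reshape(B, 1 + s)
    case = g.slice_axis(1, 0, 1).reshape(B)
    return (logsumexp(g, axis=1) - case).mean()


def full_risk_set_loss(model, data: SurvivalDataset) -> float:
    """Exact time-dependent partial likelihood (full risk sets), numpy only."""
    if data.n_events == 0:
        raise ValueError("loss needs at least one event")
    uniq = np.unique(data.t[data.d == 1])
    G = model.risk_matrix(uniq, data)                     # (k, n)
    at_risk = data.t[None, :] >= uniq[:, None]
    M = np.where(at_risk, G, -np.inf)
    mx = M.max(axis=1, keepdims=True)
    lse = (mx[:, 0] + np.log(np.exp(M - mx).sum(axis=1)))  # (k,)
    ev = np.flatnonzero(data.d == 1)
    row = np.searchsorted(uniq, data.t[ev])
    return float(np.mean(lse[row] - G[row, ev]))


def partial_likelihood_loss(model, batch: SurvivalDataset,
                            sampled_controls: int | None = None,
                            seed: int = 0) -> float:
    """Risk-set partial-likelihood loss (non-negative real).

    ``sampled_controls=None`` uses full risk sets (the exact loss); an
    integer draws that many controls per event uniformly with replacement
    from the event's risk set.
    """
    if batch.n_events == 0:
        raise ValueError("loss needs at least one event")
    if sampled_controls is None:
        return full_risk_set_loss(model, batch)
    rng = np.random.default_rng(seed)
    ev = np.flatnonzero(batch.d == 1)
    controls = _sample_controls(batch.t, ev, sampled_controls, rng)
    return float(_pair_loss(model, batch, ev, controls).data)


def _sample_controls(t: np.ndarray, event_idx: np.ndarray, s: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Uniform-with-replacement draws from each event's risk set."""
    order = np.argsort(t, kind="stable")
    start = np.searchsorted(t[order], t[event_idx], side="left")
    u = rng.random((len(event_idx), s))
    pos = (start[:, None] + u * (len(t) - start[:, None])).astype(np.intp)
    return order[pos]


def train(model, train_data: SurvivalDataset, valid: SurvivalDataset,
          config: TrainingConfig) -> dict:
    """Gradient-based fit; returns the training history.

    The returned model carries the parameters from the epoch with the lowest
    full-risk-set validation loss; training stops after ``patience`` epochs
    without improvement or at ``max_epochs``.  Fully reproducible per seed.
    """
    if train_data.n_events == 0 or valid.n_events == 0:
        raise ValueError("both training and validation sets need events")
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate,
               weight_decay=config.weight_decay)
    model.set_time_scaling(train_data.t[train_data.d == 1])
    events = np.flatnonzero(train_data.d == 1)
    history: dict = {"train_loss": [], "valid_loss": [], "best_epoch": 0}
    best_loss = np.inf
    best_state = None
    since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(events)
        batch_losses = []
        for s in range(0, len(order), config.batch_size):
            ev = order[s:s + config.batch_size]
            controls = _sample_controls(train_data.t, ev,
                                        config.sampled_controls, rng)
            opt.zero_grad()
            loss = _pair_loss(model, train_data, ev, controls)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
        vloss = full_risk_set_loss(model, valid)
        if not np.isfinite(vloss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["valid_loss"].append(vloss)
        if vloss < best_loss - 1e-12:
            best_loss = vloss
            best_state = copy.deepcopy(model.state_dict())
            history["best_epoch"] = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def linear_baseline(train_data: SurvivalDataset, valid: SurvivalDataset,
                    config: TrainingConfig) -> tuple[LinearRiskNetwork, dict]:
    """Train the linear, time-free sanity baseline with the same machinery."""
    net = LinearRiskNetwork(train_data.schema, seed=config.seed)
    history = train(net, train_data, valid, config)
    return net, history


# ---------------------------------------------------------------------------
# statsmodels-style model / results wrappers
# ---------------------------------------------------------------------------

class _SurvivalModelBase:
    """Shared fitting logic: preprocessing, training, Breslow baseline."""

    network_cls: type

    def __init__(self, data: SurvivalDataset, encoder: EncoderConfig | None = None,
                 hidden: int = 32):
        self.data = data
        self.schema = data.schema
        self.encoder = encoder
        self.hidden = hidden

    @classmethod
    def from_dataframe(cls, df, schema: FeatureSchema, **kwargs):
        from .data import dataset_from_dataframe
        return cls(dataset_from_dataframe(df, schema), **kwargs)

    def fit(self, config: TrainingConfig | None = None,
            valid: SurvivalDataset | None = None,
            valid_fraction: float = 0.2) -> "SurvivalResults":
        config = config or TrainingConfig()
        if valid is None:
            k = max(2, int(round(1.0 / valid_fraction)))
            tr_idx, va_idx = stratified_kfold(self.data, k, config.seed)[0]
            raw_train, raw_valid = self.data.subset(tr_idx), self.data.subset(va_idx)
        else:
            raw_train, raw_valid = self.data, valid
        pre = fit_preprocessor(raw_train, self.schema)
        train_p = apply_preprocessor(pre, raw_train)
        valid_p = apply_preprocessor(pre, raw_valid)
        net = self.network_cls(self.schema, encoder=self.encoder,
                               hidden=self.hidden, seed=config.seed) \
            if self.network_cls is TTSurvNetwork else \
            self.network_cls(self.schema, seed=config.seed)
        history = train(net, train_p, valid_p, config)
        hazard = breslow_fit(net, train_p)
        return SurvivalResults(self, net, pre, hazard, history, config,
                               n_train=train_p.n, n_train_events=train_p.n_events)


class TTSurvModel(_SurvivalModelBase):
    """Transformer-based time-dependent survival model for tabular data."""

    network_cls = TTSurvNetwork


class LinearCoxModel(_SurvivalModelBase):
    """Linear proportional-hazards sanity baseline on the same machinery."""

    network_cls = LinearRiskNetwork


class SurvivalResults:
    """Fitted parameters, baseline hazard, history and prediction methods."""

    def __init__(self, model: _SurvivalModelBase, network, preprocessor, hazard,
                 history: dict, config: TrainingConfig,
                 n_train: int, n_train_events: int):
        self.model = model
        self.network = network
        self.preprocessor = preprocessor
        self.baseline_hazard = hazard
        self.history = history
        self.config = config
        self.n_train = n_train
        self.n_train_events = n_train_events

    # -- predictions -----------------------------------------------------------
    def _prep(self, data: SurvivalDataset) -> SurvivalDataset:
        return apply_preprocessor(self.preprocessor, data)

    def predict_survival(self, data: SurvivalDataset):
        return predict_survival(self.network, self.baseline_hazard,
                                self._prep(data))

    def predict_median(self, data: SurvivalDataset) -> tuple[np.ndarray, np.ndarray]:
        """Per-patient median life in days + crossed flag."""
        out = [median_survival_time(c) for c in self.predict_survival(data)]
        days = np.array([d for d, _ in out])
        crossed = np.array([c for _, c in out], dtype=bool)
        return days, crossed

    def risk_score(self, data: SurvivalDataset) -> np.ndarray:
        """Scalar risk per patient: total predicted cumulative hazard.

        eta = -log S(t_max | x) summarises the whole predicted curve and is
        continuous, so concordance ties are avoided even for patients whose
        curves never cross 0.5.
        """
        curves = self.predict_survival(data)
        return np.array([-np.log(max(c.survival[-1], 1e-300)) for c in curves])

    def c_index(self, data: SurvivalDataset, tie_credit: bool = False) -> float:
        return _c_index(data.t, self.risk_score(data), data.d,
                        tie_credit=tie_credit)

    def mae(self, data: SurvivalDataset) -> float:
        days, _ = self.predict_median(data)
        return mae_uncensored(data.t, days, data.d)

    # -- reporting -------------------------------------------------------------
    def summary(self) -> str:
        kind = type(self.model).__name__
        lines = [
            f"{kind} fit results",
            "=" * 46,
            f"{'n (train)':<28}{self.n_train:>18}",
            f"{'events (train)':<28}{self.n_train_events:>18}",
            f"{'epochs run':<28}{len(self.history['train_loss']):>18}",
            f"{'best epoch':<28}{self.history['best_epoch']:>18}",
            f"{'best validation loss':<28}"
            f"{min(self.history['valid_loss']):>18.4f}",
            f"{'baseline hazard steps':<28}"
            f"{len(self.baseline_hazard.event_times):>18}",
        ]
        if isinstance(self.network, LinearRiskNetwork):
            names = ([f.name for f in self.model.schema.continuous]
                     + [f.name for f in self.model.schema.categorical])
            lines.append("-" * 46)
            lines.append(f"{'coefficient':<28}{'estimate':>18}")
            for name, b in zip(names, self.network.coefficients):
                lines.append(f"{name:<28}{b:>18.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    # -- serialisation ---------------------------------------------------------
    def save(self, path) -> None:
        import json
        arrays = {f"net.{k}": v for k, v in self.network.state_dict().items()}
        arrays["hazard.times"] = self.baseline_hazard.event_times
        arrays["hazard.increments"] = self.baseline_hazard.increments
        arrays["pre.location"] = self.preprocessor.location
        arrays["pre.scale"] = self.preprocessor.scale
        meta = {
            "model": type(self.model).__name__,
            "schema": self.model.schema.to_dict(),
            "hidden": getattr(self.model, "hidden", None),
            "encoder": (None if getattr(self.model, "encoder", None) is None
                        else vars(self.model.encoder)
                        if not hasattr(self.model.encoder, "__dataclass_fields__")
                        else {k: getattr(self.model.encoder, k)
                              for k in self.model.encoder.__dataclass_fields__}),
            "config": {k: getattr(self.config, k)
                       for k in self.config.__dataclass_fields__},
            "history": self.history,
            "n_train": self.n_train,
            "n_train_events": self.n_train_events,
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SurvivalResults":
        import json

        from .breslow import BaselineHazard
        from .data import Preprocessor
        with np.load(path) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(bytes(arrays.pop("meta")).decode())
        schema = FeatureSchema.from_dict(meta["schema"])
        enc = (EncoderConfig(**meta["encoder"]) if meta["encoder"] else None)
        if meta["model"] == "TTSurvModel":
            model = TTSurvModel.__new__(TTSurvModel)
            model.schema, model.encoder, model.hidden = schema, enc, meta["hidden"]
            net = TTSurvNetwork(schema, encoder=enc, hidden=meta["hidden"])
        else:
            model = LinearCoxModel.__new__(LinearCoxModel)
            model.schema, model.encoder, model.hidden = schema, None, None
            net = LinearRiskNetwork(schema)
        model.data = None
        net.load_state_dict(
            {k[4:]: v for k, v in arrays.items() if k.startswith("net.")})
        hazard = BaselineHazard(arrays["hazard.times"], arrays["hazard.increments"])
        pre = Preprocessor(schema, arrays["pre.location"], arrays["pre.scale"])
        cfg = TrainingConfig(**meta["config"])
        return cls(model, net, pre, hazard, meta["history"], cfg,
                   meta["n_train"], meta["n_train_events"])
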