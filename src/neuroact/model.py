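"""The ZINB single-unit-bottleneck autoencoder.

Standardized expression enters two parallel encoder stacks of [16, 8, 4]
dense units (ELU + batch normalization). One stack ends in the information
bottleneck — a dense layer with sigmoid activation, one unit by default —
whose activation is the activity score. The other stack parameterizes the
dispersion (theta, softplus) and dropout (pi, sigmoid) of a zero-inflated
negative binomial. Auxiliary covariates (cell type, dataset, depth) bypass
the bottleneck through their own two-layer branch into a six-unit layer, so
the bottleneck does not have to encode nuisance structure. Bottleneck, aux
layer and the dispersion/dropout outputs (through a stop-gradient, so they
cannot be co-opted as a bypass channel for the mean signal) are concatenated
into the penultimate decoder layer feeding the mean head:
mu = exp(dense) * size_factor. Training
minimizes the ZINB negative log-likelihood over the target genes only (or a
whole-transcriptome variant), for 10 epochs with ADAM. A binary cross-entropy
monitor reads the bottleneck through a stop-gradient, so classification
accuracy is tracked without leaking label information into the weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import autodiff as ad
from .autodiff import Adam, BatchNorm, Dense, Tensor
from .io import CountMatrix
from .preprocess import (
    PreprocessParams,
    apply_standardizer,
    augment_counts,
    fit_standardizer,
    lognormalize,
)

__all__ = [
    "ModelConfig",
    "ActivityNetwork",
    "TrainedActivityModel",
    "ActivityScores",
    "zinb_nll",
    "build",
    "build_variant",
    "train",
    "score",
    "fit_activity_model",
]

THETA_MIN, THETA_MAX = 1e-4, 1e4
MU_MIN, MU_MAX = 1e-10, 1e6


# ---------------------------------------------------------------------------
# ZINB negative log-likelihood
# ---------------------------------------------------------------------------


def zinb_nll(x, mu, theta, pi, reduce: str | None = "mean"):
    """Zero-inflated negative binomial NLL, elementwise in log space.

    NLL = -ln[ pi * 1{x=0} + (1 - pi) * NB(x; mu, theta) ] with
    NB(x) = G(x+theta)/(G(theta) x!) (theta/(theta+mu))^theta (mu/(theta+mu))^x.

    `reduce=None` returns the per-element matrix; "mean" averages over all
    entries (genes and cells).
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be strictly positive")
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi must lie in [0, 1]")
    log_theta_mu = np.log(theta + mu)
    log_nb = (
        gammaln(x + theta) - gammaln(theta) - gammaln(x + 1)
        + theta * (np.log(theta) - log_theta_mu)
        + x * (np.log(mu) - log_theta_mu)
    )
    nb_zero = np.exp(theta * (np.log(theta) - log_theta_mu))
    zero_case = np.log(pi + (1.0 - pi) * nb_zero)
    with np.errstate(divide="ignore"):
        pos_case = np.log1p(-pi) + log_nb
    nll = -np.where(x == 0, zero_case, pos_case)
    return float(nll.mean()) if reduce == "mean" else nll


def _zinb_nll_ad(x: np.ndarray, mu: Tensor, theta: Tensor, pi: Tensor) -> Tensor:
    """Autodiff twin of `zinb_nll` used as the training loss (mean-reduced)."""
    x = np.asarray(x, dtype=float)
    zero_mask = (x == 0).astype(float)
    log_theta = theta.log()
    log_theta_mu = (theta + mu).log()
    log_nb = (
        (x + theta).lgamma()
        - theta.lgamma()
        - Tensor(gammaln(x + 1))
        + theta * (log_theta - log_theta_mu)
        + x * (mu.log() - log_theta_mu)
    )
    nb_zero = (theta * (log_theta - log_theta_mu)).exp()
    zero_case = (pi + (1.0 - pi) * nb_zero + 1e-12).log()
    pos_case = (1.0 - pi + 1e-10).log() + log_nb
    nll = -(zero_mask * zero_case + (1.0 - zero_mask) * pos_case)
    return nll.mean()


# ---------------------------------------------------------------------------
# Configuration and network
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    n_input_genes: int
    target_gene_indices: list
    n_aux: int = 0
    encoder_units: tuple = (16, 8, 4)
    bottleneck_units: int = 1
    aux_units: tuple = (8, 8)
    aux_out: int = 6
    penultimate_units: int = 8
    gaussian_dropout_rate: float = 0.1
    epochs: int = 10
    learning_rate: float = 5e-3
    batch_size: int = 128
    loss_mode: str = "targets_only"
    seed: int = 0

    def __post_init__(self):
        idx = np.asarray(self.target_gene_indices)
        if idx.size == 0 or idx.min() < 0 or idx.max() >= self.n_input_genes:
            raise ValueError("target gene indices out of range")
        if self.bottleneck_units < 1:
            raise ValueError("bottleneck must have >= 1 unit")
        if self.loss_mode not in (
            "targets_only", "whole_transcriptome_equal_weight", "transcriptome_naive"
        ):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")


class _EncoderStack:
    def __init__(self, n_in, units, rng):
        self.layers = []
        for u in units:
            self.layers.append((Dense(n_in, u, rng), BatchNorm(u)))
            n_in = u

    def __call__(self, h, training):
        for dense, bn in self.layers:
            h = bn(dense(h), training).elu()
        return h

    @property
    def params(self):
        out = []
        for dense, bn in self.layers:
            out += dense.params + bn.params
        return out


class ActivityNetwork:
    """Computation graph of the autoencoder; see module docstring."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        G = config.n_input_genes
        T = len(config.target_gene_indices)
        k = config.bottleneck_units

        self.input_mask = np.ones(G)
        if config.loss_mode == "transcriptome_naive":
            self.input_mask = np.zeros(G)
            self.input_mask[np.asarray(config.target_gene_indices)] = 1.0

        self.encoder = _EncoderStack(G, config.encoder_units, rng)
        self.bottleneck_head = Dense(config.encoder_units[-1], k, rng)
        self.par_encoder = _EncoderStack(G, config.encoder_units, rng)
        self.theta_head = Dense(config.encoder_units[-1], T, rng)
        self.pi_head = Dense(config.encoder_units[-1], T, rng)
        self.aux1 = Dense(config.n_aux, config.aux_units[0], rng)
        self.aux2 = Dense(config.aux_units[0], config.aux_units[1], rng)
        self.aux3 = Dense(config.aux_units[1], config.aux_out, rng)
        pen_in = k + config.aux_out + 2 * T
        self.penultimate = Dense(pen_in, config.penultimate_units, rng)
        self.mu_head = Dense(config.penultimate_units, T, rng)
        self.monitor_head = Dense(k, 1, rng)
        self._heads_all = None
        if config.loss_mode == "whole_transcriptome_equal_weight":
            self._heads_all = (
                Dense(config.encoder_units[-1], G, rng),  # theta, all genes
                Dense(config.encoder_units[-1], G, rng),  # pi, all genes
                Dense(config.penultimate_units, G, rng),  # mu, all genes
            )
        self._rng = rng

    @property
    def params(self):
        out = (
            self.encoder.params
            + self.bottleneck_head.params
            + self.par_encoder.params
            + self.theta_head.params
            + self.pi_head.params
            + self.aux1.params
            + self.aux2.params
            + self.aux3.params
            + self.penultimate.params
            + self.mu_head.params
            + self.monitor_head.params
        )
        if self._heads_all is not None:
            for h in self._heads_all:
                out += h.params
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def forward(self, x=None, aux=None, size_factors=None, training=False,
                input_tensor: Tensor | None = None):
        """Run the graph. Returns a dict with bottleneck, mu, theta, pi (and
        mu_all/theta_all/pi_all for the whole-transcriptome variant, plus the
        monitor probability). `input_tensor` lets callers supply a
        differentiable input (for attribution)."""
        cfg = self.config
        if input_tensor is None:
            xt = Tensor(np.atleast_2d(np.asarray(x, dtype=float)))
        else:
            xt = input_tensor
        xt = xt * self.input_mask
        if training and cfg.gaussian_dropout_rate > 0:
            rate = cfg.gaussian_dropout_rate
            noise = self._rng.normal(
                1.0, np.sqrt(rate / (1.0 - rate)), xt.data.shape
            )
            xt = xt * noise
        B = xt.data.shape[0]
        if aux is None:
            aux = np.zeros((B, cfg.n_aux))
        at = Tensor(np.atleast_2d(np.asarray(aux, dtype=float)))
        if size_factors is None:
            size_factors = np.ones(B)
        sf = np.asarray(size_factors, dtype=float).reshape(-1, 1)

        enc = self.encoder(xt, training)
        bottleneck = self.bottleneck_head(enc).sigmoid()
        par = self.par_encoder(xt, training)
        theta = self.theta_head(par).softplus().clip(THETA_MIN, THETA_MAX)
        pi = self.pi_head(par).sigmoid()
        a6 = self.aux3(self.aux2(self.aux1(at).elu()).elu()).elu()
        # the dispersion/dropout *outputs* join the penultimate layer; the
        # parallel branch's hidden units do not, so the mean signal has to
        # flow through the bottleneck (or the aux covariates)
        pen = self.penultimate(ad.concat([bottleneck, a6, theta.stop_gradient(), pi.stop_gradient()], axis=1)).elu()
        mu = (self.mu_head(pen).clip(-30.0, 30.0).exp() * sf).clip(MU_MIN, MU_MAX)
        out = {"bottleneck": bottleneck, "mu": mu, "theta": theta, "pi": pi}
        out["monitor"] = self.monitor_head(bottleneck.stop_gradient()).sigmoid()
        if self._heads_all is not None:
            th_a, pi_a, mu_a = self._heads_all
            out["theta_all"] = th_a(par).softplus().clip(THETA_MIN, THETA_MAX)
            out["pi_all"] = pi_a(par).sigmoid()
            out["mu_all"] = (mu_a(pen).clip(-30.0, 30.0).exp() * sf).clip(MU_MIN, MU_MAX)
        return out


def build(config: ModelConfig) -> ActivityNetwork:
    """Construct an untrained network from its configuration."""
    return ActivityNetwork(config)


def build_variant(kind: str, base: ModelConfig, k: int = 2) -> ActivityNetwork:
    """Benchmark variants: 'transcriptome_naive' blocks non-target inputs,
    'whole_transcriptome' adds an equal-weight all-gene reconstruction head,
    'k_unit' widens the bottleneck to k units."""
    cfg = ModelConfig(**asdict(base))
    if kind == "transcriptome_naive":
        cfg.loss_mode = "transcriptome_naive"
    elif kind == "whole_transcriptome":
        cfg.loss_mode = "whole_transcriptome_equal_weight"
    elif kind == "k_unit":
        if k < 1:
            raise ValueError("k must be >= 1")
        cfg.bottleneck_units = k
    else:
        raise ValueError(f"unknown variant {kind!r}")
    return build(cfg)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainedActivityModel:
    network: ActivityNetwork
    config: ModelConfig
    preprocess: PreprocessParams
    target_genes: list
    training_log: pd.DataFrame
    aux_columns: list = field(default_factory=list)
    # the sigmoid bottleneck's sign is unidentifiable; orientation is fixed
    # after training so higher score = higher target-module expression
    orientation: int = 1


@dataclass
class ActivityScores:
    scores: np.ndarray  # (n,) bottleneck activation (first unit if k > 1)
    bottleneck: np.ndarray  # (n, k)
    cell_ids: list
    excluded: list = field(default_factory=list)  # cells below the count floor
    model_id: str = "zinb-bottleneck"


def _batches(n, batch_size, source_index, rng):
    """Yield index batches in which augmented samples ride with their source
    cell. Groups (source + its augmented companions) are shuffled each call."""
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(source_index):
        groups.setdefault(int(s), []).append(i)
    keys = rng.permutation(list(groups))
    batch: list[int] = []
    for key in keys:
        batch.extend(groups[key])
        if len(batch) >= batch_size:
            yield np.array(batch)
            batch = []
    if batch:
        yield np.array(batch)


def train(network: ActivityNetwork, z: np.ndarray, target_counts: np.ndarray,
          aux: np.ndarray | None = None, size_factors=None, labels=None,
          source_index=None, all_counts: np.ndarray | None = None,
          verbose: bool = False) -> pd.DataFrame:
    """Fit the network in place; returns the per-epoch training log.

    `z` is cells x genes standardized expression; `target_counts` the raw
    counts of the target genes (cells x T; for augmented rows, the *source*
    cell's counts). The monitor BCE is computed through a stop-gradient, so
    labels never influence the reconstruction weights.
    """
    cfg = network.config
    n = z.shape[0]
    source_index = np.arange(n) if source_index is None else np.asarray(source_index)
    if size_factors is None:
        size_factors = np.ones(n)
    rng = np.random.default_rng(cfg.seed + 99)
    params = network.params
    # the diagnostic monitor head sees few gradient steps per epoch; a larger
    # per-parameter rate lets its BCE reach its asymptote within 10 epochs
    monitor_ids = {id(p) for p in network.monitor_head.params}
    scales = [20.0 if id(p) in monitor_ids else 1.0 for p in params]
    opt = Adam(params, lr=cfg.learning_rate, lr_scales=scales)
    log_rows = []
    for epoch in range(cfg.epochs):
        losses, bces = [], []
        for idx in _batches(n, cfg.batch_size, source_index, rng):
            out = network.forward(
                z[idx],
                aux[idx] if aux is not None else None,
                np.asarray(size_factors)[idx],
                training=True,
            )
            loss = _zinb_nll_ad(
                target_counts[idx], out["mu"], out["theta"], out["pi"]
            )
            if cfg.loss_mode == "whole_transcriptome_equal_weight":
                if all_counts is None:
                    raise ValueError("whole-transcriptome loss requires all_counts")
                loss_all = _zinb_nll_ad(
                    all_counts[idx], out["mu_all"], out["theta_all"], out["pi_all"]
                )
                loss = loss * 0.5 + loss_all * 0.5
            recon = float(loss.data)
            if labels is not None:
                y = np.asarray(labels, dtype=float)[idx].reshape(-1, 1)
                p = out["monitor"].clip(1e-7, 1 - 1e-7)
                bce = -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()
                bces.append(float(bce.data))
                loss = loss + bce
            if not np.isfinite(recon):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}; aborting training"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(recon)
        row = {"epoch": epoch + 1, "reconstruction_loss": float(np.mean(losses))}
        if bces:
            row["monitor_bce"] = float(np.mean(bces))
        log_rows.append(row)
        if verbose:
            print(f"epoch {epoch + 1}: {row}")
    return pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# End-to-end fitting and scoring
# ---------------------------------------------------------------------------


def _build_aux(metadata: pd.DataFrame, aux_cols, totals) -> tuple[np.ndarray, list]:
    blocks = [np.log10(np.asarray(totals, dtype=float) + 1.0).reshape(-1, 1)]
    names = ["log10_total"]
    for col in aux_cols or []:
        d = pd.get_dummies(metadata[col].astype(str), prefix=col)
        blocks.append(d.to_numpy(dtype=float))
        names += d.columns.tolist()
    return np.column_stack(blocks), names


def fit_activity_model(counts: CountMatrix, target_genes,
                       metadata: pd.DataFrame | None = None,
                       aux_cols=(), labels=None, augment: bool = False,
                       augment_group_cols=None, scale_factor: float = 1e4,
                       **config_kwargs) -> TrainedActivityModel:
    """Preprocess a count matrix and train the activity model on it.

    Handles log-normalization, training-set standardization, size factors,
    one-hot auxiliary covariates (plus log10 depth), optional count-thinning
    augmentation (augmented samples share their source's reconstruction
    target, size factor and training batch), and the training loop.
    """
    target_genes = [g for g in target_genes if g in set(counts.gene_ids)]
    if not target_genes:
        raise ValueError("no target genes present in the count matrix")
    feature_order = list(counts.gene_ids)
    normalized, totals = lognormalize(counts, feature_order, scale_factor)
    params = fit_standardizer(normalized, feature_order, scale_factor)
    z = apply_standardizer(normalized, params).T  # cells x genes
    tgt_idx = [feature_order.index(g) for g in target_genes]
    raw = counts.dense().astype(float).T
    target_counts = raw[:, tgt_idx]
    sf = totals / np.median(totals)
    aux, aux_names = (
        _build_aux(metadata, aux_cols, totals)
        if metadata is not None
        else (np.log10(totals + 1.0).reshape(-1, 1), ["log10_total"])
    )
    source_index = np.arange(counts.n_cells)
    y = None
    if labels is not None:
        y = np.asarray(labels, dtype=float)

    if augment:
        aug, prov = augment_counts(
            counts, metadata=metadata, group_cols=augment_group_cols,
            seed=config_kwargs.get("seed", 0),
        )
        if aug.n_cells:
            aug_norm, aug_tot = lognormalize(aug, feature_order, scale_factor)
            z_aug = apply_standardizer(aug_norm, params).T
            src = [counts.cell_ids.index(s) for s in prov["source_id"]]
            z = np.vstack([z, z_aug])
            target_counts = np.vstack([target_counts, target_counts[src]])
            raw = np.vstack([raw, raw[src]])
            sf = np.concatenate([sf, sf[src]])
            aux_aug, _ = (
                _build_aux(metadata.iloc[src], aux_cols, aug_tot)
                if metadata is not None
                else (np.log10(aug_tot + 1.0).reshape(-1, 1), None)
            )
            aux = np.vstack([aux, aux_aug])
            source_index = np.concatenate([source_index, np.asarray(src)])
            if y is not None:
                y = np.concatenate([y, y[src]])

    cfg = ModelConfig(
        n_input_genes=len(feature_order),
        target_gene_indices=tgt_idx,
        n_aux=aux.shape[1],
        **config_kwargs,
    )
    network = build(cfg)
    all_counts = raw if cfg.loss_mode == "whole_transcriptome_equal_weight" else None
    log = train(
        network, z, target_counts, aux=aux, size_factors=sf, labels=y,
        source_index=source_index, all_counts=all_counts,
    )
    model = TrainedActivityModel(
        network=network, config=cfg, preprocess=params,
        target_genes=target_genes, training_log=log, aux_columns=aux_names,
    )
    bn = network.forward(z, training=False)["bottleneck"].data[:, 0]
    target_signal = z[:, tgt_idx].mean(axis=1)
    if bn.std() > 0 and np.corrcoef(bn, target_signal)[0, 1] < 0:
        model.orientation = -1
    return model


def standardize_for_model(model: TrainedActivityModel, counts: CountMatrix,
                          min_counts: float = 1000.0):
    """Map a count matrix onto the model's feature universe and standardize it.

    Genes absent from the input are imputed at standardized 0 (the training
    mean). Cells whose total over the model features falls below `min_counts`
    are excluded and reported. Returns (z cells x genes, kept_ids, excluded_ids).
    """
    params = model.preprocess
    present = [g for g in params.feature_order if g in set(counts.gene_ids)]
    if not present:
        raise ValueError("no model features found in the input counts")
    sub = counts.subset_genes(present)
    x = sub.dense().astype(float)
    totals = x.sum(axis=0)
    keep = totals >= min_counts
    excluded = [c for c, k in zip(counts.cell_ids, keep) if not k]
    x = x[:, keep]
    totals = totals[keep]
    norm = np.log1p(params.scale_factor * x / totals)
    pos = {g: i for i, g in enumerate(params.feature_order)}
    z = np.zeros((len(params.feature_order), x.shape[1]))
    rows = [pos[g] for g in present]
    z[rows, :] = (norm - params.mean[rows][:, None]) / params.sd[rows][:, None]
    for g in params.zero_sd_genes:
        z[pos[g], :] = 0.0
    kept_ids = [c for c, k in zip(counts.cell_ids, keep) if k]
    return z.T, kept_ids, excluded


def score(model: TrainedActivityModel, counts: CountMatrix,
          min_counts: float = 1000.0) -> ActivityScores:
    """Activity scores: the sigmoid bottleneck activation per cell, in [0, 1].

    The scoring path runs through the encoder only, so auxiliary covariates
    are not required (the bottleneck precedes their concatenation point).
    """
    z, kept, excluded = standardize_for_model(model, counts, min_counts)
    if excluded:
        warnings.warn(f"{len(excluded)} cells below {min_counts} counts excluded")
    out = model.network.forward(z, training=False)
    bn = out["bottleneck"].data
    s = bn[:, 0] if model.orientation >= 0 else 1.0 - bn[:, 0]
    return ActivityScores(
        scores=s.copy(), bottleneck=bn, cell_ids=kept, excluded=excluded
    )


def score_matrix(model: TrainedActivityModel, z: np.ndarray) -> np.ndarray:
    """Bottleneck activations for an already-standardized cells x genes matrix."""
    return model.network.forward(z, training=False)["bottleneck"].data


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: TrainedActivityModel, prefix: str) -> None:
    """Write weights (npz) and a JSON sidecar (config, preprocessing, log)."""
    weights = {f"p{i}": p.data for i, p in enumerate(model.network.params)}
    bn_state = {}
    for name in ("encoder", "par_encoder"):
        stack = getattr(model.network, name)
        for j, (_, bn) in enumerate(stack.layers):
            bn_state[f"{name}{j}_mean"] = bn.running_mean
            bn_state[f"{name}{j}_var"] = bn.running_var
    np.savez(prefix + ".weights.npz", **weights, **bn_state)
    sidecar = {
        "config": {
            **asdict(model.config),
            "target_gene_indices": list(map(int, model.config.target_gene_indices)),
        },
        "target_genes": list(model.target_genes),
        "aux_columns": list(model.aux_columns),
        "orientation": int(model.orientation),
        "preprocess": {
            "feature_order": list(model.preprocess.feature_order),
            "mean": model.preprocess.mean.tolist(),
            "sd": model.preprocess.sd.tolist(),
            "scale_factor": model.preprocess.scale_factor,
            "zero_sd_genes": list(model.preprocess.zero_sd_genes),
        },
        "training_log": model.training_log.to_dict(orient="records"),
    }
    with open(prefix + ".json", "w") as fh:
        json.dump(sidecar, fh)


def load_model(prefix: str) -> TrainedActivityModel:
    with open(prefix + ".json") as fh:
        sidecar = json.load(fh)
    cfg = ModelConfig(**sidecar["config"])
    network = build(cfg)
    data = np.load(prefix + ".weights.npz")
    for i, p in enumerate(network.params):
        p.data = data[f"p{i}"]
    for name in ("encoder", "par_encoder"):
        stack = getattr(network, name)
        for j, (_, bn) in enumerate(stack.layers):
            bn.running_mean = data[f"{name}{j}_mean"]
            bn.running_var = data[f"{name}{j}_var"]
    pp = sidecar["preprocess"]
    params = PreprocessParams(
        feature_order=pp["feature_order"],
        mean=np.asarray(pp["mean"]),
        sd=np.asarray(pp["sd"]),
        scale_factor=pp["scale_factor"],
        zero_sd_genes=pp["zero_sd_genes"],
    )
    return TrainedActivityModel(
        network=network, config=cfg, preprocess=params,
        target_genes=sidecar["target_genes"],
        training_log=pd.DataFrame(sidecar["training_log"]),
        aux_columns=sidecar["aux_columns"],
        orientation=sidecar.get("orientation", 1),
    )
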