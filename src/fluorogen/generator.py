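"""The molecular VAE: encoder, decoder, beta-weighted ELBO, beta schedules.

The model is a variational autoencoder over fixed-shape one-hot token
matrices. The encoder maps the flattened L x V input through one tanh
hidden layer to the posterior mean ``mu`` and log-variance ``logvar`` of a
diagonal Gaussian q(z|x); a sample z = mu + exp(logvar/2) * eps feeds a
mirror-image decoder that emits per-position token logits. The training
objective is the beta-weighted negative ELBO

    loss = -E_q[log p(x|z)] + beta * KL(q(z|x) || N(0, I)),

where beta follows one of four schedules: ``fixed`` (beta = 1 is the
standard VAE, beta = 0 the reconstruction-only "optimized AE"),
``exponential`` decay beta(t) = max(beta_end, beta_start * rho**t) with the
default rho = 0.95, ``linear`` descent clamped at beta_end, ``piecewise``
(beta_high before epoch t_switch, beta_low from t_switch on), and a
``performance`` rule that nudges beta up when the KL term collapses and
down when reconstruction stalls. Decaying beta trades early latent-space
regularization for late reconstruction fidelity — the adaptive-beta
strategy this package exists to provide.

All arithmetic is NumPy float64 with explicit gradients and Adam updates;
a single integer seed drives weight init, shuffling, and the
reparameterization noise, so training is bit-reproducible.
"""

from __future__ import annotations

import io
import json
import zlib
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .codec import (
    MoleculeRecord,
    Vocabulary,
    build_vocabulary,
    decode_to_smiles,
    encode_one_hot,
    same_molecule,
)
from .grammar import encode_smiles

# ---------------------------------------------------------------------------
# ELBO components
# ---------------------------------------------------------------------------


def kl_gaussian(mu: np.ndarray, logvar: np.ndarray) -> float | np.ndarray:
    """KL(N(mu, diag(exp(logvar))) || N(0, I)), in closed form.

    0.5 * sum_i (mu_i^2 + exp(logvar_i) - logvar_i - 1). For 2-D inputs the
    sum runs over the last axis and a per-row vector is returned.
    """
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    if mu.shape != logvar.shape:
        raise ValueError(f"shape mismatch: {mu.shape} vs {logvar.shape}")
    kl = 0.5 * np.sum(mu**2 + np.exp(logvar) - logvar - 1.0, axis=-1)
    return float(kl) if kl.ndim == 0 else kl


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    s = logits - m
    return s - np.log(np.exp(s).sum(axis=-1, keepdims=True))


def reconstruction_loglik(
    decoder_logits: np.ndarray,
    target: np.ndarray,
    mask_padding: bool = False,
    pad_index: int = 0,
) -> float:
    """Sum over positions of the log-softmax probability of the target token.

    ``decoder_logits`` and ``target`` are L x V; the target is one-hot.
    Padding positions count by default (the pad rows are real "stop"
    structure of the fixed-shape target); ``mask_padding`` drops them.
    """
    logits = np.asarray(decoder_logits, dtype=np.float64)
    tgt = np.asarray(target, dtype=np.float64)
    if logits.shape != tgt.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {tgt.shape}")
    lp = (_log_softmax(logits) * tgt).sum(axis=-1)
    if mask_padding:
        keep = tgt[..., pad_index] != 1.0
        lp = lp * keep
    return float(lp.sum())


@dataclass(frozen=True)
class ElboComponents:
    recon_loglik: float
    kl: float
    beta: float
    loss: float


def elbo_loss(recon_loglik: float, kl: float, beta: float) -> ElboComponents:
    """Negative beta-ELBO: loss = -recon_loglik + beta * kl."""
    if kl < 0:
        raise ValueError(f"KL divergence must be non-negative, got {kl}")
    return ElboComponents(
        recon_loglik=float(recon_loglik),
        kl=float(kl),
        beta=float(beta),
        loss=float(-recon_loglik + beta * kl),
    )


# ---------------------------------------------------------------------------
# Beta schedules
# ---------------------------------------------------------------------------

SCHEDULE_KINDS = ("fixed", "exponential", "linear", "piecewise", "performance")


@dataclass(frozen=True)
class BetaSchedule:
    """Schedule kind plus the parameters that define beta(t).

    ``fixed`` uses ``beta_start`` as the constant value (1.0 is the plain
    VAE, 0.0 the optimized AE). ``linear`` descends from beta_start to
    beta_end over ``horizon`` epochs, then stays clamped. ``performance``
    multiplies the previous beta by ``adjust_factor`` when the monitored KL
    falls below ``kl_floor`` and divides by it when reconstruction worsened
    over the trailing ``window`` epochs, clamped to [beta_end, beta_start].
    """

    kind: str = "exponential"
    beta_start: float = 1.0
    beta_end: float = 0.01
    rho: float = 0.95
    t_switch: int = 10
    beta_high: float = 1.0
    beta_low: float = 0.01
    horizon: int = 50
    kl_floor: float | None = None  # performance kind; default 0.1 * d
    window: int = 3
    adjust_factor: float = 1.1

    def __post_init__(self) -> None:
        if self.kind not in SCHEDULE_KINDS:
            raise ValueError(f"unknown schedule kind: {self.kind!r}")
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie in (0, 1), got {self.rho}")
        if self.beta_end > self.beta_start:
            raise ValueError("beta_end must not exceed beta_start")
        for name in ("beta_start", "beta_end", "beta_high", "beta_low"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def beta_at(
    schedule: BetaSchedule, t: int, monitors: dict | None = None
) -> float:
    """Evaluate beta at epoch t.

    For the ``performance`` kind, ``monitors`` must carry ``beta_prev``
    (last epoch's beta), ``kl`` (last epoch's mean KL) and ``recon_history``
    (per-epoch mean reconstruction log-likelihoods so far).
    """
    if t < 0:
        raise ValueError("epoch must be non-negative")
    s = schedule
    if s.kind == "fixed":
        return s.beta_start
    if s.kind == "exponential":
        return max(s.beta_end, s.beta_start * s.rho**t)
    if s.kind == "linear":
        frac = min(t / s.horizon, 1.0) if s.horizon > 0 else 1.0
        return (1.0 - frac) * s.beta_start + frac * s.beta_end
    if s.kind == "piecewise":
        return s.beta_high if t < s.t_switch else s.beta_low
    # performance-based
    if monitors is None:
        raise ValueError("performance schedule requires monitors")
    if t == 0:
        return s.beta_start
    beta = float(monitors["beta_prev"])
    kl = float(monitors["kl"])
    hist = list(monitors.get("recon_history", ()))
    kl_floor = s.kl_floor if s.kl_floor is not None else 0.0
    if kl < kl_floor:
        beta *= s.adjust_factor
    elif len(hist) > s.window and hist[-1] < hist[-1 - s.window]:
        beta /= s.adjust_factor
    return float(min(max(beta, s.beta_end), s.beta_start))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    schedule: BetaSchedule = field(default_factory=BetaSchedule)
    latent_dim: int = 64
    hidden_dim: int = 200
    max_len: int | None = None  # default: longest training sequence + 2
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    lr: float = 1e-3
    mask_padding: bool = False


_PARAM_NAMES = (
    "enc_W1", "enc_b1", "enc_Wmu", "enc_bmu", "enc_Wlv", "enc_blv",
    "dec_W1", "dec_b1", "dec_W2", "dec_b2",
)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


class GeneratorModel:
    """A trained (or freshly initialized) molecular VAE.

    Holds the weights, the vocabulary, the shape contract (L, V, d) and the
    per-epoch training history (beta, mean recon log-lik, mean KL, loss).
    """

    def __init__(
        self,
        vocab: Vocabulary,
        max_len: int,
        config: TrainConfig,
        params: dict[str, np.ndarray] | None = None,
    ) -> None:
        self.vocab = vocab
        self.max_len = max_len
        self.config = config
        self.latent_dim = config.latent_dim
        self.history: list[dict] = []
        if params is not None:
            self.params = params
        else:
            rng = np.random.default_rng(config.seed)
            self.params = self._init_params(rng)

    # -- architecture ------------------------------------------------------

    @property
    def input_dim(self) -> int:
        return self.max_len * self.vocab.size

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        nin, h, d = self.input_dim, self.config.hidden_dim, self.latent_dim

        def w(fan_in: int, shape: tuple) -> np.ndarray:
            return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)

        return {
            "enc_W1": w(nin, (nin, h)), "enc_b1": np.zeros(h),
            "enc_Wmu": w(h, (h, d)), "enc_bmu": np.zeros(d),
            "enc_Wlv": w(h, (h, d)), "enc_blv": np.zeros(d),
            "dec_W1": w(d, (d, h)), "dec_b1": np.zeros(h),
            "dec_W2": w(h, (h, nin)), "dec_b2": np.zeros(nin),
        }

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (mu, logvar) for a batch of flattened one-hot inputs."""
        p = self.params
        h = np.tanh(x @ p["enc_W1"] + p["enc_b1"])
        return h @ p["enc_Wmu"] + p["enc_bmu"], h @ p["enc_Wlv"] + p["enc_blv"]

    def decode_logits(self, z: np.ndarray) -> np.ndarray:
        """Per-position token logits, shape (..., L, V)."""
        p = self.params
        g = np.tanh(z @ p["dec_W1"] + p["dec_b1"])
        logits = g @ p["dec_W2"] + p["dec_b2"]
        return logits.reshape(*z.shape[:-1], self.max_len, self.vocab.size)

    # -- molecule-level convenience ---------------------------------------

    def _to_onehot(self, molecule: "str | MoleculeRecord") -> np.ndarray:
        tokens = (
            molecule.selfies
            if isinstance(molecule, MoleculeRecord)
            else encode_smiles(molecule)
        )
        return encode_one_hot(tokens, self.vocab, self.max_len)

    def encode_mean(self, molecule: "str | MoleculeRecord") -> np.ndarray:
        """Deterministic latent representation: the posterior mean."""
        x = self._to_onehot(molecule).reshape(1, -1)
        mu, _ = self.encode(x)
        return mu[0]

    def decode_smiles(self, z: np.ndarray) -> str:
        """Greedy (argmax) decode of a latent point to canonical SMILES."""
        logits = self.decode_logits(np.asarray(z, dtype=np.float64))
        return decode_to_smiles(logits, self.vocab)

    def reconstruct(self, molecule: "str | MoleculeRecord") -> str:
        return self.decode_smiles(self.encode_mean(molecule))

    def weights_checksum(self) -> int:
        """CRC over all weights; detects any in-place mutation."""
        crc = 0
        for k in _PARAM_NAMES:
            crc = zlib.crc32(np.ascontiguousarray(self.params[k]).tobytes(), crc)
        return crc

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: weights + vocab + config + history."""
        meta = {
            "vocab": list(self.vocab.tokens),
            "max_len": self.max_len,
            "config": _config_to_dict(self.config),
            "history": self.history,
        }
        buf = io.BytesIO()
        np.savez(buf, meta=np.array(json.dumps(meta)), **self.params)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorModel":
        with np.load(Path(path), allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            params = {k: npz[k].copy() for k in _PARAM_NAMES}
        config = _config_from_dict(meta["config"])
        model = cls(Vocabulary(tuple(meta["vocab"])), meta["max_len"],
                    config, params=params)
        model.history = meta["history"]
        return model


def _config_to_dict(c: TrainConfig) -> dict:
    d = asdict(c)
    d["schedule"] = asdict(c.schedule)
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["schedule"] = BetaSchedule(**d["schedule"])
    return TrainConfig(**d)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _prepare_dataset(
    dataset: Sequence, config: TrainConfig
) -> tuple[np.ndarray, Vocabulary, int]:
    if len(dataset) == 0:
        raise ValueError("empty training set")
    token_seqs = []
    for i, item in enumerate(dataset):
        try:
            toks = (
                item.selfies if isinstance(item, MoleculeRecord)
                else encode_smiles(item)
            )
        except Exception as exc:
            raise ValueError(f"record {i} is not encodable: {item!r}") from exc
        token_seqs.append(toks)
    vocab = build_vocabulary(token_seqs)
    max_len = config.max_len or max(len(t) for t in token_seqs) + 2
    X = np.stack(
        [encode_one_hot(t, vocab, max_len).ravel() for t in token_seqs]
    )
    return X, vocab, max_len


def train_generator(dataset: Sequence, config: TrainConfig) -> GeneratorModel:
    """Train a VAE on a molecule set; fully determined by ``config.seed``.

    ``dataset`` is a list of SMILES strings or :class:`MoleculeRecord`.
    The per-epoch history records beta exactly as ``beta_at`` defines it.
    """
    X, vocab, max_len = _prepare_dataset(dataset, config)
    cfg = config
    if cfg.schedule.kind == "performance" and cfg.schedule.kl_floor is None:
        cfg = replace(
            cfg,
            schedule=replace(cfg.schedule, kl_floor=0.1 * cfg.latent_dim),
        )
    model = GeneratorModel(vocab, max_len, cfg)
    rng = np.random.default_rng(cfg.seed + 1)  # training-time randomness
    opt = _Adam(model.params, cfg.lr)
    n = X.shape[0]
    L, V = max_len, vocab.size
    p = model.params

    recon_history: list[float] = []
    beta_prev = cfg.schedule.beta_start
    pad_keep = None

    for epoch in range(cfg.epochs):
        monitors = None
        if cfg.schedule.kind == "performance":
            monitors = {
                "beta_prev": beta_prev,
                "kl": model.history[-1]["kl"] if model.history else np.inf,
                "recon_history": recon_history,
            }
        beta = beta_at(cfg.schedule, epoch, monitors)
        beta_prev = beta

        order = rng.permutation(n)
        ep_recon = ep_kl = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = X[idx]
            B = x.shape[0]

            # forward
            h_pre = x @ p["enc_W1"] + p["enc_b1"]
            h = np.tanh(h_pre)
            mu = h @ p["enc_Wmu"] + p["enc_bmu"]
            lv = h @ p["enc_Wlv"] + p["enc_blv"]
            eps = rng.standard_normal(mu.shape)
            std = np.exp(0.5 * lv)
            z = mu + std * eps
            g = np.tanh(z @ p["dec_W1"] + p["dec_b1"])
            logits = (g @ p["dec_W2"] + p["dec_b2"]).reshape(B, L, V)

            lse = _log_softmax(logits)
            tgt = x.reshape(B, L, V)
            if cfg.mask_padding:
                keep = tgt[..., vocab.pad_index] != 1.0
            else:
                keep = np.ones((B, L), dtype=bool)
            recon_ll = ((lse * tgt).sum(-1) * keep).sum(-1)  # per-sample
            kl = 0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0, axis=1)

            ep_recon += recon_ll.sum()
            ep_kl += kl.sum()

            # backward (mean loss over batch)
            soft = np.exp(lse)
            dlogits = (soft - tgt) * keep[..., None] / B
            dflat = dlogits.reshape(B, L * V)
            grads = {
                "dec_W2": g.T @ dflat,
                "dec_b2": dflat.sum(0),
            }
            dg = dflat @ p["dec_W2"].T
            dz_pre = dg * (1 - g**2)
            grads["dec_W1"] = z.T @ dz_pre
            grads["dec_b1"] = dz_pre.sum(0)
            dz = dz_pre @ p["dec_W1"].T

            dmu = dz + beta * mu / B
            dlv = dz * eps * 0.5 * std + beta * 0.5 * (np.exp(lv) - 1.0) / B

            dh = dmu @ p["enc_Wmu"].T + dlv @ p["enc_Wlv"].T
            grads["enc_Wmu"] = h.T @ dmu
            grads["enc_bmu"] = dmu.sum(0)
            grads["enc_Wlv"] = h.T @ dlv
            grads["enc_blv"] = dlv.sum(0)
            dh_pre = dh * (1 - h**2)
            grads["enc_W1"] = x.T @ dh_pre
            grads["enc_b1"] = dh_pre.sum(0)

            opt.step(p, grads)

        mean_recon = ep_recon / n
        mean_kl = ep_kl / n
        recon_history.append(mean_recon)
        comp = elbo_loss(mean_recon, mean_kl, beta)
        model.history.append(
            {"epoch": epoch, "beta": beta, "recon_loglik": comp.recon_loglik,
             "kl": comp.kl, "loss": comp.loss}
        )
    return model


def reconstruction_rate(model: GeneratorModel, molecules: Sequence) -> float:
    """Fraction of molecules reproduced by greedy mean-latent decoding."""
    if len(molecules) == 0:
        raise ValueError("empty evaluation set")
    hits = 0
    for m in molecules:
        smiles = m.smiles if isinstance(m, MoleculeRecord) else m
        out = model.reconstruct(m)
        if out and same_molecule(out, smiles):
            hits += 1
    return hits / len(molecules)
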