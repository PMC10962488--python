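"""Conditional SMILES variational autoencoder with feature-property attention.

The generator is a character-level VAE. An embedding layer plus a stack of
LSTM layers encodes a tokenized SMILES into a Gaussian posterior (mu, log
sigma) over a continuous latent space; z = mu + exp(log sigma) * eps. A small
attention network (the feature-property-correlation, FPC, network) maps
[z; c] -- the latent code concatenated with a scalar condition property, the
molecule's QED here -- through two hidden layers to a softmax-normalised score
per latent dimension; the conditioned code Zc = scores * z reweights latent
dimensions by their learned relevance to the condition. The decoder receives
[Zc; c] as a per-timestep context next to teacher-forced token embeddings and
reconstructs the token sequence through its own LSTM stack.

Training minimises masked token cross-entropy plus a weighted KL divergence
to the standard-normal prior, with Adam and a stepped multiplicative
learning-rate decay. Training stops at a maximum epoch count or once
teacher-forced token accuracy stays above a threshold for a fixed window of
consecutive steps. Sampling draws z from the standard normal prior, applies
the FPC network at a requested condition value, and decodes token-by-token.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import _autodiff as ad
from ._nn import Adam, glorot, lstm_params
from .corpus import TokenAlphabet, build_alphabet, compute_qed, detokenize, tokenize

__all__ = [
    "GeneratorConfig",
    "TrainConfig",
    "LatentCode",
    "ConditionalSmilesVAE",
    "ConsecutiveAccuracyStop",
    "PlateauStop",
    "reparameterize",
    "kl_divergence",
    "vae_loss",
]


@dataclass
class GeneratorConfig:
    """Architecture hyperparameters of the generator."""

    embedding_dim: int = 200
    encoder_rnn_dim: int = 512
    encoder_rnn_layers: int = 3
    latent_dim: int = 200
    fpc_hidden_dims: tuple[int, int] = (64, 64)
    decoder_rnn_dim: int = 512
    decoder_rnn_layers: int = 3
    kl_weight: float = 1.0
    kl_anneal_steps: int = 0  # 0 disables annealing
    fpc_rescale: bool = False
    max_len: int = 120

    def __post_init__(self):
        dims = [
            self.embedding_dim,
            self.encoder_rnn_dim,
            self.encoder_rnn_layers,
            self.latent_dim,
            self.decoder_rnn_dim,
            self.decoder_rnn_layers,
            *self.fpc_hidden_dims,
        ]
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be positive")


@dataclass
class TrainConfig:
    """Optimisation schedule and early-stop settings."""

    batch_size: int = 64
    base_lr: float = 5e-4
    lr_decay_rate: float = 0.03
    lr_decay_steps: int = 1000
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    max_epochs: int = 8
    acc_threshold_delta: float = 0.95
    acc_window_steps: int = 500
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.acc_threshold_delta < 1.0):
            raise ValueError("acc_threshold_delta must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class LatentCode:
    """Posterior parameters and a reparameterised draw for one molecule."""

    mu: np.ndarray
    log_sigma: np.ndarray
    z: np.ndarray


def reparameterize(mu, log_sigma, epsilon):
    """z = mu + exp(log_sigma) * epsilon (elementwise)."""
    mu = np.asarray(mu, dtype=float)
    log_sigma = np.asarray(log_sigma, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    if mu.shape != log_sigma.shape or mu.shape != epsilon.shape:
        raise ValueError("mu, log_sigma and epsilon must share a shape")
    return mu + np.exp(log_sigma) * epsilon


def kl_divergence(mu, log_sigma):
    """KL(N(mu, sigma) || N(0, I)) summed over latent dims, averaged over rows.

    Closed form: -1/2 * sum_d (1 + 2*log_sigma_d - mu_d^2 - exp(2*log_sigma_d)).
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    log_sigma = np.atleast_2d(np.asarray(log_sigma, dtype=float))
    per_row = -0.5 * np.sum(
        1.0 + 2.0 * log_sigma - mu**2 - np.exp(2.0 * log_sigma), axis=-1
    )
    return float(per_row.mean())


def vae_loss(logits, targets, mask, mu, log_sigma, kl_weight=1.0):
    """(total, reconstruction, kl): masked mean token NLL + weighted KL."""
    logits = np.asarray(logits, dtype=float)
    targets = np.asarray(targets)
    mask = np.asarray(mask, dtype=float)
    m = logits - logits.max(axis=-1, keepdims=True)
    logp = m - np.log(np.exp(m).sum(axis=-1, keepdims=True))
    picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    recon = float(-(picked * mask).sum() / max(mask.sum(), 1.0))
    kl = kl_divergence(mu, log_sigma)
    return recon + kl_weight * kl, recon, kl


class ConsecutiveAccuracyStop:
    """Stop once accuracy exceeds a threshold for ``window`` consecutive steps."""

    def __init__(self, delta: float, window: int):
        self.delta = delta
        self.window = window
        self.count = 0

    def update(self, accuracy: float) -> bool:
        self.count = self.count + 1 if accuracy > self.delta else 0
        return self.count >= self.window


class PlateauStop:
    """Stop when the mean epoch loss has not improved for N consecutive epochs.

    ``best_epoch`` (1-based) marks the minimum-mean-loss epoch whose
    parameters should be restored.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.epoch = 0
        self.stale = 0

    def update(self, mean_loss: float) -> bool:
        self.epoch += 1
        if mean_loss < self.best:
            self.best = mean_loss
            self.best_epoch = self.epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class ConditionalSmilesVAE(BaseEstimator):
    """Scikit-learn style estimator around the conditional SMILES VAE.

    ``fit(smiles, condition)`` trains the generator (condition defaults to each
    molecule's QED); ``sample(n, condition)`` draws new SMILES strings. Fitted
    state lives in trailing-underscore attributes and survives
    ``get_params``/``set_params`` round trips, so the estimator composes with
    scikit-learn tooling.
    """

    def __init__(
        self,
        embedding_dim: int = 200,
        encoder_rnn_dim: int = 512,
        encoder_rnn_layers: int = 3,
        latent_dim: int = 200,
        fpc_hidden_dims: tuple[int, int] = (64, 64),
        decoder_rnn_dim: int = 512,
        decoder_rnn_layers: int = 3,
        kl_weight: float = 1.0,
        kl_anneal_steps: int = 0,
        fpc_rescale: bool = False,
        max_len: int = 120,
        batch_size: int = 64,
        base_lr: float = 5e-4,
        lr_decay_rate: float = 0.03,
        lr_decay_steps: int = 1000,
        adam_betas: tuple[float, float] = (0.9, 0.999),
        adam_eps: float = 1e-8,
        max_epochs: int = 8,
        acc_threshold_delta: float = 0.95,
        acc_window_steps: int = 500,
        seed: int = 0,
    ):
        self.embedding_dim = embedding_dim
        self.encoder_rnn_dim = encoder_rnn_dim
        self.encoder_rnn_layers = encoder_rnn_layers
        self.latent_dim = latent_dim
        self.fpc_hidden_dims = fpc_hidden_dims
        self.decoder_rnn_dim = decoder_rnn_dim
        self.decoder_rnn_layers = decoder_rnn_layers
        self.kl_weight = kl_weight
        self.kl_anneal_steps = kl_anneal_steps
        self.fpc_rescale = fpc_rescale
        self.max_len = max_len
        self.batch_size = batch_size
        self.base_lr = base_lr
        self.lr_decay_rate = lr_decay_rate
        self.lr_decay_steps = lr_decay_steps
        self.adam_betas = adam_betas
        self.adam_eps = adam_eps
        self.max_epochs = max_epochs
        self.acc_threshold_delta = acc_threshold_delta
        self.acc_window_steps = acc_window_steps
        self.seed = seed

    # -- construction -------------------------------------------------------

    def _init_params(self, alphabet: TokenAlphabet, rng: np.random.Generator):
        V = len(alphabet)
        E = self.embedding_dim
        He = self.encoder_rnn_dim
        Hd = self.decoder_rnn_dim
        L = self.latent_dim
        h1, h2 = self.fpc_hidden_dims
        p: dict[str, ad.Tensor] = {}
        p["emb_enc"] = ad.parameter(rng.normal(0, 0.1, size=(V, E)))
        p["emb_dec"] = ad.parameter(rng.normal(0, 0.1, size=(V, E)))
        dim = E
        for i in range(self.encoder_rnn_layers):
            p[f"enc{i}_wx"], p[f"enc{i}_wh"], p[f"enc{i}_b"] = lstm_params(rng, dim, He)
            dim = He
        p["mu_w"] = glorot(rng, He, L)
        p["mu_b"] = ad.parameter(np.zeros(L))
        p["ls_w"] = glorot(rng, He, L)
        p["ls_b"] = ad.parameter(np.zeros(L))
        p["fpc0_w"] = glorot(rng, L + 1, h1)
        p["fpc0_b"] = ad.parameter(np.zeros(h1))
        p["fpc1_w"] = glorot(rng, h1, h2)
        p["fpc1_b"] = ad.parameter(np.zeros(h2))
        p["fpc2_w"] = glorot(rng, h2, L)
        p["fpc2_b"] = ad.parameter(np.zeros(L))
        dim = E + L + 1
        for i in range(self.decoder_rnn_layers):
            p[f"dec{i}_wx"], p[f"dec{i}_wh"], p[f"dec{i}_b"] = lstm_params(rng, dim, Hd)
            dim = Hd
        p["out_w"] = glorot(rng, Hd, V)
        p["out_b"] = ad.parameter(np.zeros(V))
        return p

    def _param_list(self):
        return [self.params_[k] for k in sorted(self.params_)]

    # -- differentiable forward pieces --------------------------------------

    def _encode_graph(self, ids: np.ndarray, lengths: np.ndarray):
        p = self.params_
        x = ad.embedding(p["emb_enc"], ids)
        for i in range(self.encoder_rnn_layers):
            x = ad.lstm(x, p[f"enc{i}_wx"], p[f"enc{i}_wh"], p[f"enc{i}_b"])
        last = ad.gather_time(x, lengths - 1)
        mu = ad.add(ad.matmul(last, p["mu_w"]), p["mu_b"])
        logsig = ad.add(ad.matmul(last, p["ls_w"]), p["ls_b"])
        return mu, logsig

    def _fpc_graph(self, z, c):
        p = self.params_
        h = ad.concat([z, c], axis=-1)
        h = ad.tanh(ad.add(ad.matmul(h, p["fpc0_w"]), p["fpc0_b"]))
        h = ad.tanh(ad.add(ad.matmul(h, p["fpc1_w"]), p["fpc1_b"]))
        e = ad.add(ad.matmul(h, p["fpc2_w"]), p["fpc2_b"])
        return ad.softmax(e, axis=-1)

    def _decode_graph(self, zc, c, teacher_ids: np.ndarray):
        p = self.params_
        T = teacher_ids.shape[1]
        ctx = ad.concat([zc, c], axis=-1)
        x = ad.concat(
            [ad.embedding(p["emb_dec"], teacher_ids), ad.repeat_time(ctx, T)], axis=-1
        )
        for i in range(self.decoder_rnn_layers):
            x = ad.lstm(x, p[f"dec{i}_wx"], p[f"dec{i}_wh"], p[f"dec{i}_b"])
        return ad.add(ad.matmul(x, p["out_w"]), p["out_b"])

    def _batch_loss(self, ids, teacher, targets, mask, lengths, c_values, rng, kl_scale=1.0):
        """Build the full graph for one batch; returns (loss node, stats)."""
        mu, logsig = self._encode_graph(ids, lengths)
        eps = ad.constant(rng.standard_normal(mu.shape))
        z = ad.add(mu, ad.mul(ad.exp(logsig), eps))
        c = ad.constant(c_values[:, None])
        scores = self._fpc_graph(z, c)
        zc = ad.mul(scores, z)
        if self.fpc_rescale:
            zc = ad.scale(zc, float(self.latent_dim))
        logits = self._decode_graph(zc, c, teacher)
        recon = ad.masked_cross_entropy(logits, targets, mask)
        B = ids.shape[0]
        one = ad.constant(np.ones_like(mu.data))
        kl_elem = ad.sub(
            ad.add(ad.square(mu), ad.exp(ad.scale(logsig, 2.0))),
            ad.add(one, ad.scale(logsig, 2.0)),
        )
        kl = ad.mean_sum(kl_elem, k=0.5 / B)
        loss = ad.add(recon, ad.scale(kl, self.kl_weight * kl_scale))
        pred = logits.data.argmax(axis=-1)
        acc = float(((pred == targets) * mask).sum() / max(mask.sum(), 1.0))
        return loss, {
            "loss": float(loss.data),
            "recon": float(recon.data),
            "kl": float(kl.data),
            "accuracy": acc,
        }

    # -- data plumbing -------------------------------------------------------

    def _prepare(self, smiles, conditions):
        enc_ids, teacher, targets, lengths = [], [], [], []
        pad = self.alphabet_.pad_id
        start = self.alphabet_.start_id
        framed = [tokenize(s, self.alphabet_) for s in smiles]
        too_long = [s for s, f in zip(smiles, framed) if len(f) > self.max_len + 2]
        if too_long:
            raise ValueError(f"sequences exceed max_len: {too_long[:3]}")
        T = max(len(f) for f in framed)
        for f in framed:
            n = len(f)
            lengths.append(n)
            enc_ids.append(f + [pad] * (T - n))
            teacher.append([start] + f[1:-1] + [pad] * (T - n + 1))
            targets.append(f[1:] + [pad] * (T - n + 1))
        enc_ids = np.array(enc_ids)
        teacher = np.array(teacher)
        targets = np.array(targets)
        lengths = np.array(lengths)
        mask = (targets != pad).astype(float)
        # a pad target immediately after end is masked; end itself is scored
        return enc_ids, teacher, targets, mask, lengths, np.asarray(conditions, float)

    # -- public API ----------------------------------------------------------

    def fit(self, X, y=None, alphabet: TokenAlphabet | None = None):
        """Train on a SMILES corpus.

        X: list of SMILES strings. y: optional per-molecule condition values
        (defaults to computed QED). ``alphabet`` may be supplied to share one
        encoding across pretraining and transfer corpora.
        """
        smiles = list(X)
        if not smiles:
            raise ValueError("empty corpus")
        cond = np.asarray(
            [compute_qed(s) for s in smiles] if y is None else y, dtype=float
        )
        self.alphabet_ = alphabet or build_alphabet([smiles])
        rng = np.random.default_rng(self.seed)
        self.params_ = self._init_params(self.alphabet_, rng)
        self._optimizer_ = Adam(
            self._param_list(),
            base_lr=self.base_lr,
            betas=self.adam_betas,
            eps=self.adam_eps,
            decay_rate=self.lr_decay_rate,
            decay_steps=self.lr_decay_steps,
        )
        if len(smiles) < self.batch_size:
            warnings.warn("corpus smaller than one batch; using a single small batch")
        self.log_ = []
        self.stopped_early_ = False
        stopper = ConsecutiveAccuracyStop(self.acc_threshold_delta, self.acc_window_steps)
        step = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(smiles))
            for lo in range(0, len(order), self.batch_size):
                idx = order[lo : lo + self.batch_size]
                batch = self._prepare([smiles[i] for i in idx], cond[idx])
                kl_scale = (
                    min(1.0, (step + 1) / self.kl_anneal_steps)
                    if self.kl_anneal_steps
                    else 1.0
                )
                loss, stats = self._batch_loss(*batch, rng=rng, kl_scale=kl_scale)
                self._optimizer_.zero_grad()
                ad.backward(loss)
                self._optimizer_.step()
                step += 1
                stats.update(step=step, epoch=epoch + 1, lr=self._optimizer_.lr)
                self.log_.append(stats)
                if stopper.update(stats["accuracy"]):
                    self.stopped_early_ = True
                    break
            if self.stopped_early_:
                break
        self.n_steps_ = step
        return self

    def finetune(self, X, y=None, epochs: int = 100, plateau_patience: int = 5):
        """Continue training on a (target-domain) corpus with a loss-plateau stop.

        Runs up to ``epochs`` epochs; stops once the mean epoch loss has not
        decreased for ``plateau_patience`` consecutive epochs and restores the
        parameters of the minimum-mean-loss epoch. The optimizer (and its
        learning-rate schedule) is re-initialised. Returns the mean epoch losses.
        """
        self._check_fitted()
        smiles = list(X)
        cond = np.asarray(
            [compute_qed(s) for s in smiles] if y is None else y, dtype=float
        )
        rng = np.random.default_rng(self.seed + 1)
        opt = Adam(
            self._param_list(),
            base_lr=self.base_lr,
            betas=self.adam_betas,
            eps=self.adam_eps,
            decay_rate=self.lr_decay_rate,
            decay_steps=self.lr_decay_steps,
        )
        stopper = PlateauStop(plateau_patience)
        epoch_losses: list[float] = []
        snapshots: list[dict[str, np.ndarray]] = []
        for _epoch in range(epochs):
            order = rng.permutation(len(smiles))
            losses = []
            for lo in range(0, len(order), self.batch_size):
                idx = order[lo : lo + self.batch_size]
                batch = self._prepare([smiles[i] for i in idx], cond[idx])
                loss, stats = self._batch_loss(*batch, rng=rng)
                opt.zero_grad()
                ad.backward(loss)
                opt.step()
                losses.append(stats["loss"])
            epoch_losses.append(float(np.mean(losses)))
            snapshots.append({k: v.data.copy() for k, v in self.params_.items()})
            if stopper.update(epoch_losses[-1]):
                break
        if snapshots:
            best = snapshots[stopper.best_epoch - 1]
            for k, v in self.params_.items():
                v.data = best[k]
        return epoch_losses

    def encode(self, X):
        """Posterior (mu, log_sigma) arrays for a list of SMILES; deterministic."""
        self._check_fitted()
        smiles = list(X)
        ids, _, _, _, lengths, _ = self._prepare(smiles, np.zeros(len(smiles)))
        mu, logsig = self._encode_graph(ids, lengths)
        return mu.data.copy(), logsig.data.copy()

    def encode_codes(self, X, seed: int | None = None) -> list[LatentCode]:
        """Full latent codes (mu, log_sigma, z) with a seeded epsilon draw."""
        mu, logsig = self.encode(X)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        z = reparameterize(mu, logsig, rng.standard_normal(mu.shape))
        return [LatentCode(m, ls, zz) for m, ls, zz in zip(mu, logsig, z)]

    def fpc_scores(self, z, c):
        """Softmax-normalised correlation scores for latent rows z at condition c."""
        self._check_fitted()
        z = np.atleast_2d(np.asarray(z, dtype=float))
        c_arr = np.full((z.shape[0], 1), float(c))
        out = self._fpc_graph(ad.constant(z), ad.constant(c_arr))
        return out.data.copy()

    def apply_fpc(self, z, scores):
        """Conditioned latent Zc = scores * z (optionally rescaled by latent_dim)."""
        zc = np.asarray(scores, dtype=float) * np.asarray(z, dtype=float)
        return zc * self.latent_dim if self.fpc_rescale else zc

    def decode_logits(self, zc, c, teacher_ids):
        """Per-position token logits for teacher-forced decoding; deterministic."""
        self._check_fitted()
        zc = np.atleast_2d(np.asarray(zc, dtype=float))
        c_arr = np.full((zc.shape[0], 1), float(c))
        logits = self._decode_graph(
            ad.constant(zc), ad.constant(c_arr), np.atleast_2d(teacher_ids)
        )
        return logits.data.copy()

    def sample(
        self,
        n: int,
        condition: float,
        temperature: float = 1.0,
        seed: int | None = None,
        max_len: int | None = None,
    ) -> list[str]:
        """Draw n raw strings from the prior at the given condition value.

        z ~ N(0, I); the FPC network reweights z at the requested condition;
        decoding is greedy at temperature 0, multinomial otherwise. Validity of
        the returned strings is judged downstream.
        """
        self._check_fitted()
        if n < 1:
            raise ValueError("n must be >= 1")
        max_len = max_len or self.max_len
        rng = np.random.default_rng(self.seed if seed is None else seed)
        p = {k: v.data for k, v in self.params_.items()}
        L = self.latent_dim
        z = rng.standard_normal((n, L))
        scores = self.fpc_scores(z, condition)
        zc = self.apply_fpc(z, scores)
        ctx = np.concatenate([zc, np.full((n, 1), float(condition))], axis=1)
        H = self.decoder_rnn_dim
        hs = [np.zeros((n, H)) for _ in range(self.decoder_rnn_layers)]
        cs = [np.zeros((n, H)) for _ in range(self.decoder_rnn_layers)]
        tok = np.full(n, self.alphabet_.start_id)
        done = np.zeros(n, dtype=bool)
        seqs = np.full((n, max_len), self.alphabet_.pad_id)
        for t in range(max_len):
            x = np.concatenate([p["emb_dec"][tok], ctx], axis=1)
            for i in range(self.decoder_rnn_layers):
                gates = x @ p[f"dec{i}_wx"] + hs[i] @ p[f"dec{i}_wh"] + p[f"dec{i}_b"]
                ii = 1.0 / (1.0 + np.exp(-gates[:, :H]))
                ff = 1.0 / (1.0 + np.exp(-gates[:, H : 2 * H]))
                gg = np.tanh(gates[:, 2 * H : 3 * H])
                oo = 1.0 / (1.0 + np.exp(-gates[:, 3 * H :]))
                cs[i] = ff * cs[i] + ii * gg
                hs[i] = oo * np.tanh(cs[i])
                x = hs[i]
            logits = x @ p["out_w"] + p["out_b"]
            if temperature == 0:
                nxt = logits.argmax(axis=1)
            else:
                scaled = logits / temperature
                scaled -= scaled.max(axis=1, keepdims=True)
                probs = np.exp(scaled)
                probs /= probs.sum(axis=1, keepdims=True)
                u = rng.random((n, 1))
                nxt = (probs.cumsum(axis=1) < u).sum(axis=1)
                nxt = np.minimum(nxt, probs.shape[1] - 1)
            nxt = np.where(done, self.alphabet_.pad_id, nxt)
            seqs[:, t] = nxt
            done |= nxt == self.alphabet_.end_id
            if done.all():
                break
            tok = np.where(done, self.alphabet_.pad_id, nxt)
        return [detokenize(row, self.alphabet_) for row in seqs]

    # -- persistence ---------------------------------------------------------

    def save(self, path: str) -> None:
        """Persist weights + architecture + alphabet as a single .npz checkpoint."""
        self._check_fitted()
        arrays = {k: v.data for k, v in self.params_.items()}
        meta = json.dumps(
            {"params": self.get_params(), "alphabet": self.alphabet_.to_json()}
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "ConditionalSmilesVAE":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        hp = meta["params"]
        for key in ("fpc_hidden_dims", "adam_betas"):
            hp[key] = tuple(hp[key])
        model = cls(**hp)
        model.alphabet_ = TokenAlphabet.from_json(meta["alphabet"])
        model.params_ = {
            k: ad.parameter(data[k]) for k in data.files if k != "__meta__"
        }
        model.log_ = []
        model.n_steps_ = 0
        model.stopped_early_ = False
        return model

    def clone_fitted(self) -> "ConditionalSmilesVAE":
        """Deep copy including weights (used to branch transfer-learning runs)."""
        self._check_fitted()
        other = ConditionalSmilesVAE(**self.get_params())
        other.alphabet_ = self.alphabet_
        other.params_ = {k: ad.parameter(v.data.copy()) for k, v in self.params_.items()}
        other.log_ = copy.deepcopy(getattr(self, "log_", []))
        other.n_steps_ = getattr(self, "n_steps_", 0)
        other.stopped_early_ = getattr(self, "stopped_early_", False)
        return other

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
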