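"""Convolutional off-target classifier over 23x4 one-hot site encodings.

Topology: convolution -> batch normalization -> global max pooling ->
dense(100, ReLU) -> dense(23, ReLU) + dropout -> single sigmoid unit,
trained with binary cross-entropy.  Implemented directly on numpy (forward
and backward passes, Adam updates) so training is fully deterministic from a
seed and carries no framework dependency; inputs are tiny (23 positions x 4
channels) so CPU training of a few thousand examples takes seconds.

Channel order is A, T, C, G.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cutscan.genome_scan import (
    PROTOSPACER_LEN,
    SITE_LEN,
    CandidateSite,
    GuideTarget,
    count_mismatches,
)

CHANNELS = "ATCG"
_CHANNEL_INDEX = {b: i for i, b in enumerate(CHANNELS)}
MIN_NEGATIVE_MISMATCHES = 11  # "more than 10 mismatches"


def encode_site(sequence_23: str) -> np.ndarray:
    """One-hot encode a 23-nt site as a (23, 4) matrix, channels A,T,C,G."""
    seq = sequence_23.upper()
    if len(seq) != SITE_LEN:
        raise ValueError(f"sequence must be {SITE_LEN} nt, got {len(seq)}")
    mat = np.zeros((SITE_LEN, 4), dtype=np.float64)
    for i, ch in enumerate(seq):
        if ch not in _CHANNEL_INDEX:
            raise ValueError(f"non-ACGT character {ch!r} at position {i + 1}")
        mat[i, _CHANNEL_INDEX[ch]] = 1.0
    return mat


def decode_site(matrix: np.ndarray) -> str:
    """Inverse of :func:`encode_site`."""
    if matrix.shape != (SITE_LEN, 4):
        raise ValueError(f"expected ({SITE_LEN}, 4) matrix")
    return "".join(CHANNELS[j] for j in matrix.argmax(axis=1))


def encode_batch(sequences: Sequence[str]) -> np.ndarray:
    return np.stack([encode_site(s) for s in sequences])


@dataclass
class ModelConfig:
    conv_filters: int = 32
    kernel_size: int = 5
    dense_units: tuple[int, int] = (100, 23)
    dropout_rate: float = 0.3
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.dense_units) != (100, 23):
            raise ValueError("dense layer sizes are fixed at (100, 23)")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class RankedPrediction:
    site: CandidateSite
    score: float
    rank: int


def build_training_set(
    positives: Sequence[CandidateSite | str],
    guide: GuideTarget,
    negatives_per_positive: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Label positives 1 and random far-mismatch 23-mers 0.

    Negatives are rejection-sampled random 23-mers whose protospacer portion
    has at least 11 mismatches to the on-target.  Returns (X, y, sequences)
    shuffled with the seed.
    """
    if not positives:
        raise ValueError("positives must be non-empty")
    if negatives_per_positive <= 0:
        raise ValueError("negatives_per_positive must be > 0")
    rng = np.random.default_rng(seed)
    pos_seqs = [
        s.sequence_23 if isinstance(s, CandidateSite) else s for s in positives
    ]
    n_neg = int(round(len(pos_seqs) * negatives_per_positive))
    proto = guide.protospacer.upper()
    neg_seqs: list[str] = []
    while len(neg_seqs) < n_neg:
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, SITE_LEN))
        if count_mismatches(seq[:PROTOSPACER_LEN], proto) >= MIN_NEGATIVE_MISMATCHES:
            neg_seqs.append(seq)
    seqs = pos_seqs + neg_seqs
    y = np.concatenate([np.ones(len(pos_seqs)), np.zeros(len(neg_seqs))])
    order = rng.permutation(len(seqs))
    seqs = [seqs[i] for i in order]
    y = y[order]
    return encode_batch(seqs), y, seqs


class ConvSiteClassifier:
    """The numpy CNN.  Use :func:`train` to fit; ``predict_proba`` to score."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        F, K = config.conv_filters, config.kernel_size
        d1, d2 = config.dense_units

        def glorot(shape, fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, shape)

        self.params = {
            "Wc": glorot((F, K, 4), K * 4, F),
            "bc": np.zeros(F),
            "gamma": np.ones(F),
            "beta": np.zeros(F),
            "W1": glorot((F, d1), F, d1),
            "b1": np.zeros(d1),
            "W2": glorot((d1, d2), d1, d2),
            "b2": np.zeros(d2),
            "Wo": glorot((d2, 1), d2, 1),
            "bo": np.zeros(1),
        }
        self.running_mean = np.zeros(F)
        self.running_var = np.ones(F)
        self.bn_momentum = 0.9
        self.bn_eps = 1e-5
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ----- forward -----

    def _conv(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        K = self.config.kernel_size
        Xw = np.lib.stride_tricks.sliding_window_view(X, K, axis=1)  # (N,P,4,K)
        Z = np.einsum("npck,fkc->npf", Xw, self.params["Wc"]) + self.params["bc"]
        return Z, Xw

    def forward(self, X: np.ndarray, training: bool, rng: np.random.Generator | None = None):
        p = self.params
        cache: dict = {}
        Z, Xw = self._conv(X)
        cache["Xw"] = Xw
        if training:
            mean = Z.mean(axis=(0, 1))
            var = Z.var(axis=(0, 1))
            self.running_mean = (
                self.bn_momentum * self.running_mean + (1 - self.bn_momentum) * mean
            )
            self.running_var = (
                self.bn_momentum * self.running_var + (1 - self.bn_momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.bn_eps)
        Zhat = (Z - mean) * inv_std
        B = p["gamma"] * Zhat + p["beta"]
        A = np.maximum(B, 0.0)
        cache.update(Z=Z, Zhat=Zhat, inv_std=inv_std, B=B, A=A)

        pool_idx = A.argmax(axis=1)  # (N, F)
        M = np.take_along_axis(A, pool_idx[:, None, :], axis=1)[:, 0, :]
        cache.update(pool_idx=pool_idx, M=M)

        H1 = np.maximum(M @ p["W1"] + p["b1"], 0.0)
        H2 = np.maximum(H1 @ p["W2"] + p["b2"], 0.0)
        if training and self.config.dropout_rate > 0:
            keep = 1.0 - self.config.dropout_rate
            mask = (rng.random(H2.shape) < keep) / keep
            H2d = H2 * mask
            cache["drop_mask"] = mask
        else:
            H2d = H2
            cache["drop_mask"] = None
        logits = (H2d @ p["Wo"] + p["bo"]).ravel()
        prob = 1.0 / (1.0 + np.exp(-logits))
        cache.update(H1=H1, H2=H2, H2d=H2d, prob=prob)
        return prob, cache

    # ----- backward -----

    def backward(self, X: np.ndarray, y: np.ndarray, cache: dict) -> dict:
        p = self.params
        N = len(y)
        grads: dict = {}
        dlogits = (cache["prob"] - y)[:, None] / N  # (N, 1)
        grads["Wo"] = cache["H2d"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dH2d = dlogits @ p["Wo"].T
        if cache["drop_mask"] is not None:
            dH2d = dH2d * cache["drop_mask"]
        dH2 = dH2d * (cache["H2"] > 0)
        grads["W2"] = cache["H1"].T @ dH2
        grads["b2"] = dH2.sum(axis=0)
        dH1 = (dH2 @ p["W2"].T) * (cache["H1"] > 0)
        grads["W1"] = cache["M"].T @ dH1
        grads["b1"] = dH1.sum(axis=0)
        dM = dH1 @ p["W1"].T  # (N, F)

        dA = np.zeros_like(cache["A"])
        np.put_along_axis(dA, cache["pool_idx"][:, None, :], dM[:, None, :], axis=1)
        dB = dA * (cache["B"] > 0)
        grads["gamma"] = (dB * cache["Zhat"]).sum(axis=(0, 1))
        grads["beta"] = dB.sum(axis=(0, 1))
        # batch-norm backward over the (batch, position) axes per filter
        dZhat = dB * p["gamma"]
        dZ = (
            dZhat
            - dZhat.mean(axis=(0, 1))
            - cache["Zhat"] * (dZhat * cache["Zhat"]).mean(axis=(0, 1))
        ) * cache["inv_std"]
        grads["Wc"] = np.einsum("npf,npck->fkc", dZ, cache["Xw"])
        grads["bc"] = dZ.sum(axis=(0, 1))
        return grads

    def _adam_step(self, grads: dict) -> None:
        lr = self.config.learning_rate
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            g = g.reshape(self.params[k].shape)
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # ----- public API -----

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        prob, _ = self.forward(X, training=False)
        return prob

    def save(self, path) -> None:
        state = {
            "config": asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "running_mean": self.running_mean.tolist(),
            "running_var": self.running_var.tolist(),
        }
        Path(path).write_text(json.dumps(state) + "\n")

    @classmethod
    def load(cls, path) -> "ConvSiteClassifier":
        state = json.loads(Path(path).read_text())
        cfg = state["config"]
        cfg["dense_units"] = tuple(cfg["dense_units"])
        model = cls(ModelConfig(**cfg))
        model.params = {k: np.asarray(v, dtype=float) for k, v in state["params"].items()}
        model.running_mean = np.asarray(state["running_mean"], dtype=float)
        model.running_var = np.asarray(state["running_var"], dtype=float)
        return model


def train(
    config: ModelConfig, X: np.ndarray, y: np.ndarray
) -> tuple[ConvSiteClassifier, list[dict]]:
    """Fit the classifier; returns (model, per-epoch loss/accuracy history).

    ``epochs = 0`` returns an untrained model with empty history.  Data must
    contain both labels.
    """
    y = np.asarray(y, dtype=float)
    if config.epochs > 0 and len(np.unique(y)) < 2:
        raise ValueError("training data must contain both labels")
    model = ConvSiteClassifier(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    history: list[dict] = []
    n = len(y)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, accs, weights = [], [], []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            Xb, yb = X[idx], y[idx]
            prob, cache = model.forward(Xb, training=True, rng=rng)
            eps = 1e-12
            loss = -np.mean(
                yb * np.log(prob + eps) + (1 - yb) * np.log(1 - prob + eps)
            )
            acc = np.mean((prob >= 0.5) == (yb == 1))
            grads = model.backward(Xb, yb, cache)
            model._adam_step(grads)
            losses.append(loss)
            accs.append(acc)
            weights.append(len(idx))
        w = np.asarray(weights, dtype=float)
        history.append(
            {
                "epoch": epoch + 1,
                "loss": float(np.average(losses, weights=w)),
                "accuracy": float(np.average(accs, weights=w)),
            }
        )
    return model, history


def predict_rank(
    model: ConvSiteClassifier, candidates: Sequence[CandidateSite]
) -> list[RankedPrediction]:
    """Score every candidate and rank by descending sigmoid score.

    Ties are broken by (chrom, start, strand); ranks are 1-based.
    """
    if not candidates:
        return []
    X = encode_batch([c.sequence_23 for c in candidates])
    scores = model.predict_proba(X)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            -scores[i],
            candidates[i].chrom,
            candidates[i].start,
            candidates[i].strand,
        ),
    )
    return [
        RankedPrediction(site=candidates[i], score=float(scores[i]), rank=r + 1)
        for r, i in enumerate(order)
    ]


def recall_at_rank(
    ranked: Sequence[RankedPrediction], truth: set[tuple]
) -> tuple[np.ndarray, list[tuple]]:
    """Cumulative number of true sites within the top k ranks, for all k.

    Truth sites are identified by their (chrom, start, strand) keys.  Truths
    absent from the candidate list are never recovered; they are returned in
    the second element for the caller to flag.
    """
    keys = [r.site.key() for r in ranked]
    curve = np.cumsum([1 if k in truth else 0 for k in keys]).astype(np.int64)
    missing = sorted(truth - set(keys))
    return curve, missing


def history_to_frame(history: Sequence[dict]) -> pd.DataFrame:
    return pd.DataFrame(history, columns=["epoch", "loss", "accuracy"])


def predictions_to_frame(ranked: Sequence[RankedPrediction]) -> pd.DataFrame:
    rows = [
        {
            "rank": r.rank,
            "chrom": r.site.chrom,
            "start": r.site.start,
            "strand": r.site.strand,
            "sequence_23": r.site.sequence_23,
            "mismatch_count": r.site.mismatch_count,
            "pam": r.site.pam,
            "score": r.score,
        }
        for r in ranked
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "rank",
            "chrom",
            "start",
            "strand",
            "sequence_23",
            "mismatch_count",
            "pam",
            "score",
        ],
    )
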