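"""The three model families behind one handle contract.

* ``cnn`` — one-hot input, 3 convolutional hidden layers with a single-head
  self-attention block after the second, masked global average pooling and
  a sigmoid score head.  Capability: ``predict_score``.
* ``cnn_ae`` — one-hot input autoencoder: 5-layer convolutional encoder
  (attention after layer 1) to a 200-dim bottleneck, mirrored 5-layer
  decoder (attention after its 4th layer) to per-position residue
  distributions.  Capabilities: ``extract_features``, ``reconstruct``.
* ``transformer`` — 3-gram token input, 64-dim embeddings with sinusoidal
  positions, stacked pre-norm encoder blocks; the 64-dim state at the
  ``<CLS>`` position is the Extract-layer feature vector and feeds the
  sigmoid score head.  Capabilities: ``predict_score``, ``extract_features``.

Every handle exposes gradients of any scalar output with respect to the
continuous input representation (the one-hot matrix, or the embedded token
vectors), which is the contract integrated-gradients attribution needs.
Padding is masked out of attention and pooling everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .encoding import CLS_ID, EOS_ID, L_MAX, PAD_ID, VOCAB_SIZE
from .nn import Tensor

N_LETTERS = 20

_DEFAULTS: dict[str, dict] = {
    "cnn": {"channels": [32, 32, 64], "kernels": [13, 7, 7], "strides": [1, 2, 2]},
    "cnn_ae": {"channels": 32, "kernel": 7, "latent_dim": 200},
    "transformer": {"embed_dim": 64, "blocks": 2, "heads": 4, "ff_dim": 128},
}


@dataclass
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in _DEFAULTS:
            raise ValueError(f"unknown model family {self.family!r}")
        merged = dict(_DEFAULTS[self.family])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    def to_json(self) -> str:
        return json.dumps({"family": self.family, "seed": self.seed,
                           "hyperparameters": self.hyperparameters})

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(family=d["family"], hyperparameters=d["hyperparameters"],
                   seed=d["seed"])


def _length_mask(lengths: np.ndarray, L: int = L_MAX) -> np.ndarray:
    return (np.arange(L)[None, :] < np.asarray(lengths)[:, None]).astype(np.float32)


class _Handle(nn.Module):
    """Shared checkpoint plumbing for the three families."""

    capabilities: frozenset[str] = frozenset()
    input_kind: str = "one-hot"

    def __init__(self, spec: ModelSpec):
        self.spec = spec

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        path.with_suffix(".json").write_text(self.spec.to_json())

    @classmethod
    def _load_into(cls, handle: "_Handle", path: str | Path) -> "_Handle":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as data:
            handle.load_state_dict({k: data[k] for k in data.files})
        return handle


class CNNClassifier(_Handle):
    capabilities = frozenset({"predict_score"})

    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        hp = spec.hyperparameters
        c1, c2, c3 = hp["channels"]
        k1, k2, k3 = hp["kernels"]
        s1, s2, s3 = hp["strides"]
        rng = np.random.default_rng(spec.seed)
        self.conv1 = nn.Conv1d(N_LETTERS, c1, k1, rng, stride=s1)
        self.conv2 = nn.Conv1d(c1, c2, k2, rng, stride=s2)
        self.attn = nn.SelfAttention(c2, rng)
        self.conv3 = nn.Conv1d(c2, c3, k3, rng, stride=s3)
        # multi-scale readout: one head term per pooled hidden layer
        self.head1 = nn.Dense(c1, 1, rng)
        self.head2 = nn.Dense(c2, 1, rng)
        self.head3 = nn.Dense(c3, 1, rng)
        self._strides = (s1, s2, s3)

    @staticmethod
    def _masked_max(h: Tensor, lengths: np.ndarray, L: int) -> Tensor:
        # masked global max pooling: padding cannot win the max
        mask = _length_mask(lengths, L)
        return (h + Tensor((mask[:, :, None] - 1.0) * np.float32(1e9))).max(axis=1)

    def logits(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        """Score logit: global max pooling of every hidden layer into the head.

        Pooling each of the three hidden representations (rather than only
        the deepest) gives first-layer pattern detectors a direct path to
        the output, which is what makes short sequence motifs learnable
        quickly; the summed per-layer dense terms are equivalent to one
        dense head over the concatenated pooled vector.
        """
        s1, s2, s3 = self._strides
        L = x.shape[1]
        lengths = np.asarray(lengths)
        h1 = self.conv1(x).relu()
        L, lengths = -(-L // s1), -(-lengths // s1)
        p1 = self._masked_max(h1, lengths, L)
        h2 = self.conv2(h1).relu()
        L, lengths = -(-L // s2), -(-lengths // s2)
        mask = _length_mask(lengths, L)
        h2 = h2 + self.attn(h2, mask)
        p2 = self._masked_max(h2, lengths, L)
        h3 = self.conv3(h2).relu()
        L, lengths = -(-L // s3), -(-lengths // s3)
        p3 = self._masked_max(h3, lengths, L)
        out = self.head1(p1) + self.head2(p2) + self.head3(p3)
        return out.reshape(-1)

    def predict_score(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        return self.logits(Tensor(x), lengths).sigmoid().data

    def score_with_grad(self, x: np.ndarray, lengths: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Scores and d(score)/d(one-hot input), per sample."""
        xt = Tensor(x, requires_grad=True)
        scores = self.logits(xt, lengths).sigmoid()
        scores.sum().backward()   # samples are independent, so per-sample grads
        return scores.data, xt.grad


class CNNAutoencoder(_Handle):
    capabilities = frozenset({"extract_features", "reconstruct"})

    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        hp = spec.hyperparameters
        c, k = hp["channels"], hp["kernel"]
        self.latent_dim = hp["latent_dim"]
        rng = np.random.default_rng(spec.seed)
        self.enc = [nn.Conv1d(N_LETTERS if i == 0 else c, c, k, rng) for i in range(5)]
        self.enc_attn = nn.SelfAttention(c, rng)
        self.to_latent = nn.Dense(L_MAX * c, self.latent_dim, rng)
        self.from_latent = nn.Dense(self.latent_dim, L_MAX * c, rng)
        self.dec = [nn.Conv1d(c, c, k, rng) for i in range(5)]
        self.dec_attn = nn.SelfAttention(c, rng)
        self.out = nn.Conv1d(c, N_LETTERS, k, rng)
        self._c = c

    def encode(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        mask = _length_mask(lengths)
        h = self.enc[0](x).relu()
        h = h + self.enc_attn(h, mask)
        for conv in self.enc[1:]:
            h = conv(h).relu()
        h = h * Tensor(mask[:, :, None])
        return self.to_latent(h.reshape(h.shape[0], -1))

    def decode_logits(self, z: Tensor, lengths: np.ndarray) -> Tensor:
        mask = _length_mask(lengths)
        h = self.from_latent(z).reshape(z.shape[0], L_MAX, self._c)
        for conv in self.dec[:4]:
            h = conv(h).relu()
        h = h + self.dec_attn(h, mask)
        h = self.dec[4](h).relu()
        return self.out(h)      # (B, L_MAX, 20) logits

    def extract_features(self, x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        return self.encode(Tensor(x), lengths).data

    def reconstruct(self, x: np.ndarray, lengths: np.ndarray) -> list[str]:
        from .encoding import ALPHABET
        z = self.encode(Tensor(x), lengths)
        logits = self.decode_logits(z, lengths).data
        out = []
        for b, L in enumerate(np.asarray(lengths)):
            idx = logits[b, :int(L)].argmax(axis=1)
            out.append("".join(ALPHABET[i] for i in idx))
        return out

    def feature_with_grad(self, x: np.ndarray, lengths: np.ndarray, coord: int
                          ) -> tuple[np.ndarray, np.ndarray]:
        """One latent coordinate and its gradient w.r.t. the one-hot input."""
        xt = Tensor(x, requires_grad=True)
        z = self.encode(xt, lengths)
        z[:, coord].sum().backward()
        return z.data[:, coord], xt.grad


class TransformerEncoderModel(_Handle):
    capabilities = frozenset({"predict_score", "extract_features"})
    input_kind = "tokens"

    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        hp = spec.hyperparameters
        d, blocks, heads, d_ff = (hp["embed_dim"], hp["blocks"],
                                  hp["heads"], hp["ff_dim"])
        rng = np.random.default_rng(spec.seed)
        self.embedding = nn.Embedding(VOCAB_SIZE, d, rng)
        self.blocks = [nn.TransformerBlock(d, heads, d_ff, rng) for _ in range(blocks)]
        self.norm = nn.LayerNorm(d)
        self.head = nn.Dense(d, 1, rng)
        self._posenc = nn.sinusoidal_positions(L_MAX, d)
        self.extract_dim = d

    # -- embedding front end (the continuous representation IG interpolates)
    def embed_tokens(self, tokens: np.ndarray) -> np.ndarray:
        return self.embedding(tokens).data + self._posenc[None, :, :]

    def baseline_embedding(self, tokens: np.ndarray) -> np.ndarray:
        """Embedding of the all-<pad> sequence with <CLS>/<EOS> retained."""
        base = np.asarray(tokens).copy()
        content = (base != PAD_ID) & (base != CLS_ID) & (base != EOS_ID)
        base[content] = PAD_ID
        return self.embed_tokens(base)

    @staticmethod
    def token_mask(tokens: np.ndarray) -> np.ndarray:
        return (np.asarray(tokens) != PAD_ID).astype(np.float32)

    # -- forward passes
    def _encode_emb(self, emb: Tensor, mask: np.ndarray) -> Tensor:
        h = emb
        for block in self.blocks:
            h = block(h, mask)
        return self.norm(h)

    def extract_from_embedding(self, emb: Tensor, mask: np.ndarray) -> Tensor:
        return self._encode_emb(emb, mask)[:, 0, :]     # <CLS> state

    def logits_from_embedding(self, emb: Tensor, mask: np.ndarray) -> Tensor:
        return self.head(self.extract_from_embedding(emb, mask)).reshape(-1)

    def logits(self, tokens: np.ndarray) -> Tensor:
        emb = self.embedding(tokens) + Tensor(self._posenc[None, :, :])
        return self.logits_from_embedding(emb, self.token_mask(tokens))

    def predict_score(self, tokens: np.ndarray) -> np.ndarray:
        return self.logits(tokens).sigmoid().data

    def extract_features(self, tokens: np.ndarray) -> np.ndarray:
        emb = self.embedding(tokens) + Tensor(self._posenc[None, :, :])
        return self.extract_from_embedding(emb, self.token_mask(tokens)).data

    def score_with_grad(self, emb: np.ndarray, mask: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
        et = Tensor(emb, requires_grad=True)
        scores = self.logits_from_embedding(et, mask).sigmoid()
        scores.sum().backward()
        return scores.data, et.grad

    def feature_with_grad(self, emb: np.ndarray, mask: np.ndarray, coord: int
                          ) -> tuple[np.ndarray, np.ndarray]:
        et = Tensor(emb, requires_grad=True)
        z = self.extract_from_embedding(et, mask)
        z[:, coord].sum().backward()
        return z.data[:, coord], et.grad


ModelHandle = CNNClassifier | CNNAutoencoder | TransformerEncoderModel

_FAMILIES = {"cnn": CNNClassifier, "cnn_ae": CNNAutoencoder,
             "transformer": TransformerEncoderModel}


def build_cnn_classifier(spec: ModelSpec) -> CNNClassifier:
    if spec.family != "cnn":
        raise ValueError("spec.family must be 'cnn'")
    return CNNClassifier(spec)


def build_cnn_autoencoder(spec: ModelSpec) -> CNNAutoencoder:
    if spec.family != "cnn_ae":
        raise ValueError("spec.family must be 'cnn_ae'")
    return CNNAutoencoder(spec)


def build_transformer(spec: ModelSpec) -> TransformerEncoderModel:
    if spec.family != "transformer":
        raise ValueError("spec.family must be 'transformer'")
    return TransformerEncoderModel(spec)


def build_model(spec: ModelSpec) -> ModelHandle:
    return _FAMILIES[spec.family](spec)


def load_model(path: str | Path) -> ModelHandle:
    path = Path(path)
    spec = ModelSpec.from_json(path.with_suffix(".json").read_text())
    handle = build_model(spec)
    return _Handle._load_into(handle, path)
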