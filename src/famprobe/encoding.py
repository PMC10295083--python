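"""Model input encodings: zero-padded one-hot matrices and 3-gram tokens.

Two fixed-size encodings over a 700-position budget:

* a 700 x 20 binary matrix (one row per residue, alphabetical column
  order, zero rows beyond the true length), and
* a 700-long integer token sequence of overlapping 3-mers framed by
  ``<CLS>`` / ``<EOS>`` and right-padded with ``<pad>`` — a length-700
  protein fills the budget exactly (698 content 3-mers + 2 specials).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqdata import CANONICAL, SequenceRecord

L_MAX = 700
ALPHABET = CANONICAL  # alphabetical one-letter order
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

PAD, CLS, EOS, UNK = "<pad>", "<CLS>", "<EOS>", "<UNK>"


def build_vocabulary() -> dict[str, int]:
    """Token vocabulary: 4 specials then all 8000 canonical 3-mers, sorted."""
    vocab = {PAD: 0, CLS: 1, EOS: 2, UNK: 3}
    for gram in itertools.product(ALPHABET, repeat=3):
        vocab["".join(gram)] = len(vocab)
    return vocab


VOCAB = build_vocabulary()
VOCAB_SIZE = len(VOCAB)  # 8004
PAD_ID, CLS_ID, EOS_ID, UNK_ID = VOCAB[PAD], VOCAB[CLS], VOCAB[EOS], VOCAB[UNK]


@dataclass
class OneHotMatrix:
    values: np.ndarray          # (L_MAX, 20) float32 of {0,1}
    true_length: int


@dataclass
class TokenSequence:
    tokens: np.ndarray          # (L_MAX,) int64
    true_length: int            # residue count of the underlying sequence


def _seq_of(record: SequenceRecord | str) -> str:
    return record.seq if isinstance(record, SequenceRecord) else record


def one_hot_encode(record: SequenceRecord | str) -> OneHotMatrix:
    seq = _seq_of(record)
    if len(seq) > L_MAX:
        raise ValueError(f"sequence length {len(seq)} exceeds {L_MAX}")
    mat = np.zeros((L_MAX, len(ALPHABET)), dtype=np.float32)
    for i, aa in enumerate(seq):
        try:
            mat[i, _AA_INDEX[aa]] = 1.0
        except KeyError:
            raise ValueError(f"non-canonical residue {aa!r} at position {i}") from None
    return OneHotMatrix(values=mat, true_length=len(seq))


def one_hot_decode(mat: OneHotMatrix | np.ndarray,
                   true_length: int | None = None) -> str:
    values = mat.values if isinstance(mat, OneHotMatrix) else mat
    if true_length is None:
        true_length = mat.true_length if isinstance(mat, OneHotMatrix) else \
            int(values.sum())
    idx = values[:true_length].argmax(axis=1)
    return "".join(ALPHABET[i] for i in idx)


def tokenize_3gram(record: SequenceRecord | str) -> TokenSequence:
    """[<CLS>, g_1..g_{L-2}, <EOS>, <pad>...] padded to exactly 700 tokens."""
    seq = _seq_of(record)
    L = len(seq)
    if L < 3:
        raise ValueError(f"3-gram tokenization needs length >= 3, got {L}")
    if L > L_MAX:
        raise ValueError(f"sequence length {L} exceeds {L_MAX}")
    tokens = np.full(L_MAX, PAD_ID, dtype=np.int64)
    tokens[0] = CLS_ID
    for i in range(L - 2):
        tokens[1 + i] = VOCAB.get(seq[i:i + 3], UNK_ID)
    tokens[L - 1] = EOS_ID
    return TokenSequence(tokens=tokens, true_length=L)


def detokenize(ts: TokenSequence) -> str:
    """Invert 3-gram tokenization (first letters of each gram + last 2)."""
    inv = {v: k for k, v in VOCAB.items()}
    grams = []
    for tid in ts.tokens[1:]:
        if tid == EOS_ID:
            break
        grams.append(inv[int(tid)])
    if not grams:
        return ""
    return "".join(g[0] for g in grams) + grams[-1][1:]


def token_to_residue_map(record: SequenceRecord | str) -> dict[int, list[int]]:
    """Residue index -> token positions whose 3-mer window covers it.

    Content token at position ``p`` (1-based within the token array, after
    <CLS>) holds the 3-mer starting at residue ``p - 1`` and covers residues
    ``p-1 .. p+1``; each residue is covered by at most 3 tokens.
    """
    seq = _seq_of(record)
    L = len(seq)
    out: dict[int, list[int]] = {j: [] for j in range(L)}
    for p in range(1, L - 1):          # token positions 1 .. L-2
        start = p - 1
        for j in range(start, start + 3):
            out[j].append(p)
    return out


def save_vocabulary(path: str | Path) -> None:
    with open(path, "w") as fh:
        for token, tid in VOCAB.items():
            fh.write(f"{token}\t{tid}\n")


def load_vocabulary(path: str | Path) -> dict[str, int]:
    vocab: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            token, tid = line.rstrip("\n").split("\t")
            vocab[token] = int(tid)
    return vocab
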