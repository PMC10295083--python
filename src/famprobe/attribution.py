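"""Integrated gradients on scores and feature vectors, per residue.

Integrated gradients attributes a differentiable scalar F to input
coordinates as

    IG_i(x) = (x_i - b_i) * (1/m) * sum_{t=1..m} dF/dx_i evaluated at
              b + (t - 0.5)/m * (x - b),

a midpoint-rule approximation of the path integral from a baseline b to
the input x.  Its defining property (the completeness axiom) is that the
attributions sum to F(x) - F(b) as m grows.

Per-residue tracks take the absolute attribution, summed over input
channels (one-hot models) or redistributed from covering 3-mer tokens to
residues (token models), and are min-max normalized to [0, 1] per
sequence for display.  Baselines: the all-zero one-hot matrix (the "no
residue" input), and the all-<pad> embedding with <CLS>/<EOS> retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import pearsonr

from .encoding import one_hot_encode, token_to_residue_map, tokenize_3gram
from .models import CNNAutoencoder, CNNClassifier, TransformerEncoderModel
from .seqdata import SequenceRecord


@dataclass
class AttributionTrack:
    record_id: str
    family: str
    mode: str                     # score | features
    values: np.ndarray            # per-residue nonnegative floats, true length
    normalized: bool
    ig_steps: int
    baseline: str


# ------------------------------------------------------------------ core IG
def integrated_gradients(grad_fn, x: np.ndarray, baseline: np.ndarray,
                         m_steps: int = 64, batch: int = 64) -> np.ndarray:
    """Midpoint-rule integrated gradients for a single input.

    ``grad_fn(points)`` must return the gradient of the scalar function at
    each row of a stacked batch of inputs shaped ``(k, *x.shape)``.
    """
    x = np.asarray(x, dtype=np.float32)
    baseline = np.asarray(baseline, dtype=np.float32)
    if x.shape != baseline.shape:
        raise ValueError(f"shape mismatch: input {x.shape} vs baseline {baseline.shape}")
    if m_steps < 1:
        raise ValueError("m_steps must be >= 1")
    alphas = (np.arange(m_steps, dtype=np.float64) + 0.5) / m_steps
    total = np.zeros_like(x, dtype=np.float64)
    for i in range(0, m_steps, batch):
        chunk = alphas[i:i + batch]
        points = baseline[None] + chunk.reshape((-1,) + (1,) * x.ndim) * (x - baseline)[None]
        grads = grad_fn(points.astype(np.float32))
        total += grads.sum(axis=0)
    return ((x - baseline) * (total / m_steps)).astype(np.float64)


def _per_residue_onehot(attr: np.ndarray, true_length: int) -> np.ndarray:
    return np.abs(attr)[:true_length].sum(axis=1)


def _per_residue_tokens(attr: np.ndarray, record: SequenceRecord) -> np.ndarray:
    """Redistribute |token attribution| to the residues each 3-mer covers."""
    token_abs = np.abs(attr).sum(axis=1)          # (700,) per token position
    mapping = token_to_residue_map(record)
    out = np.zeros(len(record.seq))
    for residue, token_positions in mapping.items():
        out[residue] = sum(token_abs[p] for p in token_positions)
    return out


# ------------------------------------------------------------- track builders
def attribute_score(handle: CNNClassifier | TransformerEncoderModel,
                    record: SequenceRecord, m_steps: int = 64) -> AttributionTrack:
    """Per-residue |IG| of the prediction score for one sequence."""
    if "predict_score" not in handle.capabilities:
        raise ValueError(f"{type(handle).__name__} cannot predict scores")
    if getattr(handle, "input_kind", "one-hot") == "tokens":
        tokens = tokenize_3gram(record).tokens[None]
        x = handle.embed_tokens(tokens)[0]
        baseline = handle.baseline_embedding(tokens)[0]
        mask = handle.token_mask(tokens)

        def grad_fn(points):
            k = points.shape[0]
            _, g = handle.score_with_grad(points, np.repeat(mask, k, axis=0))
            return g
        attr = integrated_gradients(grad_fn, x, baseline, m_steps)
        values = _per_residue_tokens(attr, record)
        baseline_name = "all-pad-embedding"
        family = "transformer"
    else:
        mat = one_hot_encode(record)
        x = mat.values
        baseline = np.zeros_like(x)
        lengths = np.array([mat.true_length])

        def grad_fn(points):
            k = points.shape[0]
            _, g = handle.score_with_grad(points, np.repeat(lengths, k))
            return g
        attr = integrated_gradients(grad_fn, x, baseline, m_steps)
        values = _per_residue_onehot(attr, mat.true_length)
        baseline_name = "zero-one-hot"
        family = "cnn"
    return AttributionTrack(record_id=record.id, family=family, mode="score",
                            values=values, normalized=False, ig_steps=m_steps,
                            baseline=baseline_name)


def attribute_features(handle: CNNAutoencoder | TransformerEncoderModel,
                       record: SequenceRecord, m_steps: int = 64,
                       coords: list[int] | None = None) -> AttributionTrack:
    """Per-residue |IG| summed over every feature-vector coordinate.

    Each coordinate of the feature vector is treated as its own scalar
    output; per-coordinate absolute attributions are summed into a single
    track.  ``coords`` restricts the aggregation to a subset (useful when
    the full pass over 200 coordinates is not needed).
    """
    if "extract_features" not in handle.capabilities:
        raise ValueError(f"{type(handle).__name__} cannot extract features")
    is_tokens = getattr(handle, "input_kind", "one-hot") == "tokens"
    if is_tokens:
        tokens = tokenize_3gram(record).tokens[None]
        x = handle.embed_tokens(tokens)[0]
        baseline = handle.baseline_embedding(tokens)[0]
        mask = handle.token_mask(tokens)
        dim = handle.extract_dim
        family = "transformer"
    else:
        mat = one_hot_encode(record)
        x = mat.values
        baseline = np.zeros_like(x)
        lengths = np.array([mat.true_length])
        dim = handle.latent_dim
        family = "cnn_ae"
    coords = list(range(dim)) if coords is None else coords

    L = len(record.seq)
    values = np.zeros(L)
    for coord in coords:
        if is_tokens:
            def grad_fn(points, c=coord):
                k = points.shape[0]
                _, g = handle.feature_with_grad(points, np.repeat(mask, k, axis=0), c)
                return g
        else:
            def grad_fn(points, c=coord):
                k = points.shape[0]
                _, g = handle.feature_with_grad(points, np.repeat(lengths, k), c)
                return g
        attr = integrated_gradients(grad_fn, x, baseline, m_steps)
        if is_tokens:
            values += _per_residue_tokens(attr, record)
        else:
            values += _per_residue_onehot(attr, L)
    return AttributionTrack(record_id=record.id, family=family, mode="features",
                            values=values, normalized=False, ig_steps=m_steps,
                            baseline="all-pad-embedding" if is_tokens else "zero-one-hot")


def normalize_track(track: AttributionTrack) -> AttributionTrack:
    """Min-max normalize to [0, 1]; constant tracks become all zeros."""
    v = np.asarray(track.values, dtype=float)
    span = v.max() - v.min()
    normed = np.zeros_like(v) if span == 0 else (v - v.min()) / span
    return AttributionTrack(record_id=track.record_id, family=track.family,
                            mode=track.mode, values=normed, normalized=True,
                            ig_steps=track.ig_steps, baseline=track.baseline)


# -------------------------------------------------------- conservation compare
def column_conservation(msa: dict[str, str]) -> np.ndarray:
    """Per-column conservation: frequency of the modal residue, gaps excluded."""
    seqs = list(msa.values())
    ncol = len(seqs[0])
    if any(len(s) != ncol for s in seqs):
        raise ValueError("alignment rows have unequal lengths")
    out = np.zeros(ncol)
    for j in range(ncol):
        col = [s[j] for s in seqs if s[j] not in "-."]
        if col:
            _, counts = np.unique(col, return_counts=True)
            out[j] = counts.max() / len(col)
    return out


def conservation_correlation(track: AttributionTrack, msa: dict[str, str],
                             reference_id: str) -> float | None:
    """Pearson r between a per-residue track and alignment conservation.

    Conservation columns are mapped to reference residues by skipping
    reference gaps.  Returns ``None`` when conservation has no variance.
    """
    if reference_id not in msa:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    cons = column_conservation(msa)
    ref_row = msa[reference_id]
    ref_cols = [j for j, c in enumerate(ref_row) if c not in "-."]
    if len(ref_cols) != len(track.values):
        raise ValueError(
            f"track length {len(track.values)} != reference ungapped length "
            f"{len(ref_cols)}")
    cons_ref = cons[ref_cols]
    if cons_ref.std() == 0 or np.asarray(track.values).std() == 0:
        import warnings
        warnings.warn("correlation undefined for a constant vector", stacklevel=2)
        return None
    r, _ = pearsonr(track.values, cons_ref)
    return float(r)


# ------------------------------------------------------------------- exporters
def track_to_tsv(track: AttributionTrack, seq: str, path: str | Path,
                 normalized_values: np.ndarray | None = None) -> None:
    norm = normalized_values
    if norm is None:
        norm = normalize_track(track).values
    with open(path, "w") as fh:
        fh.write("id\tresidue_index\tresidue\traw\tnormalized\n")
        for i, (aa, raw, nv) in enumerate(zip(seq, track.values, norm), start=1):
            fh.write(f"{track.record_id}\t{i}\t{aa}\t{raw:.6g}\t{nv:.6g}\n")


def tracks_to_jalview(tracks: list[AttributionTrack], path: str | Path) -> None:
    """Write per-sequence BAR_GRAPH annotation rows readable by Jalview."""
    with open(path, "w") as fh:
        fh.write("JALVIEW_ANNOTATION\n")
        for track in tracks:
            normed = track.values if track.normalized else normalize_track(track).values
            label = f"IG_{track.family}_{track.mode}"
            row = "|".join(f"{v:.4f}" for v in normed)
            fh.write(f"SEQUENCE_REF\t{track.record_id}\n")
            fh.write(f"BAR_GRAPH\t{label}\t{row}\n")
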