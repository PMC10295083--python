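"""Homogeneous-batch training, checkpoint selection, and evaluation metrics.

Classifiers are trained with alternating all-positive / all-negative
batches so class imbalance cannot push the model toward the majority
label; each pool is sampled without replacement and reshuffled when it
runs out.  The autoencoder trains on positives only with a masked
per-position cross-entropy.  Reconstruction quality is summarized by the
match rate: the fraction of input positions the reconstruction reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .encoding import one_hot_encode, tokenize_3gram
from .models import CNNAutoencoder, CNNClassifier, TransformerEncoderModel
from .nn import Adam, Tensor
from .seqdata import SequenceRecord


# ------------------------------------------------------------------- batch plan
@dataclass
class BatchPlan:
    batches: list[tuple[str, list[str]]]     # (label, record ids)
    batch_size: int
    seed: int


def make_balanced_batches(pos_ids: list[str], neg_ids: list[str],
                          batch_size: int, n_steps: int, seed: int) -> BatchPlan:
    """Alternating single-label batches, sampled without replacement.

    Each label keeps its own shuffled queue; a batch pops ``batch_size``
    ids, reshuffling the full pool whenever the queue empties mid-batch.
    """
    if not pos_ids or not neg_ids:
        raise ValueError("both pools must be non-empty")
    rng = np.random.default_rng(seed)
    queues = {"positive": list(rng.permutation(pos_ids)),
              "negative": list(rng.permutation(neg_ids))}
    pools = {"positive": list(pos_ids), "negative": list(neg_ids)}
    batches: list[tuple[str, list[str]]] = []
    for step in range(n_steps):
        label = "positive" if step % 2 == 0 else "negative"
        batch: list[str] = []
        while len(batch) < batch_size:
            if not queues[label]:
                queues[label] = list(rng.permutation(pools[label]))
            batch.append(queues[label].pop(0))
        batches.append((label, batch))
    return BatchPlan(batches=batches, batch_size=batch_size, seed=seed)


# ---------------------------------------------------------------------- metrics
@dataclass
class MetricsReport:
    acc: float
    auc: float | None
    f1: float
    mcc: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {"acc": self.acc, "auc": self.auc, "f1": self.f1, "mcc": self.mcc,
                "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def classification_metrics(labels: np.ndarray, scores: np.ndarray,
                           threshold: float = 0.5) -> MetricsReport:
    """ACC/F1/MCC from thresholded confusion counts; AUC as the rank statistic.

    With a single class present AUC is undefined and reported as ``None``.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = tp + fp + tn + fn
    acc = (tp + tn) / n if n else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    if len(set(labels.tolist())) < 2:
        import warnings
        warnings.warn("AUC undefined for single-class labels", stacklevel=2)
        auc = None
    else:
        auc = float(roc_auc_score(labels, scores))
    return MetricsReport(acc=acc, auc=auc, f1=f1, mcc=float(mcc),
                         tp=tp, fp=fp, tn=tn, fn=fn)


def match_rate(input_seq: str, output_seq: str) -> float:
    """Fraction of input positions reproduced by the output (Match rate).

    Positions are compared positionwise up to the shorter length; the
    denominator is the input length, so a truncated output is penalized.
    """
    if not input_seq:
        raise ValueError("match_rate requires a non-empty input sequence")
    overlap = min(len(input_seq), len(output_seq))
    matched = sum(1 for i in range(overlap) if input_seq[i] == output_seq[i])
    return matched / len(input_seq)


# ------------------------------------------------------------------- histories
@dataclass
class TrainingHistory:
    losses: list[float] = field(default_factory=list)
    checkpoints: list[dict] = field(default_factory=list)   # {"step": .., metrics..}


@dataclass
class OptimizerConfig:
    lr: float = 3e-3
    weight_decay: float = 0.0
    batch_size: int = 32
    checkpoint_every: int = 100


def _encode_batch(records: dict[str, SequenceRecord], ids: list[str],
                  kind: str) -> tuple[np.ndarray, np.ndarray]:
    if kind == "tokens":
        toks = np.stack([tokenize_3gram(records[i]).tokens for i in ids])
        lengths = np.array([len(records[i].seq) for i in ids])
        return toks, lengths
    mats = np.stack([one_hot_encode(records[i]).values for i in ids])
    lengths = np.array([len(records[i].seq) for i in ids])
    return mats, lengths


def _bce_from_logits(logits: Tensor, y: float) -> Tensor:
    # softplus(z) - y*z, with softplus(z) = relu(z) + log(1 + exp(-|z|))
    absz = logits.relu() + (-logits).relu()
    softplus = logits.relu() + (1.0 + (-absz).exp()).log()
    return (softplus - logits * y).mean()


def train_classifier(handle: CNNClassifier | TransformerEncoderModel,
                     plan: BatchPlan,
                     records: dict[str, SequenceRecord],
                     config: OptimizerConfig = OptimizerConfig(),
                     val_labels: np.ndarray | None = None,
                     val_ids: list[str] | None = None,
                     ) -> tuple[CNNClassifier | TransformerEncoderModel, TrainingHistory]:
    """One binary-cross-entropy gradient step per homogeneous batch.

    If a validation set is supplied, the four classification metrics are
    recorded every ``checkpoint_every`` steps (and at the final step).
    """
    opt = Adam(handle.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    history = TrainingHistory()
    kind = getattr(handle, "input_kind", "one-hot")
    for step, (label, ids) in enumerate(plan.batches, start=1):
        x, lengths = _encode_batch(records, ids, kind)
        opt.zero_grad()
        if kind == "tokens":
            logits = handle.logits(x)
        else:
            logits = handle.logits(Tensor(x), lengths)
        y = 1.0 if label == "positive" else 0.0
        loss = _bce_from_logits(logits, y)
        lval = loss.item()
        if not np.isfinite(lval):
            raise FloatingPointError(f"non-finite loss at step {step}")
        loss.backward()
        opt.step()
        history.losses.append(lval)
        last = step == len(plan.batches)
        if val_ids is not None and (step % config.checkpoint_every == 0 or last):
            scores = predict_scores(handle, records, val_ids)
            report = classification_metrics(val_labels, scores)
            history.checkpoints.append({"step": step, **report.as_dict(),
                                        "state": handle.state_dict()})
    return handle, history


def predict_scores(handle, records: dict[str, SequenceRecord],
                   ids: list[str], chunk: int = 32) -> np.ndarray:
    kind = getattr(handle, "input_kind", "one-hot")
    out = []
    for i in range(0, len(ids), chunk):
        x, lengths = _encode_batch(records, ids[i:i + chunk], kind)
        if kind == "tokens":
            out.append(handle.predict_score(x))
        else:
            out.append(handle.predict_score(x, lengths))
    return np.concatenate(out)


def train_autoencoder(handle: CNNAutoencoder,
                      positive_ids: list[str],
                      records: dict[str, SequenceRecord],
                      n_steps: int,
                      seed: int,
                      config: OptimizerConfig = OptimizerConfig(),
                      eval_ids: list[str] | None = None,
                      ) -> tuple[CNNAutoencoder, TrainingHistory]:
    """Train the autoencoder on positives only with masked reconstruction loss.

    The loss is the mean cross-entropy over content positions between the
    decoder's per-position residue distribution and the input one-hot.
    Checkpoints record the mean match rate and the count of sequences
    reconstructed at match rate >= 0.9.
    """
    if any(records[i].source == "negative" for i in positive_ids):
        raise ValueError("autoencoder training pool must contain no negatives")
    rng = np.random.default_rng(seed)
    queue: list[str] = []
    opt = Adam(handle.parameters(), lr=config.lr)
    history = TrainingHistory()
    eval_ids = eval_ids if eval_ids is not None else positive_ids
    for step in range(1, n_steps + 1):
        batch = []
        while len(batch) < min(config.batch_size, len(positive_ids)):
            if not queue:
                queue = list(rng.permutation(positive_ids))
            batch.append(queue.pop(0))
        x, lengths = _encode_batch(records, batch, "one-hot")
        mask = (np.arange(x.shape[1])[None, :] < lengths[:, None]).astype(np.float32)
        opt.zero_grad()
        xt = Tensor(x)
        z = handle.encode(Tensor(x, requires_grad=False), lengths)
        logits = handle.decode_logits(z, lengths)
        logp = (logits.softmax(axis=-1) + 1e-8).log()
        ce = -(logp * xt).sum(axis=-1) * Tensor(mask)
        loss = ce.sum() / float(mask.sum())
        lval = loss.item()
        if not np.isfinite(lval):
            raise FloatingPointError(f"non-finite loss at step {step}")
        loss.backward()
        opt.step()
        history.losses.append(lval)
        if step % config.checkpoint_every == 0 or step == n_steps:
            rates = reconstruction_match_rates(handle, records, eval_ids)
            history.checkpoints.append({
                "step": step,
                "match_rate_mean": float(np.mean(rates)),
                "n_match_ge_0.9": int((np.asarray(rates) >= 0.9).sum()),
                "state": handle.state_dict(),
            })
    return handle, history


def reconstruction_match_rates(handle: CNNAutoencoder,
                               records: dict[str, SequenceRecord],
                               ids: list[str], chunk: int = 16) -> list[float]:
    rates: list[float] = []
    for i in range(0, len(ids), chunk):
        sub = ids[i:i + chunk]
        x, lengths = _encode_batch(records, sub, "one-hot")
        recon = handle.reconstruct(x, lengths)
        rates.extend(match_rate(records[r].seq, out) for r, out in zip(sub, recon))
    return rates


# ---------------------------------------------------------- checkpoint selection
_CLS_METRICS = ("acc", "auc", "f1", "mcc")


def select_checkpoint(history: TrainingHistory, criterion: str = "classifier") -> int:
    """Pick the checkpoint index to keep.

    Classifier: the checkpoint that is best on all four metrics
    simultaneously if one exists, otherwise the highest mean rank across
    metrics.  Autoencoder: lexicographic on (count of match rates >= 0.9,
    mean match rate).  Ties always resolve to the latest step.
    """
    cps = history.checkpoints
    if not cps:
        raise ValueError("history has no checkpoints")
    if criterion == "autoencoder":
        best = max(range(len(cps)), key=lambda i: (
            cps[i]["n_match_ge_0.9"], cps[i]["match_rate_mean"], cps[i]["step"]))
        return best
    # classifier: look for a simultaneous maximizer
    vals = {m: np.array([cp[m] if cp[m] is not None else -np.inf for cp in cps])
            for m in _CLS_METRICS}
    dominant = [i for i in range(len(cps))
                if all(vals[m][i] == vals[m].max() for m in _CLS_METRICS)]
    if dominant:
        return dominant[-1]
    from scipy.stats import rankdata
    ranks = np.mean([rankdata(vals[m]) for m in _CLS_METRICS], axis=0)
    best_rank = ranks.max()
    return int(np.nonzero(ranks == best_rank)[0][-1])


def restore_checkpoint(handle, history: TrainingHistory, index: int):
    handle.load_state_dict(history.checkpoints[index]["state"])
    return handle
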