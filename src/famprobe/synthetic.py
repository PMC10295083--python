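"""Seeded planted-motif family generator.

Stands in for downloaded protein families during development and testing:
positives are random background sequences with a short motif (possibly
point-mutated) planted at a random interior position; negatives are pure
background with a matched length distribution.  The ground-truth planted
interval for every positive is returned so attribution methods can be
scored on whether they recover it.

Defaults describe the study conditions used throughout the test-suite:
150 positives / 600 negatives, a length-12 motif, lengths 400-700,
uniform residue composition and a 10% per-position motif mutation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqdata import CANONICAL, SequenceRecord, generate_artificial_negatives

DEFAULT_MOTIF = "WYCHKWMFCYHP"  # length 12, rare letters so background hits are unlikely


def load_background_composition() -> np.ndarray:
    """Average residue frequencies of natural proteins, ordered like the
    canonical alphabet; pass as ``MotifFamilySpec.background`` for a more
    realistic (non-uniform) background composition."""
    path = Path(__file__).parent / "data" / "background_composition.tsv"
    freq = {}
    for line in path.read_text().strip().split("\n"):
        aa, p = line.split("\t")
        freq[aa] = float(p)
    vec = np.array([freq[a] for a in CANONICAL])
    return vec / vec.sum()


@dataclass
class MotifFamilySpec:
    n_pos: int = 150
    n_neg: int = 600
    motif: str = DEFAULT_MOTIF
    length_range: tuple[int, int] = (400, 700)
    background: np.ndarray | None = None   # composition over the 20 letters
    mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if len(self.motif) >= lo:
            raise ValueError("motif must be shorter than the minimum length")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must be in [0, 1)")
        if any(c not in CANONICAL for c in self.motif):
            raise ValueError("motif must use canonical residues")


@dataclass
class MotifTruth:
    """1-based inclusive planted interval per positive id."""
    intervals: dict[str, tuple[int, int]] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int, p: np.ndarray | None) -> str:
    letters = rng.choice(list(CANONICAL), size=length, p=p)
    return "".join(letters)


def generate_motif_family(spec: MotifFamilySpec,
                          ) -> tuple[list[SequenceRecord], list[SequenceRecord], MotifTruth]:
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    m = len(spec.motif)
    p = spec.background
    if p is not None:
        p = np.asarray(p, dtype=float)
        p = p / p.sum()

    positives: list[SequenceRecord] = []
    truth = MotifTruth()
    for i in range(spec.n_pos):
        length = int(rng.integers(lo, hi + 1))
        seq = list(_random_seq(rng, length, p))
        motif = list(spec.motif)
        for j in range(m):
            if rng.random() < spec.mutation_rate:
                motif[j] = CANONICAL[int(rng.integers(20))]
        start = int(rng.integers(1, length - m))  # interior: never at either end
        seq[start:start + m] = motif
        rid = f"pos_{i:04d}"
        positives.append(SequenceRecord(id=rid, seq="".join(seq), source="positive"))
        truth.intervals[rid] = (start + 1, start + m)  # 1-based inclusive

    negatives = [
        SequenceRecord(id=f"neg_{i:04d}",
                       seq=_random_seq(rng, int(rng.integers(lo, hi + 1)), p),
                       source="negative")
        for i in range(spec.n_neg)
    ]
    return positives, negatives, truth


def generate_repeat_decoys(min_len: int = 400, max_len: int = 700,
                           seed: int = 0) -> list[SequenceRecord]:
    """Dipeptide-repeat decoy negatives (delegates to the dataset module)."""
    return generate_artificial_negatives(min_len=min_len, max_len=max_len, seed=seed)


def write_truth(truth: MotifTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tmotif_start\tmotif_end\n")
        for rid, (s, e) in truth.intervals.items():
            fh.write(f"{rid}\t{s}\t{e}\n")
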