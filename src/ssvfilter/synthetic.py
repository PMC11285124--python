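"""Synthetic models, targets, and planted ungapped segments with ground truth.

Everything other modules need for testing without external data: random
emission profiles (symmetric Dirichlet rows), i.i.d. uniform nucleotide
targets, and planted high-scoring diagonal segments whose exact
full-precision bit score is recorded so quantization-envelope reasoning can
be tested against known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .phmm_io import STAR_SCORE, ProfileHMM
from .sequence_io import LETTER_OF

LOG2E = math.log2(math.e)


@dataclass
class TruthEntry:
    """One planted segment: location plus its exact unrounded bit score."""

    seq_index: int
    seq_start: int  # 0-based
    model_index: int
    model_start: int  # 0-based
    length: int
    score_bits: float


@dataclass
class SyntheticTruth:
    planted: list[TruthEntry] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)


def generate_model(
    K: int,
    concentration: float,
    seed: int,
    name: str | None = None,
    gumbel: tuple[float, float] | None = None,
) -> ProfileHMM:
    """Random emission profile with Dirichlet(concentration) rows.

    Scores are stored as negative natural logs of the row probabilities. No
    Gumbel statistics are attached unless ``gumbel`` is given, which forces
    downstream code through the simulation-calibration path.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet([concentration] * 4, size=K)
    # sharp Dirichlet draws can underflow to exact 0: impossible emission
    with np.errstate(divide="ignore"):
        scores = np.minimum(-np.log(probs), STAR_SCORE)
    mu, lam = gumbel if gumbel is not None else (None, None)
    return ProfileHMM(
        name=name or f"synth-K{K}-s{seed}",
        match_scores=scores,
        gumbel_mu=mu,
        gumbel_lambda=lam,
    )


def generate_targets(
    count: int, length: int, seed: int, prefix: str = "target"
) -> list[tuple[str, str]]:
    """i.i.d. uniform A/C/G/T sequences, deterministic under the seed."""
    if count < 1 or length < 1:
        raise ValueError("count and length must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(count):
        codes = rng.integers(0, 4, size=length)
        records.append((f"{prefix}{i + 1}", "".join(LETTER_OF[c] for c in codes)))
    return records


def plant_segment(
    targets: Sequence[tuple[str, str]],
    model: ProfileHMM,
    seq_index: int,
    seq_start: int,
    model_start: int,
    length: int,
    strength: float,
    seed: int,
    model_index: int = 0,
) -> tuple[list[tuple[str, str]], TruthEntry]:
    """Overwrite a diagonal run of target residues with model-favored letters.

    Per planted position the model's argmax-probability letter is written
    with probability ``strength``, otherwise a uniform random letter. The
    returned truth entry records the exact unrounded bit score of the planted
    diagonal (sum of 2 - s*log2(e) over the written letters).
    """
    if not 0 < strength <= 1:
        raise ValueError("strength must lie in (0, 1]")
    name, residues = targets[seq_index]
    if seq_start < 0 or seq_start + length > len(residues):
        raise ValueError("planted segment exceeds the target sequence")
    if model_start < 0 or model_start + length > model.K:
        raise ValueError("planted segment exceeds the model")
    rng = np.random.default_rng(seed)
    letters = list(residues)
    score_bits = 0.0
    for k in range(length):
        j = model_start + k
        if rng.random() < strength:
            code = int(np.argmin(model.match_scores[j]))
        else:
            code = int(rng.integers(0, 4))
        letters[seq_start + k] = LETTER_OF[code]
        score_bits += 2.0 - model.match_scores[j, code] * LOG2E
    out = list(targets)
    out[seq_index] = (name, "".join(letters))
    entry = TruthEntry(
        seq_index=seq_index,
        seq_start=seq_start,
        model_index=model_index,
        model_start=model_start,
        length=length,
        score_bits=score_bits,
    )
    return out, entry


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Tab-separated ground-truth sidecar."""
    with open(path, "w") as out:
        out.write("# seeds: " + ",".join(str(s) for s in truth.seeds) + "\n")
        out.write("seq_index\tseq_start\tmodel_index\tmodel_start\tlength\tscore_bits\n")
        for e in truth.planted:
            out.write(
                f"{e.seq_index}\t{e.seq_start}\t{e.model_index}\t{e.model_start}"
                f"\t{e.length}\t{e.score_bits:.10g}\n"
            )


def read_truth(path: str | Path) -> SyntheticTruth:
    truth = SyntheticTruth()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if line.startswith("# seeds:"):
                seeds = line.split(":", 1)[1].strip()
                truth.seeds = [int(s) for s in seeds.split(",") if s]
                continue
            if not line or line.startswith(("#", "seq_index")):
                continue
            f = line.split("\t")
            truth.planted.append(
                TruthEntry(int(f[0]), int(f[1]), int(f[2]), int(f[3]), int(f[4]), float(f[5]))
            )
    return truth


def argmax_letter(model: ProfileHMM, j: int) -> str:
    """The model's most probable letter at position j (lowest neg-log score)."""
    return LETTER_OF[int(np.argmin(model.match_scores[j]))]
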