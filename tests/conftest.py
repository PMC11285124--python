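import numpy as np
import pytest

from ssvfilter.phmm_io import ProfileHMM
from ssvfilter.sequence_io import EncodedSequence, build_sequence_db


@pytest.fixture
def uniform_model():
    """Single-position model with background (ln 4) emissions everywhere."""
    return ProfileHMM("uniform", np.full((1, 4), np.log(4.0)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240729)


def make_certain_model(letters, name="certain"):
    """Model whose position j emits letters[j] with probability 1 ('*' elsewhere)."""
    from ssvfilter.phmm_io import STAR_SCORE
    from ssvfilter.sequence_io import CODE_OF

    K = len(letters)
    scores = np.full((K, 4), STAR_SCORE)
    for j, letter in enumerate(letters):
        scores[j, CODE_OF[letter]] = 0.0
    return ProfileHMM(name, scores)


def make_db(code_vectors, n, seed=0, names=None):
    seqs = [
        EncodedSequence(name=(names[i] if names else f"s{i + 1}"), codes=np.asarray(c, dtype=np.uint8))
        for i, c in enumerate(code_vectors)
    ]
    return build_sequence_db(seqs, n, seed)


def straddle_fixture(first_half, second_half, tau=8.0, word=None):
    """Two sequences with a planted run crossing their boundary.

    The model emits a fixed 24-letter word with probability 1; the first
    ``first_half`` model positions are planted at the end of sequence A and
    the next ``second_half`` at the start of sequence B. At tau=8 each
    matched position contributes exactly +16. The default word is aperiodic
    so no off-diagonal can accumulate a long match run.
    """
    from ssvfilter.phmm_io import build_model_db
    from ssvfilter.projection import reproject_scores
    from ssvfilter.sequence_io import CODE_OF

    word = word or "AACGTGCTAGGCATTCAGCTTGAC"
    model = make_certain_model(word, name="word")
    proj = reproject_scores(model, tau=tau)
    a = "T" * (30 - first_half) + word[:first_half]
    b = word[first_half : first_half + second_half] + "T" * (30 - second_half)
    to_codes = lambda text: np.array([CODE_OF[c] for c in text], dtype=np.uint8)
    sdb = make_db([to_codes(a), to_codes(b)], n=4, names=["A", "B"])
    mdb = build_model_db([model])
    return sdb, mdb, proj


def brute_force_max_segment(codes, scores):
    """Exhaustive enumeration of every diagonal segment sum (independent oracle)."""
    L = len(codes)
    K = scores.shape[0]
    best = -np.inf
    for i0 in range(L):
        for j0 in range(K):
            total = 0.0
            for k in range(min(L - i0, K - j0)):
                total += scores[j0 + k, codes[i0 + k]]
                best = max(best, total)
    return best
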