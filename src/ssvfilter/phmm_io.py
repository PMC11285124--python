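"""Read and write nucleotide profile HMMs in the HMMER3 ASCII format.

Only the pieces of the format that the ungapped filter needs are retained:
model name/accession, model length, per-position match-state emission scores
(negative natural-log likelihoods) and the Gumbel statistics lines. Insert
emissions and state transitions are parsed past and discarded — the ungapped
model uses neither.

No maintained Python library reads the HMMER3 text dialect in this
environment, so the parser is written here against the published format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"

#: Negative-log score substituted for the "*" (impossible emission) sentinel.
#: Large enough that any projected 8-bit score saturates at the int8 minimum.
STAR_SCORE = 999.0

_UNIFORM = math.log(4.0)


class HMMFormatError(ValueError):
    """Raised when a .hmm file violates the HMMER3 text dialect."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class ProfileHMM:
    """One nucleotide profile HMM.

    ``match_scores`` is a (K, 4) array of negative natural-log emission
    likelihoods in alphabet order A, C, G, T. ``gumbel_mu``/``gumbel_lambda``
    hold the location/scale of the score distribution's Gumbel fit when known.
    """

    name: str
    match_scores: np.ndarray
    accession: str | None = None
    gumbel_mu: float | None = None
    gumbel_lambda: float | None = None

    def __post_init__(self) -> None:
        self.match_scores = np.asarray(self.match_scores, dtype=float)
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != 4:
            raise ValueError("match_scores must be a (K, 4) matrix")
        if self.match_scores.shape[0] < 1:
            raise ValueError("model length K must be >= 1")
        if np.any(self.match_scores < -1e-9):
            raise ValueError("negative-log emission scores must be >= 0")
        if self.gumbel_lambda is not None and self.gumbel_lambda <= 0:
            raise ValueError("gumbel_lambda must be > 0")

    @property
    def K(self) -> int:
        return self.match_scores.shape[0]

    @property
    def has_stats(self) -> bool:
        return self.gumbel_mu is not None and self.gumbel_lambda is not None


@dataclass
class ModelDB:
    """Ordered model collection with global match-position offsets."""

    models: list[ProfileHMM]
    offsets: np.ndarray = field(init=False)
    total_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ModelDB requires at least one model")
        lengths = [m.K for m in self.models]
        self.offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int64)
        self.total_length = int(sum(lengths))

    def locate(self, model_pos: int) -> tuple[int, int]:
        """Map a global model position to (model index, local 0-based position)."""
        if not 0 <= model_pos < self.total_length:
            raise IndexError(f"model position {model_pos} outside [0, {self.total_length})")
        idx = int(np.searchsorted(self.offsets, model_pos, side="right")) - 1
        return idx, model_pos - int(self.offsets[idx])


def build_model_db(models: Sequence[ProfileHMM]) -> ModelDB:
    """Concatenate models into the global model coordinate space."""
    return ModelDB(models=list(models))


def _parse_score(token: str) -> float:
    if token == "*":
        return STAR_SCORE
    return float(token)


def _format_score(value: float) -> str:
    if value >= STAR_SCORE:
        return f"{'*':>8}"
    return f"{value:8.5f}"


def read_hmm_file(path: str | Path, stats_line: str = "MSV") -> list[ProfileHMM]:
    """Parse every model record of a HMMER3 ASCII .hmm file.

    Parameters
    ----------
    path:
        File in the HMMER3 text dialect, DNA or RNA alphabet.
    stats_line:
        Which ``STATS LOCAL`` line supplies the Gumbel parameters
        (``"MSV"`` or ``"VITERBI"``). The filter's threshold statistics are
        taken from this line when present.
    """
    path = Path(path)
    with open(path) as handle:
        lines = handle.read().splitlines()

    models: list[ProfileHMM] = []
    pos = 0
    n_lines = len(lines)

    while pos < n_lines:
        # skip blank lines between records
        while pos < n_lines and not lines[pos].strip():
            pos += 1
        if pos >= n_lines:
            break

        header = lines[pos]
        if not header.startswith("HMMER3"):
            raise HMMFormatError(f"expected HMMER3 header, got {header!r}", pos + 1)
        pos += 1

        name: str | None = None
        accession: str | None = None
        leng: int | None = None
        alph: str | None = None
        gumbel: tuple[float, float] | None = None

        # key/value block up to the HMM column header
        while pos < n_lines:
            line = lines[pos]
            if line.startswith("HMM "):
                break
            fields = line.split()
            if not fields:
                pos += 1
                continue
            key = fields[0]
            if key == "NAME":
                name = fields[1] if len(fields) > 1 else ""
            elif key == "ACC":
                accession = fields[1] if len(fields) > 1 else None
            elif key == "LENG":
                try:
                    leng = int(fields[1])
                except (IndexError, ValueError):
                    raise HMMFormatError("malformed LENG line", pos + 1) from None
            elif key == "ALPH":
                alph = fields[1].upper() if len(fields) > 1 else ""
            elif key == "STATS":
                if len(fields) != 5 or fields[1] != "LOCAL":
                    raise HMMFormatError("malformed STATS line", pos + 1)
                if fields[2] == stats_line.upper():
                    gumbel = (float(fields[3]), float(fields[4]))
            pos += 1

        if pos >= n_lines:
            raise HMMFormatError("truncated record: no HMM line", n_lines)
        if name is None:
            raise HMMFormatError("record missing NAME", pos + 1)
        if leng is None:
            raise HMMFormatError(f"record {name!r} missing LENG", pos + 1)
        if alph not in ("DNA", "RNA"):
            raise HMMFormatError(
                f"record {name!r} has non-nucleotide alphabet {alph!r}", pos + 1
            )

        pos += 1  # HMM symbol header
        if pos < n_lines and "m->m" in lines[pos]:
            pos += 1  # transition header
        if pos < n_lines and lines[pos].split()[:1] == ["COMPO"]:
            pos += 1
        # node-0 insert emission and transition lines
        pos += 2
        if pos > n_lines:
            raise HMMFormatError(f"record {name!r} truncated before node 1", n_lines)

        scores = np.empty((leng, 4), dtype=float)
        for node in range(1, leng + 1):
            if pos >= n_lines:
                raise HMMFormatError(f"record {name!r} truncated at node {node}", n_lines)
            fields = lines[pos].split()
            if fields and fields[0] == "//":
                raise HMMFormatError(
                    f"record {name!r}: LENG {leng} but only {node - 1} match rows", pos + 1
                )
            if len(fields) < 5:
                raise HMMFormatError(f"malformed match emission line", pos + 1)
            try:
                got_node = int(fields[0])
            except ValueError:
                raise HMMFormatError(
                    f"expected node number, got {fields[0]!r}", pos + 1
                ) from None
            if got_node != node:
                raise HMMFormatError(
                    f"record {name!r}: expected node {node}, got {got_node}", pos + 1
                )
            try:
                scores[node - 1] = [_parse_score(tok) for tok in fields[1:5]]
            except ValueError:
                raise HMMFormatError("unparseable emission score", pos + 1) from None
            pos += 3  # skip insert emission and transition lines

        # terminator
        while pos < n_lines and not lines[pos].strip():
            pos += 1
        if pos >= n_lines or lines[pos].strip() != "//":
            raise HMMFormatError(f"record {name!r} missing '//' terminator", pos + 1)
        pos += 1

        mu, lam = gumbel if gumbel is not None else (None, None)
        models.append(
            ProfileHMM(
                name=name,
                match_scores=scores,
                accession=accession,
                gumbel_mu=mu,
                gumbel_lambda=lam,
            )
        )

    if not models:
        raise HMMFormatError("no model records found")
    return models


def write_hmm_file(models: Iterable[ProfileHMM], path: str | Path) -> None:
    """Write models as a minimal HMMER3/f dialect readable by read_hmm_file."""
    models = list(models)
    if not models:
        raise ValueError("cannot write an empty model list")
    uniform = f"{_UNIFORM:8.5f}"
    with open(path, "w") as out:
        for model in models:
            out.write("HMMER3/f [ssvfilter | minimal nucleotide dialect]\n")
            out.write(f"NAME  {model.name}\n")
            if model.accession:
                out.write(f"ACC   {model.accession}\n")
            out.write(f"LENG  {model.K}\n")
            out.write("ALPH  DNA\n")
            if model.has_stats:
                out.write(
                    f"STATS LOCAL MSV  {model.gumbel_mu:10.5f}  {model.gumbel_lambda:8.5f}\n"
                )
            out.write(f"HMM     {'        '.join(ALPHABET)}\n")
            out.write("            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n")
            out.write(f"  COMPO  {uniform} {uniform} {uniform} {uniform}\n")
            out.write(f"         {uniform} {uniform} {uniform} {uniform}\n")
            out.write("          0.00000  0.00000        *        *        *        *        *\n")
            for node in range(1, model.K + 1):
                row = " ".join(_format_score(s) for s in model.match_scores[node - 1])
                out.write(f"{node:7d}  {row} {node:7d} x - - -\n")
                out.write(f"         {uniform} {uniform} {uniform} {uniform}\n")
                out.write("          0.00000  0.00000        *        *        *        *        *\n")
            out.write("//\n")
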