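"""Resolve global DP hits to per-record coordinates and validate boundaries.

The all-to-all search concatenates sequences and models, so a raw hit's
accumulation may have drifted across a record boundary or started in the
random tail padding. Padding hits are dropped during resolution. Boundary
artifacts are removed by recomputing, per candidate, the single diagonal
through the hit cell restricted to its own (sequence, model) pair: the
recurrence along one diagonal is self-contained, so this restriction is
exactly the isolated-pair computation. Hits are kept at the restricted
diagonal's own crossing cells; a candidate whose diagonal no longer crosses
the threshold anywhere is a boundary artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence, Set

import numpy as np

from .phmm_io import ModelDB
from .sequence_io import SequenceDB
from .ssv_core import HIT_THRESHOLD, GlobalHit

VALIDATED = "validated"
PADDING_REJECTED = "padding_rejected"
BOUNDARY_REJECTED = "boundary_rejected"


@dataclass(frozen=True, order=True)
class ResolvedHit:
    """A hit in 1-based per-record coordinates (the threshold-crossing cell)."""

    seq_name: str
    seq_pos: int
    model_name: str
    model_pos: int
    status: str | None = None

    # record indices kept for validation lookups
    seq_index: int = 0
    model_index: int = 0


def resolve_hits(
    hits: Iterable[GlobalHit], sdb: SequenceDB, mdb: ModelDB
) -> list[ResolvedHit]:
    """Map global (i, j) hit cells to per-record 1-based coordinates.

    Hits landing in the random tail padding (global position >=
    ``padding_start``) are dropped. Output is deduplicated and sorted by
    (seq_name, seq_pos, model_name, model_pos).
    """
    resolved: set[ResolvedHit] = set()
    for hit in hits:
        if not 0 <= hit.seq_pos < sdb.padded_length:
            raise IndexError(f"hit sequence position {hit.seq_pos} outside padded space")
        if hit.seq_pos >= sdb.padding_start:
            continue  # padding artifact
        si, local_i = sdb.locate(hit.seq_pos)
        mi, local_j = mdb.locate(hit.model_pos)
        resolved.add(
            ResolvedHit(
                seq_name=sdb.sequences[si].name,
                seq_pos=local_i + 1,
                model_name=mdb.models[mi].name,
                model_pos=local_j + 1,
                seq_index=si,
                model_index=mi,
            )
        )
    return sorted(resolved)


def _diagonal_crossings(
    codes: np.ndarray, scores8: np.ndarray, i0: int, j0: int
) -> list[tuple[int, int]]:
    """Threshold crossings of the reset recurrence along one pair diagonal.

    The diagonal starts at local cell (i0, j0) — the first cell of that
    diagonal inside the pair rectangle — with a zero accumulator.
    """
    L = codes.size
    K = scores8.shape[0]
    crossings = []
    m = 0
    i, j = i0, j0
    while i < L and j < K:
        t = m + int(scores8[j, codes[i]])
        if t >= HIT_THRESHOLD:
            crossings.append((i, j))
            m = 0
        elif t < 0:
            m = 0
        else:
            m = t
        i += 1
        j += 1
    return crossings


def validate_hits(
    candidates: Sequence[ResolvedHit],
    sdb: SequenceDB,
    mdb: ModelDB,
    scores8_by_model: Sequence[np.ndarray],
    report_rejected: bool = False,
) -> list[ResolvedHit]:
    """Re-run each candidate's diagonal restricted to its own record pair.

    Every validated hit's restricted accumulation reaches the threshold at
    its reported cell. Candidates whose crossing only existed thanks to
    score carried over a record boundary are removed (returned flagged
    ``boundary_rejected`` when ``report_rejected`` is set); crossings that
    survive restriction are reported at the restricted diagonal's cells.
    """
    validated: set[ResolvedHit] = set()
    rejected: set[ResolvedHit] = set()
    seen_diagonals: dict[tuple[int, int, int], list[tuple[int, int]]] = {}
    for cand in candidates:
        li, lj = cand.seq_pos - 1, cand.model_pos - 1
        diag = li - lj
        key = (cand.seq_index, cand.model_index, diag)
        if key not in seen_diagonals:
            codes = sdb.sequences[cand.seq_index].codes
            scores8 = scores8_by_model[cand.model_index]
            i0, j0 = (diag, 0) if diag >= 0 else (0, -diag)
            seen_diagonals[key] = _diagonal_crossings(codes, scores8, i0, j0)
        crossings = seen_diagonals[key]
        if crossings:
            for ci, cj in crossings:
                validated.add(
                    replace(cand, seq_pos=ci + 1, model_pos=cj + 1, status=VALIDATED)
                )
        else:
            rejected.add(replace(cand, status=BOUNDARY_REJECTED))
    out = sorted(validated)
    if report_rejected:
        out += sorted(rejected)
    return out


def write_hits_tsv(hits: Sequence[ResolvedHit], path: str | Path) -> None:
    """Tab-separated hit table: seq_name, seq_pos, model_name, model_pos, status."""
    with open(path, "w") as out:
        out.write("seq_name\tseq_pos\tmodel_name\tmodel_pos\tstatus\n")
        for h in hits:
            status = h.status or ""
            out.write(f"{h.seq_name}\t{h.seq_pos}\t{h.model_name}\t{h.model_pos}\t{status}\n")


def write_hits_bed(hits: Sequence[ResolvedHit], path: str | Path, strand: str = "+") -> None:
    """BED6 rendering: one 0-based half-open single-base interval per hit cell."""
    with open(path, "w") as out:
        for h in hits:
            if h.status not in (None, VALIDATED):
                continue
            start = h.seq_pos - 1
            out.write(f"{h.seq_name}\t{start}\t{start + 1}\t{h.model_name}\t0\t{strand}\n")
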