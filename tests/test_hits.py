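import numpy as np
import pytest

from ssvfilter.hits import (
    BOUNDARY_REJECTED,
    VALIDATED,
    ResolvedHit,
    resolve_hits,
    validate_hits,
    write_hits_bed,
    write_hits_tsv,
)
from ssvfilter.phmm_io import build_model_db
from ssvfilter.projection import reproject_scores
from ssvfilter.sequence_io import CODE_OF, encode_2bit
from ssvfilter.ssv_core import GlobalHit, ssv_hits_rowmajor
from ssvfilter.synthetic import generate_model

from conftest import make_certain_model, make_db


def letters_to_codes(text):
    return np.array([CODE_OF[c] for c in text], dtype=np.uint8)


class TestResolveHits:
    def test_origin_mapping(self):
        sdb = make_db([[0, 1, 2, 3]], n=4, names=["seq"])
        mdb = build_model_db([generate_model(4, 1.0, seed=0, name="mod")])
        (hit,) = resolve_hits({GlobalHit(0, 0)}, sdb, mdb)
        assert (hit.seq_name, hit.seq_pos, hit.model_name, hit.model_pos) == (
            "seq", 1, "mod", 1,
        )

    def test_padding_hits_dropped(self):
        sdb = make_db([[0, 1, 2]], n=4)  # padding starts at global 3
        mdb = build_model_db([generate_model(2, 1.0, seed=0)])
        assert resolve_hits({GlobalHit(3, 0)}, sdb, mdb) == []

    def test_outside_padded_space_raises(self):
        sdb = make_db([[0, 1, 2]], n=4)
        mdb = build_model_db([generate_model(2, 1.0, seed=0)])
        with pytest.raises(IndexError):
            resolve_hits({GlobalHit(4, 0)}, sdb, mdb)

    def test_random_hits_match_linear_scan(self, rng):
        seq_lengths = [int(x) for x in rng.integers(5, 40, size=10)]
        model_lengths = [int(x) for x in rng.integers(3, 25, size=5)]
        sdb = make_db(
            [rng.integers(0, 4, size=k) for k in seq_lengths], n=16, seed=1
        )
        mdb = build_model_db(
            [generate_model(k, 1.0, seed=i, name=f"m{i}") for i, k in enumerate(model_lengths)]
        )
        hits = {
            GlobalHit(
                int(rng.integers(0, sum(seq_lengths))),
                int(rng.integers(0, sum(model_lengths))),
            )
            for _ in range(100)
        }
        resolved = resolve_hits(hits, sdb, mdb)

        # independent linear-scan oracle
        def scan(offsets, lengths, pos):
            for idx in range(len(lengths)):
                if offsets[idx] <= pos < offsets[idx] + lengths[idx]:
                    return idx, pos - offsets[idx]
            raise AssertionError

        expected = set()
        seq_off = [int(x) for x in sdb.offsets]
        mod_off = [int(x) for x in mdb.offsets]
        for h in hits:
            si, li = scan(seq_off, seq_lengths, h.seq_pos)
            mi, lj = scan(mod_off, model_lengths, h.model_pos)
            expected.add((sdb.sequences[si].name, li + 1, mdb.models[mi].name, lj + 1))
        assert {
            (h.seq_name, h.seq_pos, h.model_name, h.model_pos) for h in resolved
        } == expected

    def test_sorted_and_deduplicated(self):
        sdb = make_db([[0, 1], [2, 3]], n=2, names=["b", "a"])
        mdb = build_model_db([generate_model(2, 1.0, seed=0)])
        resolved = resolve_hits(
            [GlobalHit(0, 0), GlobalHit(0, 0), GlobalHit(2, 1)], sdb, mdb
        )
        assert len(resolved) == 2
        assert [h.seq_name for h in resolved] == ["a", "b"]


from conftest import straddle_fixture


class TestValidateHits:
    def test_in_pair_hit_retained(self):
        # whole accumulation inside one (sequence, model) pair
        sdb, mdb, proj = straddle_fixture(first_half=0, second_half=16)
        raw = ssv_hits_rowmajor(sdb.concatenated, proj.scores8)
        assert raw
        candidates = resolve_hits(raw, sdb, mdb)
        validated = validate_hits(candidates, sdb, mdb, [proj.scores8])
        assert validated and all(h.status == VALIDATED for h in validated)
        assert {h.seq_name for h in validated} == {"B"}

    def test_boundary_straddler_rejected(self):
        # 12 + 12 matched positions: each half sums to 192 < 256, the
        # combined run crosses only thanks to the boundary
        sdb, mdb, proj = straddle_fixture(first_half=12, second_half=12)
        raw = ssv_hits_rowmajor(sdb.concatenated, proj.scores8)
        candidates = resolve_hits(raw, sdb, mdb)
        assert candidates  # the artifact hit exists before validation
        validated = validate_hits(candidates, sdb, mdb, [proj.scores8])
        assert validated == []
        flagged = validate_hits(
            candidates, sdb, mdb, [proj.scores8], report_rejected=True
        )
        assert flagged and all(h.status == BOUNDARY_REJECTED for h in flagged)

    def test_strong_second_half_retained_at_in_pair_coordinates(self):
        # the second half alone reaches 16 x 16 = 256: kept, reported at the
        # restricted diagonal's own crossing cell
        sdb, mdb, proj = straddle_fixture(first_half=6, second_half=16)
        raw = ssv_hits_rowmajor(sdb.concatenated, proj.scores8)
        candidates = resolve_hits(raw, sdb, mdb)
        validated = validate_hits(candidates, sdb, mdb, [proj.scores8])
        assert len(validated) == 1
        (hit,) = validated
        assert hit.seq_name == "B" and hit.status == VALIDATED
        # B row 15 (1-based 16) pairs with model position 6+16 (1-based 22)
        assert (hit.seq_pos, hit.model_pos) == (16, 22)

    def test_completeness_no_in_pair_hit_lost(self, rng):
        # union of isolated per-pair searches == validated concatenated output
        for trial in range(15):
            seqs = [rng.integers(0, 4, size=int(rng.integers(10, 50))) for _ in range(3)]
            models = [generate_model(int(rng.integers(3, 20)), 0.2, seed=100 + trial * 3 + k)
                      for k in range(2)]
            projs = [reproject_scores(m, tau=float(rng.uniform(4, 40))) for m in models]
            sdb = make_db(seqs, n=8, seed=trial)
            mdb = build_model_db(models)
            scores8 = np.vstack([p.scores8 for p in projs])
            raw = ssv_hits_rowmajor(sdb.concatenated, scores8)
            validated = validate_hits(
                resolve_hits(raw, sdb, mdb), sdb, mdb, [p.scores8 for p in projs]
            )
            got = {(h.seq_name, h.seq_pos, h.model_name, h.model_pos) for h in validated}
            expected = set()
            for si, codes in enumerate(seqs):
                for mi, p in enumerate(projs):
                    for hit in ssv_hits_rowmajor(codes, p.scores8):
                        expected.add(
                            (sdb.sequences[si].name, hit.seq_pos + 1,
                             models[mi].name, hit.model_pos + 1)
                        )
            assert expected <= got

    def test_soundness_reassertable(self, rng):
        # every validated hit re-reaches the threshold along its restricted diagonal
        from ssvfilter.hits import _diagonal_crossings

        sdb, mdb, proj = straddle_fixture(first_half=6, second_half=16)
        raw = ssv_hits_rowmajor(sdb.concatenated, proj.scores8)
        validated = validate_hits(resolve_hits(raw, sdb, mdb), sdb, mdb, [proj.scores8])
        for h in validated:
            li, lj = h.seq_pos - 1, h.model_pos - 1
            d = li - lj
            i0, j0 = (d, 0) if d >= 0 else (0, -d)
            crossings = _diagonal_crossings(
                sdb.sequences[h.seq_index].codes, proj.scores8, i0, j0
            )
            assert (li, lj) in crossings


class TestOutputFormats:
    def test_tsv(self, tmp_path):
        hits = [ResolvedHit("s1", 10, "m1", 3, VALIDATED)]
        path = tmp_path / "hits.tsv"
        write_hits_tsv(hits, path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["seq_name", "seq_pos", "model_name", "model_pos", "status"]
        assert lines[1].split("\t") == ["s1", "10", "m1", "3", "validated"]

    def test_bed_single_base_half_open(self, tmp_path):
        hits = [ResolvedHit("s1", 10, "m1", 3, VALIDATED)]
        path = tmp_path / "hits.bed"
        write_hits_bed(hits, path)
        assert path.read_text() == "s1\t9\t10\tm1\t0\t+\n"
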