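import numpy as np
import pytest

from hydbeta import (
    GAP,
    PairwiseAlignment,
    PositionMap,
    ProteinRecord,
    SubstitutionScheme,
    build_position_map,
    global_align,
    map_query,
    residues_at,
)
from hydbeta.synth import make_reference_scaffold, plant_sequence

from oracles import brute_force_align_score

AA = "ACDEFGHIKLMNPQRSTVWY"


def rec(seq, name="q"):
    return ProteinRecord(id=name, residues=seq)


class TestGlobalAlign:
    def test_identical_sequences_gapless(self, blosum):
        aln = global_align(rec("MKVH", "a"), rec("MKVH", "b"), blosum)
        assert aln.a_aligned == aln.b_aligned == "MKVH"
        assert aln.identity == 1.0

    def test_linear_gap_example(self, linear_scheme):
        # MKV vs MV: match +1, mismatch -1, gap -2 -> one internal gap, score 0
        aln = global_align(rec("MKV"), rec("MV"), linear_scheme)
        assert aln.score == 0
        assert aln.a_aligned == "MKV"
        assert aln.b_aligned == "M-V"

    def test_scores_match_brute_force(self, blosum):
        rng = np.random.default_rng(42)
        for _ in range(40):
            a = "".join(rng.choice(list(AA), size=rng.integers(1, 9)))
            b = "".join(rng.choice(list(AA), size=rng.integers(1, 9)))
            got = global_align(rec(a, "a"), rec(b, "b"), blosum).score
            assert got == brute_force_align_score(a, b, blosum), (a, b)

    def test_alignment_invariants(self, blosum):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=rng.integers(3, 40)))
            b = "".join(rng.choice(list(AA), size=rng.integers(3, 40)))
            aln = global_align(rec(a, "a"), rec(b, "b"), blosum)
            assert aln.a_ungapped == a
            assert aln.b_ungapped == b  # degapping recovers inputs

    def test_deterministic(self, blosum):
        a, b = rec("MKVHEEAL", "a"), rec("MKEAL", "b")
        alns = {(global_align(a, b, blosum).a_aligned, global_align(a, b, blosum).b_aligned)
                for _ in range(3)}
        assert len(alns) == 1

    def test_rejects_empty(self, blosum):
        with pytest.raises(ValueError):
            ProteinRecord(id="a", residues="")


class TestScheme:
    def test_symmetry_enforced(self):
        m = np.zeros((2, 2), dtype=int)
        m[0, 1] = 5
        with pytest.raises(ValueError):
            SubstitutionScheme(name="bad", alphabet="AB", matrix=m, gap_open=-2, gap_extend=-1)

    def test_gap_ordering_enforced(self):
        with pytest.raises(ValueError):
            SubstitutionScheme.simple(gap_open=-1, gap_extend=-2)

    def test_ncbi_file_round_trip(self, tmp_path, blosum):
        # write BLOSUM62 in NCBI format and read it back
        from Bio.Align import substitution_matrices
        mat = substitution_matrices.load("BLOSUM62")
        p = tmp_path / "blosum62.txt"
        p.write_text(str(mat))
        scheme = SubstitutionScheme.from_ncbi_file(p)
        assert scheme.score("W", "C") == blosum.score("W", "C")


class TestPositionMap:
    def test_identity_map(self, blosum):
        aln = global_align(rec("MKVH", "a"), rec("MKVH", "b"), blosum)
        pmap = build_position_map(aln)
        assert pmap.pairs == ((1, 1), (2, 2), (3, 3), (4, 4))

    def test_insertion_relative_to_reference(self):
        # reference MKV aligned M-KV against query MAKV
        aln = PairwiseAlignment(a_aligned="M-KV", b_aligned="MAKV", score=0)
        pmap = build_position_map(aln, reference_is_a=True)
        assert pmap.pairs == ((1, 1), (2, 3), (3, 4))

    def test_deletion_maps_to_none(self):
        aln = PairwiseAlignment(a_aligned="MKV", b_aligned="M-V", score=0)
        pmap = build_position_map(aln)
        assert pmap.pairs == ((1, 1), (2, None), (3, 2))

    def test_monotone_injective_always(self, blosum):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), size=rng.integers(5, 60)))
            b = "".join(rng.choice(list(AA), size=rng.integers(5, 60)))
            aln = global_align(rec(a, "a"), rec(b, "b"), blosum)
            pmap = build_position_map(aln)  # constructor asserts monotone/injective
            qs = [q for _, q in pmap.pairs if q is not None]
            assert qs == sorted(set(qs))

    def test_invalid_map_rejected(self):
        with pytest.raises(ValueError):
            PositionMap(ref_id="r", pairs=((1, 2), (2, 1)))
        with pytest.raises(ValueError):
            PositionMap(ref_id="r", pairs=((2, 1),))


class TestResiduesAt:
    def test_simple_read_off(self, blosum):
        aln = global_align(rec("MKV", "a"), rec("MKV", "b"), blosum)
        pmap = build_position_map(aln)
        assert residues_at(rec("MKV"), pmap, [2]) == ["K"]

    def test_gap_read_off(self):
        aln = PairwiseAlignment(a_aligned="MKV", b_aligned="M-V", score=0)
        pmap = build_position_map(aln)
        assert residues_at(rec("MV"), pmap, [2]) == [GAP]

    def test_out_of_range(self):
        pmap = PositionMap(ref_id="r", pairs=((1, 1), (2, 2)))
        with pytest.raises(IndexError):
            pmap.query_position(3)

    def test_recovers_planted_residues(self, scaffold, blosum):
        """Fingerprint read-off is exact on planted sequences at identity >= 0.6."""
        positions = [232, 234, 367, 427, 428, 429, 430, 431]
        rng = np.random.default_rng(10)
        for _ in range(15):
            cls = "BF" if rng.random() < 0.5 else "nonBF"
            seed = int(rng.integers(2**31))
            q, truth = plant_sequence(scaffold, cls, background_identity=0.65, seed=seed)
            _, pmap = map_query(q, scaffold.record, blosum)
            got = residues_at(q, pmap, positions)
            assert got == [truth.planted_residues[p] for p in positions]

    def test_invariant_under_terminal_extension(self, scaffold, blosum):
        """Unrelated N-/C-terminal padding does not disturb the read-off."""
        rng = np.random.default_rng(20)
        q, truth = plant_sequence(scaffold, "BF", background_identity=0.8, seed=77)
        pad_n = "".join(rng.choice(list(AA), size=50))
        pad_c = "".join(rng.choice(list(AA), size=35))
        padded = ProteinRecord(id="padded", residues=pad_n + q.residues + pad_c)
        positions = [232, 234, 367, 427, 428, 429, 430, 431]
        _, pmap = map_query(padded, scaffold.record, blosum)
        assert residues_at(padded, pmap, positions) == [
            truth.planted_residues[p] for p in positions
        ]
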