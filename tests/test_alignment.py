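"""Progressive family alignment against a brute-force affine-gap oracle."""

import math

import numpy as np
import pytest

import rcmap as rc
from rcmap.alignment import MASKED, align_pair
from rcmap.scoring import GAP_CHARS


def brute_force_score(a, b, matrix, gap_open=10.0, gap_extend=0.5):
    """Exhaustive optimum over all global alignments; a gap run of length g
    costs open + (g - 1) * extend.  Independent of the DP implementation."""
    best = -math.inf

    def rec(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix.score(a[i], b[j]), "M")
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if last == "D" else gap_open), "D")
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if last == "I" else gap_open), "I")

    rec(0, 0, 0.0, None)
    return best


def alignment_score(aligned_a, aligned_b, matrix, gap_open=10.0, gap_extend=0.5):
    """Score an explicit alignment under the same model."""
    score, last = 0.0, None
    for x, y in zip(aligned_a, aligned_b):
        if x in GAP_CHARS:
            score -= gap_extend if last == "I" else gap_open
            last = "I"
        elif y in GAP_CHARS:
            score -= gap_extend if last == "D" else gap_open
            last = "D"
        else:
            score += matrix.score(x, y)
            last = "M"
    return score


class TestPairwise:
    def test_matches_bruteforce_on_short_strings(self, blosum62):
        cases = [("LRRLRR", "LRR"), ("LRR", "LRRLRR"), ("WCW", "WW"),
                 ("ACDEF", "ACEF"), ("LLLL", "KKKK")]
        rng = np.random.default_rng(7)
        aa20 = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            la, lb = rng.integers(2, 7, size=2)
            cases.append((
                "".join(rng.choice(list(aa20), la)),
                "".join(rng.choice(list(aa20), lb)),
            ))
        for a, b in cases:
            ra, rb, score = align_pair(a, b, blosum62)
            assert score == pytest.approx(brute_force_score(a, b, blosum62))
            # the reported alignment realizes the reported score
            assert alignment_score(ra, rb, blosum62) == pytest.approx(score)
            assert ra.replace("-", "") == a and rb.replace("-", "") == b

    def test_identical_pair_gapless(self, blosum62):
        ra, rb, _ = align_pair("LRRLRRLRR", "LRRLRRLRR", blosum62)
        assert ra == rb == "LRRLRRLRR"

    def test_empty_sequence_errors(self, blosum62):
        with pytest.raises(ValueError):
            align_pair("", "LRR", blosum62)


class TestAlignFamily:
    def test_identical_sequences_gapless(self, blosum62):
        seq = "LRRLRRLRRLRR"
        aln = rc.align_family([("a", seq), ("b", seq), ("c", seq)], matrix=blosum62)
        assert all(s == seq for _, s in aln.records)

    def test_residue_conservation_roundtrip(self, lrr24, blosum62):
        records = [(f"s{i}", rc.perfect_repeat_sequence(lrr24, 4, seed=i))
                   for i in range(4)]
        aln = rc.align_family(records, matrix=blosum62)
        for rid, seq in records:
            assert aln.ungapped(rid) == seq

    def test_order_invariance(self, lrr24, blosum62):
        spec = rc.FamilySpec(n_repeats=5, n_sequences=4, motif=lrr24,
                             background_mutation_rate=0.4, seed=3)
        records, _ = rc.generate_family(spec)
        base = rc.align_family(records, reference_id="member_1", matrix=blosum62)
        for perm in ([2, 0, 3, 1], [3, 2, 1, 0]):
            shuffled = [records[i] for i in perm]
            other = rc.align_family(shuffled, reference_id="member_1",
                                    matrix=blosum62)
            assert dict(base.records) == dict(other.records)

    def test_too_few_sequences(self, blosum62):
        with pytest.raises(ValueError):
            rc.align_family([("a", "LRR")], matrix=blosum62)

    def test_merged_pair_beats_manual_alignments(self, blosum62):
        # DP score dominates every manually proposed alignment (spot check)
        a, b = "LKRWC", "LRWC"
        _, _, score = align_pair(a, b, blosum62)
        manual = [("LKRWC", "L-RWC"), ("LKRWC", "LR-WC"), ("LKRWC", "LRW-C"),
                  ("LKRWC", "LRWC-"), ("LKRWC-", "-LRWC-")]
        for ma, mb in manual:
            if len(ma) != len(mb):
                continue
            assert alignment_score(ma, mb, blosum62) <= score + 1e-9


class TestLoadAlignment:
    def test_accepts_equal_lengths(self):
        aln = rc.load_alignment([("a", "LR-R"), ("b", "LRRR")])
        assert aln.length == 4
        assert aln.reference_id == "a"

    def test_ragged_lists_offenders(self):
        with pytest.raises(ValueError, match="b"):
            rc.load_alignment([("a", "LRR"), ("b", "LRRL")])

    def test_clustal_and_fasta_routes_agree(self, tmp_path):
        recs = [("a", "LRRL-RR"), ("b", "LRRLWRR")]
        aln_path = tmp_path / "fam.aln"
        body = "\n".join(f"{rid:<10}{seq}" for rid, seq in recs)
        aln_path.write_text(f"CLUSTAL W (1.0) multiple sequence alignment\n\n{body}\n")
        from rcmap.io import read_clustal

        assert rc.load_alignment(read_clustal(aln_path)).records == \
            rc.load_alignment(recs).records


class TestCellColumnMap:
    def test_gapless_identity(self, lrr24):
        seq = rc.perfect_repeat_sequence(lrr24, 3, seed=4)
        ann = rc.detect_repeats(seq, lrr24)
        aln = rc.load_alignment([("query", seq), ("other", seq)], "query")
        cm = rc.map_cells_to_columns(ann, aln)
        for r, rep in enumerate(ann.repeats):
            for pos, idx in rep.cells.items():
                assert cm[r, pos - 1] == idx

    def test_reference_gap_shifts_columns(self, lrr24):
        seq = rc.perfect_repeat_sequence(lrr24, 2, seed=4)
        ann = rc.detect_repeats(seq, lrr24)
        p = 30
        gapped = seq[:p] + "-" + seq[p:]
        other = seq[:p] + "W" + seq[p:]
        aln = rc.load_alignment([("query", gapped), ("other", other)], "query")
        cm = rc.map_cells_to_columns(ann, aln)
        for r, rep in enumerate(ann.repeats):
            for pos, idx in rep.cells.items():
                expect = idx if idx < p else idx + 1
                assert cm[r, pos - 1] == expect

    def test_hole_cells_masked_and_injective(self, lrr24):
        seq = rc.perfect_repeat_sequence(lrr24, 3, seed=2)
        mutated = seq[:28] + seq[29:]  # deletion -> HOLE in repeat 2
        ann = rc.detect_repeats(mutated, lrr24)
        aln = rc.load_alignment([("query", mutated), ("other", mutated)], "query")
        cm = rc.map_cells_to_columns(ann, aln)
        holes = [(r, pos) for r, rep in enumerate(ann.repeats)
                 for pos, idx in rep.cells.items() if idx is None]
        assert holes
        for r, pos in holes:
            assert cm[r, pos - 1] == MASKED
        mapped = cm[cm != MASKED]
        assert len(mapped) == len(np.unique(mapped))
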