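"""Protospacer search: scorer, seeding, strand symmetry, dedup."""

import random

import pytest

from crisprpam.search import (
    ProtospacerHit,
    SearchUsageError,
    align_spacer,
    classify_source,
    find_protospacers,
    write_bed,
)
from crisprpam.seqio import CrisprLocus, SequenceRecord, revcomp

from _oracles import semiglobal_oracle, sliding_window_hits


def _locus(spacers, locus_id="L1"):
    return CrisprLocus(
        locus_id=locus_id,
        species="synthetic",
        repeat="G" * 30,
        spacers=tuple(spacers),
    )


def _rand_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestAlignSpacer:
    def test_identical_spacer_and_window(self):
        aln = align_spacer("ACGTACGTACGT", "ACGTACGTACGT")
        assert aln.identity == 1.0 and aln.gaps == 0
        assert (aln.window_start, aln.window_end) == (0, 12)

    def test_identity_at_the_retention_threshold(self):
        spacer = "ACGTACGTACGTACGTACGT"  # 20 nt
        two_mm = "TCGTACGTACGTACGTACGA"
        three_mm = "TCGTACGTACCTACGTACGA"
        assert align_spacer(spacer, two_mm).identity == pytest.approx(0.90)
        assert align_spacer(spacer, three_mm).identity == pytest.approx(0.85)

    def test_spacer_longer_than_window_is_usage_error(self):
        with pytest.raises(SearchUsageError):
            align_spacer("ACGTACGT", "ACGT")

    @pytest.mark.parametrize("case", range(40))
    def test_matches_exhaustive_jump_dp(self, case):
        rng = random.Random(1000 + case)
        m = rng.randint(6, 12)
        n = rng.randint(m, 30)
        spacer = _rand_dna(rng, m)
        if rng.random() < 0.5:
            # embed a mutated copy so non-trivial optima occur
            copy = list(spacer)
            for _ in range(rng.randint(0, 2)):
                i = rng.randrange(m)
                copy[i] = rng.choice("ACGT")
            ins = rng.randrange(max(1, n - m))
            window = _rand_dna(rng, ins) + "".join(copy) + _rand_dna(rng, n - m - ins)
        else:
            window = _rand_dna(rng, n)
        aln = align_spacer(spacer, window)
        score, matches, neg_gaps = semiglobal_oracle(spacer, window)
        assert (aln.score, aln.matches, -aln.gaps) == (score, matches, neg_gaps)


class TestFindProtospacers:
    def test_planted_exact_match(self):
        rng = random.Random(7)
        spacer = _rand_dna(rng, 30)
        genome = _rand_dna(rng, 100) + spacer + _rand_dna(rng, 100)
        target = SequenceRecord("t1", genome)
        hits = find_protospacers([_locus([("sp1", spacer)])], [target])
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.identity) == (100, 130, "+", 1.0)
        assert h.protospacer_seq == spacer

    def test_reverse_complement_symmetry(self):
        rng = random.Random(8)
        spacers = [("sp1", _rand_dna(rng, 25)), ("sp2", _rand_dna(rng, 30))]
        genome = _rand_dna(rng, 300) + spacers[0][1] + _rand_dna(rng, 50) + revcomp(spacers[1][1]) + _rand_dna(rng, 100)
        loci = [_locus(spacers)]
        fwd = find_protospacers(loci, [SequenceRecord("t1", genome)])
        rev = find_protospacers(loci, [SequenceRecord("t1", revcomp(genome))])
        L = len(genome)
        mirrored = sorted(
            (h.spacer_id, L - h.end, L - h.start, "-" if h.strand == "+" else "+", h.matches)
            for h in fwd
        )
        observed = sorted((h.spacer_id, h.start, h.end, h.strand, h.matches) for h in rev)
        assert mirrored == observed
        assert sorted(h.protospacer_seq for h in fwd) == sorted(h.protospacer_seq for h in rev)

    @pytest.mark.parametrize("case", range(20))
    def test_equals_sliding_window_scan(self, case):
        rng = random.Random(3000 + case)
        L = rng.randint(15, 20)
        spacer = _rand_dna(rng, L)
        pieces = [_rand_dna(rng, rng.randint(40, 80))]
        for _ in range(rng.randint(1, 3)):
            copy = list(spacer)
            for _ in range(rng.randint(0, 3)):
                copy[rng.randrange(L)] = rng.choice("ACGT")
            s = "".join(copy)
            if rng.random() < 0.5:
                s = revcomp(s)
            pieces.append(s)
            pieces.append(_rand_dna(rng, rng.randint(40, 80)))
        genome = "".join(pieces)
        target = SequenceRecord("t1", genome)
        loci = [_locus([("sp1", spacer)])]
        hits = find_protospacers(loci, [target], min_identity=0.9)

        expected = set()
        for strand, query in (("+", spacer), ("-", revcomp(spacer))):
            for start, end, score, matches, gaps in sliding_window_hits(query, genome, 0.9, 2):
                expected.add((start, end, strand, score, matches, gaps))
        # every reported hit appears in the exhaustive scan
        for h in hits:
            assert (h.start, h.end, h.strand, h.score, h.matches, h.gaps) in expected
        # and every non-overlapping exhaustive hit is covered by a reported span
        for start, end, strand, score, matches, gaps in expected:
            assert any(h.start < end and start < h.end for h in hits)

    def test_filter_soundness_and_determinism(self):
        rng = random.Random(11)
        spacer = _rand_dna(rng, 24)
        genome = _rand_dna(rng, 800) + spacer + _rand_dna(rng, 100)
        loci = [_locus([("sp1", spacer)])]
        targets = [SequenceRecord("t1", genome)]
        hits1 = find_protospacers(loci, targets, min_identity=0.85)
        hits2 = find_protospacers(loci, targets, min_identity=0.85)
        assert hits1 == hits2
        assert all(h.identity >= 0.85 for h in hits1)
        assert hits1 == sorted(hits1, key=lambda h: (h.target_id, h.start))

    def test_mask_excludes_array_self_matches(self):
        rng = random.Random(12)
        spacer = _rand_dna(rng, 30)
        genome = _rand_dna(rng, 50) + spacer + _rand_dna(rng, 50)
        target = SequenceRecord("t1", genome)
        loci = [_locus([("sp1", spacer)])]
        assert len(find_protospacers(loci, [target])) == 1
        assert find_protospacers(loci, [target], mask=[("t1", 40, 90)]) == []

    def test_empty_spacer_set_is_usage_error(self):
        with pytest.raises(SearchUsageError):
            find_protospacers([], [SequenceRecord("t1", "ACGT")])

    def test_empty_target_set_returns_empty(self):
        assert find_protospacers([_locus([("sp1", "ACGTACGTACGTACGTACGT")])], []) == []


class TestClassifyAndExport:
    def _hit(self, **kw):
        defaults = dict(
            spacer_id="sp1", locus_id="L1", target_id="t1", start=0, end=20,
            strand="+", identity=1.0, matches=20, gaps=0, score=20,
            protospacer_seq="A" * 20,
        )
        defaults.update(kw)
        return ProtospacerHit(**defaults)

    def test_declared_class_is_applied(self):
        assert classify_source(self._hit(), {"t1": "phage"}).source_class == "phage"

    def test_undeclared_target_is_unknown(self):
        assert classify_source(self._hit(), {}).source_class == "unknown"

    def test_bed_output_format(self, tmp_path):
        p = tmp_path / "hits.bed"
        write_bed([self._hit(identity=0.95)], p)
        assert p.read_text() == "t1\t0\t20\tsp1\t950\t+\n"
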