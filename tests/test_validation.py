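"""Splice-motif checking, junction-evidence lookup and the retention rule."""

import numpy as np
import pytest

from isocurate import (
    GenomeSequence,
    InvariantError,
    Junction,
    build_junction_db,
    check_splice_motifs,
    extract_junctions,
    validate_alignment,
    validate_all,
)
from conftest import make_alignment


def motif_oracle(bases: str, start: int, end: int, strand: str):
    """Independent brute-force motif check by direct text slicing.

    The minus-strand pattern is derived here from first principles: the
    reverse complement of the transcript-oriented intron GT...AG.
    """
    from Bio.Seq import Seq

    if start < 0 or end > len(bases):
        return False, strand
    donor_rc = str(Seq("GT").reverse_complement())  # AC
    acceptor_rc = str(Seq("AG").reverse_complement())  # CT
    plus = bases[start : start + 2] == "GT" and bases[end - 2 : end] == "AG"
    minus = bases[start : start + 2] == acceptor_rc and bases[end - 2 : end] == donor_rc
    if strand == "+":
        return plus, "+"
    if strand == "-":
        return minus, "-"
    if plus and minus:
        return True, "."
    if plus:
        return True, "+"
    if minus:
        return True, "-"
    return False, "."


class TestExtractJunctions:
    def test_one_junction_per_consecutive_exon_pair(self):
        aln = make_alignment([(100, 200), (300, 400), (500, 600)])
        assert [(j.start, j.end) for j in extract_junctions(aln)] == [(200, 300), (400, 500)]

    def test_single_exon_yields_no_junctions(self):
        assert extract_junctions(make_alignment([(100, 600)])) == []

    def test_touching_exons_violate_the_intron_gap_invariant(self):
        with pytest.raises(Exception, match="intron"):
            make_alignment([(100, 200), (200, 300)])

    def test_tiny_intron_has_no_room_for_both_dinucleotides(self):
        aln = make_alignment([(100, 200), (203, 300)])
        with pytest.raises(InvariantError, match="shorter"):
            extract_junctions(aln)


def _genome_with_intron(donor="GT", acceptor="AG", start=200, end=300, length=500):
    bases = list("A" * length)
    bases[start : start + 2] = donor
    bases[end - 2 : end] = acceptor
    return GenomeSequence("chr1", "".join(bases))


class TestCheckSpliceMotifs:
    def test_canonical_plus_strand_intron(self):
        g = _genome_with_intron()
        ok, strand = check_splice_motifs(Junction("chr1", "+", 200, 300), g)
        assert ok and strand == "+"

    def test_non_canonical_donor_fails(self):
        g = _genome_with_intron(donor="GC")
        ok, _ = check_splice_motifs(Junction("chr1", "+", 200, 300), g)
        assert not ok

    def test_minus_strand_inferred_from_reverse_complement_motif(self):
        g = _genome_with_intron(donor="CT", acceptor="AC")
        ok, strand = check_splice_motifs(Junction("chr1", ".", 200, 300), g)
        assert ok and strand == "-"

    def test_known_strand_only_tests_that_orientation(self):
        g = _genome_with_intron(donor="CT", acceptor="AC")  # minus-strand text
        ok, _ = check_splice_motifs(Junction("chr1", "+", 200, 300), g)
        assert not ok

    def test_plus_strand_inferred_when_strand_unknown(self):
        g = _genome_with_intron()
        ok, strand = check_splice_motifs(Junction("chr1", ".", 200, 300), g)
        assert ok and strand == "+"

    def test_out_of_bounds_junction_is_motif_invalid(self, caplog):
        g = _genome_with_intron(length=250)
        with caplog.at_level("WARNING"):
            ok, _ = check_splice_motifs(Junction("chr1", "+", 200, 300), g)
        assert not ok
        assert "bounds" in caplog.text

    def test_agrees_with_brute_force_oracle_on_random_junctions(self):
        """1,000 random junctions on a 100 kb random genome."""
        rng = np.random.default_rng(42)
        bases = "".join(rng.choice(list("ACGT"), size=100_000))
        g = GenomeSequence("chr1", bases)
        for _ in range(1000):
            start = int(rng.integers(0, g.length - 200))
            end = start + int(rng.integers(4, 200))
            strand = rng.choice(["+", "-", "."])
            j = Junction("chr1", strand, start, end)
            assert check_splice_motifs(j, g) == motif_oracle(bases, start, end, strand)


class TestJunctionDB:
    def test_aggregation_then_threshold(self):
        j = Junction("chr1", "+", 200, 400)
        db = build_junction_db([(j, 3), (j, 4)], min_support=5)
        assert db.supports(j) and db.count(j) == 7

    def test_below_threshold_dropped(self):
        j = Junction("chr1", "+", 200, 400)
        db = build_junction_db([(j, 2)], min_support=5)
        assert not db.supports(j)

    def test_empty_input_fails_every_lookup(self):
        db = build_junction_db([])
        assert len(db) == 0
        assert not db.supports(Junction("chr1", "+", 200, 400))

    def test_lookup_is_strand_agnostic_by_default(self):
        db = build_junction_db([(Junction("chr1", "+", 200, 400), 5)])
        assert db.supports(Junction("chr1", "-", 200, 400))
        strict = build_junction_db([(Junction("chr1", "+", 200, 400), 5)], strand_aware=True)
        assert not strict.supports(Junction("chr1", "-", 200, 400))


class TestValidateAlignment:
    def _setup(self):
        bases = list("A" * 700)
        for s, e in [(200, 300), (400, 500)]:
            bases[s : s + 2] = "GT"
            bases[e - 2 : e] = "AG"
        genome = GenomeSequence("chr1", "".join(bases))
        aln = make_alignment([(100, 200), (300, 400), (500, 600)])
        junctions = [Junction("chr1", "+", 200, 300), Junction("chr1", "+", 400, 500)]
        return genome, aln, junctions

    def test_all_junctions_passing_retains_the_read(self):
        genome, aln, junctions = self._setup()
        db = build_junction_db([(j, 10) for j in junctions])
        assert validate_alignment(aln, genome, db).retained

    def test_one_junction_missing_from_evidence_drops_the_read(self):
        genome, aln, junctions = self._setup()
        db = build_junction_db([(junctions[0], 10)])
        res = validate_alignment(aln, genome, db)
        assert not res.retained and res.n_evidence_fail == 1 and res.n_motif_fail == 0

    def test_single_exon_reads_are_never_retained(self):
        genome, _, junctions = self._setup()
        db = build_junction_db([(j, 10) for j in junctions])
        assert not validate_alignment(make_alignment([(100, 600)]), genome, db).retained


class TestOnSimulatedData:
    def test_error_free_simulation_retains_every_multi_exon_read(self, clean_dataset):
        ds = clean_dataset
        db = build_junction_db(ds.junction_records)
        results, retained = validate_all(ds.reads, ds.genome.chromosomes, db)
        multi = [r for r in ds.reads if r.n_exons >= 2]
        assert len(retained) == len(multi) == len(ds.reads)

    def test_raising_min_support_never_adds_retained_reads(self, default_dataset):
        """Monotonicity of the evidence threshold."""
        ds = default_dataset
        previous = None
        for min_support in (1, 10, 30, 60):
            db = build_junction_db(ds.junction_records, min_support=min_support)
            _, retained = validate_all(ds.reads, ds.genome.chromosomes, db)
            ids = {r.id for r in retained}
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_donor_shifted_reads_fail_validation(self):
        from isocurate import SimulationConfig, simulate

        ds = simulate(SimulationConfig(seed=5, p_donor_shift=0.15))
        db = build_junction_db(ds.junction_records)
        _, retained = validate_all(ds.reads, ds.genome.chromosomes, db)
        shifted = {r.read_id for r in ds.truth.reads if r.shifted_junctions}
        assert shifted, "expected some shifted reads at p=0.15"
        assert not shifted & {r.id for r in retained}

    def test_strand_inference_recovers_true_strand_of_minus_genes(self, clean_dataset):
        """Unstranded input reads get their strand back from the motifs."""
        from dataclasses import replace

        ds = clean_dataset
        db = build_junction_db(ds.junction_records)
        strand_of_iso = {iso.id: iso.strand for iso in ds.genome.isoforms}
        unstranded = [replace(r, strand=".") for r in ds.reads if r.n_exons >= 2]
        results, retained = validate_all(unstranded, ds.genome.chromosomes, db)
        truth = {rec.read_id: strand_of_iso[rec.isoform_id] for rec in ds.truth.reads}
        checked = 0
        for res in results:
            if res.inferred_strand != ".":
                assert res.inferred_strand == truth[res.alignment_id]
                checked += 1
        assert checked > len(results) * 0.9  # ambiguity is rare on random sequence
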