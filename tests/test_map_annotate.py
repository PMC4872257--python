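"""Motif scanning, instance tallies, database matching and layout export."""

import io
import math
from collections import Counter

import numpy as np
import pytest

from promotif.map_annotate import (MatchResult, MotifInstance,
                                   consensus_alignment_distance, export_map,
                                   match_database, read_instances_bed,
                                   scan_regions, tally_instances,
                                   write_instances_bed)
from promotif.motifs import (DatabaseMotif, Motif, pwm_from_instances,
                             reverse_complement, reverse_complement_word)
from promotif.synthetic import (make_database_fixture, motif_from_consensus,
                                sample_background_sequences)


@pytest.fixture
def point_motif():
    return pwm_from_instances(["ACGTCA"], pseudocount=0)


def embed(word, length=60, at=20):
    seq = "A" * length
    return seq[:at] + word + seq[at + len(word):]


class TestScanRegions:
    def test_exact_copy_single_plus_instance(self, point_motif,
                                             flat_background,
                                             region_factory):
        region = region_factory(embed("ACGTCA"), gene_id="g1")
        (inst,) = scan_regions(point_motif, [region], flat_background,
                               score_fraction=1.0)
        assert inst.strand == "+"
        assert inst.offset == 20 - 60
        assert inst.matched_word == "ACGTCA"

    def test_revcomp_copy_minus_instance_same_locus(self, point_motif,
                                                    flat_background,
                                                    region_factory):
        region = region_factory(embed(reverse_complement_word("ACGTCA")))
        (inst,) = scan_regions(point_motif, [region], flat_background,
                               score_fraction=1.0)
        assert inst.strand == "-"
        assert inst.offset == 20 - 60
        assert inst.matched_word == "ACGTCA"

    def test_n_windows_skipped(self, point_motif, flat_background,
                               region_factory):
        region = region_factory(embed("ACGNCA"))
        assert scan_regions(point_motif, [region], flat_background,
                            score_fraction=0.5) == []

    def test_matches_naive_oracle(self, flat_background, rng):
        """Instance set equals a per-position, per-strand scoring oracle."""
        motif = Motif(rng.dirichlet(np.ones(4) * 0.3, size=6))
        regions = sample_background_sequences(flat_background, 50, 80,
                                              seed=61)
        got = {(i.gene_id, i.offset, i.strand)
               for i in scan_regions(motif, regions, flat_background,
                                     score_fraction=0.8)}
        lods = np.log2(np.maximum(motif.matrix, 1e-12) / 0.25)
        thresh = 0.8 * lods.max(axis=1).sum()
        expected = set()
        for r in regions:
            for i in range(r.length - 5):
                window = r.sequence[i:i + 6]
                fwd = sum(lods[j, "ACGT".index(b)]
                          for j, b in enumerate(window))
                rev = sum(lods[j, "ACGT".index(b)] for j, b in enumerate(
                    reverse_complement_word(window)))
                if fwd >= thresh - 1e-12:
                    expected.add((r.gene_id, i - r.length, "+"))
                if rev >= thresh - 1e-12:
                    expected.add((r.gene_id, i - r.length, "-"))
        assert got == expected

    def test_threshold_monotonicity(self, flat_background, rng):
        motif = Motif(rng.dirichlet(np.ones(4), size=6))
        regions = sample_background_sequences(flat_background, 20, 100,
                                              seed=62)
        counts = [len(scan_regions(motif, regions, flat_background, f))
                  for f in (0.6, 0.75, 0.9, 1.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_strand_consistency(self, flat_background, rng):
        """Scanning the reverse-complement motif flips strands, keeps loci."""
        motif = Motif(rng.dirichlet(np.ones(4) * 0.3, size=6))
        regions = sample_background_sequences(flat_background, 30, 80,
                                              seed=63)
        a = scan_regions(motif, regions, flat_background, 0.8)
        b = scan_regions(reverse_complement(motif), regions,
                         flat_background, 0.8)
        flip = {"+": "-", "-": "+"}
        assert {(i.gene_id, i.offset, i.strand) for i in a} == \
            {(i.gene_id, i.offset, flip[i.strand]) for i in b}


class TestTally:
    def make_instances(self):
        return [
            MotifInstance("m1", "g1", -10, "+", "ACGTCA", 1.0),
            MotifInstance("m1", "g1", -30, "-", "ACGTCA", 1.0),
            MotifInstance("m1", "g2", -10, "+", "ACGTCA", 1.0),
        ]

    def test_counts_and_totals(self):
        result = tally_instances(self.make_instances(), ["m1", "m2"],
                                 ["g1", "g2", "g3"])
        assert result.table.loc["m1", "g1"] == 2
        assert result.table.loc["m2"].sum() == 0  # zero cells included
        assert result.totals["m1"] == 3
        assert (result.totals == result.table.sum(axis=1)).all()

    def test_empty_instances(self):
        result = tally_instances([], ["m1"], ["g1"])
        assert (result.table.to_numpy() == 0).all()

    def test_random_set_matches_groupby_oracle(self, rng):
        motifs = [f"m{i}" for i in range(4)]
        genes = [f"g{i}" for i in range(6)]
        instances = [MotifInstance(rng.choice(motifs), rng.choice(genes),
                                   -int(rng.integers(6, 50)), "+", "ACGTCA",
                                   0.0) for _ in range(200)]
        result = tally_instances(instances, motifs, genes)
        oracle = Counter(i.motif_id for i in instances)
        for m in motifs:
            assert result.totals[m] == oracle.get(m, 0)

    def test_identical_layouts_flagged(self):
        shared = [("mA", -50, "+"), ("mB", -20, "-")]
        instances = []
        for g in ("g1", "g2"):
            for m, off, s in shared:
                instances.append(MotifInstance(m, g, off, s, "ACGTCA", 0.0))
        instances.append(MotifInstance("mA", "g3", -10, "+", "ACGTCA", 0.0))
        result = tally_instances(instances, ["mA", "mB"],
                                 ["g1", "g2", "g3"])
        assert result.identical_layout_groups == [("g1", "g2")]

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            tally_instances(self.make_instances(), ["m1"], ["g1"])


def brute_force_match(query_consensus, db_consensus, min_overlap=4):
    """All-offsets, both-orientations mismatch oracle using IUPAC sets."""
    from promotif.motifs import iupac_compatible, iupac_reverse_complement
    best = None
    for q in (query_consensus,
              iupac_reverse_complement(query_consensus)):
        lq, ld = len(q), len(db_consensus)
        for off in range(-(lq - min_overlap), ld - min_overlap + 1):
            lo, hi = max(0, off), min(ld, off + lq)
            if hi - lo < min_overlap:
                continue
            mm = sum(not iupac_compatible(q[i - off], db_consensus[i])
                     for i in range(lo, hi))
            if best is None or mm < best:
                best = mm
    return best


class TestMatchDatabase:
    def test_printed_pair_single_mismatch(self):
        query = pwm_from_instances(["TACCAC"], pseudocount=0)
        (hit,) = match_database(query, [DatabaseMotif("S1F", "TACCAT")],
                                top_n=1)
        assert hit.mismatches == 1
        assert hit.best_offset == 0 and hit.orientation == "+"

    def test_identical_entry_rank_one(self):
        query = pwm_from_instances(["ACGTCAGT"], pseudocount=0)
        db = [DatabaseMotif("other", "TTTTTTTT"),
              DatabaseMotif("self", "ACGTCAGT")]
        hits = match_database(query, db)
        assert hits[0].database_id == "self"
        assert hits[0].mismatches == 0 and hits[0].rank == 1

    def test_full_ranking_matches_brute_force(self, rng):
        truths = [motif_from_consensus("".join(rng.choice(list("ACGT"),
                                                          size=7)))
                  for _ in range(3)]
        db, _ = make_database_fixture(truths, n_decoys=47,
                                      mutation_rate=1.0, seed=64)
        query = truths[0]
        hits = match_database(query, db, top_n=50)
        for hit in hits:
            entry = next(e for e in db if e.id == hit.database_id)
            assert hit.mismatches == brute_force_match(query.consensus,
                                                       entry.consensus)
        assert [h.mismatches for h in hits] == sorted(
            h.mismatches for h in hits)

    def test_symmetry_for_plain_words(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=6))
        b = "".join(rng.choice(list("ACGT"), size=6))
        qa = motif_from_consensus(a)
        qb = motif_from_consensus(b)
        (ha,) = match_database(qa, [DatabaseMotif("x", b)], top_n=1)
        (hb,) = match_database(qb, [DatabaseMotif("x", a)], top_n=1)
        assert ha.mismatches == hb.mismatches


class TestConsensusAlignmentDistance:
    @pytest.mark.parametrize("a,b,d", [
        ("TACCAC", "TACCAT", 1),
        ("ACGTCAGT", "ACGTCAGT", 0),
        ("ACGTCAGT", "ACTGACGT", 0),   # reverse complement pair
        ("ACGTCAG", "ACGTCAGT", 1),    # one overhanging position
        ("ACGTCAGT", "ACGTCAGw", 0),   # 'w' covers T
    ])
    def test_examples(self, a, b, d):
        assert consensus_alignment_distance(a, b) == d


class TestExport:
    def test_bed_coordinates_and_round_trip(self, region_factory,
                                            tmp_path):
        region = region_factory("A" * 1000, gene_id="g1")
        inst = MotifInstance("m1", "g1", -6, "+", "ACGTCA", 2.5)
        buf = io.StringIO()
        write_instances_bed([inst], [region], buf)
        line = buf.getvalue().strip().split("\t")
        assert (line[1], line[2]) == ("994", "1000")
        buf.seek(0)
        (back,) = read_instances_bed(buf, [region])
        assert back == inst

    def test_export_map_empty_track_present(self, region_factory,
                                            tmp_path):
        regions = [region_factory("A" * 50, gene_id="g1"),
                   region_factory("A" * 50, gene_id="g2")]
        inst = MotifInstance("m1", "g1", -10, "+", "ACGTCA", 1.0)
        layout = export_map([inst], regions, str(tmp_path / "i.bed"),
                            str(tmp_path / "l.json"))
        assert layout["g2"] == []
        assert len(layout["g1"]) == 1
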