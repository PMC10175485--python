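"""Lesion calling: read-to-dipyrimidine assignment, conservation,
strand symmetry, bedGraph round-trips and density profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import uvhotspot as uv
from uvhotspot.genome import ReferenceGenome, revcomp
from uvhotspot.lesions import region_density_profile
from uvhotspot.synthetic import (DamageModelParams, default_cohort,
                                 make_genome, simulate_reads,
                                 variant_cohort_spec, GenomeSpec,
                                 PlantedMotif)
from uvhotspot.tracks import LesionTrack

from conftest import make_reads


def brute_force_call(reads, genome):
    """Independent per-read scanner: locates the candidate dinucleotide
    by the documented offset convention with plain python string ops."""
    track = {}
    retained = dropped = off = 0
    for _, r in reads.iterrows():
        seq = genome[r["chrom"]]
        if r["strand"] == "+":
            left, lesion_strand = r["start"] - 2, "-"
        else:
            left, lesion_strand = r["end"], "+"
        if left < 0 or left + 1 >= len(seq):
            off += 1
            continue
        b0, b1 = seq[left], seq[left + 1]
        if lesion_strand == "+":
            dinuc = b0 + b1
        else:
            dinuc = revcomp(b0 + b1)
        if dinuc[0] in "CT" and dinuc[1] in "CT":
            retained += 1
            for p in (left, left + 1):
                key = (r["chrom"], lesion_strand, p)
                track[key] = track.get(key, 0) + 1
        else:
            dropped += 1
    return track, retained, dropped, off


def track_to_dict(track: LesionTrack):
    out = {}
    for name in track.index.names:
        arr = track.contig(name)
        for si, strand in enumerate("+-"):
            for p in np.flatnonzero(arr[si]):
                out[(name, strand, int(p))] = arr[si, p]
    return out


class TestConvention:
    GENOME = ReferenceGenome({"c": "AAGGAACC"})

    def test_plus_read_assigns_minus_strand_dipyrimidine(self):
        reads = make_reads([("c", 4, 6, "+")])
        track = uv.call_lesions(reads, self.GENOME)
        assert track.total_dipyrimidine_reads == 1
        assert track.contig("c")[1, 2] == 1 and track.contig("c")[1, 3] == 1

    def test_minus_read_assigns_plus_strand_dipyrimidine(self):
        reads = make_reads([("c", 3, 6, "-")])  # rightmost aligned = 5
        track = uv.call_lesions(reads, self.GENOME)
        assert track.contig("c")[0, 6] == 1 and track.contig("c")[0, 7] == 1

    def test_purine_candidate_dropped(self):
        g = ReferenceGenome({"c": "AATTCGGA"})
        reads = make_reads([("c", 4, 6, "+")])  # candidate -strand (2,3)=A,A
        track = uv.call_lesions(reads, g)
        assert track.total_dipyrimidine_reads == 0
        assert track.dropped_reads == 1
        assert track.total() == 0

    def test_unknown_contig_and_bad_strand_error(self):
        with pytest.raises(KeyError, match="nope"):
            uv.call_lesions(make_reads([("nope", 4, 6, "+")]), self.GENOME)
        with pytest.raises(ValueError, match="strand"):
            uv.call_lesions(make_reads([("c", 4, 6, "*")]), self.GENOME)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_oracle_equivalence_and_conservation(seed):
    """On small genomes the vectorised caller matches a brute-force
    per-read scanner exactly, and retained+dropped+off == input."""
    rng = np.random.default_rng(seed)
    length = int(rng.integers(20, 200))
    seq = "".join(rng.choice(list("ACGT"), size=length))
    genome = ReferenceGenome({"c1": seq, "c2": seq[::-1]})
    n = int(rng.integers(1, 60))
    rows = []
    for _ in range(n):
        contig = rng.choice(["c1", "c2"])
        s = int(rng.integers(0, length - 1))
        e = int(rng.integers(s + 1, min(length, s + 31) + 1))
        rows.append((contig, s, min(e, length),
                     rng.choice(["+", "-"])))
    reads = make_reads(rows)
    track = uv.call_lesions(reads, genome)
    ref, retained, dropped, off = brute_force_call(reads, genome)
    assert track_to_dict(track) == ref
    assert track.total_dipyrimidine_reads == retained
    assert (track.total_dipyrimidine_reads + track.dropped_reads
            + track.off_contig_reads) == len(reads)
    assert track.total() == 2 * retained


def test_strand_mirror_symmetry(rng):
    """Calling on the reverse-complemented genome with strand-flipped,
    coordinate-mirrored reads yields the mirrored track exactly."""
    length = 120
    seq = "".join(rng.choice(list("ACGT"), size=length))
    g_fwd = ReferenceGenome({"c": seq})
    g_rev = ReferenceGenome({"c": revcomp(seq)})
    rows, mirrored = [], []
    for _ in range(80):
        s = int(rng.integers(2, length - 5))
        e = s + int(rng.integers(1, 4))
        strand = rng.choice(["+", "-"])
        rows.append(("c", s, e, strand))
        mirrored.append(("c", length - e, length - s,
                         "-" if strand == "+" else "+"))
    t_fwd = uv.call_lesions(make_reads(rows), g_fwd)
    t_rev = uv.call_lesions(make_reads(mirrored), g_rev)
    fwd = t_fwd.contig("c")
    rev = t_rev.contig("c")
    assert np.array_equal(rev[0], fwd[1][::-1])
    assert np.array_equal(rev[1], fwd[0][::-1])


class TestDinucFractions:
    def test_all_tt(self):
        g = ReferenceGenome({"c": "AATTAATTAA"})
        # '-' reads with end=2: candidate (2,3)='TT' on '+'
        reads = make_reads([("c", 0, 2, "-")] * 5)
        frac = uv.dinucleotide_fractions(reads, g)
        assert frac["TT"] == 1.0
        assert sum(frac.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_errors(self):
        g = ReferenceGenome({"c": "ACGT"})
        with pytest.raises(ValueError):
            uv.dinucleotide_fractions(make_reads([]), g)

    def test_no_uv_matches_genomic_dipyrimidine_frequency(self):
        """Background reads point at uniform positions, so the dipy
        fraction approaches the genome's candidate-level frequency
        (exhaustively enumerated)."""
        spec = variant_cohort_spec(n_sites=6, seed=3, region_length=400)
        genome, regions, truth = make_genome(spec)
        params = DamageModelParams(seed=3, background_rate=2.0)
        reads = simulate_reads(genome, truth, params, "no_uv")
        frac = uv.dinucleotide_fractions(reads, genome)

        # exhaustive candidate enumeration: every (strand, position) pair
        dipy = total = 0
        for name in genome:
            seq = genome[name]
            for i in range(len(seq) - 1):
                for strand in "+-":
                    d = seq[i:i + 2] if strand == "+" \
                        else revcomp(seq[i:i + 2])
                    total += 1
                    dipy += d[0] in "CT" and d[1] in "CT"
        expected = dipy / total
        observed = 1 - frac["other"]
        assert observed == pytest.approx(expected, abs=0.02)

    def test_lesion_library_without_background_is_pure_dipy(self):
        spec = variant_cohort_spec(n_sites=4, seed=5, region_length=200)
        genome, regions, truth = make_genome(spec)
        params = DamageModelParams(seed=5, background_rate=0.0,
                                   sequencing_depth=500)
        reads = simulate_reads(genome, truth, params, "cellular")
        frac = uv.dinucleotide_fractions(reads, genome)
        assert frac["other"] == 0.0


class TestTrackIO:
    def test_round_trip_identity(self, rng, tmp_path):
        g = ReferenceGenome({"a": "ACGT" * 30, "b": "TTGGCCAA" * 10})
        track = LesionTrack.zeros(g.index)
        pos = rng.choice(g.index.total, size=40, replace=False)
        track.data[rng.integers(0, 2, 40), pos] = rng.integers(1, 9, 40)
        uv.write_track(track, tmp_path / "t")
        back = uv.read_track(tmp_path / "t", g.index)
        assert np.array_equal(back.data, track.data)

    def test_empty_track_round_trip(self, tmp_path):
        g = ReferenceGenome({"a": "ACGTACGT"})
        track = LesionTrack.zeros(g.index)
        plus, minus = uv.write_track(track, tmp_path / "e")
        assert open(plus).readline().startswith("track")
        back = uv.read_track(tmp_path / "e", g.index)
        assert back.total() == 0

    def test_overlap_and_malformed_errors(self, tmp_path):
        g = ReferenceGenome({"a": "ACGTACGTAC"})
        p = tmp_path / "bad.plus.bedGraph"
        (tmp_path / "bad.minus.bedGraph").write_text("")
        p.write_text("a\t0\t5\t1\na\t3\t6\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            uv.read_track(tmp_path / "bad", g.index)
        p.write_text("a\t0\tfive\t1\n")
        with pytest.raises(ValueError, match=":1"):
            uv.read_track(tmp_path / "bad", g.index)


class TestRegionProfile:
    def test_unit_spike_and_zero(self):
        g = ReferenceGenome({"r": "A" * 101})
        regions = pd.DataFrame([{"chrom": "r", "start": 0, "end": 100,
                                 "name": "r", "score": 0, "strand": "+",
                                 "class": "ETS"}])
        track = LesionTrack.zeros(g.index)
        prof = region_density_profile(track, regions, halfwidth=20)
        assert (prof["ETS"] == 0).all()
        track.data[0, 50] = 3
        prof = region_density_profile(track, regions, halfwidth=20)
        assert prof.loc[0, "ETS"] == 3
        assert prof.drop(index=0)["ETS"].sum() == 0

    def test_ets_class_has_central_peak_coding_does_not(self):
        plants = [PlantedMotif(i, 200, "ETS_variant", True, "+", "TC")
                  for i in range(4)]
        spec = GenomeSpec(n_regions=8, region_length=400,
                          planted_motifs=plants,
                          region_classes=["ETS"] * 4 + ["coding"] * 4,
                          seed=9)
        genome, regions, truth = make_genome(spec)
        params = DamageModelParams(seed=9)
        reads = simulate_reads(genome, truth, params, "cellular")
        track = uv.call_lesions(reads, genome)
        prof = region_density_profile(track, regions, halfwidth=180)
        centre = prof.loc[-10:10]
        flank = pd.concat([prof.loc[-180:-100], prof.loc[100:180]])
        assert centre["ETS"].mean() > 2 * flank["ETS"].mean()
        assert centre["coding"].mean() < 2 * flank["coding"].mean()
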