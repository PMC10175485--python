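"""Lesion calling: aligned read positions -> strand-resolved per-base
putative-CPD counts.

CPD-seq-style libraries sequence away from the lesion: the free 3'-OH
created immediately 5' of the cleaved dimer is ligated to the second
adapter, so the mapped read starts adjacent to the lesion and the
candidate dipyrimidine lies on the strand OPPOSITE the read's mapped
strand, occupying the two genomic positions immediately past the read's
5' end.  For a '+' read with leftmost aligned coordinate p the candidate
is (p-2, p-1) on '-'; for a '-' read with rightmost aligned coordinate q
it is (q+1, q+2) on '+'.  The offset is a module constant so an
alternative convention is a one-line change.

A read is retained iff both candidate bases on the lesion strand are
pyrimidines; each retained read adds one count at each of the two
positions.  Duplicate reads are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import COMP, ReferenceGenome
from .tracks import LesionTrack

#: gap between a read's 5' end and the candidate dipyrimidine (bp)
LESION_OFFSET = 2

#: dinucleotide classes reported by :func:`dinucleotide_fractions`
DINUC_CLASSES = ("TT", "TC", "CT", "CC", "other")

_PYR = np.zeros(5, dtype=bool)
_PYR[[1, 3]] = True  # C, T


def _candidate_positions(reads: pd.DataFrame, genome: ReferenceGenome):
    """Vectorised candidate-dinucleotide location for every read.

    Returns (lesion_strand_row, cand_left_global, valid, contig_slot).
    ``valid`` is False where the candidate falls off-contig.
    """
    idx = genome.index
    chrom = reads["chrom"]
    if isinstance(chrom.dtype, pd.CategoricalDtype):
        cats = chrom.cat.categories
        slot_of_cat = np.array([idx.slot(c) for c in cats], dtype=np.int64)
        slots = slot_of_cat[chrom.cat.codes.to_numpy()]
    else:
        slots = np.array([idx.slot(c) for c in chrom], dtype=np.int64)

    strand = reads["strand"]
    if isinstance(strand.dtype, pd.CategoricalDtype):
        scats = list(strand.cat.categories)
        bad = [c for c in scats if c not in ("+", "-")]
        if bad:
            raise ValueError(f"malformed strand {bad[0]!r}")
        plus_code = np.array([c == "+" for c in scats])
        is_plus = plus_code[strand.cat.codes.to_numpy()]
        is_minus = ~is_plus
    else:
        svals = strand.to_numpy()
        is_plus = svals == "+"
        is_minus = svals == "-"
        if not np.all(is_plus | is_minus):
            bad = svals[~(is_plus | is_minus)][0]
            raise ValueError(f"malformed strand {bad!r}")

    start = reads["start"].to_numpy(dtype=np.int64)
    end = reads["end"].to_numpy(dtype=np.int64)

    # candidate leftmost position (contig-local) and lesion strand
    cand_left = np.where(is_plus, start - LESION_OFFSET, end)
    lesion_row = np.where(is_plus, 1, 0)  # '+' read -> '-' lesion strand

    lengths = idx.lengths[slots]
    valid = (cand_left >= 0) & (cand_left + 1 < lengths)
    gpos = idx.offsets[slots] + np.clip(cand_left, 0, lengths - 2)
    return lesion_row, gpos, valid, slots


def _dinuc_codes(lesion_row, gpos, genome: ReferenceGenome):
    """5'->3' lesion-strand dinucleotide codes (first, second) per read."""
    codes = genome.codes
    b0, b1 = codes[gpos], codes[gpos + 1]
    # on '-' the 5'->3' dinucleotide is comp(right), comp(left)
    first = np.where(lesion_row == 0, b0, COMP[b1])
    second = np.where(lesion_row == 0, b1, COMP[b0])
    return first, second


def call_lesions(reads: pd.DataFrame, genome: ReferenceGenome,
                 sample: str = "", condition: str = "") -> LesionTrack:
    """Convert aligned reads (BED6 table) into a :class:`LesionTrack`.

    Retained + dropped + off-contig always equals the input read count.
    """
    track = LesionTrack.zeros(genome.index, sample=sample,
                              condition=condition)
    track.total_input_reads = len(reads)
    if len(reads) == 0:
        return track

    lesion_row, gpos, valid, _ = _candidate_positions(reads, genome)
    first, second = _dinuc_codes(lesion_row, gpos, genome)
    dipy = _PYR[first] & _PYR[second]
    keep = valid & dipy

    total = genome.index.total
    flat = lesion_row[keep] * total + gpos[keep]
    counts = np.bincount(flat, minlength=2 * total)
    counts += np.bincount(flat + 1, minlength=2 * total)
    track.data += counts.reshape(2, total)

    track.total_dipyrimidine_reads = int(keep.sum())
    track.off_contig_reads = int((~valid).sum())
    track.dropped_reads = int((valid & ~dipy).sum())
    return track


@dataclass
class DinucSummary:
    """Fraction of input reads whose candidate lesion dinucleotide falls in
    each class (5'->3' on the lesion strand)."""

    fractions: dict

    def __getitem__(self, key: str) -> float:
        return self.fractions[key]


def dinucleotide_fractions(reads: pd.DataFrame,
                           genome: ReferenceGenome) -> DinucSummary:
    if len(reads) == 0:
        raise ValueError("empty read set")
    lesion_row, gpos, valid, _ = _candidate_positions(reads, genome)
    first, second = _dinuc_codes(lesion_row, gpos, genome)

    n = len(reads)
    counts = dict.fromkeys(DINUC_CLASSES, 0)
    code_of = {"A": 0, "C": 1, "G": 2, "T": 3}
    for name in DINUC_CLASSES[:4]:
        f, s = code_of[name[0]], code_of[name[1]]
        counts[name] = int((valid & (first == f) & (second == s)).sum())
    counts["other"] = n - sum(counts[k] for k in DINUC_CLASSES[:4])
    return DinucSummary({k: v / n for k, v in counts.items()})


def write_track(track: LesionTrack, prefix) -> tuple[str, str]:
    """bedGraph pair (`.plus.bedGraph`, `.minus.bedGraph`), 0-based
    half-open; ``read_track(write_track(x)) == x`` exactly."""
    return track.write_bedgraph(prefix)


def read_track(prefix, index, **meta) -> LesionTrack:
    return LesionTrack.read_bedgraph(prefix, index, **meta)


def region_density_profile(track: LesionTrack, regions: pd.DataFrame,
                           halfwidth: int = 360) -> pd.DataFrame:
    """Mean strand-summed count per offset from the region centre,
    averaged within each region class.

    Returns a DataFrame indexed by offset (-halfwidth..halfwidth) with one
    column per class.
    """
    offsets = np.arange(-halfwidth, halfwidth + 1)
    out = {}
    idx = track.index
    for cls, sub in regions.groupby("class", observed=True):
        acc = np.zeros(offsets.size)
        for _, r in sub.iterrows():
            slot = idx.slot(r["chrom"])
            centre = (int(r["start"]) + int(r["end"])) // 2
            gpos = idx.offsets[slot] + centre + offsets
            lo, hi = idx.offsets[slot], idx.offsets[slot + 1]
            ok = (gpos >= lo) & (gpos < hi)
            acc[ok] += track.position_sum(gpos[ok])
        out[cls] = acc / len(sub)
    return pd.DataFrame(out, index=pd.Index(offsets, name="offset"))
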