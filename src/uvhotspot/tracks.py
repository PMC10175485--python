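"""Per-base genomic count tracks and bedGraph round-tripping.

`LesionTrack` is strand-resolved (putative-CPD counts); `CoverageTrack`
is unstranded (accessibility densities).  Both store one dense float
array over a shared :class:`~uvhotspot.genome.ContigIndex` — dense is
cheap at capture-panel scale (a few Mbp) and keeps every downstream
window operation a vectorised gather.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ContigIndex

STRANDS = ("+", "-")


def _runs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and run values of maximal constant runs."""
    if values.size == 0:
        return np.empty(0, dtype=np.int64), values
    change = np.flatnonzero(np.diff(values) != 0) + 1
    starts = np.concatenate([[0], change])
    return starts, values[starts]


@dataclass
class LesionTrack:
    """Strand-resolved per-position putative-CPD read counts.

    ``data`` has shape (2, index.total): row 0 = '+' strand, row 1 = '-'.
    Every counted position is one base of a dipyrimidine on its strand,
    and each retained read contributes exactly two position counts.
    """

    index: ContigIndex
    data: np.ndarray
    sample: str = ""
    condition: str = ""
    total_input_reads: int = 0
    total_dipyrimidine_reads: int = 0
    dropped_reads: int = 0
    off_contig_reads: int = 0

    @classmethod
    def zeros(cls, index: ContigIndex, **meta) -> "LesionTrack":
        return cls(index, np.zeros((2, index.total)), **meta)

    def copy(self) -> "LesionTrack":
        out = LesionTrack(self.index, self.data.copy(), self.sample,
                          self.condition, self.total_input_reads,
                          self.total_dipyrimidine_reads, self.dropped_reads,
                          self.off_contig_reads)
        return out

    def scaled(self, factor: float) -> "LesionTrack":
        out = self.copy()
        out.data = self.data * factor
        return out

    def total(self) -> float:
        return float(self.data.sum())

    def total_in(self, regions: pd.DataFrame) -> float:
        """Sum of counts (both strands) inside BED-style regions."""
        tot = 0.0
        for _, r in regions.iterrows():
            i = self.index.slot(r["chrom"])
            lo = self.index.offsets[i] + int(r["start"])
            hi = self.index.offsets[i] + int(r["end"])
            tot += float(self.data[:, lo:hi].sum())
        return tot

    def contig(self, name: str) -> np.ndarray:
        """(2, L) view of one contig."""
        i = self.index.slot(name)
        return self.data[:, self.index.offsets[i] : self.index.offsets[i + 1]]

    def position_sum(self, gpos: np.ndarray) -> np.ndarray:
        """Both-strand count sums at global positions."""
        return self.data[0, gpos] + self.data[1, gpos]

    # bedGraph IO ------------------------------------------------------
    def write_bedgraph(self, prefix) -> tuple[str, str]:
        """One bedGraph per strand: `<prefix>.plus.bedGraph` / `.minus...`."""
        paths = []
        for si, tag in ((0, "plus"), (1, "minus")):
            path = f"{prefix}.{tag}.bedGraph"
            with open(path, "w") as fh:
                fh.write(f"track type=bedGraph name={self.sample or 'track'}"
                         f" strand={STRANDS[si]}\n")
                for ci, name in enumerate(self.index.names):
                    lo, hi = self.index.offsets[ci], self.index.offsets[ci + 1]
                    vals = self.data[si, lo:hi]
                    starts, rv = _runs(vals)
                    ends = np.concatenate([starts[1:], [hi - lo]])
                    nz = rv != 0
                    for s, e, v in zip(starts[nz], ends[nz], rv[nz]):
                        fh.write(f"{name}\t{s}\t{e}\t{v:.10g}\n")
            paths.append(path)
        return tuple(paths)

    @classmethod
    def read_bedgraph(cls, prefix, index: ContigIndex, **meta) -> "LesionTrack":
        track = cls.zeros(index, **meta)
        for si, tag in ((0, "plus"), (1, "minus")):
            _read_bedgraph_into(f"{prefix}.{tag}.bedGraph", index,
                                track.data[si])
        return track


def _read_bedgraph_into(path, index: ContigIndex, row: np.ndarray) -> None:
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: malformed bedGraph line")
            chrom, s, e, v = parts
            try:
                s, e, v = int(s), int(e), float(v)
            except ValueError:
                raise ValueError(f"{path}:{ln}: malformed bedGraph line") \
                    from None
            if e <= s:
                raise ValueError(f"{path}:{ln}: empty or inverted interval")
            if s < last_end.get(chrom, 0):
                raise ValueError(f"{path}:{ln}: overlapping interval")
            last_end[chrom] = e
            off = index.offsets[index.slot(chrom)]
            if e > index.lengths[index.slot(chrom)]:
                raise ValueError(f"{path}:{ln}: interval beyond contig end")
            row[off + s : off + e] = v


@dataclass
class CoverageTrack:
    """Unstranded per-base density (e.g. DNase-seq read density)."""

    index: ContigIndex
    data: np.ndarray
    name: str = ""

    @classmethod
    def zeros(cls, index: ContigIndex, name: str = "") -> "CoverageTrack":
        return cls(index, np.zeros(index.total), name)

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"track type=bedGraph name={self.name or 'coverage'}\n")
            for ci, cname in enumerate(self.index.names):
                lo, hi = self.index.offsets[ci], self.index.offsets[ci + 1]
                vals = self.data[lo:hi]
                starts, rv = _runs(vals)
                ends = np.concatenate([starts[1:], [hi - lo]])
                nz = rv != 0
                for s, e, v in zip(starts[nz], ends[nz], rv[nz]):
                    fh.write(f"{cname}\t{s}\t{e}\t{v:.10g}\n")

    @classmethod
    def read_bedgraph(cls, path, index: ContigIndex, name: str = "") \
            -> "CoverageTrack":
        track = cls.zeros(index, name)
        _read_bedgraph_into(path, index, track.data)
        return track
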