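"""Reference-sequence containers.

Sequences are held as uppercase strings plus cached uint8 code arrays
(A=0, C=1, G=2, T=3, N=4).  All coordinates are 0-based half-open
internally; 1-based coordinates appear only in human-facing TSV reports.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping

import numpy as np

BASES = "ACGTN"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: complement in code space (A<->T, C<->G, N->N)
COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

#: codes of the pyrimidines C and T
PYR_CODES = (1, 3)


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 code array."""
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    return decode(COMP[encode(seq)][::-1])


class ContigIndex:
    """Maps contig names to slots in one concatenated coordinate space."""

    def __init__(self, names: list[str], lengths: list[int]):
        if len(names) != len(set(names)):
            raise ValueError("duplicate contig names")
        self.names = list(names)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        self.total = int(self.offsets[-1])
        self._slot = {n: i for i, n in enumerate(names)}

    def slot(self, name: str) -> int:
        try:
            return self._slot[name]
        except KeyError:
            raise KeyError(f"contig {name!r} absent from genome") from None

    def global_pos(self, name: str, pos: int) -> int:
        return int(self.offsets[self.slot(name)]) + pos

    def __len__(self) -> int:
        return len(self.names)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ContigIndex)
            and self.names == other.names
            and np.array_equal(self.lengths, other.lengths)
        )


class ReferenceGenome(Mapping):
    """Mapping of contig name -> sequence with vectorised helpers."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}
        self.index = ContigIndex(
            list(self._seqs), [len(s) for s in self._seqs.values()]
        )
        self._codes: np.ndarray | None = None

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    # helpers ----------------------------------------------------------
    @property
    def codes(self) -> np.ndarray:
        """Concatenated uint8 codes for all contigs (no separators)."""
        if self._codes is None:
            self._codes = (
                np.concatenate([encode(s) for s in self._seqs.values()])
                if self._seqs
                else np.empty(0, dtype=np.uint8)
            )
        return self._codes

    def contig_codes(self, name: str) -> np.ndarray:
        i = self.index.slot(name)
        return self.codes[self.index.offsets[i] : self.index.offsets[i + 1]]

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), rebuild=True, build_index=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})
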