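"""ETS motif scanning and mutation-site annotation.

The ETS core is GGAA on the purine strand / TTCC on the pyrimidine
strand; we scan the fixed pentamers TTCCG and CTTCC on both strands.
The site midpoint is the first C of the TTCC core on the pyrimidine
strand — this makes the conventional offsets self-consistent: the TC
step sits at -1/0, the CC step at 0/+1, and the variant dipyrimidine at
-4/-3.  A site is *variant* when the pyrimidine-strand bases at -4 and
-3 are both pyrimidines (the class with the strongest damage hotspot).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, revcomp

#: pentamers scanned on the pyrimidine strand
ETS_PENTAMERS = ("TTCCG", "CTTCC")

#: pyrimidine-strand offset of the first C of the TTCC core within each
#: pentamer match
_MID_IN_PENTAMER = {"TTCCG": 2, "CTTCC": 3}

#: mutation offsets counted as overlapping an ETS motif
ETS_OVERLAP_OFFSETS = (-4, -3, 0, 1)

_PYRIMIDINES = frozenset("CT")


def _find_all(seq: str, pattern: str):
    start = seq.find(pattern)
    while start != -1:
        yield start
        start = seq.find(pattern, start + 1)


def scan_ets(sequence: str, contig: str = "", offset: int = 0,
             pentamers=ETS_PENTAMERS) -> pd.DataFrame:
    """Scan a sequence for ETS binding motifs on both strands.

    Returns one row per site: contig, midpoint (0-based, + ``offset``),
    strand (of the pyrimidine strand), pentamer, variant.  Overlapping
    TTCCG/CTTCC matches around one core merge into one site; sites with
    an N anywhere in pyrimidine-strand offsets -4..+2 are dropped (and
    tallied in ``df.attrs['n_dropped']``).
    """
    seq = sequence.upper()
    hits: dict[tuple, set] = {}
    for pat in pentamers:
        k = _MID_IN_PENTAMER.get(pat)
        for i in _find_all(seq, pat):
            hits.setdefault(("+", i + k if k is not None else i), set()) \
                .add(pat)
        rc = revcomp(pat)
        for i in _find_all(seq, rc):
            # pattern read 5'->3' on '-': genomic index of pentamer pos j
            # is i + len-1 - j
            mid = i + len(pat) - 1 - k if k is not None else i
            hits.setdefault(("-", mid), set()).add(pat)

    rows, dropped = [], 0
    for (strand, mid), pats in sorted(hits.items(),
                                      key=lambda kv: (kv[0][1], kv[0][0])):
        ctx = _pyr_strand_window(seq, mid, strand, -4, 2)
        if ctx is None or "N" in ctx:
            dropped += 1
            continue
        variant = ctx[0] in _PYRIMIDINES and ctx[1] in _PYRIMIDINES
        rows.append({
            "contig": contig, "midpoint": mid + offset, "strand": strand,
            "pentamer": "|".join(sorted(pats)), "variant": variant,
        })
    out = pd.DataFrame(rows, columns=["contig", "midpoint", "strand",
                                      "pentamer", "variant"])
    out.attrs["n_dropped"] = dropped
    return out


def _pyr_strand_window(seq: str, mid: int, strand: str, lo: int, hi: int):
    """Pyrimidine-strand bases at offsets lo..hi (inclusive) of a site,
    or None when the window runs off the sequence."""
    if strand == "+":
        a, b = mid + lo, mid + hi + 1
        if a < 0 or b > len(seq):
            return None
        return seq[a:b]
    a, b = mid - hi, mid - lo + 1
    if a < 0 or b > len(seq):
        return None
    return revcomp(seq[a:b])


def scan_genome(genome: ReferenceGenome, pentamers=ETS_PENTAMERS) \
        -> pd.DataFrame:
    """Run :func:`scan_ets` over every contig."""
    frames = [scan_ets(genome[name], contig=name, pentamers=pentamers)
              for name in genome]
    out = pd.concat(frames, ignore_index=True) if frames else scan_ets("")
    out.attrs["n_dropped"] = sum(f.attrs.get("n_dropped", 0) for f in frames)
    return out


def classify_variant(site, genome: ReferenceGenome) -> str | None:
    """``'variant'`` / ``'canonical'``; None (with a warning) when the
    -4/-3 bases are degenerate (N)."""
    contig = site["contig"] if isinstance(site, (dict, pd.Series)) \
        else site.contig
    mid = site["midpoint"] if isinstance(site, (dict, pd.Series)) \
        else site.midpoint
    strand = site["strand"] if isinstance(site, (dict, pd.Series)) \
        else site.strand
    ctx = _pyr_strand_window(genome[contig], mid, strand, -4, -3)
    if ctx is None or "N" in ctx:
        warnings.warn(f"site {contig}:{mid} has degenerate -4/-3 bases; "
                      "excluded from variant classification")
        return None
    return "variant" if set(ctx) <= _PYRIMIDINES else "canonical"


def annotate_mutations(catalog: pd.DataFrame, sites: pd.DataFrame,
                       offsets=ETS_OVERLAP_OFFSETS) -> pd.DataFrame:
    """Flag mutations that overlap an ETS motif at the conventional
    offsets (-4, -3, 0, +1 from the midpoint, pyrimidine-strand
    orientation).

    Adds ``ets_overlap``, ``ets_offset`` and ``ets_variant`` columns;
    idempotent.  When two sites qualify, the nearest midpoint wins
    (ties: '+' pyrimidine strand, then lower midpoint — deterministic).
    """
    lookup: dict[tuple, list] = {}
    for site in sites.itertuples():
        sign = 1 if site.strand == "+" else -1
        for off in offsets:
            key = (site.contig, site.midpoint + sign * off)
            lookup.setdefault(key, []).append(
                (abs(off), site.strand != "+", site.midpoint, off,
                 bool(site.variant)))

    out = catalog.copy()
    ets_overlap = np.zeros(len(out), dtype=bool)
    ets_offset = np.full(len(out), np.nan)
    ets_variant = np.zeros(len(out), dtype=bool)
    for i, m in enumerate(out.itertuples()):
        cands = lookup.get((m.contig, m.position))
        if cands:
            _, _, _, off, var = min(cands)
            ets_overlap[i] = True
            ets_offset[i] = off
            ets_variant[i] = var
    out["ets_overlap"] = ets_overlap
    out["ets_offset"] = ets_offset
    out["ets_variant"] = ets_variant
    return out


def tss_distance(catalog: pd.DataFrame, tss_table: pd.DataFrame) \
        -> pd.DataFrame:
    """Absolute bp distance from each mutation to the annotated TSS of
    its gene; genes missing from the table get NaN and
    ``tss_missing=True``."""
    tss = tss_table.set_index("gene")["position"]
    out = catalog.copy()
    dist = np.full(len(out), np.nan)
    missing = np.zeros(len(out), dtype=bool)
    for i, m in enumerate(out.itertuples()):
        if m.gene in tss.index:
            dist[i] = abs(int(m.position) - int(tss.loc[m.gene]))
        else:
            missing[i] = True
    out["tss_distance"] = dist
    out["tss_missing"] = missing
    return out
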