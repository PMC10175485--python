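"""Damage-induction statistics.

Induction is the per-position difference between the cellular lesion
track and the naked-DNA control after the control has been scaled to
the same number of dipyrimidine-associated reads inside the capture
regions.  By that construction induction sums to zero over the capture
panel, so localised protein-induced hotspots are paid for by a slightly
negative flanking baseline; the flanking mean/SD form the empirical
null used to Z-score within-motif induction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .genome import ReferenceGenome
from .lesions import _candidate_positions, _dinuc_codes, _PYR
from .tracks import LesionTrack


@dataclass
class ScalingInfo:
    scale_factor: float
    cellular_total: float
    naked_total: float


def scale_naked(cellular: LesionTrack, naked: LesionTrack,
                regions: pd.DataFrame):
    """Scale the naked control so its dipyrimidine-read total inside the
    capture regions matches the cellular library's.

    Returns ``(ScalingInfo, scaled_naked_track)``.
    """
    cell_total = cellular.total_in(regions)
    naked_total = naked.total_in(regions)
    if naked_total == 0:
        raise ValueError("naked library has no reads within capture regions")
    if cell_total == 0:
        raise ValueError("cellular library has no reads within capture "
                         "regions")
    factor = cell_total / naked_total
    return ScalingInfo(factor, cell_total, naked_total), naked.scaled(factor)


def _site_offset_positions(site, index, offsets: np.ndarray):
    """Global genomic positions of pyrimidine-strand offsets for a site
    (oriented so the motif reads left-to-right on the pyrimidine strand)."""
    base = index.offsets[index.slot(site.contig)] + site.midpoint
    sign = 1 if site.strand == "+" else -1
    return base + sign * offsets


def site_offset_counts(track: LesionTrack, sites: pd.DataFrame,
                       halfwidth: int = 10) -> np.ndarray:
    """(n_sites, 2*halfwidth+1) matrix of both-strand counts per
    pyrimidine-strand offset."""
    offsets = np.arange(-halfwidth, halfwidth + 1)
    out = np.zeros((len(sites), offsets.size))
    idx = track.index
    for i, site in enumerate(sites.itertuples()):
        gpos = _site_offset_positions(site, idx, offsets)
        lo = idx.offsets[idx.slot(site.contig)]
        hi = lo + idx.lengths[idx.slot(site.contig)]
        ok = (gpos >= lo) & (gpos < hi)
        out[i, ok] = track.position_sum(gpos[ok])
    return out


def motif_profile(cellular: LesionTrack, scaled_naked: LesionTrack | None,
                  sites: pd.DataFrame, halfwidth: int = 10) -> pd.DataFrame:
    """Mean count per pyrimidine-strand offset across sites.

    Columns: ``cellular`` and (when a control is given) ``naked``.
    Canonical and variant sites should be profiled separately by passing
    the corresponding subset of sites.
    """
    if len(sites) == 0:
        raise ValueError("empty site list")
    offsets = pd.Index(np.arange(-halfwidth, halfwidth + 1), name="offset")
    data = {"cellular": site_offset_counts(cellular, sites,
                                           halfwidth).mean(axis=0)}
    if scaled_naked is not None:
        data["naked"] = site_offset_counts(scaled_naked, sites,
                                           halfwidth).mean(axis=0)
    return pd.DataFrame(data, index=offsets)


#: flanking window, bp from the site midpoint (both sides)
FLANK_WINDOW = (6, 180)


def _flank_gpos(site, index, window=FLANK_WINDOW):
    lo_w, hi_w = window
    base = index.offsets[index.slot(site.contig)] + site.midpoint
    clo = index.offsets[index.slot(site.contig)]
    chi = clo + index.lengths[index.slot(site.contig)]
    left = np.arange(base - hi_w, base - lo_w + 1)
    right = np.arange(base + lo_w, base + hi_w + 1)
    g = np.concatenate([left, right])
    return g[(g >= clo) & (g < chi)]


def capture_efficiency_filter(sites: pd.DataFrame, cellular: LesionTrack,
                              window=FLANK_WINDOW,
                              min_per_bp: float = 1.0) -> np.ndarray:
    """Keep mask: mean cellular lesion count per flanking bp >= threshold.

    Sites whose local sequencing yield is too low to measure induction
    ("fewer than one lesion site per base pair in flanking DNA") are
    excluded from per-site analyses.
    """
    keep = np.zeros(len(sites), dtype=bool)
    for i, site in enumerate(sites.itertuples()):
        g = _flank_gpos(site, cellular.index, window)
        if g.size:
            keep[i] = cellular.position_sum(g).sum() / g.size >= min_per_bp
    return keep


#: offsets summed for the cluster-plot ordering key
MATRIX_ORDER_OFFSETS = (-4, -3, -1, 0, 1)


def induction_matrix(cellular: LesionTrack, scaled_naked: LesionTrack,
                     sites: pd.DataFrame, halfwidth: int = 10,
                     apply_filter: bool = True):
    """Per-site x per-offset induction matrix (cluster-plot substrate).

    Rows are the sites passing the capture-efficiency filter, ordered by
    increasing summed within-motif induction.  Returns ``(matrix_df,
    ordered_sites_df)``.
    """
    sites = sites.reset_index(drop=True)
    keep = (capture_efficiency_filter(sites, cellular)
            if apply_filter else np.ones(len(sites), dtype=bool))
    kept = sites[keep].reset_index(drop=True)
    cell = site_offset_counts(cellular, kept, halfwidth)
    naked = site_offset_counts(scaled_naked, kept, halfwidth)
    ind = cell - naked
    offsets = np.arange(-halfwidth, halfwidth + 1)
    cols = np.isin(offsets, MATRIX_ORDER_OFFSETS)
    order = np.argsort(ind[:, cols].sum(axis=1), kind="stable")
    matrix = pd.DataFrame(ind[order], columns=offsets)
    return matrix, kept.iloc[order].reset_index(drop=True)


@dataclass
class FlankNull:
    """Empirical null for damage induction in flanking DNA."""

    mu_flank: float
    sigma_flank: float
    n_positions: int
    window: tuple = FLANK_WINDOW


def flank_null(cellular: LesionTrack, scaled_naked: LesionTrack,
               sites: pd.DataFrame, genome: ReferenceGenome,
               window=FLANK_WINDOW) -> FlankNull:
    """Mean/SD of induction per CPD-forming position in DNA flanking the
    sites (default 6-180 bp from the midpoint, both sides).

    All CPD-forming positions (part of a dipyrimidine on either strand)
    are included; positions shared between sites are counted once.
    """
    idx = cellular.index
    gset = np.unique(np.concatenate(
        [_flank_gpos(s, idx, window) for s in sites.itertuples()]))
    codes = genome.codes
    contig_id = np.repeat(np.arange(len(idx)), idx.lengths)
    pyr = (codes == 1) | (codes == 3)
    same = np.zeros(codes.size, dtype=bool)
    same[:-1] = contig_id[:-1] == contig_id[1:]
    pair_any = np.zeros(codes.size, dtype=bool)       # dipy on either strand
    both = np.zeros(codes.size, dtype=bool)
    both[:-1] = (pyr[:-1] == pyr[1:]) & same[:-1]     # pyr-pyr or pur-pur
    pair_any[:-1] |= both[:-1]
    pair_any[1:] |= both[:-1]
    gset = gset[pair_any[gset]]
    if gset.size < 100:
        raise ValueError("flank null needs >= 100 CPD-forming positions")
    diffs = cellular.position_sum(gset) - scaled_naked.position_sum(gset)
    sigma = float(diffs.std(ddof=0))
    if sigma == 0:
        raise ValueError("flanking induction has zero variance")
    return FlankNull(float(diffs.mean()), sigma, int(gset.size), window)


def zscore(induction, null: FlankNull):
    """Z-score induction values against the flanking null."""
    return (np.asarray(induction, dtype=float) - null.mu_flank) \
        / null.sigma_flank


# --------------------------------------------------------------------------
# Hexamer screen
# --------------------------------------------------------------------------

def _read_hexamers(reads: pd.DataFrame, genome: ReferenceGenome):
    """Hexamer code (base-4 int) per retained read: 2 nt 5' flank +
    lesion dinucleotide + 2 nt 3' flank on the lesion strand; -1 for
    dropped reads or lesions too close to a contig edge."""
    if len(reads) == 0:
        return np.empty(0, dtype=np.int64)
    lesion_row, gpos, valid, _ = _candidate_positions(reads, genome)
    first, second = _dinuc_codes(lesion_row, gpos, genome)
    keep = valid & _PYR[first] & _PYR[second]

    idx = genome.index
    codes = genome.codes
    cid = np.searchsorted(idx.offsets, gpos, side="right") - 1
    local = gpos - idx.offsets[cid]
    inside = (local >= 2) & (local + 4 <= idx.lengths[cid])
    keep &= inside

    g = gpos[keep]
    row = lesion_row[keep]
    hexes = np.stack([codes[g + k] for k in range(-2, 4)], axis=1)
    from .genome import COMP
    rc = COMP[hexes[:, ::-1]]
    hexes = np.where(row[:, None] == 0, hexes, rc)
    if hexes.size and hexes.max() > 3:
        ok = (hexes <= 3).all(axis=1)
        hexes = hexes[ok]
    weights = np.array([4 ** k for k in range(5, -1, -1)])
    return hexes @ weights


def _hexamer_string(code: int) -> str:
    bases = "ACGT"
    return "".join(bases[(code >> (2 * k)) & 3] for k in range(5, -1, -1))


def hexamer_screen(cellular_reads: pd.DataFrame, naked_reads: pd.DataFrame,
                   genome: ReferenceGenome, scale_factor: float | None = None,
                   q_threshold: float = 0.05,
                   lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Per-hexamer cellular vs scaled-naked read totals with enrichment
    calls (de novo screen for damage-modulating binding motifs).

    Each retained read contributes one count, attributed to the hexamer
    centred on its lesion dinucleotide.  Significance: two-sided test of
    the cellular count against the scaled-naked-implied expectation
    (exact binomial for small libraries, normal approximation above
    1e4 reads), Benjamini-Hochberg across hexamers; enriched/depleted
    flags require q < ``q_threshold`` and |log2 ratio| >=
    ``lfc_threshold``.
    """
    hc = _read_hexamers(cellular_reads, genome)
    hn = _read_hexamers(naked_reads, genome)
    cell = np.bincount(hc, minlength=4096).astype(float)
    naked = np.bincount(hn, minlength=4096).astype(float)
    present = (cell + naked) > 0
    if not present.any():
        warnings_msg = "no central-dipyrimidine hexamer occurrences"
        import warnings as _w
        _w.warn(warnings_msg)
        return pd.DataFrame(columns=["hexamer", "cellular", "naked_scaled",
                                     "log2_ratio", "p", "q", "flag"])
    if scale_factor is None:
        scale_factor = cell.sum() / naked.sum() if naked.sum() else 1.0

    codes = np.flatnonzero(present)
    c = cell[codes]
    n_raw = naked[codes]
    ns = n_raw * scale_factor
    with np.errstate(divide="ignore"):
        lfc = np.log2(np.where(ns > 0, c / np.where(ns > 0, ns, 1), np.inf))
    lfc[(c == 0) & (ns == 0)] = 0.0
    lfc[(c == 0) & (ns > 0)] = -np.inf

    total_c = c.sum()
    exp_p = np.where(n_raw.sum() > 0, n_raw / n_raw.sum(), 0.0)
    pvals = np.ones_like(c)
    use_exact = total_c < 1e4
    for i in range(codes.size):
        if exp_p[i] <= 0 or exp_p[i] >= 1:
            pvals[i] = 1.0 if c[i] == exp_p[i] * total_c else 0.0
            continue
        if use_exact:
            pvals[i] = scipy.stats.binomtest(
                int(c[i]), int(total_c), exp_p[i]).pvalue
        else:
            mu = total_c * exp_p[i]
            sd = np.sqrt(total_c * exp_p[i] * (1 - exp_p[i]))
            z = (abs(c[i] - mu) - 0.5) / sd
            pvals[i] = 2 * scipy.stats.norm.sf(max(z, 0.0))
    qvals = scipy.stats.false_discovery_control(pvals)

    flag = np.where(
        (qvals < q_threshold) & (lfc >= lfc_threshold), "enriched",
        np.where((qvals < q_threshold) & (lfc <= -lfc_threshold),
                 "depleted", ""))
    return pd.DataFrame({
        "hexamer": [_hexamer_string(k) for k in codes],
        "cellular": c.astype(int), "naked_scaled": ns,
        "log2_ratio": lfc, "p": pvals, "q": qvals, "flag": flag,
    }).set_index("hexamer")
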