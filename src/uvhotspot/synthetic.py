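"""Synthetic cohorts with the statistical structure of CPD-capture-seq.

The generator emulates a capture panel of ~720 bp regions, each with an
optionally planted transcription-factor motif.  UV lesion counts are
Poisson at every dipyrimidine with dinucleotide-class base rates;
protein binding multiplies the rate of specific motif-internal
dipyrimidine steps in the *cellular* library only, and only at bound
sites.  A matched naked-DNA library shares the sequence and capture
efficiencies but never sees induction; a no-UV library carries only
uniform background reads.  Recurrent-mutation catalogs are drawn from a
log-linear (Poisson) damage->mutation model, and accessibility
densities are generated through a Gaussian rank copula so their
population Spearman correlation with per-site damage induction equals a
target value.

Every simulated lesion is emitted as one aligned read whose mapped
5' end sits exactly where :func:`uvhotspot.lesions.call_lesions` expects
it, so lesion calling inverts the simulation identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .genome import COMP, ReferenceGenome, decode, encode, revcomp
from .lesions import call_lesions
from .tracks import CoverageTrack, LesionTrack
from .utils import derive_rng

# --------------------------------------------------------------------------
# Generator constants.  The induction factors, sequencing depth and
# background mutation rate are calibration constants: they were solved
# numerically (scratch calibration against the analytic expectation
# functions below) so that the default cohort reproduces the observed
# aggregate behaviour of the real capture panel -- ~7-fold cellular vs
# scaled-naked damage at variant-site offsets -4/-3, ~4-fold -4/-3 vs
# -1/0 within the motif, a flanking induction mean near -1.5 reads per
# position, and ~60-fold trinucleotide-context mutation enrichment.
# --------------------------------------------------------------------------

#: relative CPD formation rate per dinucleotide class (TT dominant)
DEFAULT_BASE_RATE = {"TT": 1.0, "TC": 0.5, "CT": 0.2, "CC": 0.3}

# induction multipliers, keyed by (motif kind, pair offset); the offset is
# the pyrimidine-strand position of the 5'-most base of the dipyrimidine
# step relative to the motif midpoint (first C of the TTCC core for ETS).
F_ETS_43 = 16.6     # variant-site -4/-3 dipyrimidine
F_ETS_TC = 2.6      # TC step at -1/0
F_ETS_CC = 1.15     # CC step at 0/+1
F_SUPPRESS = 0.3    # CT at -3/-2 (protein contact shields)
F_ETS_TT = 0.05     # TT at -2/-1 (core contact, strongly shielded)

DEFAULT_INDUCTION = {
    ("ETS_variant", -4): F_ETS_43,
    ("ETS_variant", -3): F_SUPPRESS,
    ("ETS_variant", -2): F_ETS_TT,
    ("ETS_variant", -1): F_ETS_TC,
    ("ETS_variant", 0): F_ETS_CC,
    ("ETS_canonical", -2): F_ETS_TT,
    ("ETS_canonical", -1): F_ETS_TC,
    ("ETS_canonical", 0): F_ETS_CC,
    ("NFY", 0): 2.5,
    ("AP1", 0): 0.3,
    ("AP1", 1): 0.3,
    ("SRF", 0): 2.0,
}

#: expected naked-library dipyrimidine reads per capture region
DEFAULT_SEQUENCING_DEPTH = 16650.0

#: uniform background (non-lesion) reads per bp, all libraries
DEFAULT_BACKGROUND_RATE = 0.05

#: fraction of planted sites occupied by their factor ("two-thirds or fewer")
DEFAULT_BOUND_FRACTION = 0.65

#: mix of -4/-3 dinucleotide classes among planted variant sites
DEFAULT_DINUC_MIX = {"TC": 0.35, "TT": 0.20, "CC": 0.20, "CT": 0.25}

#: pyrimidine-strand trinucleotide weights for background mutations
#: (UV signature: C>T dominant, dipyrimidine 5' neighbour)
def _default_trinuc_weights() -> dict:
    w = {}
    for five in "ACGT":
        for centre in "CT":
            for three in "ACGT":
                if centre == "C":
                    w[five + centre + three] = 1.0 if five in "CT" else 0.25
                else:
                    w[five + centre + three] = 0.2 if five in "CT" else 0.05
    return w


#: background mutation intensity per weight unit (calibrated: ~60-fold
#: enrichment of the damage-driven site mutations over context expectation)
DEFAULT_MUTATION_BACKGROUND = 0.0925


# --------------------------------------------------------------------------
# Motif registry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class _MotifDef:
    """Planted context on the pyrimidine strand plus midpoint index."""

    context: str          # {XY} expands to the variant -4/-3 dinucleotide
    mid_idx: int          # index of the motif midpoint within context


MOTIF_DEFS = {
    # midpoint = first C of the TTCC core; purine flanks isolate the
    # planted dipyrimidine steps from the random background sequence
    "ETS_canonical": _MotifDef("AGATTCCGA", 5),
    "ETS_variant": _MotifDef("A{XY}TTCCGA", 5),
    "NFY": _MotifDef("GA{XY}GGA", 2),      # ATTGG box, TT step induced
    "AP1": _MotifDef("ATGA{XY}CAA", 4),    # GACTCA, CT/TC steps suppressed
    "SRF": _MotifDef("AGG{XY}AAATGGA", 3),  # CArG-adjacent CT step induced
}
_MOTIF_DEFAULT_DINUC = {"ETS_variant": "TC", "NFY": "TT", "AP1": "CT",
                        "SRF": "CT"}
MOTIF_CLASS = {"ETS_canonical": "ETS", "ETS_variant": "ETS",
               "NFY": "TFBS", "AP1": "TFBS", "SRF": "TFBS"}


def motif_context(kind: str, dinuc: str | None = None) -> str:
    try:
        d = MOTIF_DEFS[kind]
    except KeyError:
        raise ValueError(f"unknown motif kind {kind!r}") from None
    dinuc = dinuc or _MOTIF_DEFAULT_DINUC.get(kind, "")
    return d.context.format(XY=dinuc) if "{XY}" in d.context else d.context


# --------------------------------------------------------------------------
# Specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedMotif:
    region: int
    offset: int                 # genomic midpoint within the region
    kind: str                   # ETS_canonical | ETS_variant | NFY | AP1 | SRF
    bound: bool = True
    strand: str = "+"           # strand carrying the pyrimidine-strand motif
    dinuc: str = "TC"           # -4/-3 dinucleotide for ETS_variant


@dataclass
class GenomeSpec:
    """Deterministic recipe for a toy capture panel."""

    n_regions: int
    region_length: int = 720
    planted_motifs: list = field(default_factory=list)
    region_classes: list | None = None   # per-region class for motif-free ones
    gc_background: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.region_length < 41:
            raise ValueError("region_length must be >= 41")
        for p in self.planted_motifs:
            ctx = motif_context(p.kind, p.dinuc)
            start = _context_start(p, ctx)
            if start < 0 or start + len(ctx) > self.region_length:
                raise ValueError(
                    f"motif in region {p.region} does not fit inside region"
                )


@dataclass
class DamageModelParams:
    """Rates and coefficients of the generative damage/mutation model."""

    sequencing_depth: float = DEFAULT_SEQUENCING_DEPTH
    base_rate: dict = field(default_factory=lambda: dict(DEFAULT_BASE_RATE))
    induction: dict = field(default_factory=lambda: dict(DEFAULT_INDUCTION))
    background_rate: float = DEFAULT_BACKGROUND_RATE
    glm_beta0: float = 2.0
    glm_beta_cell: float = 0.001182
    glm_beta_naked: float = -0.01532
    mutation_background: float = DEFAULT_MUTATION_BACKGROUND
    trinuc_weights: dict = field(default_factory=_default_trinuc_weights)
    efficiency_sigma: float = 0.25   # lognormal spread of capture efficiency
    read_length: int = 30
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.base_rate.values()):
            raise ValueError("base rates must be >= 0")
        if any(v < 0 for v in self.induction.values()):
            raise ValueError("induction factors must be >= 0")
        if self.background_rate < 0 or self.sequencing_depth < 0:
            raise ValueError("rates must be >= 0")


CONDITIONS = ("cellular", "naked", "no_uv")


def _context_start(p: PlantedMotif, ctx: str) -> int:
    if p.strand == "+":
        return p.offset - MOTIF_DEFS[p.kind].mid_idx
    return p.offset - (len(ctx) - 1 - MOTIF_DEFS[p.kind].mid_idx)


# --------------------------------------------------------------------------
# Genome construction
# --------------------------------------------------------------------------

def make_genome(spec: GenomeSpec):
    """Build the toy panel.

    Returns ``(genome, regions, truth)`` where ``regions`` is a
    BED-writable table with a class column and ``truth`` lists every
    planted motif (contig, midpoint, strand, kind, variant, bound,
    dinuc).
    """
    rng = derive_rng(spec.seed, "genome")
    p_gc = spec.gc_background
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T

    names = [f"region_{i:05d}" for i in range(spec.n_regions)]
    seqs, truth_rows, region_rows = {}, [], []
    by_region: dict[int, list] = {}
    for p in spec.planted_motifs:
        if not 0 <= p.region < spec.n_regions:
            raise ValueError(f"planted motif region {p.region} out of range")
        by_region.setdefault(p.region, []).append(p)

    for ri, name in enumerate(names):
        codes = rng.choice(4, size=spec.region_length,
                           p=probs).astype(np.uint8)
        intervals = []
        cls = None
        for p in by_region.get(ri, []):
            ctx = motif_context(p.kind, p.dinuc)
            if p.strand == "-":
                ctx_g = revcomp(ctx)
            elif p.strand == "+":
                ctx_g = ctx
            else:
                raise ValueError(f"bad motif strand {p.strand!r}")
            start = _context_start(p, ctx)
            end = start + len(ctx)
            for s0, e0 in intervals:
                if start < e0 and s0 < end:
                    raise ValueError(
                        f"overlapping planted motifs in region {ri}: "
                        f"[{s0},{e0}) and [{start},{end})"
                    )
            intervals.append((start, end))
            codes[start:end] = encode(ctx_g)
            cls = cls or MOTIF_CLASS[p.kind]
            truth_rows.append({
                "contig": name, "midpoint": p.offset, "strand": p.strand,
                "kind": p.kind, "variant": p.kind == "ETS_variant",
                "bound": bool(p.bound), "dinuc": p.dinuc,
            })
        if cls is None:
            cls = (spec.region_classes[ri]
                   if spec.region_classes is not None else "coding")
        seqs[name] = decode(codes)
        region_rows.append({"chrom": name, "start": 0,
                            "end": spec.region_length, "name": name,
                            "score": 0, "strand": "+", "class": cls})

    genome = ReferenceGenome(seqs)
    regions = pd.DataFrame(region_rows)
    truth = pd.DataFrame(
        truth_rows, columns=["contig", "midpoint", "strand", "kind",
                             "variant", "bound", "dinuc"])
    return genome, regions, truth


# --------------------------------------------------------------------------
# Dipyrimidine enumeration and analytic expectations
# --------------------------------------------------------------------------

def _rate_lut(base_rate: dict) -> np.ndarray:
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    lut = np.zeros(25)
    for dinuc, r in base_rate.items():
        lut[code[dinuc[0]] * 5 + code[dinuc[1]]] = r
    return lut


def enumerate_pairs(genome: ReferenceGenome, base_rate: dict):
    """All dipyrimidine steps on both strands.

    Returns a dict of parallel arrays: ``gleft`` (global genomic leftmost
    position), ``strand_row`` (0 '+', 1 '-'), ``rate`` (base formation
    rate), ``contig_id`` and ``encodable`` (whether a read pointing at
    this pair fits on the contig).
    """
    idx = genome.index
    codes = genome.codes
    if codes.size == 0:
        z = np.empty(0, dtype=np.int64)
        return {"gleft": z, "strand_row": z, "rate": z.astype(float),
                "contig_id": z, "encodable": z.astype(bool)}
    contig_id = np.repeat(np.arange(len(idx)), idx.lengths)
    pyr = (codes == 1) | (codes == 3)
    pur = (codes == 0) | (codes == 2)
    same = contig_id[:-1] == contig_id[1:]

    plus = pyr[:-1] & pyr[1:] & same
    minus = pur[:-1] & pur[1:] & same
    lut = _rate_lut(base_rate)

    g_plus = np.flatnonzero(plus)
    g_minus = np.flatnonzero(minus)
    rate_plus = lut[codes[g_plus] * 5 + codes[g_plus + 1]]
    rate_minus = lut[COMP[codes[g_minus + 1]] * 5 + COMP[codes[g_minus]]]

    gleft = np.concatenate([g_plus, g_minus])
    strand_row = np.concatenate([np.zeros(g_plus.size, dtype=np.int64),
                                 np.ones(g_minus.size, dtype=np.int64)])
    rate = np.concatenate([rate_plus, rate_minus])
    cid = contig_id[gleft]
    local = gleft - idx.offsets[cid]
    # '+' lesion needs a '-' read ending at local-1 (>=0); '-' lesion needs
    # a '+' read starting at local+2 (< contig length)
    encodable = np.where(strand_row == 0, local >= 1,
                         local + 2 < idx.lengths[cid])
    return {"gleft": gleft, "strand_row": strand_row, "rate": rate,
            "contig_id": cid, "encodable": encodable}


def _pair_key(strand_row, gleft, total):
    return strand_row * total + gleft


def _site_pair_positions(site, idx, offset: int):
    """Global leftmost position + strand row of the dipyrimidine step at
    pyrimidine-strand pair offset ``offset`` of a motif site."""
    off = idx.offsets[idx.slot(site.contig)]
    if site.strand == "+":
        return off + site.midpoint + offset, 0
    return off + site.midpoint - offset - 1, 1


def pair_lambdas(genome: ReferenceGenome, truth: pd.DataFrame,
                 params: DamageModelParams, condition: str):
    """Expected lesion count per dipyrimidine step (analytic oracle).

    The returned ``lam`` is in reads; induction factors are applied for
    the cellular condition at bound planted sites only.  Capture
    efficiency has unit mean and is excluded here.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    pairs = enumerate_pairs(genome, params.base_rate)
    naked_total = float(pairs["rate"][pairs["encodable"]].sum())
    if naked_total == 0:
        raise ValueError("genome contains no encodable dipyrimidines")
    d = params.sequencing_depth * len(genome.index) / naked_total

    factor = np.ones_like(pairs["rate"])
    if condition == "cellular" and len(truth):
        total = genome.index.total
        keys = _pair_key(pairs["strand_row"], pairs["gleft"], total)
        order = np.argsort(keys)
        sorted_keys = keys[order]
        for site in truth.itertuples():
            if not site.bound:
                continue
            for (kind, off), f in params.induction.items():
                if kind != site.kind:
                    continue
                g, row = _site_pair_positions(site, genome.index, off)
                k = row * total + g
                j = np.searchsorted(sorted_keys, k)
                if j < sorted_keys.size and sorted_keys[j] == k:
                    factor[order[j]] *= f
    lam = pairs["rate"] * factor * d
    lam[~pairs["encodable"]] = 0.0
    return pairs, lam


def expected_position_lambda(genome, truth, params, condition) -> np.ndarray:
    """Expected per-position lesion-track values, shape (2, total)."""
    pairs, lam = pair_lambdas(genome, truth, params, condition)
    total = genome.index.total
    out = np.zeros(2 * total)
    np.add.at(out, pairs["strand_row"] * total + pairs["gleft"], lam)
    np.add.at(out, pairs["strand_row"] * total + pairs["gleft"] + 1, lam)
    return out.reshape(2, total)


# --------------------------------------------------------------------------
# Read simulation
# --------------------------------------------------------------------------

def region_efficiencies(n_regions: int, params: DamageModelParams) \
        -> np.ndarray:
    """Per-region capture-efficiency scalars (unit-mean lognormal), shared
    between the matched cellular/naked/no-UV libraries."""
    rng = derive_rng(params.seed, "efficiency")
    s = params.efficiency_sigma
    if s == 0:
        return np.ones(n_regions)
    return rng.lognormal(mean=-s * s / 2, sigma=s, size=n_regions)


def _reads_frame(index, strand_row, gleft, read_length, cid=None):
    """BED6 rows for lesions at (strand_row, gleft)."""
    if cid is None:
        cid = np.searchsorted(index.offsets, gleft, side="right") - 1
    local = (gleft - index.offsets[cid]).astype(np.int32)
    plus_lesion = strand_row == 0
    n = gleft.shape[0]
    start = np.empty(n, dtype=np.int32)
    end = np.empty(n, dtype=np.int32)
    pl = plus_lesion
    mn = ~pl
    start[pl] = np.maximum(0, local[pl] - read_length)
    end[pl] = local[pl]
    lm = local[mn] + 2
    start[mn] = lm
    end[mn] = np.minimum(index.lengths[cid[mn]].astype(np.int32),
                         lm + read_length)
    chrom = pd.Categorical.from_codes(cid.astype(np.int32, copy=False),
                                      categories=index.names)
    # '+' lesion -> read on '-' (code 1); '-' lesion -> read on '+'
    strand = pd.Categorical.from_codes(
        plus_lesion.astype(np.int8), categories=["+", "-"])
    name = pd.Categorical.from_codes(np.zeros(n, dtype=np.int8),
                                     categories=["."])
    return pd.DataFrame({
        "chrom": chrom, "start": start, "end": end, "name": name,
        "score": np.zeros(n, dtype=np.int16), "strand": strand,
    }, copy=False)


def simulate_reads(genome: ReferenceGenome, truth: pd.DataFrame,
                   params: DamageModelParams, condition: str,
                   seed: int | None = None) -> pd.DataFrame:
    """Simulate one aligned-read library (BED6 table).

    ``condition`` is ``cellular`` (induction at bound sites), ``naked``
    (no induction) or ``no_uv`` (background reads only).  The default
    stream is derived from ``params.seed`` and the condition label, so a
    matched pair of libraries is reproducible from one seed.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = derive_rng(seed if seed is not None else params.seed,
                     f"reads:{condition}")
    idx = genome.index

    frames = []
    if condition != "no_uv":
        pairs, lam = pair_lambdas(genome, truth, params, condition)
        eff = region_efficiencies(len(idx), params)
        counts = rng.poisson(lam * eff[pairs["contig_id"]])
        nz = counts > 0
        rep = np.repeat(np.flatnonzero(nz), counts[nz])
        frames.append(_reads_frame(idx, pairs["strand_row"][rep],
                                   pairs["gleft"][rep], params.read_length,
                                   cid=pairs["contig_id"][rep]))

    n_bg = rng.poisson(params.background_rate * idx.total)
    if n_bg:
        g = rng.integers(0, idx.total - 1, size=n_bg)
        row = rng.integers(0, 2, size=n_bg)
        cid = np.searchsorted(idx.offsets, g, side="right") - 1
        local = g - idx.offsets[cid]
        ok = np.where(row == 0, local >= 1,
                      local + 2 < idx.lengths[cid])
        ok &= local + 1 < idx.lengths[cid]
        frames.append(_reads_frame(idx, row[ok], g[ok], params.read_length))

    if not frames:
        return _reads_frame(idx, np.empty(0, dtype=int),
                            np.empty(0, dtype=int), params.read_length)
    out = pd.concat(frames, ignore_index=True) if len(frames) > 1 \
        else frames[0]
    out.attrs["condition"] = condition
    return out


# --------------------------------------------------------------------------
# Mutation simulation
# --------------------------------------------------------------------------

def variant_query_positions(truth: pd.DataFrame, index) -> pd.DataFrame:
    """Genomic positions at pyrimidine-strand offsets -4/-3 of variant
    sites (one row per position, two per site)."""
    rows = []
    for site in truth[truth["variant"]].itertuples():
        sign = 1 if site.strand == "+" else -1
        for off in (-4, -3):
            rows.append({"contig": site.contig,
                         "position": site.midpoint + sign * off,
                         "site": site.Index, "offset": off})
    return pd.DataFrame(rows)


def site_damage_sums(cellular: LesionTrack, naked: LesionTrack,
                     truth: pd.DataFrame) -> pd.DataFrame:
    """Per variant site: both-strand cellular/naked count sums over the
    two -4/-3 positions (the Poisson-regression covariates)."""
    idx = cellular.index
    rows = []
    for site in truth[truth["variant"]].itertuples():
        off = idx.offsets[idx.slot(site.contig)]
        sign = 1 if site.strand == "+" else -1
        gpos = np.array([off + site.midpoint + sign * o for o in (-4, -3)])
        rows.append({
            "site": site.Index, "contig": site.contig,
            "x_cell": float(cellular.position_sum(gpos).sum()),
            "x_naked": float(naked.position_sum(gpos).sum()),
        })
    return pd.DataFrame(rows)


def _context_weight_lut(weights: dict) -> np.ndarray:
    """64-entry LUT over pyrimidine-strand trinucleotide codes."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    lut = np.zeros(64)
    for ctx, w in weights.items():
        lut[code[ctx[0]] * 16 + code[ctx[1]] * 4 + code[ctx[2]]] = w
    return lut


def position_context_codes(genome: ReferenceGenome) -> np.ndarray:
    """Pyrimidine-strand-collapsed trinucleotide code per position
    (-1 where undefined: contig edges or N)."""
    codes = genome.codes
    idx = genome.index
    n = codes.size
    out = np.full(n, -1, dtype=np.int64)
    if n < 3:
        return out
    contig_id = np.repeat(np.arange(len(idx)), idx.lengths)
    interior = np.zeros(n, dtype=bool)
    interior[1:-1] = (contig_id[1:-1] == contig_id[:-2]) & \
        (contig_id[1:-1] == contig_id[2:])
    g = np.flatnonzero(interior)
    left, centre, right = codes[g - 1], codes[g], codes[g + 1]
    has_n = (left > 3) | (centre > 3) | (right > 3)
    is_pyr = (centre == 1) | (centre == 3)
    fwd = left * 16 + centre * 4 + right
    rev = COMP[right] * 16 + COMP[centre] * 4 + COMP[left]
    out[g] = np.where(is_pyr, fwd, rev)
    out[g[has_n]] = -1
    return out


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def simulate_mutations(cellular: LesionTrack, naked: LesionTrack,
                       truth: pd.DataFrame, genome: ReferenceGenome,
                       regions: pd.DataFrame, params: DamageModelParams,
                       seed: int | None = None) -> pd.DataFrame:
    """Draw a recurrent-mutation catalog.

    Per variant site, the summed mutation count at the two -4/-3
    positions is Poisson with log-rate ``beta0 + beta_cell*C +
    beta_naked*N`` where C and N are the summed cellular and (scaled)
    naked track counts at those positions.  Background mutations are
    scattered over all other region positions in proportion to a
    pyrimidine-strand trinucleotide weight table, so context-expected
    frequencies are estimable downstream.
    """
    rng = derive_rng(seed if seed is not None else params.seed, "mutations")
    idx = genome.index
    cls_of = dict(zip(regions["chrom"], regions["class"]))

    sums = site_damage_sums(cellular, naked, truth)
    records = []
    query_global = set()
    for site, s in zip(truth[truth["variant"]].itertuples(),
                       sums.itertuples()):
        if s.x_cell == 0 and s.x_naked == 0:
            warnings.warn(f"no track coverage at site {site.contig}; "
                          "treating damage sums as 0")
        mu = np.exp(params.glm_beta0 + params.glm_beta_cell * s.x_cell
                    + params.glm_beta_naked * s.x_naked)
        y = rng.poisson(mu)
        split = rng.binomial(y, 0.5)
        sign = 1 if site.strand == "+" else -1
        for off, cnt in zip((-4, -3), (split, y - split)):
            pos = site.midpoint + sign * off
            query_global.add(idx.global_pos(site.contig, pos))
            if cnt > 0:
                ref = genome[site.contig][pos]
                records.append({
                    "contig": site.contig, "position": pos, "ref": ref,
                    "alt": _TRANSITION[ref], "tumor_count": int(cnt),
                    "class": cls_of.get(site.contig, "TFBS"),
                    "gene": site.contig, "cancer_gene": False,
                })

    # context-weighted background
    ctx = position_context_codes(genome)
    lut = _context_weight_lut(params.trinuc_weights)
    rate = np.where(ctx >= 0, lut[np.clip(ctx, 0, 63)], 0.0)
    rate = rate * params.mutation_background
    if query_global:
        rate[np.fromiter(query_global, dtype=np.int64)] = 0.0
    counts = rng.poisson(rate)
    for g in np.flatnonzero(counts):
        cid = int(np.searchsorted(idx.offsets, g, side="right") - 1)
        contig = idx.names[cid]
        pos = int(g - idx.offsets[cid])
        ref = genome[contig][pos]
        records.append({
            "contig": contig, "position": pos, "ref": ref,
            "alt": _TRANSITION.get(ref, "N"), "tumor_count": int(counts[g]),
            "class": cls_of.get(contig, "coding"), "gene": contig,
            "cancer_gene": False,
        })
    return pd.DataFrame(
        records, columns=["contig", "position", "ref", "alt", "tumor_count",
                          "class", "gene", "cancer_gene"])


# --------------------------------------------------------------------------
# Accessibility simulation (Gaussian rank copula)
# --------------------------------------------------------------------------

#: relative depths of the three emitted replicate tracks
DNASE_REPLICATE_WEIGHTS = (0.45, 0.35, 0.20)


def simulate_dnase(truth: pd.DataFrame, induction: np.ndarray,
                   target_rho: float, seed: int,
                   index=None, halfwidth: int = 50):
    """Per-site accessibility densities rank-correlated with induction.

    The Gaussian copula correlation is chosen so the *population*
    Spearman correlation with the supplied per-site induction equals
    ``target_rho``.  Three replicate tracks are emitted (fixed relative
    depths); their summed within-window means reconstruct the density.

    Returns ``(per_site_table, tracks)``; ``tracks`` is empty when no
    ContigIndex is supplied.
    """
    n = len(truth)
    if n < 10:
        raise ValueError("need >= 10 sites for a meaningful correlation")
    if not 0 < target_rho <= 1:
        raise ValueError("target_rho must be in (0, 1]")
    induction = np.asarray(induction, dtype=float)
    if induction.shape != (n,):
        raise ValueError("induction must have one value per site")

    rng = derive_rng(seed, "dnase")
    rho_g = 2 * np.sin(np.pi * target_rho / 6)
    ranks = scipy.stats.rankdata(induction, method="average")
    z_ind = scipy.stats.norm.ppf((ranks - 0.5) / n)
    z = rho_g * z_ind + np.sqrt(max(0.0, 1 - rho_g**2)) * \
        rng.standard_normal(n)
    density = 10.0 * np.exp(0.5 * z)

    table = pd.DataFrame({
        "contig": truth["contig"].to_numpy(),
        "midpoint": truth["midpoint"].to_numpy(),
        "density": density,
    })
    for r, w in enumerate(DNASE_REPLICATE_WEIGHTS):
        table[f"rep{r + 1}"] = density * w

    tracks = []
    if index is not None:
        for r, w in enumerate(DNASE_REPLICATE_WEIGHTS):
            t = CoverageTrack.zeros(index, name=f"dnase_rep{r + 1}")
            for row in table.itertuples():
                off = index.offsets[index.slot(row.contig)]
                lo = max(0, row.midpoint - halfwidth)
                hi = min(int(index.lengths[index.slot(row.contig)]),
                         row.midpoint + halfwidth + 1)
                t.data[off + lo : off + hi] += row.density * w
            tracks.append(t)
    return table, tracks


# --------------------------------------------------------------------------
# Cohort builders
# --------------------------------------------------------------------------

def variant_cohort_spec(n_sites: int = 300, seed: int = 0,
                        region_length: int = 720,
                        bound_fraction: float = DEFAULT_BOUND_FRACTION,
                        dinuc_mix: dict | None = None) -> GenomeSpec:
    """A panel of ETS-variant capture regions, one centred site each."""
    mix = dinuc_mix or DEFAULT_DINUC_MIX
    rng = derive_rng(seed, "cohort")
    dinucs = rng.choice(list(mix), size=n_sites, p=list(mix.values()))
    bound = rng.random(n_sites) < bound_fraction
    plants = [
        PlantedMotif(region=i, offset=region_length // 2, kind="ETS_variant",
                     bound=bool(bound[i]), strand="+" if i % 2 == 0 else "-",
                     dinuc=str(dinucs[i]))
        for i in range(n_sites)
    ]
    return GenomeSpec(n_regions=n_sites, region_length=region_length,
                      planted_motifs=plants, seed=seed)


def driver_fixture(seed: int = 0):
    """The 12-site driver-candidate fixture.

    Twelve recurrent mutation sites previously nominated as non-coding
    drivers: seven sit at offsets -3 of *bound* variant ETS sites (their
    recurrence is explained by the damage hotspot), two sit in unbound
    ETS motifs and three carry no ETS motif at all (TERT-promoter-like:
    candidate drivers).  Returns ``(genome, regions, truth, catalog,
    params)``; running the classifier over the simulated libraries calls
    exactly the seven hotspot sites likely passengers.
    """
    from .motifs import scan_genome

    rng = derive_rng(seed, "driver_fixture")
    plants = []
    for i in range(7):
        plants.append(PlantedMotif(region=i, offset=360, kind="ETS_variant",
                                   bound=True,
                                   strand="+" if i % 2 == 0 else "-",
                                   dinuc="TC"))
    for i in (7, 8):
        plants.append(PlantedMotif(region=i, offset=360,
                                   kind="ETS_canonical", bound=False,
                                   strand="+"))
    spec = GenomeSpec(n_regions=12, region_length=720,
                      planted_motifs=plants,
                      region_classes=["promoter"] * 12, seed=seed)
    genome, regions, truth = make_genome(spec)
    regions["class"] = "promoter"

    all_sites = scan_genome(genome)
    rows = []
    for i in range(12):
        contig = f"region_{i:05d}"
        if i < 7:
            strand = "+" if i % 2 == 0 else "-"
            pos = 360 - 3 if strand == "+" else 360 + 3
            cancer = False
        elif i < 9:
            pos = 360
            cancer = True
        else:
            pos = _dipy_position_clear_of_ets(genome, all_sites, contig, rng)
            cancer = True
        ref = genome[contig][pos]
        rows.append({"contig": contig, "position": pos, "ref": ref,
                     "alt": _TRANSITION.get(ref, "N"),
                     "tumor_count": int(rng.integers(5, 40)),
                     "class": "promoter", "gene": contig,
                     "cancer_gene": cancer})
    catalog = pd.DataFrame(rows)
    params = DamageModelParams(seed=seed)
    return genome, regions, truth, catalog, params


def _dipy_position_clear_of_ets(genome, sites, contig: str, rng) -> int:
    """A dipyrimidine position near the region centre at least 8 bp from
    every scanned ETS midpoint (so no overlap annotation can fire)."""
    seq = genome[contig]
    mids = sites.loc[sites["contig"] == contig, "midpoint"].to_numpy()
    candidates = [p for p in range(300, 420)
                  if seq[p] in "CT" and (seq[p - 1] in "CT"
                                         or seq[p + 1] in "CT")
                  and (mids.size == 0 or np.abs(mids - p).min() >= 8)]
    if not candidates:
        raise RuntimeError(f"no clear dipyrimidine position in {contig}")
    return int(candidates[int(rng.integers(0, len(candidates)))])


def default_cohort(seed: int = 0, n_sites: int = 300,
                   params: DamageModelParams | None = None):
    """The default synthetic melanocyte cohort: genome + matched cellular
    and naked read libraries under the default calibration."""
    spec = variant_cohort_spec(n_sites=n_sites, seed=seed)
    genome, regions, truth = make_genome(spec)
    params = params if params is not None else DamageModelParams(seed=seed)
    params = replace(params, seed=seed)
    reads_cell = simulate_reads(genome, truth, params, "cellular")
    reads_naked = simulate_reads(genome, truth, params, "naked")
    cellular = call_lesions(reads_cell, genome, sample="melanocyte",
                            condition="cellular")
    naked = call_lesions(reads_naked, genome, sample="naked",
                         condition="naked")
    return genome, regions, truth, params, cellular, naked
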