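"""Passenger-vs-driver classification of recurrent mutation sites.

A recurrent mutation whose position shows *elevated* cellular CPDs
relative to the scaled naked control (at least twofold AND an absolute
difference of at least a read threshold, both inclusive) and which
overlaps an ETS motif is most parsimoniously a recurrent *passenger*:
its recurrence is explained by locally elevated UV damage, not
selection.  A site without damage elevation remains a candidate driver;
elevation without an ETS motif is called ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import mann_whitney
from .tracks import LesionTrack


@dataclass
class ClassifierConfig:
    fold_threshold: float = 2.0
    abs_threshold: float = 50.0
    window: int = 0          # bp either side of the mutation base

    def __post_init__(self):
        if self.fold_threshold <= 0 or self.abs_threshold <= 0:
            raise ValueError("thresholds must be > 0")


CALLS = ("likely_passenger", "candidate_driver", "ambiguous")


def elevated_cpd(cellular: float, scaled_naked: float,
                 config: ClassifierConfig = ClassifierConfig()) -> bool:
    """Inclusive elevated-CPD rule: cellular >= fold * naked and
    cellular - naked >= abs threshold."""
    return (cellular >= config.fold_threshold * scaled_naked
            and cellular - scaled_naked >= config.abs_threshold)


def _counts_at(track: LesionTrack, contig: str, position: int,
               window: int) -> float:
    idx = track.index
    off = idx.offsets[idx.slot(contig)]
    length = int(idx.lengths[idx.slot(contig)])
    lo = max(0, position - window)
    hi = min(length, position + window + 1)
    g = np.arange(off + lo, off + hi)
    return float(track.position_sum(g).sum())


def classify_sites(catalog: pd.DataFrame, cellular: LesionTrack,
                   scaled_naked: LesionTrack, regions: pd.DataFrame,
                   config: ClassifierConfig = ClassifierConfig()):
    """Classify every annotated mutation record.

    ``catalog`` must carry ``ets_overlap`` (see
    :func:`uvhotspot.motifs.annotate_mutations`).  Returns ``(calls,
    summary)``: per-site calls plus a per-class summary table (n, n_ets,
    n_elevated and their fractions).  Mutations outside any capture
    region are reported with ``covered=False`` and excluded from the
    summary fractions.
    """
    if "ets_overlap" not in catalog.columns:
        raise ValueError("catalog lacks ets_overlap; run annotate_mutations "
                         "first")
    idx = cellular.index
    cover = {}
    for r in regions.itertuples():
        cover.setdefault(r.chrom, []).append((int(r.start), int(r.end)))

    rows = []
    for _, m in catalog.iterrows():
        covered = any(s <= m["position"] < e
                      for s, e in cover.get(m["contig"], []))
        cell = naked = ind = np.nan
        elevated = False
        call = "uncovered"
        if covered:
            cell = _counts_at(cellular, m["contig"], int(m["position"]),
                              config.window)
            naked = _counts_at(scaled_naked, m["contig"], int(m["position"]),
                               config.window)
            ind = cell - naked
            elevated = elevated_cpd(cell, naked, config)
            if elevated and m["ets_overlap"]:
                call = "likely_passenger"
            elif not elevated:
                call = "candidate_driver"
            else:
                call = "ambiguous"
        rows.append({
            "contig": m["contig"], "position": m["position"],
            "gene": m["gene"], "class": m["class"],
            "tumor_count": m["tumor_count"], "cellular": cell,
            "scaled_naked": naked, "induction": ind,
            "elevated": bool(elevated),
            "ets_overlap": bool(m["ets_overlap"]),
            "covered": covered, "call": call,
        })
    calls = pd.DataFrame(rows)

    cov = calls[calls["covered"]]
    summary_rows = []
    for cls, sub in cov.groupby("class"):
        n = len(sub)
        summary_rows.append({
            "class": cls, "n": n,
            "n_ets": int(sub["ets_overlap"].sum()),
            "n_elevated": int(sub["elevated"].sum()),
            "n_likely_passenger": int((sub["call"]
                                       == "likely_passenger").sum()),
            "frac_ets": sub["ets_overlap"].mean(),
            "frac_elevated": sub["elevated"].mean(),
        })
    summary = pd.DataFrame(summary_rows)
    return calls, summary


def tss_group_compare(calls: pd.DataFrame, catalog_with_tss: pd.DataFrame):
    """Mann-Whitney comparison of TSS distances: ETS-overlapping vs
    non-ETS coding mutations.

    Returns ``(U, p, median_ets, median_non_ets)``.
    """
    merged = calls.drop(columns=["tss_distance"], errors="ignore").merge(
        catalog_with_tss[["contig", "position", "tss_distance"]],
        on=["contig", "position"], how="left")
    coding = merged[(merged["class"] == "coding")
                    & merged["tss_distance"].notna()]
    ets = coding.loc[coding["ets_overlap"], "tss_distance"].to_numpy()
    non = coding.loc[~coding["ets_overlap"], "tss_distance"].to_numpy()
    if ets.size == 0 or non.size == 0:
        raise ValueError("need coding mutations in both ETS and non-ETS "
                         "groups")
    u, p = mann_whitney(ets, non)
    return u, p, float(np.median(ets)), float(np.median(non))
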