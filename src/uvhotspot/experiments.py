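"""Cohort-level recovery experiments.

These functions run the whole pipeline — generator, lesion calling,
scaling, induction statistics, mutation model, regression — on
replicate synthetic cohorts, and return the recovered quantities.  They
back the reproduction script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .induction import (MATRIX_ORDER_OFFSETS, capture_efficiency_filter,
                        flank_null, motif_profile, scale_naked,
                        site_offset_counts)
from .stats import correlate, dnase_density, fit_poisson_glm, \
    trinuc_enrichment
from .synthetic import (default_cohort, simulate_dnase, simulate_mutations,
                        site_damage_sums, variant_query_positions)
from .utils import derive_seed


def mutation_sums_per_site(catalog: pd.DataFrame, sites: pd.DataFrame,
                           index) -> np.ndarray:
    """Per-site melanoma mutation sums at the -4/-3 positions."""
    q = variant_query_positions(sites, index)
    at = {}
    for m in catalog.itertuples():
        at[(m.contig, m.position)] = \
            at.get((m.contig, m.position), 0) + m.tumor_count
    y = np.zeros(len(sites))
    for row in q.itertuples():
        y[row.site] += at.get((row.contig, row.position), 0)
    return y


def glm_recovery(n_seeds: int = 100, n_sites: int = 300,
                 base_seed: int = 0) -> pd.DataFrame:
    """Refit the damage->mutation regression on replicate cohorts.

    Per seed: simulate matched libraries at the default calibration,
    call lesions, scale the naked control, apply the capture-efficiency
    filter, draw the mutation catalog, and fit the Poisson GLM.  Returns
    one row per seed with the coefficient estimates and their Wald 95%
    CI bounds.
    """
    rows = []
    for i in range(n_seeds):
        seed = derive_seed(base_seed, f"glm:{i}")
        genome, regions, truth, params, cellular, naked = \
            default_cohort(seed=seed, n_sites=n_sites)
        info, scaled = scale_naked(cellular, naked, regions)
        vs = truth[truth["variant"]].reset_index(drop=True)
        keep = capture_efficiency_filter(vs, cellular)
        vs = vs[keep].reset_index(drop=True)
        catalog = simulate_mutations(cellular, scaled, vs, genome, regions,
                                     params)
        y = mutation_sums_per_site(catalog, vs, genome.index)
        sums = site_damage_sums(cellular, scaled, vs)
        res = fit_poisson_glm(y, sums["x_cell"], sums["x_naked"])
        rows.append({
            "seed": seed,
            "beta_cell": res.beta_cell,
            "beta_naked": res.beta_naked,
            "cell_lo": res.conf_int.loc["x_cell", 0],
            "cell_hi": res.conf_int.loc["x_cell", 1],
            "naked_lo": res.conf_int.loc["x_naked", 0],
            "naked_hi": res.conf_int.loc["x_naked", 1],
            "lrt_p": res.lrt_p, "pseudo_r2": res.pseudo_r2,
        })
    return pd.DataFrame(rows)


def cohort_statistics(seed: int, n_sites: int = 300) -> dict:
    """Flank-null mean, aggregate induction ratios and the
    trinucleotide-context mutation enrichment of one default cohort."""
    genome, regions, truth, params, cellular, naked = \
        default_cohort(seed=seed, n_sites=n_sites)
    info, scaled = scale_naked(cellular, naked, regions)
    vs = truth[truth["variant"]].reset_index(drop=True)

    profile = motif_profile(cellular, scaled, vs)
    cell_43 = profile.loc[[-4, -3], "cellular"].sum()
    ratio_cell_naked = cell_43 / profile.loc[[-4, -3], "naked"].sum()
    ratio_43_10 = cell_43 / profile.loc[[-1, 0], "cellular"].sum()

    null = flank_null(cellular, scaled, vs, genome)

    catalog = simulate_mutations(cellular, scaled, vs, genome, regions,
                                 params)
    q = variant_query_positions(vs, genome.index)
    enr = trinuc_enrichment(catalog, genome, q, regions)

    return {
        "flank_mean": null.mu_flank,
        "flank_sd": null.sigma_flank,
        "flank_n": null.n_positions,
        "ratio_cell_naked_43": float(ratio_cell_naked),
        "ratio_43_over_10": float(ratio_43_10),
        "trinuc_fold": enr.fold,
        "n_sites": len(vs),
    }


def site_induction(cellular, scaled, sites, halfwidth: int = 10) \
        -> np.ndarray:
    """Per-site summed within-motif induction (cluster-plot ordering
    key; also the accessibility-copula anchor)."""
    ind = (site_offset_counts(cellular, sites, halfwidth)
           - site_offset_counts(scaled, sites, halfwidth))
    offs = np.arange(-halfwidth, halfwidth + 1)
    return ind[:, np.isin(offs, MATRIX_ORDER_OFFSETS)].sum(axis=1)


def dnase_recovery(n_seeds: int = 200, n_sites: int = 324,
                   base_seed: int = 0, target_rho: float = 0.41) \
        -> pd.DataFrame:
    """Accessibility-correlation recovery on one cohort.

    Simulates three replicate accessibility tracks per seed at the
    default correlation target, measures per-site density (mean within
    50 bp, summed over tracks) and correlates it with measured per-site
    induction.
    """
    cohort_seed = derive_seed(base_seed, "dnase-cohort")
    genome, regions, truth, params, cellular, naked = \
        default_cohort(seed=cohort_seed, n_sites=n_sites)
    info, scaled = scale_naked(cellular, naked, regions)
    vs = truth[truth["variant"]].reset_index(drop=True)
    key = site_induction(cellular, scaled, vs)

    rows = []
    for i in range(n_seeds):
        seed = derive_seed(base_seed, f"dnase:{i}")
        _, tracks = simulate_dnase(vs, key, target_rho, seed=seed,
                                   index=genome.index)
        dens = dnase_density(tracks, vs)
        sp = correlate(dens, key)
        rows.append({"seed": seed, "rho": sp.rho, "ci_low": sp.ci_low,
                     "ci_high": sp.ci_high})
    return pd.DataFrame(rows)
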