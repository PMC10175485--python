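"""Statistical layer: the damage->mutation Poisson regression,
trinucleotide-context mutation enrichment, accessibility correlation and
rank tests.

The regression predicts per-site melanoma mutation sums at the variant
-4/-3 positions from the cellular and naked-DNA CPD sums at the same
positions: log E[y] = b0 + b_cell*C + b_naked*N.  A positive b_cell with
a negative b_naked means the *scaled difference* (damage induction)
drives mutation counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


@dataclass
class PoissonRegressionResult:
    """Fitted damage->mutation Poisson model (log link).

    Log-likelihoods of the fitted (cellular+naked), null (naked-only)
    and intercept-only models support the likelihood-ratio test for the
    cellular term and McFadden's pseudo-R^2.
    """

    params: pd.Series            # const, x_cell, x_naked (log-rate scale)
    bse: pd.Series
    conf_int: pd.DataFrame       # 95% Wald
    llf: float
    llf_naked_only: float
    llf_intercept: float
    lrt_stat: float
    lrt_p: float
    pseudo_r2: float             # McFadden, vs intercept-only
    nobs: int

    @property
    def beta_cell(self) -> float:
        return float(self.params["x_cell"])

    @property
    def beta_naked(self) -> float:
        return float(self.params["x_naked"])

    def summary(self) -> str:
        lines = [
            "Poisson regression of mutation counts on CPD counts",
            f"  n sites: {self.nobs}",
            f"  {'term':<10}{'coef':>12}{'std err':>12}"
            f"{'[0.025':>12}{'0.975]':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<10}{self.params[name]:>12.6g}"
                f"{self.bse[name]:>12.3g}"
                f"{self.conf_int.loc[name, 0]:>12.6g}"
                f"{self.conf_int.loc[name, 1]:>12.6g}")
        lines += [
            f"  log-likelihood (fitted):        {self.llf:.3f}",
            f"  log-likelihood (naked-only):    {self.llf_naked_only:.3f}",
            f"  log-likelihood (intercept):     {self.llf_intercept:.3f}",
            f"  LRT cellular term: chi2(1) = {self.lrt_stat:.3f}, "
            f"p = {self.lrt_p:.3g}",
            f"  pseudo-R2 (McFadden):           {self.pseudo_r2:.4f}",
        ]
        return "\n".join(lines)


def fit_poisson_glm(y, x_cell, x_naked) -> PoissonRegressionResult:
    """ML Poisson fit of per-site mutation sums on cellular/naked CPD
    sums (IRLS, Wald 95% CIs, LRT of the cellular term on 1 df)."""
    y = np.asarray(y, dtype=float)
    x_cell = np.asarray(x_cell, dtype=float)
    x_naked = np.asarray(x_naked, dtype=float)
    if y.size < 3:
        raise ValueError("need >= 3 sites to fit the regression")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("mutation counts must be non-negative integers")
    if not y.any():
        raise ValueError("all mutation counts are zero; model degenerate")

    X = pd.DataFrame({"const": 1.0, "x_cell": x_cell, "x_naked": x_naked})
    fam = sm.families.Poisson()
    try:
        fit = sm.GLM(y, X, family=fam).fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # noqa: BLE001 - surface convergence failures
        raise RuntimeError(f"Poisson GLM failed to converge: {exc}") from exc
    if not fit.converged:
        raise RuntimeError(
            f"Poisson GLM did not converge; last params {fit.params.values}")

    fit_naked = sm.GLM(y, X[["const", "x_naked"]], family=fam).fit(
        maxiter=100, tol=1e-10)
    fit_icept = sm.GLM(y, X[["const"]], family=fam).fit(maxiter=100,
                                                        tol=1e-10)
    lrt = max(0.0, 2 * (fit.llf - fit_naked.llf))
    return PoissonRegressionResult(
        params=fit.params, bse=fit.bse, conf_int=fit.conf_int(alpha=0.05),
        llf=float(fit.llf), llf_naked_only=float(fit_naked.llf),
        llf_intercept=float(fit_icept.llf), lrt_stat=float(lrt),
        lrt_p=float(scipy.stats.chi2.sf(lrt, df=1)),
        pseudo_r2=float(1 - fit.llf / fit_icept.llf), nobs=int(y.size))


@dataclass
class EnrichmentResult:
    observed: float          # mutations at query positions
    expected: float          # context-expected mutations at those positions
    fold: float
    n_query: int


def trinuc_enrichment(catalog: pd.DataFrame, genome, query: pd.DataFrame,
                      background_regions: pd.DataFrame) -> EnrichmentResult:
    """Observed over context-expected mutation counts at query positions.

    The expectation is built per pyrimidine-strand-collapsed
    trinucleotide context: background rate = background mutations in
    that context / background occurrences, summed over the query
    positions.  Query positions are excluded from the background.
    Mutations are tumor-count weighted.
    """
    from .synthetic import position_context_codes

    idx = genome.index
    ctx = position_context_codes(genome)

    in_bg = np.zeros(idx.total, dtype=bool)
    for r in background_regions.itertuples():
        off = idx.offsets[idx.slot(r.chrom)]
        in_bg[off + int(r.start): off + int(r.end)] = True

    qpos = np.array([idx.global_pos(c, p) for c, p in
                     zip(query["contig"], query["position"])])
    q_mask = np.zeros(idx.total, dtype=bool)
    q_mask[qpos] = True

    mut = np.zeros(idx.total)
    for m in catalog.itertuples():
        mut[idx.global_pos(m.contig, int(m.position))] += m.tumor_count

    bg = in_bg & ~q_mask & (ctx >= 0)
    occ = np.bincount(ctx[bg], weights=None, minlength=64)
    muts = np.bincount(ctx[bg], weights=mut[bg], minlength=64)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ > 0, muts / np.maximum(occ, 1), np.nan)

    q_ctx = ctx[qpos]
    if np.any(q_ctx < 0):
        raise ValueError("query position with undefined trinucleotide "
                         "context")
    missing = occ[q_ctx] == 0
    if missing.any():
        bad = int(q_ctx[missing][0])
        bases = "ACGT"
        name = bases[bad // 16] + bases[(bad // 4) % 4] + bases[bad % 4]
        raise ValueError(f"context {name} absent from background regions")

    expected = float(rate[q_ctx].sum())
    observed = float(mut[qpos].sum())
    if expected <= 0:
        raise ValueError("expected mutation count is zero; background too "
                         "sparse")
    return EnrichmentResult(observed, expected, observed / expected,
                            int(qpos.size))


def dnase_density(tracks, sites: pd.DataFrame, halfwidth: int = 50) \
        -> np.ndarray:
    """Accessibility density per site: mean per-bp count within
    ``halfwidth`` of the midpoint, computed per dataset and summed
    across datasets (the three-accession convention)."""
    out = np.zeros(len(sites))
    for t in tracks:
        idx = t.index
        for i, site in enumerate(sites.itertuples()):
            off = idx.offsets[idx.slot(site.contig)]
            length = int(idx.lengths[idx.slot(site.contig)])
            lo = max(0, site.midpoint - halfwidth)
            hi = min(length, site.midpoint + halfwidth + 1)
            out[i] += t.data[off + lo: off + hi].mean()
    return out


@dataclass
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def correlate(density, induction, alpha: float = 0.05) -> SpearmanResult:
    """Spearman correlation with a Fisher-z 95% CI."""
    density = np.asarray(density, dtype=float)
    induction = np.asarray(induction, dtype=float)
    n = density.size
    if n < 4:
        raise ValueError("need >= 4 observations")
    rho, p = scipy.stats.spearmanr(density, induction)
    z = np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
    half = scipy.stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return SpearmanResult(float(rho), float(np.tanh(z - half)),
                          float(np.tanh(z + half)), float(p), n)


def mann_whitney(group_a, group_b):
    """Two-tailed Mann-Whitney U.

    Exact enumeration when nA+nB <= 20 and tie-free, otherwise the
    normal approximation with tie and continuity corrections.  Returns
    ``(U_A, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 20 and tie_free) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))
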