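"""Pipeline configuration (YAML) and the end-to-end orchestrator.

One declarative YAML file drives every stage; a single global seed fans
out to per-stage child streams (stable label derivation, so adding a
stage never perturbs earlier streams).  Unknown keys are rejected and
the file round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as uio
from .classify import ClassifierConfig, classify_sites
from .genome import ReferenceGenome
from .induction import (flank_null, hexamer_screen, induction_matrix,
                        motif_profile, scale_naked)
from .lesions import call_lesions, dinucleotide_fractions, write_track
from .motifs import annotate_mutations, scan_genome, tss_distance
from .stats import correlate, dnase_density, fit_poisson_glm, \
    trinuc_enrichment
from .synthetic import (DamageModelParams, make_genome, simulate_dnase,
                        simulate_mutations, simulate_reads,
                        site_damage_sums, variant_cohort_spec,
                        variant_query_positions)
from .tracks import CoverageTrack
from .utils import derive_seed


@dataclass
class CohortConfig:
    n_sites: int = 60
    region_length: int = 720
    bound_fraction: float = 0.65


@dataclass
class StatsConfig:
    flank_window: tuple = (6, 180)
    fold_threshold: float = 2.0
    abs_threshold: float = 50.0
    profile_halfwidth: int = 10
    dnase_rho: float = 0.41


@dataclass
class PathsConfig:
    """External inputs; when unset, the synthetic cohort is generated."""

    genome: str | None = None
    regions: str | None = None
    reads_cellular: str | None = None
    reads_naked: str | None = None
    mutations: str | None = None
    tss: str | None = None
    accessibility: list = field(default_factory=list)


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    damage: dict = field(default_factory=dict)   # DamageModelParams overrides
    stats: StatsConfig = field(default_factory=StatsConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, data, where):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(
                    f"unknown config key(s) {sorted(unknown)} in {where}")
            return klass(**data)

        raw = dict(raw or {})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}")
        cfg = cls(seed=int(raw.get("seed", 0)),
                  damage=dict(raw.get("damage", {})))
        if "cohort" in raw:
            cfg.cohort = build(CohortConfig, raw["cohort"], "cohort")
        if "stats" in raw:
            data = dict(raw["stats"])
            if "flank_window" in data:
                data["flank_window"] = tuple(data["flank_window"])
            cfg.stats = build(StatsConfig, data, "stats")
        if "paths" in raw:
            cfg.paths = build(PathsConfig, raw["paths"], "paths")
        allowed = {f.name for f in dataclasses.fields(DamageModelParams)}
        bad = set(cfg.damage) - allowed
        if bad:
            raise ValueError(f"unknown damage parameter(s) {sorted(bad)}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stats"]["flank_window"] = list(d["stats"]["flank_window"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def damage_params(self) -> DamageModelParams:
        return DamageModelParams(seed=derive_seed(self.seed, "damage"),
                                 **self.damage)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage in dependency order under ``outdir``.

    Inputs listed under ``paths`` are loaded; anything unset is
    generated by the synthetic module.  Re-running with the same config
    and seed reproduces byte-identical outputs.  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.paths

    declared = [p.genome, p.regions, p.reads_cellular, p.reads_naked,
                p.mutations, p.tss, *p.accessibility]
    missing = [str(x) for x in declared
               if x is not None and not Path(x).exists()]
    if missing:
        raise FileNotFoundError(
            "missing input file(s): " + ", ".join(missing))

    params = config.damage_params()

    # --- stage: cohort -------------------------------------------------
    if p.genome is None:
        spec = variant_cohort_spec(
            n_sites=config.cohort.n_sites, seed=config.seed,
            region_length=config.cohort.region_length,
            bound_fraction=config.cohort.bound_fraction)
        genome, regions, truth = make_genome(spec)
    else:
        genome = ReferenceGenome.from_fasta(p.genome)
        regions = uio.read_regions(p.regions)
        truth = pd.DataFrame(columns=["contig", "midpoint", "strand",
                                      "kind", "variant", "bound", "dinuc"])
    genome.to_fasta(outdir / "genome.fasta")
    uio.write_regions(regions, outdir / "regions.bed")

    if p.reads_cellular is None:
        reads_cell = simulate_reads(genome, truth, params, "cellular")
        reads_naked = simulate_reads(genome, truth, params, "naked")
        uio.write_bed6(reads_cell, outdir / "reads_cellular.bed")
        uio.write_bed6(reads_naked, outdir / "reads_naked.bed")
    else:
        reads_cell = uio.read_bed6(p.reads_cellular)
        reads_naked = uio.read_bed6(p.reads_naked)

    # --- stage: lesion calling ----------------------------------------
    cellular = call_lesions(reads_cell, genome, sample="cellular",
                            condition="cellular")
    naked = call_lesions(reads_naked, genome, sample="naked",
                         condition="naked")
    write_track(cellular, outdir / "cellular")
    write_track(naked, outdir / "naked")
    frac = dinucleotide_fractions(reads_cell, genome)
    pd.Series(frac.fractions).rename("fraction").to_csv(
        outdir / "dinucleotide_fractions.tsv", sep="\t")

    # --- stage: scaling + induction -----------------------------------
    info, scaled = scale_naked(cellular, naked, regions)
    sites = scan_genome(genome)
    uio.write_sites(sites, outdir / "ets_sites.tsv")
    variant_sites = (truth[truth["variant"]].reset_index(drop=True)
                     if len(truth) else
                     sites[sites["variant"]].reset_index(drop=True))
    hw = config.stats.profile_halfwidth
    if len(variant_sites):
        profile = motif_profile(cellular, scaled, variant_sites, hw)
        profile.to_csv(outdir / "motif_profile.tsv", sep="\t")
        matrix, ordered = induction_matrix(cellular, scaled, variant_sites,
                                           hw)
        matrix.to_csv(outdir / "induction_matrix.tsv", sep="\t")
        null = flank_null(cellular, scaled, variant_sites, genome,
                          config.stats.flank_window)
        pd.Series({"mu_flank": null.mu_flank,
                   "sigma_flank": null.sigma_flank,
                   "n_positions": null.n_positions}).to_csv(
            outdir / "flank_null.tsv", sep="\t", header=False)
    hexamers = hexamer_screen(reads_cell, reads_naked, genome,
                              scale_factor=info.scale_factor)
    hexamers.to_csv(outdir / "hexamer_screen.tsv", sep="\t")

    # --- stage: mutations + annotation --------------------------------
    if p.mutations is None:
        catalog = simulate_mutations(cellular, scaled, truth, genome,
                                     regions, params,
                                     seed=derive_seed(config.seed,
                                                      "mutations"))
    else:
        catalog = uio.read_catalog(p.mutations)
    catalog = annotate_mutations(catalog, sites)
    if p.tss is not None:
        catalog = tss_distance(catalog, uio.read_tss(p.tss))
    uio.write_catalog(catalog, outdir / "mutations_annotated.tsv")

    # --- stage: regression + enrichment -------------------------------
    results = {}
    if len(variant_sites) >= 3 and len(catalog):
        sums = site_damage_sums(cellular, scaled, variant_sites)
        q = variant_query_positions(variant_sites, genome.index)
        mut_at = {}
        for m in catalog.itertuples():
            mut_at[(m.contig, m.position)] = \
                mut_at.get((m.contig, m.position), 0) + m.tumor_count
        y = np.zeros(len(variant_sites))
        for row in q.itertuples():
            y[row.site] += mut_at.get((row.contig, row.position), 0)
        if y.any():
            glm = fit_poisson_glm(y, sums["x_cell"], sums["x_naked"])
            (outdir / "glm_summary.txt").write_text(glm.summary() + "\n")
            results["beta_cell"] = glm.beta_cell
            results["beta_naked"] = glm.beta_naked
            enr = trinuc_enrichment(catalog, genome, q, regions)
            pd.Series({"observed": enr.observed, "expected": enr.expected,
                       "fold": enr.fold}).to_csv(
                outdir / "trinuc_enrichment.tsv", sep="\t", header=False)
            results["trinuc_fold"] = enr.fold

    # --- stage: accessibility -----------------------------------------
    if len(variant_sites) >= 10:
        from .induction import MATRIX_ORDER_OFFSETS, site_offset_counts
        ind = (site_offset_counts(cellular, variant_sites, hw)
               - site_offset_counts(scaled, variant_sites, hw))
        offs = np.arange(-hw, hw + 1)
        key = ind[:, np.isin(offs, MATRIX_ORDER_OFFSETS)].sum(axis=1)
        if p.accessibility:
            tracks = [CoverageTrack.read_bedgraph(a, genome.index)
                      for a in p.accessibility]
        else:
            _, tracks = simulate_dnase(
                variant_sites, key, config.stats.dnase_rho,
                seed=derive_seed(config.seed, "dnase"), index=genome.index)
            for r, t in enumerate(tracks):
                t.write_bedgraph(outdir / f"dnase_rep{r + 1}.bedGraph")
        dens = dnase_density(tracks, variant_sites)
        sp = correlate(dens, key)
        pd.Series({"rho": sp.rho, "ci_low": sp.ci_low, "ci_high": sp.ci_high,
                   "p": sp.p, "n": sp.n}).to_csv(
            outdir / "dnase_correlation.tsv", sep="\t", header=False)
        results["dnase_rho"] = sp.rho

    # --- stage: classification ----------------------------------------
    cc = ClassifierConfig(fold_threshold=config.stats.fold_threshold,
                          abs_threshold=config.stats.abs_threshold)
    calls, summary = classify_sites(catalog, cellular, scaled, regions, cc)
    out_calls = calls.copy()
    out_calls["pos"] = out_calls.pop("position").astype(int) + 1
    out_calls.to_csv(outdir / "site_calls.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "call_summary.tsv", sep="\t", index=False)

    # --- manifest -------------------------------------------------------
    from . import __version__
    manifest = {
        "version": __version__, "seed": config.seed,
        "config": config.to_dict(), "results": results,
        "outputs": {f.name: _sha256(f)
                    for f in sorted(outdir.iterdir())
                    if f.is_file() and f.name != "run_manifest.json"},
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
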