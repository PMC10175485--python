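# uvhotspot

Targeted UV-damage sequencing (CPD-capture-seq) analysis: from aligned
read positions to single-nucleotide cyclobutane-pyrimidine-dimer (CPD)
lesion tracks, transcription-factor damage-induction statistics, a
Poisson damage→mutation regression, a hexamer sequence-context screen,
and a passenger-vs-driver classification of recurrent melanoma
mutation sites.

## The problem

Recurrent somatic mutations — the same position mutated in many
independent melanomas — are usually read as evidence of positive
selection (driver mutations).  But melanoma mutations are overwhelmingly
caused by UV photoproducts, and bound ETS-family transcription factors
photosensitize specific dipyrimidines in their binding sites, creating
localized CPD hotspots and hence localized mutation hotspots with no
selective advantage.  Capture-based CPD sequencing measures damage
deeply enough at individual sites to tell the two apart: a recurrent
mutation sitting on a strong cellular-specific damage hotspot in an ETS
motif is most parsimoniously a recurrent **passenger**; one without
damage elevation remains a **candidate driver**.

## What the package computes

* **Lesion calling** — each aligned read is assigned to the
  dipyrimidine just past its 5' end on the opposite strand; reads not
  at dipyrimidines are discarded; each retained read counts at both
  lesion bases (`call_lesions`, bedGraph output per strand).
* **Induction** — the naked-DNA control is scaled to equal
  dipyrimidine-read totals within the capture panel; induction =
  cellular − scaled naked, per position, with an empirical flanking
  null (mean/SD at 6–180 bp from site midpoints) for Z-scores
  (`scale_naked`, `motif_profile`, `induction_matrix`, `flank_null`).
* **ETS annotation** — fixed-pentamer scan (TTCCG/CTTCC, both strands),
  midpoint at the first C of the TTCC core, variant sites = pyrimidine
  dinucleotide at offsets −4/−3, mutation overlap at offsets
  {−4, −3, 0, +1} (`scan_ets`, `annotate_mutations`).
* **Statistics** — Poisson GLM
  `log E[mutations] = b0 + b_cell·C + b_naked·N` with LRT and McFadden
  pseudo-R², trinucleotide-context mutation enrichment, DNase-density
  Spearman correlation, Mann-Whitney tests (`fit_poisson_glm`,
  `trinuc_enrichment`, `dnase_density`, `mann_whitney`).
* **Classification** — elevated CPDs (≥2-fold and ≥50-read difference,
  inclusive) plus ETS overlap → `likely_passenger`
  (`classify_sites`).
* **Synthetic cohorts** — a generator producing toy capture panels,
  matched cellular/naked/no-UV read libraries, mutation catalogs and
  accessibility tracks with the statistical structure the analysis
  assumes (`uvhotspot.synthetic`), used by the tests and the
  reproduction script.

## Worked example

Run the whole pipeline on a 60-site synthetic cohort:

```python
from uvhotspot.config import PipelineConfig, run_all

cfg = PipelineConfig.from_dict({"seed": 1, "cohort": {"n_sites": 60}})
manifest = run_all(cfg, "demo_out")
print(manifest["results"])
```

```
{'beta_cell': 0.0010560679947128708,
 'beta_naked': -0.013728332782566377,
 'trinuc_fold': 62.58177330556817,
 'dnase_rho': 0.35565434843011956}
```

and `demo_out/glm_summary.txt` holds the fitted regression:

```
Poisson regression of mutation counts on CPD counts
  n sites: 60
  term              coef     std err      [0.025      0.975]
  const          1.98699       0.112     1.76752     2.20647
  x_cell      0.00105607    0.000116 0.000828059  0.00128408
  x_naked     -0.0137283     0.00146  -0.0165872  -0.0108694
  LRT cellular term: chi2(1) = 107.215, p = 3.99e-25
  pseudo-R2 (McFadden):           0.3754
```

Reading: the cellular CPD coefficient is positive and the naked-DNA
coefficient negative — mutation counts track the *scaled difference*
(damage induction), not raw damageability; the LRT says adding cellular
damage to a naked-only model is a dramatic improvement.  `trinuc_fold`
is the ~60-fold excess of mutations at variant-ETS −4/−3 positions over
their trinucleotide-context expectation, and `dnase_rho` the Spearman
correlation between site accessibility and damage induction (noisy at
60 sites; ~0.41 at full cohort size).  The same stages are available as
a CLI (`uvhotspot simulate | call-lesions | induction | annotate |
fit-glm | enrich | dnase-corr | classify | run-all`); external FASTA /
BED / TSV inputs go through the `paths:` block of the YAML config.

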