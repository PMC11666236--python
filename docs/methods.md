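# Methods

This note documents the models, defaults, and numerical choices behind
`ehtact`, and what the synthetic-data tests do and do not establish about
real data.

## Synthetic data model

All generators are driven by one `SimulationConfig` and a single seeded
`numpy` random stream; identical (config, seed) gives bit-identical output.

**Counts.** UMI counts are gamma-Poisson (negative binomial) with a shared
dispersion (gamma shape) of 10 — mild over-dispersion typical of droplet
data. Marker programs are *additive* mean shifts on a shared per-gene
baseline: the simplest structure under which clustering and marker-panel
annotation are well-posed. There is no batch effect, ambient-RNA
transcriptome, or doublet model (deliberately out of scope), so passing
tests demonstrate the statistics recover planted structure under clean
over-dispersed noise — not robustness to those artefacts.

**Perturbation design.** Four libraries of 2,000 cells (a non-targeting
control line and a 49-guide activation pool, each ± doxycycline) over a
300-gene panel: six endothelial markers (GJA4/DLL4 arterial, NRP2/APLNR
venous, RUNX1/CD44 haemogenic), two pan-endothelial genes (PECAM1/CDH5,
downregulated in EHT cells), nine target TFs, the effector IGFBP2, five
mitochondrial genes, and log-normal background. Planted effects, all
configurable:

* *Activation*: in DOX-induced pool cells, a carried target's mean is
  multiplied by its activation fold (2.0 for eight targets; 1.0 for the
  ZNF124-class null, so its guides are inert).
* *Arterial expansion*: the arterial base fraction (0.15) is multiplied by
  1.63 in the induced control line and 3.33 in the induced pool line, the
  other populations renormalised proportionally. The folds are fractions of
  a fold-expansion read-out, so they scale the base fraction rather than
  absolute counts.
* *Driver enrichment*: in the induced pool library, carriers of
  RUNX1T1-class guides are twice as likely to be arterial as non-carriers,
  with the non-carrier rate renormalised against the realised carrier
  fraction so the library-level arterial fraction is preserved in
  expectation. A side effect of a fixed per-cell guide budget is that other
  targets become *weakly depleted* among arterial cells; the enrichment
  read-out therefore flags "enriched" only when the odds ratio exceeds 1.
* *Effector induction*: IGFBP2's mean is multiplied 3-fold in arterial
  driver-carrier cells of the induced pool library.

**Guides.** The pool has 49 targeting guides (5–7 per target, summing to
49) plus one non-targeting guide. The number of distinct guides detected
per pool cell follows the pmf {1: 0.10, 2: 0.25, 3: 0.30, 4: 0.20, 5: 0.10,
6: 0.05} — the empirical distribution at the experimental multiplicity of
infection is not knowable from a published read-out, so this is a design
choice representing high-MOI infection with imperfect capture, not an
inferred quantity. Truly present guides get capture counts of
`1 + NB(mean 19)` — guaranteed nonzero, so with zero ambient noise and
`min_umi = 1` the decided assignment equals the planted truth exactly, a
property the tests rely on. Ambient noise adds Poisson(0.01) spurious
single-count guide molecules per pool cell.

**QC outliers.** 4% of cells are perturbed into QC-failing states (half
low-coverage at 12% depth, half with 8× mitochondrial load), emulating
damaged cells. QC gates are the same closed-interval rule used on real data
(1,000–7,500 genes, 1–15% mitochondrial) with the gene bounds scaled to the
synthetic panel (13%–85% of panel size; `pipeline.synthetic_qc_for`).

**Reference panel.** Gene-level detection probabilities (fraction of cells
with count > 0) are planted directly and converted to negative-binomial
means by inverting `P(count > 0) = 1 − (r/(r+m))^r`. Nine TFs are planted
at 0.70 detection in aHEC and 0.10 in the in vitro endothelium; decoy TFs
detected everywhere (0.80) or nowhere (0.05) and a strong non-TF haemogenic
marker (CD44) exercise every gate of the selection rule.

**Seahorse.** Per condition, wells carry three phases of three reads with
additive Gaussian noise truncated at zero. Phase means must satisfy
basal ≥ oligo ≥ rot. The effector condition lowers basal ECAR (30 → 18
mpH/min), modelling reduced glycolysis at equal respiration.

**Time course.** The two-timepoint ± effector design reuses the same count
machinery with a condition label: at day 13 the effector multiplies an
oxidative-phosphorylation program 2.5×, glycolytic genes 0.5×, RUNX1 2×,
and DLL4 0.6×; day 10 is untouched.

## Statistical choices

* **Marker/DE test**: two-sided Wilcoxon rank-sum per gene
  (`scipy.stats.mannwhitneyu`), exact when the pooled sample is ≤ 25 cells
  (matching enumeration of the permutation null), tie-corrected normal
  approximation otherwise; BH adjustment throughout. Effect sizes are log2
  ratios of linear depth-normalised means with pseudocount `1/target_sum`
  (default 1e-4), which stabilises ratios of sparsely expressed genes
  without the distortion of a unit pseudocount.
* **Normalisation**: per-cell target sum 10,000 then log1p; raw counts and
  the linear normalised matrix are kept as layers. Detection ("count > 0")
  is always evaluated on raw counts.
* **Clustering**: PCA (arpack, ≤ 30 components) → kNN graph (15
  neighbours) → Leiden (igraph flavour, 2 iterations), all seeded. Under
  cell-order permutation the partition is reproduced up to label renaming
  and floating-point summation order; tests assert adjusted Rand ≥ 0.99.
* **Annotation**: clusters are labelled by the marker panel with the
  highest mean z-scored expression; exact ties go to the earlier panel in
  declaration order (arterial, venous, EHT); repeated winners get `_1`,
  `_2` suffixes.
* **Composition**: per cluster, a cluster-vs-rest × library table is tested
  by chi-square; a 2×2 table with any expected *or observed* cell below 5
  falls back to the two-sided Fisher exact test (larger sparse tables keep
  the chi-square with a logged warning — an exact r×c network algorithm was
  judged out of scope). Because expanding one population necessarily
  shrinks the rest, a significant association alone cannot identify *which*
  cluster grew: the `expanded` flag therefore requires BH-adjusted p < α
  *and* proportion fold-change > 1 between the named comparison pair
  (induced pool vs induced control by default). Both the raw significance
  and the expansion flag are reported.
* **Enrichment**: per target (guides pooled; per-guide mode available),
  two-sided Fisher exact on carriage × cluster membership over kept cells,
  BH across targets, Haldane-corrected odds ratios (0.5 added to all cells
  when any is zero); `enriched` requires adjusted p < α and OR > 1.
* **ATP arithmetic**: implemented exactly as printed, including `MitoPER`
  using total mitochondrial OCR (basal − rot) rather than the ATP-linked
  portion — a known difference from some published conventions, documented
  rather than resolved. ECAR enters the PER as the basal-phase mean. Wells
  violating basal ≥ oligo ≥ rot are flagged and excluded, never clamped;
  no per-cell-count normalisation is applied by default.

## Selection-rule boundaries

Detection-fraction gates are strict inequalities ("more than 50%", "less
than 25%"), QC gates are closed intervals; both boundary behaviours are
unit-tested. Detection fractions are computed within each dataset on raw
counts, so the cross-dataset gates need no integration step; the merge
affects only marker ranking. This is a deliberate simplification: anchors
or other batch-integration methods are out of scope.

## Problem sizes

Multi-seed checks run at the design scale of the study they model: 20 seeds
of the full 4 × 2,000-cell pipeline for effect recovery, 20 + 20 seeds of
the 2,000 + 2,000-cell reference panels for candidate selection and its
null, and 100 seeds of an all-effects-off design at 500 cells/library and a
60-gene panel for type-I calibration of the composition and enrichment
tests (evaluated on the generator's true labels, isolating the tests'
calibration from clustering variability). The exact-test oracle sweep
covers all 46,376 2×2 tables with grand total ≤ 30.

## Known limitations

* The generator's additive marker model and shared dispersion make
  clustering easier than on real data; annotation purity numbers do not
  transfer.
* Guide capture is modelled per-cell i.i.d.; there is no cell-to-cell
  capture-efficiency covariance, which in real screens inflates
  multi-guide dropout.
* Depth normalisation induces small compositional (anti-correlated)
  effects in unperturbed genes of strongly induced cells; visible as weak
  negative DE of background genes in the arterial contrast.
* The composition exact fallback covers only 2×2 tables; with many
  libraries and tiny clusters the chi-square approximation is flagged, not
  replaced.
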