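# Methods

## Coordinate frame and data model

All statistics defined here are transcript-level, so the package works in
transcript space: 0-based, half-open coordinates over the concatenation
5′UTR | CDS | 3′UTR. Annotation is a five-column "GTF-lite" table carrying
only the three segment lengths — strand and exon structure are never
consumed by any statistic, so they are deliberately out of the format.
Coverage is windowed (default 50 nt): RNA is fragmented to roughly 200 nt
before immunoprecipitation, so 50 nt windows give at least four windows per
fragment-scale enriched region. Segment boundaries belong to the downstream
segment everywhere (half-open convention).

## Peak calling

For each acRIP/input library pair, every window is tested one-sided against
a Poisson background:

- λ = (input estimate + pseudocount) × r, p = P(X ≥ acRIP count),
  BH-adjusted across all windows of the pair;
- a window is significant when adjusted p < 0.05 **and** FE > 2 (both
  thresholds configurable; the defaults are the screen this analysis is
  built around);
- significant windows merge into a peak when separated by ≤ 1
  non-significant window; runs with fewer than 2 significant windows are
  discarded, since a ~200 nt enriched fragment must light up several
  adjacent 50 nt windows and isolated single-window excursions are the
  signature of count noise, not enrichment;
- the summit is the start of the member window with the highest acRIP
  count (leftmost on ties); peak p/q are the minima over member windows.

Three numerical choices deserve explanation:

**Background estimate (λ).** The input estimate defaults to
max(window-local count, transcript-wide mean) + pseudocount 1. A purely
window-local estimate is noisy, and that sampling noise inflates the upper
tail of the test: on Poisson-simulated null data at 50 reads/window the
window-local form rejects at 5.4% for a nominal 5%, while the floored form
rejects at 2.4% (conservative, as a screening test should be). Flooring
against a broader rate is also how genome-scale callers behave when local
rate options are disabled. The pseudocount guards λ = 0 and infinite FE.
Both alternatives (`background="window"` / `"transcript"`) remain
available.

**Scale factor (r).** The acRIP:input ratio defaults to the median
per-window count ratio rather than the total-library-size ratio
(`normalization="background"` vs `"library"`). The two differ whenever the
amount of true signal differs between samples: a condition with strongly
boosted peaks carries more acRIP library mass, and dividing by library
totals then deflates *every* FE in that sample — in simulations with a 3×
day-6 effect this compressed the measured transcript fold change from the
expected ~2.7 to ~1.9 and halved recovery of the affected set. The median
window ratio tracks the non-enriched background, which is what the scaling
is meant to equalise; composition-robust normalisation (edgeR's TMM is the
canonical example) exists for exactly this reason. `raw_fe=True` skips
scaling entirely.

**Peak FE.** The FE attached to a peak is computed from the summed counts
of a fixed-width core around the summit (summit window ± 1, clipped to the
peak). A full-span FE is biased against strong peaks: their
partially-covered edge windows also pass the screen, the called span
widens, and the span average dilutes toward background — weak peaks keep
narrow spans and suffer no dilution, so between-condition ratios compress
asymmetrically. A summit-only FE is width-invariant but rests on a single
overdispersed window (CV ≈ 32% at the default dispersion). The fixed
three-window core is both width-invariant and averaged.

## Replicate consensus and reliability

Peaks from different replicates on the same transcript are clustered by
single-linkage with ≥ 1 nt overlap; the cluster interval is the union span,
its support is the number of distinct replicates contributing, and clusters
with support ≥ 2 (of 3) are the reliable set. The consensus FE is the mean
of member-peak FE values across replicates (pooling raw counts across
replicates is the alternative; averaging keeps replicates exchangeable and
weights them equally regardless of depth). For pooled single-library
designs, consensus filtering is skipped and peaks pass through with
support 1, flagged in the run report. Low-input synaptosome data can
additionally be filtered to transcripts present in ≥ 2 of ≥ 3 reference
synaptosome lists (`syn_reliability_filter`).

## Transcript-level statistics and classification

- ΣFE ("FE of ac4C"): arithmetic sum of peak FE over the whole transcript,
  UTRs included. Transcripts without peaks carry an explicit zero record.
- FC = (ΣFE_case + 1)/(ΣFE_ref + 1). The +1 pseudocount keeps FC finite
  when the reference has no acetylation; the transcript universe is the
  union of both sides with the missing side at ΣFE = 0.
- MISA rule: FC > 2 at day 6, FC ≤ 2 at days 1 and 20 — strict at day 6,
  non-strict at the flanking days, matching the asymmetric phrasing of the
  day-6-specific upregulation criterion. A time point missing from the
  input defaults to FC = 1 (no evidence of change); `strict=True` excludes
  incomplete transcripts instead.
- NASA rules, applied to every transcript acetylated in control:
  *diminished* when ΣFE_cko < 1 or no reliable knockout peak survives;
  *downregulated* when still detectable (ΣFE_cko ≥ 1) but
  (ΣFE_ctrl + 1)/(ΣFE_cko + 1) > 2 — the attenuation branch is only
  described qualitatively ("significantly reduced but still detectable"),
  so it is operationalised with the same pseudocount-FC machinery and
  cutoff as the MISA rule; *unchanged* otherwise. The three categories are
  disjoint and exhaustive; NASA = diminished ∪ downregulated.

## Metagene, region test, distributions

Peaks are assigned to UTR5/CDS/UTR3 by summit position only (a peak
spanning a boundary contributes to exactly one region); metagene profiles
bin the summit's fractional position within its region, 30 bins per region,
normalised to total density 1. The summit-region chi-square compares
observed region counts with expectation proportional to aggregate region
lengths (2 df; empty regions collapse, and a single surviving region skips
the test with an explicit status). TPM follows the standard
rate-normalised definition with detection at TPM > 1 and log2 TPM reported
for positive values. Two-sample KS tests use the exact null distribution
below a combined n of 50 and the asymptotic one above; when a family of KS
comparisons is reported together, BH-adjusted values are emitted alongside
the raw ones. Quartiles use the type-7 (linear interpolation) convention.

## Motif enrichment

Candidate motifs are exact k-mers (default k = 8, guard at k ≤ 12). Each
k-mer is ZOOPS-counted (a sequence contributes at most once) in foreground
and background, scored by the upper-tail hypergeometric probability of the
foreground count in the pooled collection, and BH-corrected across all 4^k
candidates; ties sort lexicographically. Without an explicit background, a
first-order Markov resample of each foreground sequence (dinucleotide
frequencies preserved in expectation) serves as background. Degenerate
IUPAC queries are supported in matching (`zoops_count`) but not discovered
de novo, and reverse-complement collapsing is off by default because an
RNA modification is strand-defined.

## Synthetic experiments

`SimConfig` defines a complete scenario; generation is a pure function of
the config (same seed → bit-identical output), with independent noise
streams per library spawned deterministically. Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| n_transcripts | 1000 | study scale for recovery experiments |
| segment lengths | gamma, means 150/1500/800 nt | typical mRNA architecture |
| window_size | 50 nt | ≥ 4 windows per 200 nt fragment |
| n_replicates | 3 | the 2-of-3 reliability design |
| mean_input_depth | 50 reads/window | recovery-scenario depth |
| dispersion | 10 (NB); None → Poisson | over-dispersion stresses the Poisson caller; the caller's Poisson assumption is a modelling choice, not a property of data |
| acrip_background_ratio | 0.25 | IP depletes unmodified RNA |
| acetylated_fraction | 0.55 | roughly half of detected mRNAs acetylated |
| peak_rate | 1.8 | ~1.8 peaks per acetylated transcript |
| peak width | 200 nt ± 25% | fragment scale |
| cds_placement_bias | 0.8 | CDS-dominant placement |
| baseline_enrichment | 6 | peak FE comfortably above the FE > 2 screen at this depth |
| misa_fraction | 0.30 | ~⅓ of acetylated transcripts memory-responsive |
| misa_effect | 3 | scenario effect size; the real effect is only known as a distribution shift |
| nat10_dependent_fraction | 0.85 | most acetylation writer-dependent |
| cko_diminish_prob / cko_attenuation | 0.75 / 0.4 | abolition : attenuation roughly 3:1 |
| expression_sd | 0.5 (log-normal) | between-transcript abundance variation |

Planted peaks are placed ≥ 4 windows apart so that edge-window bleed
cannot merge two true peaks into one called peak, and the target region
(CDS vs UTR) is drawn once per peak before placement attempts so that
overlap rejection in a crowded CDS cannot spill draws into the UTRs and
erode the configured placement bias. An unplaceable peak is dropped.

The generator emulates: segmented transcripts, fragment-scale peaks with
CDS bias, replicate-level NB/Poisson noise, between-transcript expression
variation, a day-6-only multiplicative memory effect on a designated
subset, and knockout abolition/attenuation on a writer-dependent subset.
It does **not** emulate read-level effects (mappability, GC and positional
coverage bias, duplicate reads), isoform structure, between-replicate
batch effects, or sequence-dependent antibody affinity — so passing
recovery tests demonstrates correctness of the statistical machinery under
the stated noise model, not robustness to every artefact of real
libraries.

## Problem sizes and determinism

Recovery experiments run at 1000 transcripts × 3 replicates × 6
condition/time-point cells; calibration studies use 100 seeded simulations
of 25–30 transcripts for the window-level null, 1000 trials of n = 500 for
KS calibration, and 20 seeded runs for the motif null — sizes chosen so
the whole suite completes in a few minutes on one core while keeping
Monte-Carlo error well inside the asserted bounds. The orchestrated run is
a pure function of (inputs, parameters): reports carry no timestamps and
rerunning on identical inputs is byte-identical.

## Known limitations

- Genomic coordinates and lift-over are out of scope; peaks live on
  transcripts.
- The Poisson window test is anti-conservative on strongly over-dispersed
  data by construction; the screening thresholds and the 2-of-3 replicate
  rule absorb this in practice, and the type-I guarantee is stated (and
  tested) for Poisson-generated data only.
- Peak boundaries are window-quantised; sub-window summit localisation is
  not attempted.
- De novo motif discovery is fixed-length exact-match; degenerate motifs
  can be matched but not discovered.
- The mitochondrial/lncRNA exclusion the analysis design calls for is
  implemented as a user-supplied identifier list, since the annotation
  format carries no biotype.
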