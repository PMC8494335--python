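# Methods

## Scope and data model

`irmut` analyses lists of called germline mutations from clonal *C. elegans*
lines exposed to ionizing radiation (IR). Each line is one sample: a genotype
(wild-type or a DNA-repair mutant), a dose in Gray, and a replicate index.
Coordinates are 1-based inclusive throughout. Indels are normalized to an
unanchored internal form (ref = deleted bases, alt = inserted bases) by
left-trimming the shared VCF anchor, because classification operates on pure
event lengths. Multi-allelic VCF lines are split into one record per ALT;
DELLY-style breakend pairs are treated as one event per BND record, with
intra-chromosomal breakends mapped to TRSL and inter-chromosomal ones to
INTCHR.

## The 119-channel scheme

96 SNV channels follow the COSMIC pyrimidine-centered convention (6
substitution types × 16 flanking contexts; purine-reference substitutions are
reverse-complemented together with both flanks). One DNV and one MNV
aggregate channel cover di- and ≥3-base equal-length substitutions. Indels
occupy 14 channels: deletions and insertions in size bins {1, 2–5, 6–50,
51–400, >400 bp} and deletion-with-insertion (delins) events binned by
deleted length {1–5, 6–50, 51–400, >400 bp}. The published class totals fix
96 + 14 + 7 with DNV/MNV counted as distinct substitution types; the exact
bin edges above 50 bp are this package's convention. Seven SV channels hold
TD, DEL, INV, COMPLEX, TRSL, INTCHR and FOLDBACK. SNVs at chromosome
boundaries or with N in their context have no defined channel; they are
routed to an `unclassified` bucket so that classified + unclassified always
equals the input count.

## Dose-response rates

Per-class rates come from identity-link additive Poisson regression,
`count_i ~ Poisson(b + r·dose_i)` with `b, r ≥ 0`, maximized with a
boundary-aware quasi-Newton optimizer (analytic gradient, multi-start).
The additive (not log-link) mean is deliberate: IR adds mutations on top of a
dose-independent background, and the signature model below shares this
structure. Standard errors come from the observed Fisher information at the
MLE; at a boundary (b = 0 or r = 0) the profile curvature of the free
parameter is used and the fit is marked degenerate when all counts are zero.
Rates are reported per 80 Gy, the design's maximum dose.

The dose-dependence screen computes, per genotype, Pearson r and its
two-sided p between per-sample class totals and dose for the three reporting
classes (substitutions = SNV+DNV+MNV, indels, SVs). A genotype passes when at
least two classes show a significant positive correlation. The significance
threshold (default α = 0.05) and the required number of classes (default 2)
are exposed as options, since only the criterion itself — not its α — is
fixed by the analysis design. Genotypes failing the screen are excluded from
signature fitting by the pipeline (override available).

## Hierarchical signature model

For genotype g, per-channel sample counts follow
`Y_gk ~ Poisson(G_gk + (dose/80)·IR_k·exp(LFC_gk))` with wild-type LFC pinned
at zero. Dose is scaled by 80 internally so `IR` is directly "per 80 Gy".

Priors, and why they look the way they do:

- `G_gk` (background per sample): half-normal with scale
  `max(2·T_g/119, 0.02)` where `T_g` is the genotype's mean total burden at
  its lowest dose. The scale matters: 119 weakly-identified non-negative
  parameters under a flat-ish prior would each carry ~1/n of posterior mass
  above zero and jointly absorb a visible share of the dose-dependent signal.
- `IR_k`: sampled on the log scale with a lognormal prior centered on the
  crude moment estimate of the mean channel rate (sd 2 on the log scale,
  ≈ two decades). A flat-in-rate prior adds one pseudo-count per channel to
  the conditional Gamma shape; summed over 96 SNV channels that inflates the
  fitted signature total by tens of percent at worm-scale counts. The
  scale-type prior removes this.
- `LFC_gk ~ N(mu_gc, tau_gc)` hierarchically within each mutation class c,
  with `mu_gc ~ N(0, 2)` and `tau_gc` learned under a conjugate inverse-gamma
  prior centered on 0.3. The class mean absorbs a genotype-wide fold-change
  and is informed by class-total counts (so a 2-fold effect is recovered
  without per-channel shrinkage bias), while the learned spread lets a
  genotype whose signature genuinely tilts within a class escape the
  shrinkage.

Inference is a seeded, vectorized Metropolis-within-Gibbs sampler. The
likelihood factorizes over channels, so all 119 channels take their
random-walk proposals simultaneously with per-channel accept/reject; the
class-level means and spreads have conjugate Gibbs updates. Three additional
moves target known slow directions of this posterior: a joint translation of
`(mu_gc, LFC_g·)` per genotype × class (the class-level fold-change), a joint
per-class rescale of IR (the class-total rate), and a complementary move that
rescales a class's IR while counter-shifting every mutant's LFC so that only
wild-type predictions change. Step sizes adapt toward 35% acceptance during
warmup only, preserving detailed balance afterwards. Defaults: 4 chains,
1000 warmup + 1000 draws, all exposed in `SamplerSettings`. Convergence is
monitored on the per-genotype class-total rates (split-R̂ ≤ 1.1, ESS ≥ 100);
fits failing either are flagged and refused by downstream consumers.

Genotype comparisons use `z = (r_g − r_wt)/√(SE_g² + SE_wt²)` — on posterior
draws of class-total rate differences for a fitted model, or on two additive
Poisson rate estimates — with two-sided normal p-values and
Benjamini–Hochberg adjustment across the genotype × class family (q < 0.05).
Profile divergence is the cosine distance between `IR·exp(LFC_g)` and `IR`,
reported at the posterior mean with a 95% interval from paired draws; a
profile is flagged "significant" when any of the genotype's class comparisons
has q < 0.05, a documented convention.

## Clustered mutations

Cluster input is the start points of all substitutions and indels (SVs
excluded). The window caller returns maximal runs of ≥ 2 positions in which
every consecutive gap is ≤ 1000 bp — the connected components any fixed
1000-bp window scan would link, with no extra parameter. Clusters are called
per sample by default (a physical cluster cannot span animals); a pooled
per-genotype mode is available for fidelity with analyses that pool samples.
The HMM caller Viterbi-decodes a two-state chain over inter-mutation gaps
with geometric emissions; transition probabilities default to 0.1
(non-clustered → clustered) and 0.01 (reverse), and emission means default to
100 bp (clustered) and genome_length/n_mutations (background) — the emission
family and means are this package's choice and configurable.

Summaries per genotype report clusters per genome per 80 Gy (additive Poisson
fit of per-sample cluster counts on dose), the clustered proportion, and
median/IQR of spans and sizes. The clustered proportion's dose trend is
fitted by OLS (`P ~ dose + ε, ε ~ N(0, σ²)`), and genotype-vs-wild-type
clustering differences use the same z-test + BH machinery as the rates.

## Humanization

Trinucleotide frequencies of a genome are counted over all overlapping
windows (skipping any window containing N), collapsed to the 32
pyrimidine-centered contexts, and normalized. A spectrum is adjusted between
genomes by multiplying each SNV channel by the target/source frequency ratio
of its context and renormalizing; this is the standard signature-translation
convention (cosine similarity is scale-invariant, so renormalization does not
affect downstream comparisons). When a full 119-vector is supplied only the
96 SNV channels are reweighted. A context with observed mutations but zero
source frequency is an error. Frequency tables are computed from
user-supplied FASTAs; nothing is bundled and no download is required.

## Synthetic data generator

The generator emulates the study design, not sequencing: per sample it draws
channel counts from Poisson(background + (dose/80)·IR·exp(LFC)) and realizes
them as concrete records on a toy genome (default 5 × 1 Mb of i.i.d. uniform
bases — small enough for desk-scale runs, large enough that all 32 contexts
are abundant). SNV positions are sampled from a precomputed index of context
positions, so context and channel are consistent by construction; indel and
SV lengths are drawn uniformly within their bins; inter-chromosomal SVs pick
two distinct chromosomes. A configurable fraction of substitution/indel
events (default 6%) is re-placed into clusters of 2–3 mutations spanning
10–20 bp; clustered substitutions keep their pyrimidine-centered substitution
type (the nearest matching base within the span is used) while their
flanking context is re-read from the genome at the new position, so the
emitted record always classifies to a channel consistent with its sequence.
Default per-80-Gy class totals are the wild-type study conditions: 36.63
SNVs spread flat over the 96 channels, 1.3 DNVs, 0 MNVs (no separate MNV
rate is established for wild-type; the channel exists and is exercised by
mutant configurations), 4 indels and 1.4 SVs spread flat within class. The
dose-0 background is a flat vector totalling 1 mutation per genome, a
documented convention. Output is deterministic given the seed, down to
byte-identical VCFs.

What the generator does *not* emulate — sequencing noise, calling/filtering
artifacts, heterozygosity, selection against lethal genotypes, and realistic
genome composition (the toy genome has uniform trinucleotide frequencies) —
bounds what passing tests show: they validate the statistical machinery under
the stated generative model, not robustness to real-data artifacts upstream
of variant calls.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's own design scale
(15 samples per genotype; 10 per genotype for two-genotype model fits) with
reduced sampler budgets (2 chains × 500–800 draws) chosen so the full suite
completes in about a minute while keeping monitored ESS above the flagging
floor; the acceptance script uses the full 4 × 1000 + 1000 sampler. Cluster
rate summaries average 500 simulated genomes. Monte-Carlo tolerance choices
(3–4 standard errors, 3σ fold-change bands for ~20-count classes) follow the
statistics of the quantity tested rather than fixed percentages. Poisson
likelihood terms use a 1e-300 floor inside logs so zero means with zero
counts contribute exactly −mean; ties in sorting are broken by (ref, alt) to
make outputs total-ordered and byte-reproducible.

## Known limitations

- The HMM emission family (geometric) is a modeling convenience; only the
  transition probabilities are anchored in the analysis design.
- The signature model assumes Poisson (no over-dispersion) counts, matching
  the analysis it implements.
- Channel-level fold-changes for channels with expected counts ≪ 1 are
  prior-dominated; only class-level aggregates are well identified at
  worm-scale burdens.
- The humanization step translates composition, not selection or chromatin
  effects; comparisons against external catalogues inherit those caveats.
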