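# Methods

## Scope and data model

`mirswitch` analyses small-RNA sequencing data from cells carrying Dicer
RNase III domain mutations, together with matched AGO-IP, RNA-seq and CLASH
libraries. All coordinates are 0-based half-open on the hairpin written
5′→3′. A hairpin annotation carries the 5p-arm, loop and 3p-arm intervals
(arms 18–25 nt, loop ≥ 4 nt), a declared duplex pairing register with 2-nt
3′ overhangs on both strands, and RNA alphabet (DNA input is transliterated
silently; mixed T/U is rejected). Mature species are identified as
`<hairpin>-5p`, `-3p`, `-5pLoop` and `-3pLoop`.

## Read classification

Reads are matched to hairpins by exact substring comparison with at most one
mismatch, anchored at candidate start positions within ±2 nt of the
annotated arm starts (an isomiR-tolerant approximation of collapsed
canonical counting; both the end tolerance and the mismatch budget are
configuration). Classes: FIVE_P / THREE_P when both ends fall within the
tolerance of the arm boundaries; FIVE_P_LOOP when the 5′ end matches the 5p
arm but the 3′ end runs ≥ 3 nt into the loop — the 3-nt floor separates true
nicked-precursor intermediates from templated 3′ additions; THREE_P_LOOP is
the symmetric class for RNase IIIa-mutant products. Everything else is
UNASSIGNED and tallied per sample, so class counts + UNASSIGNED always equal
the input read count exactly.

Normalization: total-RNA libraries are scaled so each sample's spike-in sum
equals the across-sample mean spike-in sum (anchoring to the mean rather
than a reference sample makes the result invariant to sample order, and
rescaling the recorded spike counts alongside makes the operation
idempotent). AGO-IP libraries are scaled to counts per million assigned
miRNA reads, since IP material contains no spike-ins.

## Strand selection and the loading model

Guide calling uses the conventional rule: the arm with **>70%** of the
duplex's mean normalized WT reads **and >100** mean reads is the guide
(both boundaries exclusive, applied to the mean over WT replicates); the
other arm is the passenger; duplexes satisfying neither are excluded from
guide/passenger contrasts.

Each strand's 5′-end score is `s = w(nt5) + γ·ΔG3`. ΔG3 sums the
nearest-neighbor stacking free energies of the two stacks formed by the base
pairs at strand positions 1–3; the Watson–Crick stacking table (Turner-2004
style values, 37 °C) ships in `_nn.py`. Positions that are unpaired in the
declared register, or not Watson–Crick complementary (including G·U wobble),
contribute zero and are flagged. The score weights (w_A = w_U = 1,
w_G = w_C = 0, γ = 0.25 per kcal/mol) are configuration: the published
asymmetry-score coefficients are not reproduced here, so the defaults are
chosen to preserve the qualitative ordering (A/U 5′ ends and weak terminal
pairing favor loading) rather than to claim calibrated coefficients.

Loading (logistic σ, all parameters configurable):

* duplex — the strands compete: `p5 = L·σ(Δs/τ)`, `p3 = L·σ(−Δs/τ)`,
  so at most one AGO loading per duplex event (L = 1 by default);
* 5p-nicked precursor (IIIb mutant product) — `p5 = 0` exactly (the 3′ end
  is covalently joined to the loop); the free 3p strand loads on its own
  score, `p3 = σ((s3p − s0)/τ)`, independent of s5p;
* 3p-nicked precursor (IIIa mutant product) — `p3 = 0` exactly (the loop
  blocks the 5′ end at the MID domain); the free 5p strand is additionally
  attenuated by non-covalent occlusion of its 3′ end,
  `p5 = (1−κ)·σ((s5p − s0)/τ)`.

Defaults τ = 0.25 score units, s0 = −0.8, κ = 0.9. The midpoint s0 sits
near the score of a typical weak (G/C-start) strand. That placement encodes
two observations at once: a guide 3p strand loads about as well from a
nicked precursor as from its duplex (its usual 5p competitor scores that
low anyway), while a high-scoring passenger 3p strand — freed from a strong
competitor — loads far better. τ is comparable to the score gap between
A/U-start and G/C-start strands, which makes strand switching selective for
favorable 5′ ends instead of uniform across all passengers.

Strand-switch detection runs Welch's unequal-variance t-test (two-sided) on
all 3p species between genotypes, adjusts with Benjamini–Hochberg, and
flags passenger 3p species with log2FC > 1 and q < 0.05.

## Enrichment, correlation and shift statistics

AGO enrichment is `E = (mean IP + c)/(mean input + c)` with pseudocount
c = 1 normalized unit (replicate means first, then the ratio — stabler at
low counts than averaging per-replicate ratios). Correlations between
enrichment and strand scores use log E, since E is a ratio; Pearson R² and
two-sided p via the exact t distribution. Distribution-shift tests are
one-sided two-sample Kolmogorov–Smirnov with the direction always given
explicitly by the caller. For n_fg + n_bg ≤ 16 the exact permutation null is
used (verified identical to exhaustive enumeration over all group
assignments); above that, a continuity-corrected asymptotic tail
`exp(−2·ne·(D + 1/(6·ne))²)` with `ne = mn/(m+n)`, which tracks the exact
null to ≈ 0.005 mean absolute error at moderate sizes where the plain
asymptotic formula understates p by ~20% relative.

## Target classes

Predictions (TargetScan-style miRNA/gene/context-score rows) are filtered
to each miRNA's strongest 10% of targets (most negative context scores,
ties broken by gene id), then genes in the top and bottom 25% of the
WT-expression ranking are removed. Per gene, cumulative targeting
abundances are summed by regulator class (5p, guide 3p, passenger 3p) from
WT and mutant mean normalized miRNA counts. A gene is a **5p-target** when
5p targeting exceeds all 3p targeting in WT, and a **passenger-3p-target**
when the passenger-3p gain (HM − WT) exceeds the 5p loss (WT − HM); a gene
satisfying both goes to passenger-3p-target so the two contrast sets stay
disjoint; strict inequalities throughout. Each category's RNA-seq
fold-change distribution is tested against the NEITHER background:
5p-targets for an upward shift, passenger-3p-targets for a downward shift.

## CLASH hybrids

Chimeras are miRNA-first (the miRNA's 3′ end ligates to the target's 5′
end, per the intermolecular ligation chemistry); reversed-orientation reads
are not called. A callable read is ≥ 36 nt: the longest mature-miRNA prefix
(≥ 16 nt, ≤ 1 mismatch, found via exact 8-mer anchor lookup) followed by an
ungapped UTR match (≥ 18 nt, ≤ 2 mismatches, seeded by exact 12-mers).
Records are annotated with the canonical site type (8mer > 7mer-m8 >
7mer-A1 > 6mer > none, judged from miRNA positions 2–8) and filtered
against the prediction table — the stated false-positive control — so
detection can keep seed-less records visibly annotated. Summaries report
per-sample arm fractions, the passenger share of 3p hybrids, and per-miRNA
hybrid counts normalized to total-RNA expression.

## The simulator

The generator produces every data type with full ground truth. Catalogs:
paired length 18–21 nt + 2-nt overhangs, loops 12–18 nt, arms ≥ 80%
Watson–Crick paired with ~10% sprinkled internal mismatches; 5′-terminal
nucleotides sampled uniformly (partners forced complementary; the first
three pairs are never mutated) so scores span their range and both guide-5p
and guide-3p duplexes occur.

Per hairpin: transcription rate λ ~ lognormal(0, 0.7); intermediate
detectability s_int ~ Beta(0.3, 0.3) — strongly bimodal, reproducing the
observation that only some 5p+loop intermediates survive library
construction (modeled as detectability without a mechanistic claim); and a
duplex-competition offset η ~ N(0, 1.0 score units) added to Δs. η
represents strand-selection determinants beyond the scored 5′-end features;
without it, strand identity would be a deterministic function of the
scores, and conditioning on "guide = 5p" would induce an artifactual s5p–s3p
correlation in the passenger subset that real duplexes do not show. Nicked
loading carries no offset, so mutant 3p loading remains a clean function of
the 3p-score.

Expected abundances per genotype (ρ = 5 protection multiplier for loaded
strands, δ = 0.5 survival for unloaded strands):

* WT / HetKO: duplex products; each strand's abundance is
  λ·(p·ρ + (1−p)·δ). HetKO is identical to WT by default (Dicer dosage is
  compensated); a dosage knob exists but defaults off.
* IIIb mutant (HM): a residual fraction ε = 0.02 of precursors is processed
  as duplex (residual 5p cleavage); the remaining 1−ε yield a free 3p strand
  loaded at σ((s3p−s0)/τ) plus a 5p+loop intermediate surviving with
  probability s_int.
* IIIa mutant: 3p+loop intermediates plus occluded free 5p strands; no
  residual channel.

With these defaults the planted switch effects span roughly 4–12×, guide-3p
species stay within ±0.5 log2, and free 5p species drop by log2(ε) ≈ −5.6.
Per hairpin, the summed strand abundance never exceeds λ·(ρ+1) — one loaded
strand (×ρ) plus one unloaded strand surviving at most fully — and in the
neutral limit ρ = δ = s_int = 1 the mutant's expected 3p abundance equals
WT's exactly.

Counts are negative binomial (var = m + φm², shared φ = 0.1) around
expected abundances times a per-library size factor with lognormal jitter
(σ = 0.15); expected depth 10⁶ reads per total library, 5×10⁵ per AGO-IP
library (IP counts sample loaded-RISC abundance only). Spike-ins are eight
defined oligos spanning a 128× ladder drawn with Poisson noise only — they
are synthetic molecules with no biological dispersion, which is what makes
spike normalization informative. Setting `noise=False` replaces draws with
rounded expectations ("deterministic loading" conditions for
score-recovery measurements).

Transcriptome: each of 500 genes gets 1 + Poisson(0.7) predicted
regulators with context scores −|N(0.4, 0.2)| (clipped to [−1.2, −0.05]);
affinity = |context score|. Gene mean = lognormal baseline ×
exp(−r·Σ a·loaded/mean WT loaded) with r = 1.5, i.e. a strong single site
from an average-abundance loaded miRNA represses ~0.5–1 log2 — NB counts as
above. CLASH reads: hybrid frequency ∝ loaded abundance × affinity; each
chimera is the full mature miRNA + a 20–40-nt UTR fragment containing its
planted 8mer site (synthetic UTRs are random sequence with one planted site
per predicted interaction); 20% background (random inserts and unligated
mature miRNAs).

What the generator does **not** emulate: real hairpin secondary structure
(pairing is catalog-declared, no folding), 5′ isomiR fidelity shifts,
sequencing error within reads, UMI/adapter artifacts, paralogous miRNA
families with near-identical sequences, or correlated biological replicates.
Passing recovery tests therefore demonstrates the statistical machinery and
the mechanism's identifiability under the stated noise model — not
robustness to mapping ambiguity or real-library artifacts.

## Verification runs and problem sizes

The recovery measurements in `mirswitch.evaluation` (reported by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`) use:
200 hairpins × 6 replicates per genotype for the 5p-loss and switch-F1
runs; 250 hairpins (→ ~100 passenger species) with noise-free counts for
the score–enrichment correlations; 500 genes × 6 replicates for the target
shifts, with 50 null seeds for their calibration; 50,000 CLASH reads per
genotype; 50 WT-vs-WT splits for Welch/BH calibration; exhaustive
enumeration (126 assignments) and a 4,000-draw Monte-Carlo permutation null
for the KS oracles; and the full 301² integer grid for the guide-rule
oracle. These sizes make each measurement stable to seed choice while the
whole verification completes in about a minute.

## Numerical and degenerate-input conventions

Zero-expression duplexes get `guide_arm="none"` with an explicit flag;
zero-variance Welch tests with equal means give p = 1 by convention (and
p = 0 when means differ); enrichment of species with zero IP and input is
pseudocount-limited to 1 and flagged low-evidence rather than dropped
silently; undefined hybrid fractions (no hybrids) are NaN with
`defined=False`; prediction-filter ties break lexicographically by gene id;
stochastic stages require an explicit seed (no wall-clock seeding), and a
run log with seed, parameters and package version is always written.

## Known limitations

The asymmetry-score coefficients are package defaults, not the published
calibration; absolute loading probabilities are therefore
order-preserving rather than quantitative. AGO slicing-dependent passenger
ejection (which bypasses unwinding) is not modeled. The prediction filter
assumes per-miRNA target lists; a pooled alternative is available by flag.
The CLASH caller is ungapped and will miss hybrids whose target fragment
carries indels.
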