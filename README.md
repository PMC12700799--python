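# mirswitch

Analysis pipeline for **miRNA arm switching under Dicer RNase IIIb hotspot
mutations**, with a fully seeded simulator of the underlying biogenesis and
AGO-loading mechanism.

## The problem

Dicer's two RNase III domains cleave the two arms of a pre-miRNA hairpin:
RNase IIIa cuts the 3p arm, RNase IIIb the 5p arm, releasing a ~22-nt duplex
with 2-nt 3′ overhangs. Cancer-associated hotspot mutations inactivate RNase
IIIb, so the mutant enzyme produces a *nicked precursor*: a free 3p strand
plus the 5p strand still covalently joined to the terminal loop (a 5p+loop
intermediate). The consequence is not just loss of 5p-miRNAs. Because AGO
needs access to both ends of a strand to load and unwind it, the loop-blocked
5p strand can never be loaded — and 3p strands that were *passengers* in
wild-type cells (ejected after losing the duplex competition) are loaded as
functional guides when the competition disappears. Which passengers switch is
predicted by their own 5′-end features.

`mirswitch` implements that analysis end to end for anyone working with
small-RNA-seq, AGO-IP, RNA-seq and CLASH data from Dicer-mutant systems:
spike-in-normalized quantification of 5p / 3p / 5p+loop read classes,
guide/passenger calling, 5′-end asymmetry scoring, a quantitative
end-accessibility loading model, strand-switch detection, target-set
distribution tests and chimeric-read (CLASH) hybrid calling. A synthetic-data
module generates all of these data types with known ground truth, so every
stage is verifiable without any external sequencing data.

## The model

Each strand of a duplex gets an asymmetry score from its 5′-end features:

```
s = w(nt5) + γ · ΔG3
```

where `nt5` is the 5′-terminal nucleotide (defaults w_A = w_U = 1,
w_G = w_C = 0), `ΔG3` is the nearest-neighbor stacking free energy
(kcal/mol) of the first three base pairs at the strand's 5′ end, and
γ = 0.25 per kcal/mol. Loading probabilities by substrate form:

| substrate | p(load 5p) | p(load 3p) |
|---|---|---|
| intact duplex | σ(Δs/τ) | σ(−Δs/τ) |
| 5p nicked to loop (IIIb mutant) | **0** (3′ end covalently blocked) | σ((s3p−s0)/τ) |
| 3p nicked to loop (IIIa mutant) | (1−κ)·σ((s5p−s0)/τ) | **0** (5′ end blocked at MID) |

with Δs = s5p − s3p, logistic σ, temperature τ, single-strand midpoint s0
and loop-occlusion κ. The hard zeros are the mechanism's signature: a
loop-attached strand never loads, and for nicked precursors the free
strand's loading depends on *its own* score only.

Downstream rules follow the field's conventions: guide = arm with >70% of
duplex reads and >100 reads in WT; total-RNA libraries normalized to
spike-ins, AGO-IP libraries to total miRNA; AGO enrichment E = IP / input;
Welch's t with Benjamini–Hochberg for differential expression; one-sided
Kolmogorov–Smirnov for target-set shifts (exact null for small samples).

## Worked example

Run the full simulated pipeline (WT vs hotspot-mutant, 120 hairpins, 6
replicates per genotype):

```python
from mirswitch.pipeline import run_pipeline

res = run_pipeline({
    "seed": 11, "out_dir": "demo", "n_replicates": 6,
    "clash_reads": 20000, "params": {"n_hairpins": 120, "n_genes": 300},
})
sw = res["strands"]["switch"]
print(sw[sw["switched"]].sort_values("log2fc", ascending=False).head(3))
```

prints the top strand-switched passenger 3p-miRNAs:

```
            log2fc      q strand_class
species_id
hp0113-3p    3.601  0.003    passenger
hp0097-3p    3.489  0.002    passenger
hp0025-3p    3.370  0.002    passenger
```

36 passenger 3p species are flagged as switched (log2FC > 1 at q < 0.05,
i.e. the 4–12× upregulation band), and none of the guide 3p species. The
run directory also contains the AGO-enrichment correlations — in the mutant,
log enrichment of passenger 3p species tracks the 3p-score (R² = 0.60) far
more than the 5p-score — the CLASH summary, where the passenger share of
3p hybrids rises from 4.7% (WT) to 31.3% (mutant):

```
sample  n_hybrids  fraction_5p  fraction_3p  passenger_share_3p
WT          16000        0.522        0.478               0.047
HM          16000        0.018        0.982               0.313
```

and the transcriptome shift tests: predicted passenger-3p-target genes move
down (one-sided KS p = 4.0e-4) and 5p-target genes move up (p = 2.5e-3)
relative to background, the expected signature of gained and lost repression.

There is also a CLI: `mirswitch run --seed 11 --out-dir demo`, with
subcommands `simulate`, `quantify`, `strands`, `scores`, `enrich`,
`targets`, `clash`.

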