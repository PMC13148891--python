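# Methods

## Absolute sgRNA quantification

The standard curve is fitted exactly in the orientation the lab workflow
uses: ordinary least squares of `y = log10(amount in ng)` on `x = mean Ct`
per dilution point. The conventional Ct-on-log10 regression is the
algebraic inverse and is not fitted separately. Amplification efficiency is
derived from the slope as `E = 10^(−m) − 1`, so a perfect per-cycle
doubling (`m = −log10 2`) reads as 100%. The curve is fitted per plate from
that plate's `standard` rows only and never reused across runs.

Dilution ladders are modelled as a fold-step series anchored at one
measured concentration (the top point), with downstream concentrations
inferred by division — mirroring the practice of quantifying a single
dilution and inferring the rest. Amounts are carried in nanograms, volumes
in microlitres, titers in copies/μL.

Copy conversion uses `copies = ng · N_A / (L · 330 · 10⁹)` with
`N_A = 6.022×10²³`, `L` the amplicon length in bp (69 for the scaffold
assay) and 330 g/mol the average mass of one nucleotide of single-stranded
DNA. The reaction-level count is scaled to the preparation by multiplying
by the cDNA dilution factor (10 or 100) and the cDNA reaction volume
(20 μL), dividing by the RNA volume used in cDNA synthesis
(sample-specific), multiplying by the RNA elution volume (30 μL), and
dividing by the prep volume extracted (5 μL). The dilution factor is
applied exactly once, in this chain; the narrative phrase "adjusted for the
dilution of cDNA" describes this same correction, not a second
application. The 2.5 μL of cDNA pipetted into each 10 μL reaction is
deliberately not part of the chain — the chain is implemented as the
workflow states it.

**Replicate QC.** A replicate group whose Ct sample standard deviation
(ddof = 1) exceeds 0.5 cycles has the single value farthest from the
median removed (ties broken toward the higher Ct, the weaker signal) and
is re-tested; at most one value is ever removed, and a group that still
fails is excluded from curves and quantification rather than trimmed
further. Non-detects are recorded and never imputed. Singletons pass
through flagged. The threshold is configurable; lowering it can only
shrink the set of kept replicates.

**Genome-normalized plasmid load.** Plasmid carry-over in transduced cells
is expressed as copies per 100 genomes: plasmid and internal-control
(e.g. RPLP0) copies are each computed against their own curve and amplicon
length, and genome count = control copies ÷ control copies-per-genome
(default 2, autosomal diploid, overridable).

## Live-cell kinetics

Each well's series is divided by its own pre-treatment reading, which
cancels well-to-well scale exactly; replicate wells are then averaged per
time point. The plateau is defined by a tolerance band: the plateau level
is the mean of the final window (default 1 h) of the mean curve, and the
plateau time is the earliest time after which the curve never leaves
±5% (relative) of that level. The band definition is a stated choice — the
underlying phenomenon is described only qualitatively as a sigmoidal rise
that levels off — and both the tolerance and the window are parameters. A
curve still moving at the last sample is flagged censored rather than
assigned a time.

Fold changes are reported as control/treated, so a 4-fold signal reduction
reads as 4.0; time points are matched by nearest neighbour within half the
local sampling interval, with no interpolation. Dose response is summarized
as the ratio of each dose's mean signal to the smallest dose's, flagged
proportional within ±30% of the volume ratio, else saturated/superlinear.
The editing correlation is an OLS of editing % (response) on log10 RLU
(predictor), using replicate-level points when available.

For the lytic assay, background is the mean of same-plate buffer (PBS)
wells, subtracted in linear space before any log transform; negative
differences floor at zero with a flag, and log10 summaries exclude
non-positive readings.

## Dose standardization

Adjusted volumes are `v_i = v_ref · value_ref / value_i` after rescaling
all metrics to an undiluted basis (`value × dilution`). The delivered
amount `v_i · value_i` is then identical across preps by construction — an
exact arithmetic identity the tests assert. A prep with zero metric value
cannot be normalized and is excluded with a flag; an optional maximum
volume caps (and flags) impractically large doses instead of silently
truncating. CLI output rounds volumes to 0.01 μL (pipettable precision);
full precision is kept internally.

## Motif scanning

Scanning is over whole-frame conceptual translations, not ORFs: stops are
kept as `*` and translation continues through them, since a cross-reactive
peptide need not sit in an annotated reading frame. Windows containing a
stop are never reported (a translatable peptide is required). Codons
containing any non-ACGT base translate to `X`; `X` counts as a mismatch in
Hamming mode and as a class mismatch in property mode, which preserves the
containment `exact ⊆ hamming ⊆ property` at any common threshold.

The default property alphabet groups the 20 residues into five classes —
hydrophobic `AVLIMFWY`, special `GPC`, polar `STNQ`, positive `KRH`,
negative `DE` — as a named, overridable configuration; the underlying idea
(grouping by biochemical character) admits many groupings and this one is
a documented default, not a reconstruction. The default Hamming reporting
threshold is 3 of 11 positions; full distances are always recorded so any
threshold can be re-applied. Hits order by (distance, source, frame in the
order +1,+2,+3,−1,−2,−3, offset), and per-source ranking keeps the best
`N` under the same key. All coordinates are 0-based, half-open, on the
forward strand; a reverse-frame window's coordinate is the leftmost
forward-strand base it covers.

In-silico PCR requires full-length exact primer matches (no mismatches):
one primer on the forward strand and the reverse complement of the other
downstream, in either orientation. With multiple possible products the
shortest is reported and flagged; circular templates can be handled by
scanning the sequence extended by its first primer-length−1 bases, off by
default since the bundled checks use linear oligonucleotides.

Peptide average mass is the standard average-isotope residue sum plus one
water (Biopython's tables); the bundled 11-residue query masses to 1.3 kDa.

## Synthetic data

The generators emulate the statistical structure the analyses assume, with
defaults chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| true titer | 6×10⁶ copies/μL | magnitude of a PEG-precipitated prep |
| amplification efficiency | 0.95 | middle of the assay's ~0.92–0.98 range |
| curve intercept | 1.0 log10 ng | puts a 7-point, 10-fold ladder at Ct ≈ 10–31 |
| Ct noise | σ = 0.15 cycles | visual spread of replicate qPCR triplicates |
| no-RT offset | uniform 20–26-fold | residual plasmid signal below the RT signal |
| RLU noise | 10% CV, log-normal | multiplicative plate-reader error |
| kinetics | logistic, k = 3/h, t₅₀ = 1 h | simplest curve with sigmoidal rise and ~2.5–3 h plateau |
| baseline RLU / plateau | 100 / 10⁵ per μL dose | ~3-log dynamic range of the reporter |
| dose saturation | above 5 μL | endocytic-capacity ceiling as a generator feature |
| inhibitor effect | ÷4 on the plateau | acidification-block magnitude |

Each generator is the analytic inverse of its pipeline counterpart: with
noise set to zero, a generated ladder refits to the exact slope/intercept,
a generated prep quantifies back to the exact titer (to 10⁻⁹ relative), a
logistic course reproduces its closed-form plateau crossing within one
sampling interval, and a planted peptide is found at its recorded
frame/offset/coordinate. All randomness flows through a single recorded
seed, and identical seeds give byte-identical outputs.

What the generators do **not** emulate: PCR inhibition and primer-dimer
artifacts, between-plate batch effects, substrate depletion or cell death
in long time courses, sequence composition bias in plasmids. Passing the
recovery tests therefore demonstrates correctness of the computations
under the stated noise model, not robustness to every artifact of real
instruments.

## Numerical and scale choices

Replicate SDs use ddof = 1. Regression is `scipy.stats.linregress`.
Extrapolation beyond the fitted Ct range is permitted but flagged, since
test samples (and especially no-RT controls) can fall below the lowest
standard. The end-to-end recovery checks run 200 simulated preps against a
7-point triplicate ladder — large enough that the median relative error is
a stable statistic, small enough to run in seconds; scanner/oracle
equivalence uses 50 random 2-kb sequences, which covers every frame parity
and several hundred thousand window comparisons.

## Known limitations

Quantification assumes the qPCR reports the cDNA of the sgRNA scaffold
with the standard oligo's hybridization behaviour; differences in RT
efficiency between standard and sample are outside the model. The plateau
detector is sensitive to late-course noise (a noisy curve plateaus
"later" because points leave the tolerance band), which is visible with
the default 10% RLU CV. In-silico PCR is exact-match only — it will not
predict products from primers with mismatches or degenerate bases.
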