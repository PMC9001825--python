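# Methods

## Reporter model and coordinates

All coordinates are 0-based, half-open, oriented along the top strand with
the barcode/watermark block on the left. The reporter is
`barcode(20) + watermark(20) + left repeat(152) + spacer(42) + right repeat(152)`.
The repeat ("F segment") is a fixed 152-mer derived from the central window
of the eGFP coding sequence, lightly edited so that it carries exactly 19
CpG dinucleotides — the count the methylation assay normalizes against —
with no CpG overlapping the central variant. The variant sits at offset 76;
for an even-length segment "the centre" is ambiguous between 75 and 76, and
76 is fixed by convention. All sequence logic is agnostic to the fixture's
actual bases.

A mismatch code `X:Y` means the annealed heteroduplex presents `X` on the
top strand and `Y` on the bottom strand. Because SSA anneals the left
repeat's top strand to the right repeat's bottom strand, the left repeat
carries `X` on its top strand while the right repeat carries `Y` on its
bottom strand (hence `complement(Y)` on its top strand). The five construct
codes are A:G, T:G, A:C, T:C and the strand-swap control G:T.

The 42-nt spacer embeds the 18-nt I-SceI recognition sequence flush at its
right end. This placement is not printed anywhere; it is reconstructed from
the flap arithmetic: the documented I-SceI flaps (33 top / 13 bottom, 4-nt
3′ overhang) force `top_cut = 33` and `bottom_cut = 29`, which fall inside
the recognition site exactly when the site occupies spacer offsets 24–42.
For any cut, `top_flap = top_cut` and `bottom_flap = 42 − bottom_cut`; every
blunt cut conserves `top_flap + bottom_flap = 42`, and a d-nt overhang adds
d. The two guide-RNA cuts are blunt at offsets 31 (flaps 31/11) and 0
(flaps 0/42).

NHEJ is modelled as a site-destroying deletion of the overhang (minimum
1 nt for blunt cuts); the indel spectrum is out of scope. One consequence:
a blunt cut at spacer offset 0 cannot destroy the recognition site at the
other end of the spacer with a local scar, so the "no product retains an
intact I-SceI site" guarantee is enforced (and tested) for cuts falling
within the site — I-SceI and the control guide. SSA products always lose
the spacer entirely.

## Synthetic data: what it emulates, and what it does not

The generator produces every input the pipeline consumes with known ground
truth, under one root seed (`numpy.random.SeedSequence` spawning), with
byte-identical FASTQ output on reruns.

**Toy genome.** Four chromosomes (80/60/40/50 kb) tiled with repeating
expressed-gene / intergenic / silent-gene blocks; `chrX` is sampled at half
dose (haploid analogue); a 1-kb block of chr1 is duplicated into chr2 so
multi-mapping fragments exist. Insertion loci are drawn per bp, optionally
weighted 1.35× in expressed genes, and redrawn when the downstream fragment
would be unmappable (shorter than 20 nt before the next CATG, or
non-unique) — the analogue of restricting to the mappable genome.

**Chromatin.** 78 binary occupancy tracks over 200-bp windows, each
covering a random 1–10% of windows, plus GC content in 10-kb and 1-Mb
windows computed from the toy sequence. A designated track can carry a
planted additive effect on the local strand bias, and another can carry a
methylation "protection" factor. The tracks are independent Bernoulli
fields: they do not reproduce the spatial autocorrelation, co-occurrence
structure, or copy-number texture of real chromatin maps, so a passing
context test shows the estimator works, not that real chromatin behaves
this way.

**Repair.** One template molecule per barcode per run — the inference the
discordance analysis supports (the great majority of barcodes show no
conflicting UMI). Per replicate and barcode: NHEJ with probability
1 − `ssa_fraction` (default 0.7); otherwise SSA, unresolved with
probability `unrepaired_fraction` (default 0.05), else resolved toward the
longer-flap strand with probability `strand_bias` (default 0.7, the middle
of the observed 60–80% range). Control (no-induction) runs instead mark a
`pre_recombined_fraction` (default 0.05) of barcodes as clonally
recombined, with one fixed outcome in every replicate; the rest stay uncut.

**Amplification.** UMI-LA: 50 cycles of linear amplification copy the top
strand only; each sequenced UMI is a copy made at a uniformly drawn cycle.
UMI-PCR: 6 cycles sample both strands, so each UMI of an unresolved
heteroduplex reports the allele of the strand it copied — the LA/PCR
discordance signature. The number of sequenced UMIs per barcode is Poisson
(mean 8) — a sequencing-depth choice, since not every amplicon is read —
and reads per UMI are geometric with mean 3, so the ≥2-read filter retains
about two thirds of UMIs. Polymerase errors (1e-4/base) are drawn once per
UMI copy; sequencing errors (1e-3/base) per read; both are substitutions
only. Template switching re-emits a UMI's reads under a second barcode with
probability 1e-3, which is exactly the signature the chimera filter keys on.

**Deamination.** During LA only, each template cytosine deaminates with a
per-cycle rate — 3e-4 for methylated CpG cytosines, 3e-5 otherwise, chosen
to keep the methylated:unmethylated ratio at the observed ~10× while giving
percent-scale barcode discordance at calibration depth; both are config
values. A deamination at cycle t converts the template C to T for all
copies made at cycles ≥ t, which is what makes a discordant UMI pool a
deamination signature. Synthesis errors on oligos are drawn once per
molecule, so all UMIs share them and the concordance screen excludes them
at any rate.

**Read geometry.** Forward amplicon read: `barcode + watermark +` the right
half of the distal repeat from position 73 (3 nt past the midpoint);
reverse read: `UMI(18) +` the reverse complement of the proximal repeat's
left half up to position 79. Both reads therefore cover the variant; after
SSA they cover the *same* molecule and the variant bases they report are
reverse complements, which is the SSA signature the parser checks. Reads
are emitted with placeholder quality strings; quality models, PCR
efficiency/GC bias, and real mm9 sequence content are out of scope.

## Pipeline numerics

- **Approximate matching** uses edlib. `find_approximate` returns the
  minimum-edit-distance span, leftmost end on ties (none beyond the error
  budget: 3 edits for the 20-nt watermark, 10 for the 79-nt half
  segments). The variant base is read through the alignment path, so
  upstream indels cannot shift it.
- **Clustering** (barcodes, UMIs, oligo split barcodes, radius 2) is greedy
  by descending read count with lexicographic ties: a sequence joins the
  most abundant canonical within edit distance 2, else founds a cluster.
  Candidates come from exact matches on three sequence chunks, which is
  exhaustive for ≤2 substitutions (pigeonhole) and approximate for indels;
  message-passing schemes are out of scope.
- **Locus assignment**: candidate sites are those with ≥10% of a barcode's
  reads; the diameter (max pairwise distance; infinite across chromosomes
  or when a candidate multi-maps) must be ≤30 — strictly greater than 30
  discards; the retained position is the modal site, lowest coordinate on
  ties.
- **Filters**: read-level ties within a UMI reject the UMI (conservative;
  ties are rare at ≥2 reads). "More NHEJ than SSA" is a strict inequality;
  ties are retained. Control matching uses clustered barcode sequences.
  The filters are idempotent: re-calling on retained output changes nothing.
- **Bias** is pooled at the UMI level (the published estimator) with a
  Wilson 95% interval; a per-barcode majority variant feeds the mutual
  information. For comparing an estimate with a generative per-event
  probability, the binomial scale is the number of repair events
  (barcodes): UMIs within a barcode replicate one molecule.
- **Mutual information** is the plug-in estimator in bits with 0·log 0 = 0,
  over barcodes with ≥5 allele-reporting UMIs seen in ≥2 replicates,
  majority-voted (exact ties excluded to keep the statistic deterministic);
  each unordered replicate pair contributes one count split evenly between
  the two orientations, since replicate order is arbitrary. No
  bias-corrected estimator is applied; the plug-in upward bias is about
  1/(2N ln 2) and the tests account for it.

## The Beta-likelihood network

Inputs: 7 bookkeeping variables (4 construct indicators under
reference-level coding, time point, amplification technology, TRIP pool),
plus 78 chromatin tracks and the two GC variables for the full model (87;
85 on the GC-prediction task, where the GC columns are removed from the
predictors). Hidden stack: three layers of 100 units, each batch-normalized
(ε = 1e-5, running-stat momentum 0.9) then ReLU; dropout 0.3 after hidden
layers 1 and 2; a residual connection adds the first hidden activation to
the third before the 2-unit output layer; outputs pass through
softplus + 1e-6 so the Beta parameters are strictly positive. Loss is the
negative Beta log-likelihood; its parameter gradients use the digamma
function and the whole backward pass is verified against finite
differences. Optimizer: Adam, learning rate 1e-3, batches of 256, 100
epochs. The 10% test split is drawn once per experiment seed and shared
across restarts; each restart re-seeds initialization, shuffling and
dropout. Proportion-valued outcomes (including binary conflict indicators)
are clamped to [1e-3, 1−1e-3] so they are representable under a continuous
Beta density; a Beta-binomial likelihood would be the principled
alternative for binary outcomes and is noted as future work. Defaults use
10 restarts; the published comparison style uses 100, and the restart count
is a parameter. The full-vs-null verdict calls "signal" only when the full
model's converged median test loss (median over the last quarter of epochs)
falls below the null model's 1st-percentile band.

## Methylation inference

Evidence is barcode-level: an alteration X>Y is evidenced iff the barcode
has at least one UMI consensus identical to the reference and one differing
by exactly that single substitution. UMI consensi are per-position majority
votes over ≥2 reads, ambiguity ('N') on ties; minority-length reads are
dropped. For reporters, the per-UMI consensus of the F segment is stitched
from the reverse-read window (positions 0–78) and the forward-read window
(79–151). The CpG ratio normalizes per assayable cytosine — events per
in-CpG C (19 sites) over events per out-of-CpG C — so it estimates the
deamination-rate ratio; a bootstrap over barcodes gives its interval.
Classification thresholds: ratio ≥6 methylated-like, ≤4 unmethylated-like,
else indeterminate, splitting the observed 2–4× vs ~10× regimes. The naive
closed form 1−(1−p)^cycles is only an upper bound on barcode-level
discordance: with finitely many sequenced UMIs, an early deamination can
leave no reference UMI and a late one no altered UMI. The exact expectation
given a barcode's UMI depth k sums p(1−p)^(t−1)·(1 − E[q^k] − E[(1−q)^k])
over cycles t, with q = (cycles−t+1)/cycles the altered-copy fraction; the
test suite checks the simulator and caller against this form.

## Problem sizes and defaults

Tests and the acceptance script run at desk scale: 2,000 barcodes for the
mutual-information studies, 5,000 barcodes per construct for strand-swap
recovery, 500–1,500 for discordance and deamination studies, and 3,000
records × 10 restarts × 100 epochs for the learning-curve comparison —
sizes at which the targeted effects exceed their Monte-Carlo error by a
comfortable margin while a full run stays in the minutes range. Headline
real-data magnitudes (10^5 mapped reporters, ~3×10^5 repair events) are not
reproducible from simulation at desk scale and are covered by the
property-based checks instead.

## Known limitations

- The toy aligner is exact-match and unique-hit; it stands in for read
  mapping only because the synthetic genome is fully controlled.
- Chromatin tracks are spatially unstructured Bernoulli fields; genuine
  multi-mark combinatorics are absent, so the network comparison tests
  estimator behaviour, not biology.
- Sequencing and polymerase errors are substitution-only; the clustering
  radius still accepts indels, but none are generated.
- Deamination applies two rates (methylated vs unmethylated cytosine); the
  intermediate elevation of unmethylated CpGs over non-CpG cytosines seen
  in calibration data is not modelled separately.
- Repair pathway choice is context-independent by default; NHEJ indel
  diversity, resection kinetics and the G:T-specific glycosylase pathway
  are out of scope.
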