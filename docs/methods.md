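# Methods

## Window geometry and encoding

All model inputs are 60 bp windows in a fixed frame: the PAM's first base at
0-based index 32 (1-based position 33), so the NGG motif occupies positions
33–35 and the Cas9 blunt cut site (3 bp upstream of the PAM) falls between
positions 30 and 31 — the window centre. A window therefore covers 32 bases
left of the PAM's first base and 27 to its right. Minus-strand sites are
extracted on the forward strand and reverse-complemented, so the model only
ever sees one orientation. Flank that runs off the end of the source
sequence is padded with 'N' on whichever side is short; 'N' encodes as the
uniform 0.25 column so every one-hot column sums to 1. Lower-case input is
uppercased; IUPAC ambiguity codes other than N are rejected rather than
silently coerced, since a wrong unit column would corrupt training data.

Coordinates are 0-based half-open everywhere internally (BED-like); 1-based
positions appear only in reports and VCF I/O, with the conversions
centralised in the variants module.

## Outcome statistics

Each read reduces to its net indel length, ΣI − ΣD over the CIGAR
operations. A read with several indel operations contributes **one** outcome,
classified by the net — the net is what determines the reading frame. Reads
with net 0 (including balanced internal insertion/deletion pairs) count as
non-indel outcomes and are excluded from both numerator and denominator; the
denominator of all six statistics is the number of indel outcomes I+D.
Frameshift classes use |net| mod 3, so −1 and +1 both land in fs1, and
fs_total = fs1 + fs2 holds identically. Targets whose indel read support
falls below a threshold (default 1; 10 in the demo pipeline) are dropped
with a log entry rather than yielding noisy profiles.

## Model

Fixed stems, searched middle: a linear convolution stem (kernel 8) expands
the 4-channel input to `base_filters × width_scale` channels; eight searched
layers follow, each one of conv4/conv8 (dilation 1), dconv4/dconv8
(dilation 4) with ReLU, max/average pooling (size 4, stride 1), or identity;
then global average pooling, one ReLU dense layer (32 units), and six
sigmoid heads. Same-padding and stride 1 everywhere keep length 60, so a
residual token can always add layer r's output into layer t's input without
reshaping (all searched layers share the same channel count, so no
projection is ever needed). Dropout is applied after each searched layer
only, during training only — not inside the stems, following the
architecture contract literally.

Average pooling over same-padded borders divides by the count of in-bounds
elements; max pooling pads with −inf. The loss is binary cross-entropy with
*soft* targets (the six statistics are probabilities, not labels), summed
over tasks and averaged over examples, with predictions clipped to
[1e-7, 1 − 1e-7] before logs. The optimiser is Adam (lr 1e-3, batch 128 by
default; the reference experiments below use 5e-3/64), and early stopping
keeps the best-validation-epoch weights with a default patience of 50
epochs. Weights use Kaiming-uniform init (variance 2/fan_in): with smaller
init scales the desk-scale network's effective learning rate is far too low
to fit within sensible epoch budgets.

Everything runs on a small reverse-mode autodiff engine over numpy float64
(`editnas.autodiff`). Float64 keeps finite-difference gradient checks
meaningful; convolution and pooling are implemented as kernel-tap loops,
each tap a vectorised einsum, which is fast enough at desk scale.

## Architecture search

One LSTM step per searched layer: the embedded previous operation token is
the input; operation probabilities are softmax(W_o·h_t) and each residual
bit for an earlier layer r uses the additive attention score
σ(vᵀ tanh(W_r1·h_t + W_r2·h_r)). Only the operation token feeds forward into
the next LSTM input. W_o and v start at exactly zero, so an untrained
controller samples operations uniformly (1/7 each) and residual bits at 1/2
— which is also the sampling density used for random cohorts.

REINFORCE with an EMA baseline: the update ascends
(1/m) Σ_k ∇θ log π(a_k;θ)(R_k − b). The baseline is initialised to the first
batch's mean reward (so the controller discriminates within batches from
step one) and then updated as b ← 0.9·b + 0.1·mean(R). The controller's own
optimiser is Adam with lr 0.1: measured on the reduced 3-layer space, lr of
order 1e-3…0.05 produces no visible policy movement within a 10–15 step
budget, while 0.1 concentrates the policy on the best operations within ~6
steps. Records passed to an update are replayed under the current
parameters and must reproduce their recorded log-likelihoods (tolerance
1e-6); anything else indicates stale records and raises.

Children are trained from scratch for a small fixed epoch budget — no
weight-sharing supernet. That keeps rewards unbiased and reproducible;
weight sharing would be the natural extension if child training became the
bottleneck. A child whose predictions are constant on some task has an
undefined rank correlation there; that task contributes 0 to the reward and
the event is logged, so degenerate children cannot crash the search.
"Best architecture" at the end of a search means the argmax-reward sample
within the final controller step (the global best is also in the log). The
post-search grid refinement retrains the chosen tokens at every
(width_scale, dropout) pair, scanning in sorted order and keeping strict
improvements only, so ties break toward smaller width, then smaller dropout.

## Evaluation

Per task: Pearson, Spearman, Kendall's tau (scipy), and an AUC-ROC after
binarizing observations at their median. "High" means strictly greater than
the median — values equal to the median go to the low class, which matters
on tied data. Constant vectors yield an explicit undefined flag, never a
silent zero. Metrics are reported as fractions; percentage formatting is
presentation only.

## Saturated mutagenesis

For each window, all 180 single-base substitutions plus the reference run in
one batched forward pass; entry (b, p) of a task's 4×60 importance matrix is
prediction(reference) − prediction(substituted), so positive values mean the
reference base elevates the prediction. Reference-base entries are exactly
zero; 'N' positions are skipped and logged. Only windows predicted within a
tolerance (default 0.05) of their measured statistics — on **all six** tasks
simultaneously, the strictest reading; a per-task mode exists — enter the
averaged matrices. Plain averaging lets structural zeros dilute the mean; a
mask-mean option divides each entry by the number of sequences in which it
was actually computed.

## Variant effects

Exonic NGG sites are scanned on both strands (forward: GG at p+1..p+2;
reverse: CC at p−2..p−1, reported as a minus-strand NGG whose first base is
p). Any single-nucleotide variant falling anywhere in a site's 60 bp window
is paired with it — the model consumes the whole window, and known sequence
determinants sit well outside the 3 bp PAM. Alleles are reverse-complemented
into the window frame for minus-strand sites; a REF allele that disagrees
with the window base raises a consistency error instead of being dropped,
since it indicates a coordinate or strand bug. One variant is substituted at
a time (no haplotypes). Sites are ranked ascending by the mean absolute
prediction difference over all their SNVs and all six statistics; SNV-free
sites rank first with score 0 and an explicit flag. The headline report
highlights the 1 bp insertion task with a configurable large-effect
threshold (default 0.30), but all six differences are always stored.

## Synthetic data

The generator emulates the upstream data the pipeline would consume, with
known ground truth. Windows are uniform random over ACGT with GG fixed at
positions 34–35. The planted rule drives ins1 from the base at 1-based
position 29 — 4 nt upstream of the PAM, mirroring the strongest determinant
reported for real Cas9 repair data, so interpretation tests double as a
qualitative check of that finding — with effect levels A→0.8, C→0.55,
G→0.3, T→0.1 and Gaussian noise (sd 0.05), clipped to [0.01, 0.99]. The
other five statistics are drawn consistently by assigning the remaining
probability mass to net-length classes {+2, −1, −2, −3}; because only the
classes {+1, +2, −1, −2, −3} carry mass, fs1 = ins1 + del1 holds by
construction and the map from the six statistics back to class
probabilities is exact and invertible, which is what lets
`simulate_event_table` sample read tables whose recomputed profiles converge
to the inputs (binomially, ~0.01 at depth 1e5).

An optional pairwise interaction (+0.15 on ins1 when the bases at positions
27 and 29 agree) exists for architecture-search experiments: a purely
additive single-position rule is fit almost equally well by every
architecture in the space, leaving nothing for a controller to discover,
whereas the interaction makes nonlinear convolution layers genuinely better
than pooling/identity stacks.

What the generator does **not** emulate: microhomology-driven deletion
spectra, position-dependent deletion size profiles, sequencing error, or
realistic genome composition. Passing tests therefore demonstrate that the
machinery recovers a known signal under controlled conditions — not that the
desk-scale models reach published accuracy on real repair datasets.

The toy genome fixture is a 5 kb uniform-random chromosome with four
declared exons (~60% coverage), at least 20 NGG sites per strand inside
them, and ≥30 SNVs placed two-thirds inside / one-third outside scan
windows; the generator records its own placement counts, which the
variant-effect tests compare against. Same seed, byte-identical files.

## Reference experiments and problem sizes

`editnas.experiments` fixes the protocols shared by tests, examples and the
reproduction script. Parameter recovery trains on 5000 windows (8:1:1
split) with a width-scale-1 model, Adam 5e-3, batch 64, ≤32 epochs,
patience 12 — a few minutes per seed on one CPU core. The recovery
architecture uses two dilated kernel-8 convolutions: with global average
pooling the network is otherwise nearly translation invariant, and the
planted determinant lives at an *absolute* position; receptive spans of 29
that reach the padded window edge are what make absolute position readable.
The search experiment uses the interaction rule, a 3-layer space, 12
controller steps of 4 architectures (children: 5 epochs on ~1000 windows),
and compares the final step's mean reward with a random cohort of equal
total size. Splits here are 76/23/1 — the search needs only train and
validation data.

## Known limitations

- Desk-scale budgets: published-scale width (×6) and datasets are out of
  reach of the bundled experiments; the machinery supports them
  (`width_scale`, `dropout` are config), but nothing here validates
  published accuracy numbers.
- The controller treats residual bits as conditionally independent given the
  hidden states; no mechanism enforces architecture diversity late in a
  search, so the policy typically collapses onto one operation pattern.
- Rewards are single-seed child trainings; reward noise (sd ≈ 0.03 at the
  default sizes) is visible in search traces.
- The outcome statistics assume one outcome per read via net indel length;
  datasets that count multiple indels per read separately would need a
  different reduction.
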