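# Methods

## Problem and model

A nanopore sequencer reports, per read, a sequence of *events*: segments of
the pore current each summarised by a mean, a standard deviation and a
duration.  The current level is determined mostly by the k = 6 bases inside
the pore, and ideally the context shifts by one base per event, but event
segmentation also produces *falsely split* events (one context, two events)
and *missed* events (two contexts, one event).  Base calling is therefore a
sequence-labelling problem in which each event accounts for zero, one or
two bases.

`porecall` models this with a stacked bidirectional gated-recurrent-unit
(GRU) network.  Each layer scans the event features in both directions and
concatenates the per-position hidden states; the final concatenated state
h_i feeds two independent softmax heads,

    P[b_i^(k) = q] ∝ exp(θ_q^(k) · h_i),   k ∈ {1, 2},  q ∈ {A, C, G, T, −},

a per-event *bigram* over the DNA alphabet extended with a no-base dash.
Zero bases is (−, −), one base is (−, b) — the single base always occupies
the second slot — and two bases fill both slots.  Greedy decoding takes the
argmax of each slot and skips dashes, so a call is at most twice the event
count.  Two independent 5-way heads are used rather than one 21/25-way
head.  The GRU cell is

    u = σ(W_u x + U_u h' + b_u),  r = σ(W_r x + U_r h' + b_r),
    n = tanh(W x + r ∘ U h'),     h = u ∘ h' + (1 − u) ∘ n,

with h' the previous state; the candidate has no bias and the initial state
h_0 of every direction is a trained parameter.  The output weights act
directly on the concatenated final-layer state; there is no intermediate
projection.

## Training

The exact event-to-base labelling of a read is unknown — only the
reference region it maps to — so training is EM-like:

1. **Initial alignment.**  Events are matched against the *expected
   signal*: the pore model's level means simulated from the reference.  A
   dynamic program minimises Σ|expected − observed mean| over monotone
   alignments, with additive penalties (default 2.0 signal units each) for
   split moves (no context advance, event labelled 0 bases) and skip moves
   (two contexts, 2 bases).  Each diagonal event is labelled with the base
   entering its context.
2. **Gradient fitting.**  The loss is the negative log likelihood of the
   target bigrams under both heads.  Gradients are exact backpropagation
   through time across all layers, both directions, h_0 and θ.  One read is
   one update: full-sequence gradient, L2-clipped at norm 5, applied with
   Nesterov momentum 0.9 (gradient evaluated at the lookahead point).  The
   learning rate (default 0.01) halves when the epoch-mean loss stalls for
   10 epochs.  No regularisation is applied.  Training is bitwise
   reproducible from the seed; the best epoch-mean-loss parameters are
   returned.
3. **Posterior realignment.**  Every `realign_every` epochs the targets are
   rebuilt by a second dynamic program that maximises the summed log output
   probabilities of the current network over all monotone 0/1/2-base
   emissions consuming the reference.  Because the realignment maximises
   exactly the per-event log probabilities the loss sums, the loss under
   the new targets never exceeds the loss under the old ones.

An L-BFGS fine-tuning phase is not built in; the flat parameter-vector
loss/gradient interface (`NetworkParams.pack`/`unpack_`,
`training.loss_and_grad`) is the attachment point for one.

## 2D calling

Template and complement reads of the same fragment are combined by first
running both 1D networks, mapping the complement's output distributions
into template orientation (event order reversed, base probabilities
complement-swapped, output slots swapped because reversal also flips the
intra-event bigram order), and aligning the two event sequences with a
third dynamic program: a paired column scores the log expected agreement
ln Σ_q P_t(q) P_c(q) summed over both heads (summation, i.e. expected
agreement, rather than a max over agreeing bases), an unpaired event scores
ln 0.1.  Each column becomes an 8-wide joint input — the two strands'
features plus two presence flags, absent strands zero-filled — for a 2D
network trained like the 1D ones, with initial targets projected from the
template strand's expected-signal alignment onto the columns.

## Preprocessing

Per-pore gain and offset drift make raw signal incomparable across reads.
Each read is rescaled so that the 25th/75th percentiles of its event means
and the median of its event stdevs hit targets; targets default to the same
statistics of the pore model, making scaled signal directly comparable to
expected signal.  Conventions fixed here: means transform as
`(mean + shift) · scale`, percentiles interpolate linearly between order
statistics, and no time-linear drift term is fitted (flag reserved).  The
network additionally consumes a fixed affine featurisation (means centred
on the model's median level and divided by its IQR, stdevs by the median
spread, durations raw); the constants travel in the model file.

## Synthetic data

No public event-level corpus is assumed; the simulator defines the study
conditions.  A pore model draws one expected (mean, stdev) per k-mer —
means i.i.d. uniform on [50, 150] signal units, stdevs on [0.5, 3.0].  A
read walks the k-mer windows of a fragment (the complement strand walks the
reverse complement) emitting per window one event with Gaussian noise on
mean and stdev and exponential duration; with probability `p_split` (0.05)
the window emits twice (second event: 0 bases), else with `p_skip` (0.05)
two windows merge into one event (2 bases) whose expected mean is their
equal-weight average; finally a per-read affine distortion (gain uniform in
[0.9, 1.1], offset in [−15, 15]) is applied to means, and the gain to
stdevs.  Defaults: `noise_mean` = 1.0 and `noise_stdev` = 0.3 signal units
(roughly the per-event repeatability of real pores relative to a ~100-unit
level range), `duration_rate` = 25/s.  Events are labelled with the base
entering the context, so a read's truth labels concatenate to
`fragment[k−1:]` — the first k − 1 bases only prime the context and are
never called; all truth-based evaluation uses this trimmed convention.

What the simulator does *not* emulate: raw-current waveforms and event
segmentation itself, time-correlated drift within a read, per-strand pore
chemistry (both strands share one pore model by default; per-strand models
are a config option), homopolymer-specific dwell behaviour, and — most
importantly — the *structured* physics of real pores, where k-mer levels
are roughly additive in per-base contributions.  An i.i.d. random level
table is a strictly harder decoding target than a physical pore map, since
levels of overlapping contexts share no structure a network could
extrapolate from; passing results here exercise the machinery
(alignment, gradients, EM loop, 2D fusion) rather than predicting real-data
accuracy in either direction.

## Numerical choices

* Logs are natural throughout; probabilities are clipped at 1e−300 before
  logs inside the DPs, and target probabilities at 1e−30 in the loss
  (warning, not exception).
* Softmaxes subtract the row max before exponentiation.
* DP tie-breaks are fixed: expected-signal, diagonal > split > skip;
  posterior, one base > zero > two; pairing, pair > template gap >
  complement gap; sequence alignment, diagonal > up > left.  Greedy decode
  breaks argmax ties in alphabet order A < C < G < T < −.
* Parameter init: matrices and θ uniform(−0.08, 0.08), biases and h_0 zero,
  from the run's seeded generator.
* The three event-level DPs are full O(n·m); banding is left as an
  optimisation seam.

## Problem sizes used in the shipped tests

The test-suite and acceptance-script experiments run at desk scale on one
CPU: oracle cross-checks use hidden sizes 1–6 and sequences ≤ 10 events;
the end-to-end recovery experiment uses a 20 kb genome, 60 paired reads of
150–300 bases at the default error rates, a 3-layer hidden-32 template
network per strand (~90 epochs each, learning rate 0.03, realignment
every 15 epochs), and a 3-layer hidden-48 2D network — the 2D stage
consumes both strands' information and needs more capacity than a single
strand's network to profit from it.  These sizes
are the package's chosen trade-off between statistical signal and a
single-CPU desk run; the networks are far smaller and trained far more
briefly than the 100–250-hidden-unit production configuration the
architecture targets, and the measured synthetic accuracies reflect that.

## Known limitations

* Under the i.i.d. uniform pore model, held-out accuracy at the shipped
  desk scale plateaus well below what structured (physical) pore maps
  permit: the network must memorise a 4096-entry random code through a
  scalar signal channel, and a hidden-32 network trained for ~100 epochs
  generalises it only partially.  The training loss itself drops sharply
  (the EM loop and gradients work); the gap is representational/statistical,
  not a defect of the optimisation path.  At k = 3 (64 contexts) the same
  pipeline learns visibly within a minute.
* The matches/alignment-length identity has a floor of roughly 0.5 for
  *unrelated* sequences under the +1/−1/−1 global scoring at read-scale
  lengths — global alignment manufactures spurious matches.  Identity
  values should be read against that floor, not against the 25% per-base
  chance level.
* The expected-signal DP scores a skipped event against the landing
  context's level, while the simulator generates merged events at the
  average of the two levels; initial alignments around skips are therefore
  approximate (the posterior realignment later corrects them).
* No FAST5/raw-signal ingestion: any adapter producing `EventSequence`
  objects is the extension point.
* No base-quality emission; calls are plain FASTA.
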