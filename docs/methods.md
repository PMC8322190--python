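# Methods

## Problem and model

The decoder addresses dichotic listening: two speech streams, one per ear,
with the listener attending to one of them while 128-channel EEG is
recorded.  Low-frequency (2–30 Hz) EEG tracks the slow amplitude envelope
of attended speech more strongly than of ignored speech; the decoder's job
is to report, continuously in time, which ear is attended.

Decoding is cast as a sequential decision process.  A probabilistic
state-space view summarizes the observation window ending at step *t* into
a Markovian state **S**ₜ; an agent maps **S**ₜ to an action
*A*ₜ ∈ {left, right} and the environment returns the next state together
with a reward *R*ₜ = +1 for a correct attention call and −1 otherwise.
Transitions are action-independent — the next signal window arrives
regardless of the decision — so the transition model is degenerate and the
optimal policy is simply the per-state myopic one; the return/Q-value
machinery is nevertheless retained so tabular and deep Q-learning apply
unchanged.  There is no separate training stage: each learner adapts
online while it decodes, and every prediction is made *before* the step's
label is used for learning.

Two exact identities anchor the evaluation: rewards take no values other
than ±1, and cumulative accuracy obeys ACC = (ΣR + T)/(2T) on every trace.

## State features

For each window (1 s, hop 125 ms at 64 Hz) the EEG channels are averaged
within 8 contiguous groups, and each group's signal is correlated (Pearson)
with the left and the right envelope at lags {0, 62.5, 125, 187.5, 250} ms,
giving 2 × 8 × 5 correlation features; 8 log window energies are appended
(D = 88).  Windows start after the maximum lag so every lagged envelope
window lies inside the trial; a 60 s trial at 64 Hz therefore yields
⌊(3840 − 64 − 16)/8⌋ + 1 = 471 states.  Zero-variance windows define a
correlation of 0 rather than an undefined value.

Features are z-scored causally (running mean/variance over states 0..t),
with one important refinement: each correlation feature shares its running
statistics with its left/right twin.  A purely per-dimension z-score would
subtract each column's own mean — on a constant-attention trial that mean
*is* the class signal, and removing it destroys cross-trial transfer
(verified directly: frozen-decoder transfer accuracy 0.99 with pooled
statistics vs 0.0 without).  Pooling preserves the attended-side contrast
while still normalizing scale.  An optional seeded random projection
reduces D for the tabular learner, which discretizes each dimension into
quantile bins (B = 3 by default, edges fit on the first 20% of states) and
indexes states by the mixed-radix bin tuple.

## Learners

**Recurrent classifier.**  Stacked recurrent layers
*h*ₜˡ = tanh(W_hh[l] *h*ₜ₋₁ˡ + W_sh[l] *x*ₜˡ) with a linear two-unit output
*ô*ₜ = W_ho *h*ₜ, bias-free — the model is exactly its weight set.
Reference architecture: 10 layers × 100 tanh units.  At each step the
squared error against one-hot targets over the trailing 3-step window is
minimized by truncated backpropagation through time, iterating gradient
steps until the window loss drops below the stop threshold 10⁻³ (safety
cap 100 iterations; learning rate 0.01, a package choice).  The truncation
boundary hidden state is advanced with the current weights as states leave
the window.

**Tabular Q-learning.**  For explicitly known MDPs, value iteration
Q₍ᵢ₊₁₎(s,a) = Σ_s′ P(s′|s,a)[R + γ max_a′ Qᵢ(s′,a′)] with γ = 0.9 and a
sweep cap of 50; this solver is verified against a depth-50 expectimax
recursion and against exhaustive policy enumeration on small MDPs.  For
the decoding stream the model-free TD rule with learning rate α = 0.1
(package choice) and ε-greedy exploration decaying linearly 0.2 → 0.01
over the episode is used, single-pass (the online protocol has no second
look at the stream).

**Deep Q-learning.**  Experiences (Sₜ, Aₜ, Rₜ, Sₜ₊₁) enter a bounded FIFO
replay memory; batches of 32 are sampled uniformly without replacement and
the online network is trained against a frozen target copy synchronized
every 50 updates, minimizing mean squared TD error with targets
y = r (terminal) or y = r + γ max Q(s′; θ₋).  Each update iterates
gradient descent on its batch until the loss falls below the agent's stop
threshold (10⁻², cap 25 iterations).  Two agents: a feedforward network
(3 sigmoid hidden layers) and a recurrent network (3 tanh recurrent
layers, one-step truncated backpropagation; each stored experience carries
the hidden state it was encountered with, a stored-state recurrent-replay
approximation).  Both reference widths are 100 units.  Unlike the
classifier, the Q-networks carry bias terms: without one, a zero-mean tanh
network cannot represent the common offset of the ±1 value targets, and
training demonstrably thrashes.

Two defaults depart from the obvious choices, deliberately:

- **Discount γ = 0 for DQL.**  Transitions are action-independent, so the
  greedy policy is invariant to γ; myopic targets (expected immediate
  reward) make the learning problem stationary.  With γ = 0.9 the Q-scale
  (≈ 1/(1−γ) = 10) dwarfs the fixed action margin of 2 and the
  target-network relaxation does not settle within a 471-step episode,
  leaving decisions noisy.  γ stays configurable; tabular QL keeps 0.9.
- **Replay capacity 100 steps (12.5 s).**  A memory holding the whole
  episode pins the network to stale labels after an attention switch;
  a ~10 s memory lets the decoder re-lock within a few seconds, the time
  scale a tracking decoder must achieve, while still decorrelating
  batches.

During an episode the trace records the *greedy* prediction and its ±1
reward at every step (so the accuracy identity holds exactly), while the
executed ε-greedy action generates the experience the agent learns from.

## Evaluation

The cumulative-accuracy curve is curve[t] = #correct in 0..t / (t+1).
Detection delay is t*·hop where t* is the earliest index from which the
curve stays within ε = 0.02 of its final value; a curve that only reaches
the band at its last point is flagged not-stabilized.  Shrinking ε can
only increase the delay.

**Permutation test.**  Whole-trial attended-side labels are randomly
relabeled; per repetition the pipeline is trained online on one fold of
trials and scored *frozen* (greedy, no updates) on the held-out fold
against the relabeled labels, two folds per repetition, 100 repetitions.
Cross-folded scoring is essential: a purely online learner relearns a
flipped mapping within a trial and would be insensitive to the
manipulation.  The default relabeling mirrors each trial left↔right with
an independent fair coin, which makes the null center exactly 50% for any
decoder; the classical exchange of the label multiset (exact balance) is
available as an option but couples the folds negatively at small trial
counts and centers below chance.

**Switching report.**  For alternating schedules of 5/10/15/30 s segments
over 60 s, the report tabulates mean ± sd final accuracy and mean delay
per condition.  Errors concentrate in the windows overlapping a switch
plus the re-locking steps after it, so accuracy increases with segment
length — the qualitative ordering the decoder is expected to reproduce.

## Synthetic data

Real dichotic-EEG recordings are external, so the generator emulates the
one property the decoder relies on.  Speech envelopes are rectified,
8 Hz-low-passed Gaussian noise (non-negative, >99% of spectral power below
8 Hz).  Each EEG channel applies a seeded unit-norm random FIR kernel
(support 0–250 ms) to the attended envelope at gain 1.0 and to the
unattended envelope at gain 0.2, plus white noise of sd 0.5; kernels are
seeded by the *subject* seed in the generator config, not the per-trial
seed, because a listener's stimulus→EEG forward model is stable across
trials — without this, cross-trial protocols are meaningless.  Attention
switches are instantaneous at segment boundaries.  Trials are generated at
128 channels / 128 Hz and preprocessed like real data (zero-phase
Butterworth band-pass 2–30 Hz, polyphase resampling to 64 Hz, optional
50 Hz notch off by default).

What the generator does *not* model: physiological TRF shapes, cortical
nonlinearity and adaptation, subject-to-subject variability, artifacts,
HRTF acoustics.  Passing tests therefore show that the decoding machinery
recovers a lagged-envelope-correlation signal embedded in noise under the
stated SNR, not that the system reaches any particular accuracy on real
EEG.

A subtlety of online evaluation: because the ±1 reward reveals the true
label at every step, *any* temporally persistent label sequence is
partially predictable from the reward stream alone, without stimulus
information.  The zero-information control therefore uses equal gains
*and* an iid random side per 0.125 s segment (one decision hop), for which
reward-tracking strategies are provably at chance; slow schedules would
sit above 0.5 for reasons unrelated to decoding.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 128-channel, 60 s pipeline
but scale network widths down (16 hidden units, one hidden/recurrent
layer) — the properties under test (gradient exactness, null centering,
accuracy orderings) do not depend on width, and the reduced configuration
keeps the 100-repetition permutation run at minutes on one CPU.  Gradient
implementations are validated against central finite differences to a
relative error below 10⁻⁴.  Ties in every argmax (predictions, greedy
actions) resolve to "left"; "left" is also the positive class in the
confusion bookkeeping, though the accuracy measure is symmetric.  A
diverging inner-loop loss (non-finite) raises immediately rather than
propagating NaNs.

## Known limitations

Tabular Q-learning needs the random projection + quantization front end
and is the weakest learner on switching streams, consistent with its
ranking among the methods.  The recurrent agent's replayed hidden states
are those stored at encounter time and drift relative to the current
weights; sequence replay would remove this approximation at substantially
higher cost.  Detection delay is a property of the cumulative curve, so a
late switch inflates it even when re-locking is fast.  EDF files can be
read (via mne) but trials are written only as delimited text/JSON/WAV.
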