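# Methods

`semhub` implements a recurrent hub-and-spoke network of semantic
cognition together with the artificial environment it learns from, the
damage models used to simulate two neuropsychological syndromes, and the
forced-choice tasks and analyses used to evaluate it.  This note records
the model, the parameter choices that matter, and the places where the
package had to make a design decision.

## The model

The network has 590 units in five pools: 64 verbal input units (one per
word, clamped by the environment), 64 verbal prediction units, 162
sensory-motor (S-M) feature units, a 150-unit transmodal hub, and a
150-unit context buffer.  Trainable full connections run verbal→hub,
context→hub, S-M↔hub, hub→hub and hub→prediction.  Every unit has a
fixed, untrainable bias of −2, so units rest near their minimum activation
(σ(−2) ≈ 0.119) absent input.

Each stimulus is processed for 7 time steps with activations updated 4
times per step (28 ticks).  Hub and S-M units are logistic with output
integration `a ← (1−dt)·a + dt·σ(net)`, `dt = 1/4`; the prediction pool
integrates its net input and applies a softmax, so its activity sums to
one at every tick.  Updates are synchronous from previous-tick values.
Free pools restart from their resting state on every stimulus; only the
context pool carries history: after each stimulus the final hub state is
copied onto the context units (a buffer operation, not a connection — no
gradient flows through it) and clamped there for the next stimulus.

The connection list is a design decision: the text requires S-M→hub
feedback and describes the network as fully recurrent, so the hub carries
full self-connections; there are no prediction→hub links.  The list is
configuration-exposed for ablations.

## Training

When a concrete word or homonym is presented verbally, the network is
trained (cross-entropy, last 2 time steps = 8 ticks) to activate the
item's 9 S-M features; abstract words and directly presented S-M patterns
carry no S-M target.  Every stimulus except the last in an episode also
carries a next-word prediction target (Kullback–Leibler divergence on the
softmax pool).  Error is injected uniformly over the 8 target-window
ticks; cross-entropy activations are clipped at 1e−7.

Gradients are exact backpropagation through the 28-tick unrolling,
implemented in numpy and verified against central finite differences
(relative error < 1e−4 on small architectures; in practice ~1e−8).
Derivatives accumulate over 100 episodes; the pre-momentum step
−lr·∇ is rescaled to a global Euclidean norm of at most 1 before the
momentum term is added (norm-bounded "Doug's" momentum, lr 0.1, momentum
0.9), with multiplicative weight decay of 1e−6 per update.  Weights are
initialized uniformly in [−0.2, 0.2].

The published schedule is five passes over a 400,000-episode corpus
(20,000 updates) for each of ten models.  To keep routine runs inside
ordinary CPU budgets the package defines a *scaled* preset: two models,
one pass over the first 250,000 episodes of the corpus, presented as 100
parallel continuous streams (float32).  Within each stream the context
copy crosses episode
boundaries exactly as in the single-stream schedule, and the 100-episode
accumulation per update is preserved; parallel streams change only the
order in which the corpus is visited.  The scaled schedule reproduces the
qualitative phenomena with attenuated effect sizes (noted below).

## The environment

The vocabulary holds 22 concrete nouns in six taxonomic categories, 32
abstract nouns in 16 related pairs, and 10 homonyms with two concrete
senses tied to different categories.  Each concrete item (and each
homonym sense) has 6 S-M features shared with its category and 3 unique
features; 6×6 + 42×3 = 162 feature slots, exactly exhausted.  Labels are
ordinary English nouns but are purely cosmetic.

Episodes of five stimuli are sampled from 35 hand-designed topics
(10–19 members each; two contain only abstract words).  A topic is chosen
with probability proportional to its base weight — eight "heavy" topics
carry weights 5 or 10 — then five concepts are drawn i.i.d. from the
topic's distribution.  Concrete items and homonyms appear verbally or as
their S-M pattern with equal probability; abstract items are always
verbal; a homonym's sense (hence its S-M pattern) is fixed by the topic.

Topic membership follows explicit design rules: same-category concrete
items cluster; abstract pairs share several topics but not all; each
homonym's two senses occupy disjoint topic groups with roughly 3:1
exposure; designated cross-category pairs (e.g. *deer/hunter*) share
event topics, creating purely associative relationships.  Within-topic
probabilities combine role weights (core/regular/occasional) with
per-word masses set by a deterministic calibration loop targeting the
environment's design statistics: a 17:1 frequency spread, dominant-sense
probe→target co-occurrence rates near .077 (subordinate ≈ .033), and a
positive frequency–diversity correlation.  `validate_corpus` reports the
measured statistics of any generated corpus against these targets.

### Semantic diversity

A word's semantic diversity (SemD) is −log of the mean pairwise cosine
similarity among the latent-space vectors of all episodes containing it.
Episode count vectors are reduced by truncated SVD; the mean pairwise
cosine is computed in closed form from the sum of unit vectors and
floored at 1e−6 before the log.  The default dimensionality is 18: with
35 topics this compresses related topics onto shared components so that
within-cluster episode similarities — and hence the overall SemD scale
and its correlation with frequency — match the environment's design
targets.  (At 30 dimensions every topic is nearly orthogonal and all
SemD values inflate by ~0.15.)  Words appearing in fewer than two
episodes have undefined SemD.

## Controlled retrieval and response selection

In a k-alternative forced choice the verbal clamp carries the probe at 1
plus each option j at weight I_j.  Weights start at 1/k; from tick 12
(the start of the fourth time step) they are recomputed every tick as
`I_j = exp(s·P_j)/Σ exp(s·P_k)` with s = 200, where P are the options'
prediction activations on the previous tick.  The onset delay lets
bottom-up processing of the probe develop before the high-gain softmax
starts amplifying differences; without it the mechanism can lock onto
whichever option the (uninformative) starting context happened to favor.
Onset and cadence are configuration fields.  `mode="none"` removes the
mechanism (probe only); `mode="static"` clamps options at 1/k throughout.

At the end of settling, i.i.d. Gaussian noise (sd 0.01 intact) is added
to each option's prediction activation and the argmax is the response.

A trial's context is randomized per presentation (no-cue conditions) or
set by settling on a single cue word and copying the hub state.  A
"random pattern of activity" for the context buffer is drawn per unit as
σ(−2 + u), u ~ U(−2, 2): random activity in the operating regime of the
hub units whose states the buffer holds.  Trained hub states have mean
activation ≈ 0.02; uniform values on (0, 1) would give the buffer about
five times the drive of any state it can actually hold and push the
network into spurious attractors.

## Damage models

Representational damage (the semantic-dementia analogue) masks a uniform
random 30% of the connections into and out of the hub — including
context→hub and hub self-links; the copy function itself is never
lesioned.  Masks are applied multiplicatively, gradients respect them,
and lesions are reversible (weights untouched).  Control damage (the
semantic-aphasia analogue) leaves weights intact: controlled retrieval is
switched off and selection noise is raised to 0.045 (homonym task) or
0.04 (judgment tasks).

## Tasks

* **Homonym comprehension**: per homonym, a dominant- and a
  subordinate-sense trial (probe, designated target, three foils that
  never follow the probe in the corpus), each under correct-cue, miscue
  and no-cue contexts.  Cue words are the strongest sense-specific topic
  co-members not otherwise used in the trial.
* **Synonym judgment**: one trial per non-homonym word (54); concrete
  targets are the most co-occurring same-category item, abstract targets
  the pair partner; two cross-category zero-co-occurrence foils.
* **Taxonomic vs. associative matching**: the 22 concrete synonym trials,
  and 22 four-option trials whose targets are the designated
  cross-category associates.

Accuracy denominators default to 200 presentations per trial per
condition at the published scale (intact/control damage: models ×
repetitions; hub damage: models × lesions × repetitions); the scaled
preset uses 2 models × 100 repetitions (intact/control) and 2 models ×
40 lesions × 5 repetitions (hub damage).  Statistical summaries use
repeated-measures ANOVA over models (homonym task) and standardized-beta
OLS over trials with a hierarchical F-change step adding probe–target
co-occurrence rate.

## Representational analyses

Context-averaged representations present every word after every word
(the context word is settled from a random context and its hub state
copied), average each word's 64 hub states, and correlate the averages;
the procedure repeats with fresh random contexts (50 at full scale, 10
scaled) and matrices are averaged.  Representational consistency is the
mean pairwise correlation of one word's 64 context-specific states.
Acquired embodiment probes report mean S-M activation per
category-shared feature group for words presented in random or specified
contexts.

## Scaled-run caveats

The scaled preset (two models, one pass) reproduces the qualitative
pattern of every analysis but attenuates several quantities relative to
the published schedule: within-category hub similarity and the
consistency–diversity correlation grow with training; the benefit of
controlled retrieval on subordinate-sense trials is smaller at reduced
training because option-driven constraint satisfaction requires
well-separated attractors; four-option associative judgments (the
weakest links in the environment) fall short of the published ~90 %
intact accuracy; and the robustness advantage of concrete (imageable)
words under damage — which in the full model arises from sensory-motor
grounding — does not reliably emerge, so imageability effects under
damage are near zero or reversed.  Effects reported as significant at
the published ensemble size are checked by sign and ordering at the
scaled size.  The synthetic environment also idealizes real
language: no syntax, single-word contexts, binary imageability, and
topic-stationary statistics — passing tests demonstrate the mechanism,
not coverage of natural-language variability.

## Numerical notes

Settling is float64 by default; training defaults to float32 in the
scaled preset (gradient checks and optimizer tests run in float64).
Softmaxes are log-sum-exp stabilized.  Non-finite activations or losses
raise immediately.  Corpus sampling, training, lesions and experiments
are reproducible from explicit integer seeds.
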