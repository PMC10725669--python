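# Methods

## Problem and data model

The unit of classification is a *candidate instance*: one unordered pair
of drug mentions inside one sentence. A sentence with n mentions yields
C(n, 2) candidates. Corpora arrive in the community XML dialect of the
DDI-extraction shared tasks (documents → sentences → entities with
character offsets → annotated pairs); offsets are 0-based with inclusive
start and end, matching the corpus files in the wild, and are validated
against the sentence text on parse. Discontinuous mentions (offset lists
like `12-18;25-30`) keep only the first span for positioning — the
representation needs a single anchor per mention, and the secondary spans
are rare qualifiers. Candidate enumeration is done per *sentence* (the
shared-task definition), even though informal descriptions of the method
sometimes say "document"; pairs across sentence boundaries are never
candidates.

## Pharmacological representation

Tokenization splits on whitespace and then on punctuation characters;
punctuation-only fragments are dropped by default (a retain mode exists
via `keep_punctuation`), so hyphenated compounds become contiguous runs
of word tokens and the token count is at least the whitespace word count.
Word vectors are random encodings: components uniform in
[−1/√d, 1/√d] with d = 400 by default, drawn once per vocabulary entry
from a seeded generator and trained along with the rest of the network.
The vocabulary is built from the training corpora; unseen tokens map to a
reserved UNK row.

The four filters are computed in token coordinates. The distance r used
by the importance metric I = 1/(r+1)² is the token-position distance to
the nearest token of the nearest target run; every token inside a
multi-token mention has r = 0. Token distance (rather than character
distance) is the reading consistent with the published anchor cases
(r = 0 on the target, r = 1 adjacent). The neighbor filter fires within a
radius of 1 token of a run; the radius is configurable because the
definition in prose ("a neighbor of the target drug") does not fix it.
The path filter fires strictly between the end of the earlier run and the
start of the later run. By construction the filters are symmetric under
swapping the two targets.

## Recurrent cells

The base cell and its printed equations are given in the README and in
`recurrent_core.py`. Two fidelity decisions deserve a note:

* **Gate roles as printed.** The published recursion applies the gate
  labelled "input" to the previous cell state C_{t−1} and the gate
  labelled "forget" to the candidate — the reverse of textbook naming.
  The cell implements exactly that arrangement; a
  `conventional_gate_roles` flag swaps the two for comparison. Since
  both gates are free parameters the two arrangements define the same
  function class, so this affects naming and initialisation only.
* **The candidate term reads P_t.** One printed occurrence of the
  candidate argument is lower-case ("p_t"); it is read as P_t — there is
  no lower-case quantity defined anywhere.

The phar-gate output dimension is unstated in the source description;
the default is 4, preserving the scale of the filter signal, and it is
configurable (`p_dim`). The hidden size default is 128. Peephole and
full-gate-recurrence variants use full weight matrices over concatenated
inputs, exactly as the printed equations show concatenation (not the
diagonal peepholes of some LSTM literature). The FGR state additionally
carries the previous gate activations (I, F, O), initialised to zeros.

The classifier consumes H_n, the hidden state at the final token, which
is what the classification equation uses; no pooling over the hidden
sequence is applied.

There is no neural-framework dependency: the cells run on a small
reverse-mode autodiff engine (`_autodiff.py`) over NumPy with a closed
operation set (affine maps, sigmoid/tanh, concatenation, embedding
lookup with scatter-add, fused softmax cross-entropy). Analytic
gradients are validated against central finite differences (relative
error < 1e−4) for every parameter of every variant in the test suite.

## Training

Cross-entropy plus ridge on the classifier weights, J = −log p(gold) +
(λ/2)‖W‖²; λ defaults to 1e−4 (unstated in the source; a small standard
value). Optimiser is RMSprop (lr 0.001, smoothing 0.9, ε 1e−8 — the
common library defaults, recorded in the run manifest); dropout 0.2 on
the embedded inputs and on H_n, train-time only; batch size 32; 200
epochs by default.

The pretrain/fine-tune split is implemented as: phase 1
(`pretrain_epochs`, default 20 of the 200) trains the shared embedding
and cell parameters under throwaway softmax heads; phase 2 attaches
freshly initialised heads and fine-tunes everything jointly. This honours
"all parameters except the output layer are pretrained" while staying
simple; the optimiser state is restarted at the phase boundary. Both
tasks are trained simultaneously by alternating mini-batches, shuffled
across tasks in proportion to corpus sizes.

All randomness (embedding init, weight init, batch order, dropout masks)
derives from a single seed via spawned generators, and execution is
single-threaded NumPy, so a fixed seed reproduces the loss and F traces
bit for bit. Argmax ties break toward the lowest class index.

Degenerate inputs: an empty task dict or all-empty corpora raise a
configuration error; a non-finite loss raises with the epoch index;
metric 0/0 cases return 0 with a warning (a NaN-propagating mode exists)
so empty classes do not poison macro averages.

## Evaluation metrics

Per-class P, R, F and accuracy come from one-vs-rest contingency tables;
CLA is the micro-averaged F computed from the summed (global) table and
MAVG the unweighted mean of per-class F. Both averages include all
classes by default — the published fine-grained results report an F for
the NEGATIVE class, implying it participates — and an exclusion set
reproduces the official challenge convention (drop NEGATIVE) when asked.
The scalability score 1 − σ uses the population (divide-by-n) deviation,
matching its printed ½-weighted definition; so do the reproducibility
sums (per-epoch variance and standard deviation across runs). Welch's
t-test is computed from the Welch statistic and Welch–Satterthwaite
degrees of freedom with scipy supplying only the t distribution; the
zero-variance corner returns t = 0, p = 1 for equal means and p = 0
(significant) for different means, the limit of vanishing variance.

## Synthetic corpus generator

The generator emulates the structure of the shared-task corpora:
template sentences of filler tokens with 2 (configurable up to more)
drug mentions, every C(n, 2) pair annotated. The gold label of a pair is
the class of the *first* trigger token strictly between its two
mentions, NEGATIVE if there is none — so labels are a deterministic
function of path tokens, the path/importance filters carry signal by
design, and a noiseless corpus has Bayes-optimal F = 1. A `label_noise`
rate flips labels to a random other class. Defaults: 500 sentences, two
mentions per sentence, 120 filler words, 1–3 fillers per gap (sentences
of roughly 5–11 tokens), class priors ½ NEGATIVE and ½ spread over the
trigger classes — negatives dominate real DDI corpora and an even split
keeps both tasks learnable at small n. Drug surfaces are pronounceable
pseudo-names, unique within a sentence and distinct from fillers and
triggers.

What the generator does *not* emulate: natural syntax, lexical
statistics of DrugBank/MedLine, discontinuous mentions, inter-annotator
noise structure, or class imbalance as extreme as the real fine-grained
task. Passing tests on synthetic corpora therefore demonstrate that the
pipeline learns a path-token-determined relation under the published
architecture and training regime — not that it attains the published
corpus-level scores, which require the licensed corpora and their far
longer training runs.

A consequence of perfect separability is that *every* gated variant
saturates on these corpora given enough epochs; comparisons between
variants (e.g. the output-gate ablations NOG/NOAF against the full cell)
are therefore made on the distribution of per-epoch held-out F-scores
over the training trajectory — the same protocol the published
consistency analysis uses — rather than on the final score alone.

## Problem sizes used by the test suite

The gradient checks run at hidden 3, d 4, p_dim 2 over 3-step sequences
(full finite-difference sweep of every weight entry). The end-to-end
experiment trains on a noiseless 2,000-instance binary corpus (1,500
train / 500 held out) for 50 epochs at the default architecture
(hidden 128, d 400); smaller unit tests use reduced widths. These sizes
are the package's own test conditions; the library itself has no scale
assumptions beyond memory.

## Known limitations

* Single forward recurrent layer only — no bidirectional or stacked
  encoders, mirroring the published architecture.
* No pretrained word vectors by design (random encoding is part of the
  method); no GPU path; no early stopping or hyperparameter search.
* The autodiff engine is deliberately minimal; it is not a general
  tensor library and supports exactly the operations the model needs.
* `CandidateInstance` pairs are enumerated within sentences; documents
  whose interactions span sentences are out of reach of the model.
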