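# Methods

## Match score

Records carry n fields indexed by i; each field has an empty flag
δᵢ ∈ {0, 1} (1 = non-empty) and, when present, an encoded value.  The
similarity score of records x and y is

    S(x, y) = s(x, y) / w(x, y),
    s(x, y) = Σᵢ δᵢ wᵢ simᵢ(xᵢ, yᵢ),     w(x, y) = Σᵢ δᵢ wᵢ,

where δᵢ here denotes the *pairwise* flag δᵢ(x)·δᵢ(y): a field
contributes only when both records fill it, so missing values drop out of
numerator and denominator alike rather than being punished.  Weights
follow the Fellegi–Sunter-motivated rule wᵢ = log₂((1 − eᵢ)/fᵢ), where eᵢ
is the assumed probability that two registrations of the same person
disagree on field i and fᵢ is the average value frequency (the chance two
*random* people agree on it).  Agreement on a rare, reliable field is
strong evidence; the boundary fᵢ = 1 − eᵢ yields weight 0 (an
uninformative field) and larger fᵢ is rejected.

The division is never evaluated.  Scores travel as pairs (s, w) and are
ranked by the **tie-solving order**

    (s₁, w₁) > (s₂, w₂)  ⇔  s₁w₂ > s₂w₁  ∨  (s₁w₂ = s₂w₁ ∧ w₁ > w₂),

i.e. quotients compared by cross-multiplication, with the larger
denominator winning equal quotients (more fields contributed) and a
(0, 0) pair losing against any pair with w > 0.  On *full* equality
(equal cross products and equal denominators) our fold keeps the earlier
candidate, which makes the best-match result independent of the fold-tree
shape; the order is total and transitive on non-negative pairs (property-
tested).

**Exchange groups.**  Fields that are plausibly interchanged at data
entry (given, sur- and birth name) form a group G.  For every permutation
σ of G the group sub-score uses the averaged weight
w_{i,σ(i)} = (wᵢ + w_{σ(i)})/2 and pairwise flags δᵢ(x)·δ_{σ(i)}(y); the
group's (s_G, w_G) is the maximum over all |G|! permutations under the
tie-solving order.  Averaged weights keep S(x, y) = S(y, x).  Group size
is capped at 4 (24 permutations) — larger name groups do not occur in
practice and the permutation set is enumerated explicitly.

**bestMatch and matchCardinality.**  A query x against a database
{y_j, 0 ≤ j < N} returns the argmax index under a balanced binary-tree
fold of the tie-solving comparison plus the match bit [s* > T·w*] for a
threshold 0 < T ≤ 1.  A second, lower threshold T_t (when configured)
marks a *tentative* band T_t·w* < s* ≤ T·w*; tentative matches are
reported but count as non-matches everywhere, including in
matchCardinality, which is simply the number of queries whose best match
crosses T.  No blocking or candidate filtering is performed — every pair
is scored — because data-dependent pruning is exactly what the secure
formulation must avoid.

## Field comparison

Equality fields (date-of-birth components, ZIP) compare as 0/1 on
lb-bit integers.  String fields use the Sørensen–Dice coefficient of
bigram Bloom filters: text is uppercased, diacritics are folded to ASCII,
consecutive overlapping bigrams are hashed into an m-bit mask by a
double-hashing family g_i(t) = (h₁(t) + i·h₂(t)) mod m, i < k, with two
keyed 64-bit hashes (deterministic per salt), and

    sim(x, y) = 2·Hw(Bl(x) ∧ Bl(y)) / (Hw(Bl(x)) + Hw(Bl(y))).

Conventions: tokenization is unpadded (an optional `_text_` padding mode
exists); a single-character string is its own token, so no non-empty
value encodes to an empty filter; two all-zero filters compare as 0.  The
coefficient ignores shared zero bits, and a one-letter substitution
touches at most two bigrams, hence sets at most 2k new bits and clears at
most 2k.  Defaults m = 500, k = 10.  The filters are an encoding for
circuit-friendly similarity, **not** a privacy mechanism; confidentiality
comes from the secure-computation layer.

## Fixed-point formulation

Arithmetic circuit components work mod 2^L, L ∈ {8, 16, 32, 64}.  Two
real-valued inputs must be quantized: weights to l_w bits (rescaled so the
largest weight is exactly 2^{l_w} − 1) and similarities to the scale
2^{l_s} (equality: a bit shifted by l_s; Dice: the rounding integer
division ((2·H_∧ ≪ l_s) + d/2)/d with d = H_x + H_y; threshold:
T_q = ⌊T·2^{l_s}⌉).  Rounding is half-away-from-zero everywhere; averaged
group weights truncate, (wᵢ + w_j) ÷ 2, matching free-shift semantics.
The match predicate becomes s > T_q·w with both sides at scale
2^{l_w + l_s}.

The widest intermediate is the tie-comparison product z = s·w′: a sum of
n values of length l_w + l_s times a sum of n values of length l_w, i.e.
⌈log₂ n²⌉ + 2·l_w + l_s bits.  With r = L − ⌈log₂ n²⌉ the precisions are

    l_w = ⌈r/3⌉, l_s = ⌊r/3⌋  if r mod 3 = 2,
    l_w = ⌊r/3⌋, l_s = ⌈r/3⌉  otherwise,

so 2·l_w + l_s = r exactly: the word is fully used and overflow is
impossible by construction (asserted on adversarial all-max inputs for
every supported (L, n)).  For L = 32, n = 8 this gives (l_w, l_s) =
(9, 8); for L = 16, (3, 4); for L = 64, (19, 20).

**Accuracy.**  The error budget per record pair is dominated by Dice
quantization (≤ 2^{−(l_s+1)} per string field) plus weight-rescaling
error (relative ≤ 2^{−(l_w+1)} per field, entering through the weighted
mean).  The accuracy study (`experiments.measure_deviation`, also run by
the acceptance script) scores 10,000 seeded pairs — half corrupted copies
of the same person, half unrelated people — with both pipelines and
reports the maximum absolute score difference.  At L = 64 the deviation
is negligible (< 10⁻⁴).  Note that a *maximum* over 10⁴ pairs approaches
the aligned worst case: with the default configuration the four string
fields carry ≈ 76% of the total weight, so the attainable worst case is
roughly 0.76·2^{−(l_s+1)} — about 0.15% at L = 32 and about 2.4% at
L = 16.  The measured maxima sit close to these bounds; tighter headline
figures are only possible for much smaller corpora or weight profiles
with less mass on string fields.

## Circuit model

The best-match computation is a fixed DAG (no data-dependent control
flow): per database record a score subcircuit (equality: Boolean equality
reduce + free shift; Dice: bitwise AND, Hamming-weight adder trees of
output width ⌈log₂(m+1)⌉, a free shift for the 2·H numerator, and a
combinational restoring rounding-division with quotient width l_s + 1,
built from compare/subtract/multiplex steps with the same I/O contract as
a compiled division block), δ-gated weight multiplications, permutation
sums, and the group and global maxima as balanced folds of a
MaxQuotient comparator (two products, a greater-than, an equality, the
tie rule, and multiplexers routing s, w and the ⌈log₂ N⌉-bit index).
With an all-zero Dice denominator the raw quotient bits are garbage by
design; every use is multiplied by the pairwise empty flag, which is then
zero, so outputs are unaffected.

Gates carry a domain tag — Boolean/logic (protocol β: GMW or Yao) or
arithmetic mod 2^L (protocol α: β itself or additive sharing) — with
explicit conversion nodes where α ≠ β, giving the four variants GMW,
GMW/A, Yao and Yao/A.  All variants compute identical values; they differ
only in domain tags and conversion points (tested).

**Round accounting** is structural: XOR, NOT, shifts and constants are
free; AND, ADD, MUL, comparisons, multiplexers and conversions cost one
round per gate level; Yao-based variants cost a constant independent of
the circuit.  Because the per-record part evaluates in parallel and only
the fold grows with N, modeled rounds are exactly affine in ⌈log₂ N⌉
with a constant per-level increment (tested).  The model claims the
*structure*, not the absolute constants of any particular framework;
`round_model_predict` therefore calibrates rounds(N) = a + c·⌈log₂ N⌉
through two anchor measurements published for an ABY-based
implementation of this circuit (266 rounds at size 1, 378 at size 100,
GMW/A), requiring
the fitted increment to be integral.  The calibrated model reproduces all
other published sizes (330 @ 10 … 506 @ 25,000).

## Secret-sharing simulator

Both parties run in one process.  Boolean wires are XOR-shared, arithmetic
wires additively shared mod 2^L.  Linear gates are local; every AND/MUL
consumes a Beaver triple from a seeded trusted dealer (a functional model
of the setup phase — no oblivious transfer, no garbling, and no security
claim; the simulator preserves the protocol arithmetic and the share-level
view, nothing more).  Compound gates decompose into the textbook gadgets:
Kogge–Stone carry computation for Boolean addition (and comparison via
the carry of x + ¬y + 1), an AND-reduce for equality, one masked AND per
multiplexer, per-bit b₁ + b₂ − 2b₁b₂ conversions for B2A and a shared
adder over re-input shares for A2B.  A message log records one
round and two messages per opening.  End-to-end, reconstruction of the
shared evaluation equals the cleartext evaluation exactly on every tested
circuit; share marginals pass a χ² uniformity check.

## Synthetic data

The generator emulates two institutions' registries of the same
population: person records with given name, surname, birth name, city,
birth day/month/year and ZIP.  Names come from bundled synthetic banks —
a core of common German-style names extended with deterministic
syllable-built names (600 given names, 3,000 surnames, 500 cities) —
sampled with shifted power-law weights p_i ∝ 1/(i + shift).  Spelling
diversity is deliberate: unrelated surnames overlap in at most short
affixes, so their Dice similarity distribution (mean ≈ 0.17, 99th
percentile ≈ 0.46) resembles real name data.  ZIP codes attach to cities
roughly proportionally to city size (~1,070 codes; a ZIP never spans two
cities), dates are uniform (1940–2005, day 1–28), and the birth name
equals the surname except for a 15% married-name fraction, so every field
is populated before corruption.  The default configuration's frequency
parameters fᵢ are exactly these distributions' collision probabilities
(given 0.0041, sur/birth 0.0012, city 0.0062, day 0.036, month 1/12,
year 1/66, ZIP 0.001), and eᵢ = 0.1 matches the corruption rate below.

**Corruption** models the stated 10% per-field discrepancy between the
two registrations of one person, applied to the B-side copy: each field
independently with probability 0.1 receives one error — strings one edit
(substitute 0.4 / transpose 0.2 / delete 0.2 / insert 0.2), dates a
redraw within their valid range, ZIPs one digit change.  Separate rates
add missingness (default 0.01, blanking the field) and given/surname
swaps (default 0.01, the error exchange groups absorb).  Corruption never
touches the ground-truth index bookkeeping.

What the generator does **not** emulate: household and family structure,
culturally correlated name–city distributions, age-dependent name
fashions, shared typographic error modes (keyboard adjacency, OCR), or
duplicate registrations within one registry.  Linkage quality measured
here therefore shows that the scoring machinery separates same-entity
noise from population coincidences under a realistic frequency profile —
it does not certify performance on any particular real registry.

**Threshold calibration.**  The match threshold is an operating point
that real deployments tune on labeled data; the package default
(T = 0.58, tentative 0.50) was calibrated once on the synthetic study
corpus (10,000 × 10,000, 60% overlap, 10% error, fixed seed) as the
largest threshold below the observed minimum true-pair score, i.e. the
value that preserves perfect recall while keeping chance coincidences
(same surname + same ZIP plus a partial extra agreement) below the match
line.  Under these conditions the full cross-linkage attains precision
≈ 0.99 with recall 1.0; both quantities are recomputed, never assumed, by
the acceptance script (full scale) and the test suite (1,000 × 1,000
scaled run).

## Problem sizes used by the default runs

The test suite keeps simulations at sizes chosen for quick iteration:
linkage quality at 1,000 × 1,000; fixed-point accuracy at 10⁴ pairs;
circuit/cleartext equivalence on 200 instances with N ≤ 32 and 32-bit
Bloom filters; shared evaluation on full N = 8 circuits; engine
agreement on a 10 × 20 corpus (shared engine on a 3-query prefix).  The
acceptance script runs the linkage-quality study at the full
10,000 × 10,000 scale.  The Python gate-level engines are exact but not
meant for large corpora; the vectorized `reference` and `fixed_point`
engines handle the full study in under two minutes on one core
(the vectorized fixed-point path requires L ≤ 32 so tie products fit in
64-bit integers; L = 64 uses the per-record path).

## Numerical and interface conventions

* Record indices are 0-based row orders; CSV is UTF-8 with a header row;
  empty strings and the tokens NA, N/A, NULL, NONE, "." set δ = 0.
* Weights may be configured directly or via (eᵢ, fᵢ); validation is
  idempotent and attaches derived weights and precisions.
* Bit 0 is the least significant position in all integer/hex
  serializations of Bloom filters.
* ⌊·⌉ is round-half-away-from-zero for weights, thresholds and
  similarities; rounding division truncates after adding d/2.
* The LID (linkage ID) service is an in-process functional model:
  per-party 256-bit keys, tokens of the form
  Enc(key, 0⁸ ‖ id₁₆ ‖ match-bit) under an XOR-keystream-plus-HMAC
  scheme, zero-padding checked on decryption.  Match and non-match tokens
  are format-identical; the in-circuit alternative (XOR of both parties'
  per-record randomness on match) is provided as a function with the same
  format-identity property.  None of this claims cryptographic hardening.

## Known limitations

* The sharing layer is a simulator: triples come from a seeded dealer,
  messages from an in-process log; no transport, no malicious security.
* Yao variants are modeled at the round-accounting level only (constant
  rounds); garbling costs and communication volumes are out of scope.
* The fixed-point accuracy attainable at L = 16 is limited by l_s = 4 —
  see the error-budget discussion above; use L = 32 (the default) or
  L = 64 when score fidelity matters.
* Full cross-linkage is O(M·N) by design (no blocking); the exact
  engines (circuit, shared) are for validation at small N, not
  production linkage.
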