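# Methods

## Model

A candidate storage sequence of length L is a point in the discrete space
{A,T,C,G}^L, represented inside the optimizers as a continuous vector in
[0,3]^L. Digitization is round-half-up after clipping; fitness is always
evaluated on the digitized sequence, and the continuous vector is purely
optimizer-internal state. The digit→base order is 0→A, 1→T, 2→C, 3→G
(configurable bijection); under this order complementation is the xor-1
permutation, which the evaluator exploits.

The scalar objective is a weighted sum of six non-negative penalty terms
(three objectives, three soft constraints), minimized:

- **GC composition** `(GC% − 50)²`. Quadratic so that small imbalances are
  cheap and large ones expensive.
- **Homopolymer load** `Σ_k (h_k − 3)²` over all maximal runs `h_k > 3`.
  Cumulative rather than max-based: two runs of 5 are worse than one.
- **Stacking energy** `|mean per-step ΔG − ΔG_target| · 100` with
  ΔG_target = −1.45 kcal/mol. The divisor is the number of dinucleotide
  steps (L − 1), not L, so a sequence whose every step sits at the target
  scores exactly zero at any length; the deviation is taken as an absolute
  value because a signed term would reward overshooting in a minimization.
  The default step energies are SantaLucia-style unified nearest-neighbor
  stacking free energies at 37 °C, shipped as `data/stacking_dg.yaml` and
  replaceable by any 16-entry table.
- **Melting temperature** `Tm = 64.9 + 41·(GC% − 16.4)/100` (salt-corrected
  empirical model; a function of composition only), penalized by squared
  distance to the nearest bound of [55, 65] °C.
- **Hamming distance** to an archive of existing sequences: squared
  violation of a minimum distance d_min. An empty archive (single-sequence
  design mode) contributes zero. Benchmark runs archive the encoded payload
  with d_min = ⌈0.75·L⌉, the random-pair expectation.
- **Reverse-complement similarity**: the global position-wise match
  fraction against the full-length reverse complement (windowed variants
  are out of scope); `(ratio − 0.15)·100` above the 15% threshold.

Note a structural conflict: Tm ∈ [55, 65] requires GC ≤ 16.6% while the GC
term wants 50%, so the all-zero fitness is unreachable under the default
band and every optimizer settles on a composition trade-off (≈ 35–40% GC
under default weights). This mirrors the practical observation that long
single-block designs sit above the Tm target band.

**Weights.** Defaults w_obj = (1, 10, 1) for (GC, HP, ΔG) and
w_cons = (5, 1, 5) for (Tm, Hamming, RC): homopolymer and
melting-temperature/hairpin terms dominate synthesizability and carry the
larger weights. No canonical weight set exists for this objective, so all
reported fitness values are weight-relative; comparisons are only
meaningful within a fixed weight configuration.

## The tri-phase optimizer

Phase switch at T_HGS = round(SR·Tmax), SR = 0.5.

**Phase 1 — hunger-driven exploration (t < T_HGS).** Each individual
carries a hunger memory H_i: reset to 0 when it matches the global best,
otherwise incremented by a U(0,1] draw (scale configurable; only relative
hungers matter because they enter through the normalized sensitivity
s_i = H_i/ΣH_j, with the all-zero case mapped to uniform). Per individual,
with fresh r1, r2 ~ U(0,1): if r1 < s_i, self-perturbation
x·(1 + randn(d)); else if r2 < sech|f_i − f_best|, attraction to the best
x_best + R·W·|x_best − x|; else the peer move x_r1 + R·W·|x_r1 − x_r2| with
distinct random peers. W = w1·e^(−(N−i)/N) + w2 (defaults 1, 1);
R is uniform in [−a(t), a(t)] with a(t) = a_range·(1 − t/T_HGS).
Once per iteration a Cauchy jump proposes x_best + δ_cauchy·β(t),
β(t) = β_start·(1 − t/T_HGS), β_start = 0.015, accepted only on
improvement.

`a_range` defaults to 1.0. Because W multiplies R, only the product W·a is
identifiable (verified: scaling one and inversely scaling the other gives
identical traces); with W ≈ 1.4–2.4 under default w1 = w2 = 1, a peak
amplitude of 1.0 puts the effective attraction amplitude at ≈ 2 — the
canonical hunger-games value — whereas a = 2 doubles it and measurably
destabilizes convergence on this objective.

**Phase 2 — elite refinement (t ≥ T_HGS).** The best elite_frac = 30% of
the population receives proposals x_best + r·f_refine(t)·(x_best − x_rand),
r ~ U(0,1)^L, f_refine(t) = f0·e^(−decay·t/Tmax) with f0 = 0.008,
decay = 3. Proposals are accepted greedily (into the elite slot, and into
the global best when improving). Steps this small flip a digit only where
the best's continuous coordinate lies near a rounding boundary, so
refinement is a genuinely local polish.

**Phase 3 — adaptive surgical mutation (alongside phase 2).** Mutation
rate ramps linearly 0.02 → 0.05 over the second half. Targets are the
positions inside homopolymer runs > 3 and positions matching the reverse
complement of their mirror position. Each such position is rewritten with
probability `rate`; homopolymer rewrites avoid the run base *and both
current neighbors* (so a full-rate pass provably leaves no run > 3 and
never creates one), reverse-complement rewrites avoid the mirror's
complement. Applied to a uniformly random 20% of the population each
iteration, and additionally — mirroring the greedy Cauchy elite update of
phase 1 — one repair candidate of the incumbent best is evaluated greedily
per iteration. This elite repair is the package's own design choice: the
refinement steps above cannot retune base composition (they move too few
digits), and without a repair channel acting on the best solution the
second half of the run stalls on the GC/Tm trade-off.

Elitism is global: the best-so-far is tracked outside the population and
the per-iteration best-fitness trace is non-increasing by construction.
One seeded generator drives all randomness; identical seeds give
bit-identical runs.

## Baselines

PSO (global-best velocity form, c1 = c2 = 2.05, w = 0.4), GWO
(alpha/beta/delta averaging, control parameter linear 2 → 0), HGS (original
two-weight hunger model, update probability 0.08, hunger cap 10,000) and
RUN (fourth-order Runge–Kutta search mechanism with the
enhanced-solution-quality step). For RUN only parameter values are
canonical here (a = 20 randomness control, f = 0.1 step scaling); they
enter the scale factor SF = 2(0.5 − rand)·f·a·e^(−b·rand·t/T) with b = 12.
All baselines share the fitness evaluator, the [0,3] representation, the
digitization rule and the elitist trace bookkeeping, so differences
reflect search dynamics alone. Baseline implementations are comparison
scaffolding, not tuned reference implementations of record.

## Synthetic payloads

No benchmark text ships with the package; `make_benchmark_text(target_nt,
seed)` generates a deterministic random byte payload encoding to exactly
`target_nt` nucleotides at 2 bits/nt (MSB-first bit pairs; a non-multiple-
of-4 target pads the final byte with zero bits, dropped on decode). The
default study condition is a 1853-nt payload. A uniform random payload
emulates compressed/encrypted user data — the hardest, assumption-free
case; it does not model the letter-frequency structure of natural-language
payloads, so passing tests say nothing about entropy-coding interactions.
Random payloads also make archive Hamming distances concentrate at 0.75·L,
which real correlated payloads need not do.

## Error channel

Three noise regimes model PCR amplification load: low / medium / high at
50 / 200 / 500 central cycles (ranges 10–100, 50–400, 100–1000).
Per-position probabilities scale linearly with central cycles from
per-cycle base rates (substitution 6e−5, insertion 1.6e−4, deletion 4e−5),
calibrated so the high regime lands at 0.03 / 0.08 / 0.02 — an
insertion-dominant, nanopore-like profile. This linear map is a modeling
choice, not a reproduction of any particular simulator. Reads are drawn in
a single left-to-right pass: per reference position one categorical draw
among deletion, insertion-before, substitution, match; indel probabilities
are multiplied by 3 inside homopolymer runs ≥ 4 nt (slippage), renormalized
if boosting would push the total above 1. Substitution alternatives are
uniform over the three other bases; inserted bases uniform over four. Every
read carries a replayable event log, so empirical rate estimates need no
alignment step.

Scoring: NED = Levenshtein distance / max(len) (edlib), in [0,1]. The
decomposition into substitution/insertion/deletion counts uses an in-house
DP backtrace with the deterministic tie-break match > substitution >
deletion > insertion; counts always sum to the edit distance (checked
against an exhaustive recursive oracle and edlib in tests). Homopolymer
attribution: an indel is homopolymer-associated when its reference
position lies in or within 1 nt of a run ≥ 3; "HP count" counts maximal
runs ≥ 3 (the penalty threshold), both configurable. Percentages
conditioned on substitutions are reported as missing, never 0, when no
substitution occurred. The channel is memoryless across positions and
reads; it does not model platform-specific burst errors, quality scores,
or strand bias.

## Numerical choices and degenerate inputs

- sech is computed as 2e^(−d)/(1 + e^(−2d)) to avoid overflow at large
  fitness gaps (where it correctly underflows to 0 — at realistic fitness
  scales the attraction branch fires only between near-equal individuals).
- dg penalty of a length-1 sequence is 0 with a warning (no steps exist).
- Round-half-up digitization (1.5 → 2), NaN positions rejected.
- Friedman comparison: scipy for ≥ 3 algorithms; for exactly 2 the
  classical rank chi-square is computed directly (scipy requires k ≥ 3).
  Identical columns short-circuit to statistic 0, p = 1.
- Per-run seeds in experiments are master_seed + run_index; whole
  experiments are bit-reproducible apart from measured wall-clock times.

## Problem sizes used in the shipped checks

Unit and property tests run on sequences of 4–500 nt. The optimizer
ordering check runs L = 400 nt, N = 30, T = 60, 10 seeds per algorithm
under default weights; channel calibration uses 10⁴ reads of a 1000-nt
reference. These sizes give stable statistics while keeping the full suite
in the minutes range; the library itself handles the full 1853-nt,
N = 50, T = 100, 30-run protocol through `tchur bench`.

## Known limitations

- Absolute fitness values depend on the (non-canonical) weight defaults;
  only orderings under a fixed configuration are meaningful.
- The Tm model is composition-only; no salt/concentration parameterization
  beyond the fixed empirical form, and no secondary-structure prediction
  (MFE folding, hairpin enumeration) — the RC similarity term is a proxy.
- Single-sequence design: no joint design of orthogonal sequence libraries
  or cross-hybridization terms.
- The channel is a structural model of substitution/indel noise, not a
  port of any platform-specific simulator; absolute NED values are
  simulator-specific and not comparable across tools.
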