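# Methods

## The optimization problem

A frequency allocation map (fMAP) assigns each active electrode `i` (indexed
apex-first) a band `[f_low_i, f_high_i]` of the acoustic spectrum. Valid maps
are contiguous (`f_low_{i+1} = f_high_i`), non-overlapping, at least
`min_band_width_hz` wide per band, and every edge lies on the device grid
`global_f_min + k · freq_step_hz`. Deactivated electrodes are excluded up
front: the remaining electrodes are re-chained from the global minimum
frequency, so a dropped electrode's spectral range is absorbed by its apical
neighbour (or simply truncated when the most basal electrode is off). The
most apical active band's lower edge is pinned to the device's global
minimum; only interior edges move.

The search space is parameterized by the vector of upper edges alone. Each
`f_high_i` may range over the *exploration domain*
`[default f_low_i, 1.2 × default f_high_i]` (ceiling quantized down to the
grid), computed from the active-array default map. Because lower edges follow
by chaining, any upper-edge vector determines a unique candidate map after
repair.

### Repair operator

`chain_and_repair` walks apex → base: the chained lower edge is the previous
(repaired) upper edge; the proposed upper edge is clamped into
`[max(f_low + min_width, domain.lo), domain.hi]` and snapped to the grid
(nearest grid point, then re-clamped to the grid-aligned bracket). This is
deterministic, idempotent (a property test exercises both), and perturbs
apical bands least, which matters because the clinically interesting
adjustments concentrate apically. Infeasibility (cumulative minimum widths
exceeding a domain ceiling) raises an error naming the first blocked
electrode; it cannot occur for the shipped profiles' own domains.

### Center frequency

A band's representative frequency is the geometric mean `√(f_low · f_high)`,
the standard summary for logarithmically laid-out analysis channels; an
arithmetic-mean option exists behind a flag. Degenerate bands `(a, a)` map to
`a`.

## The evolutionary loop

Defaults (all in `EvolutionConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_parents` | 4 | random initial maps P1–P4 |
| `children_per_generation` | 3 | C1–C3, C4–C6, C7–C9 |
| `n_generations` | 3 | fixed stop; 13 evaluations in total |
| `mutation_prob` | 0.2 | per-band Gaussian mutation probability |
| `mutation_sigma_frac` | 0.1 | σ as a fraction of the band width |
| `domain_expansion` | 1.2 | upper-edge ceiling over the default |
| `tournament_size` | 2 | drawn with replacement |
| `tournament_win_prob` | 1.0 | better of the draw wins deterministically |
| `crossover_mix` | 0.5 | per-locus probability of copying parent a |

The budget (13 speech tests ≈ one clinical session) is the defining
constraint; there is no convergence criterion.

- **Initialization** samples each upper edge uniformly on the feasible part
  of its domain interval given the already-sampled predecessor (apex → base),
  then repairs onto the grid.
- **Tournament selection** draws two pool members with replacement and keeps
  the higher-scoring one; ties among the drawn break uniformly at random.
  The `tournament_win_prob` knob (default 1.0 = standard deterministic
  2-tournament) allows a stochastic winner if wanted.
- **Crossover** copies each electrode's upper edge verbatim from one parent
  or the other (Bernoulli 0.5 per locus); edges are never averaged. The raw
  child vector may be non-monotone; repair resolves it.
- **Mutation** perturbs upper edges only. Since lower edges are defined by
  chaining, perturbing `f_high` alone spans the same space while structurally
  preserving the no-overlap constraint (mutating both edges independently
  would need a second repair pass for no added expressiveness). σ is scaled
  by the band width of the chained, repaired candidate; `sigma_reference =
  "default"` switches to the default-map width.
- **Survivor selection** is elitist by construction: before each generation
  the breeding pool is recomputed as the `n_parents` highest-scoring maps
  among *all* maps generated so far (so pools are drawn from 4, 7, then 10
  candidates, and the final winner from all 13). Ties at the pool boundary
  break toward the earlier generation, then the earlier creation index —
  deterministic and reproducible.
- **Final selection** returns the highest-scoring map; when several tie, the
  interactive front end presents the candidates for a listener preference,
  and batch mode defaults to the most recently generated of the tied (a
  deterministic stand-in for that preference, on the view that later maps
  incorporate more feedback).

### Determinism and resumability

All randomness derives from per-operation substreams
(`SeedSequence(seed, spawn_key=(k,))`: operation 0 initializes the parents,
operation k ≥ 1 breeds child k). Identical (profile, config, seed, fitness)
therefore give byte-identical transcripts, and a session replayed from its
JSONL event log — one event per proposal, score, survivor update, selection —
resumes bit-identically after an interruption, without serializing raw
generator state. This mirrors the clinical reality that some listeners stop
mid-protocol; the partial state still yields its best-so-far map.

## Fitness

The interactive oracle presents the candidate's band table and asks for an
integer word count (0–10); nothing about previous maps or scores is shown to
the listener. Intermediate tests use 10-word lists; initial and final
evaluations use 20-word lists reported out of ten (hence half-point scores).
The signal-to-noise ratio is fixed per listener and carried as metadata only.

### Simulated listener

The simulated listener is a synthetic construct for testing the optimizer —
no per-candidate band data exist in print that it could be calibrated to, so
its role is property-based validation, not reproduction of any clinical
value. Its components:

- **Hidden ideal map**: drawn uniformly in the exploration domain (one per
  listener seed).
- **Mismatch**: `d = Σ_i w_i · |log2 Fc_i(map) − log2 Fc_i(ideal)|`, a
  weighted octave distance of center frequencies. Weights decay
  geometrically base-ward (`w_i ∝ 0.7^{i−1}`, normalized), making the
  objective most sensitive to apical allocation — the region where
  evolutionary refitting produces its characteristic changes in practice.
- **Psychometric function**: `p = 1 / (1 + exp(−(a − b·d)))` with defaults
  `a = 4`, `b = 25` per octave. `a = 4` saturates the ideal map
  (p ≈ 0.98 → 10/10 noise-free). `b` was sized to the geometry of the search
  space: inside a 1.2× exploration domain the attainable weighted mismatch
  between two random maps averages only ~0.08–0.18 octaves (device-
  dependent), so a slope of 25/octave places random candidates in the
  clinical mid-range (p ≈ 0.4–0.8) instead of on a logistic plateau. These
  values were fixed once from that measurement and are all configurable.
- **Scoring**: `Binomial(n_words, p)` in binomial mode (the realistic case:
  10-word lists are noisy) or `round(n_words · p)` noise-free (for
  deterministic properties such as elitism per seed).

What the simulation does *not* model: SNR dependence, learning or fatigue
across the session, acclimatization between fitting and final evaluation,
channel interaction, or any vocoder-level acoustics. Consequently, passing
the in-silico gain tests shows that the operator stack can recover a hidden
optimum through binomial noise at a 13-test budget — it does not show that
human listeners improve, and the package makes no such claim. In particular
the clinical effect size (4.17 → 6.46 words) is not reproducible in silico
and is only ever *reported* from the packaged study table.

## Tonotopy

Greenwood's human place-frequency function is
`F(x) = 165.4 · (10^{2.1x} − 0.88)` Hz. The implementation takes `x` as the
*relative distance from the apex* (`F(0) = 19.85` Hz at the apex,
`F(1) ≈ 20677` Hz at the base), which is the standard convention and the
only orientation consistent with the function's values — source texts
sometimes describe `x` as measured from the round window while tabulating
apex-referenced measurements, so `ElectrodeGeometry` makes the orientation
explicit (`from_apex` / `from_round_window`) and converts via the involution
`x ↦ L − x`. The inverse (frequency → place) is closed-form and round-trips
to better than 1e−9. No basilar-membrane vs lateral-wall length correction
is applied to CT measurements, and spiral-ganglion mappings are out of scope.

## Session-table statistics

The packaged table (`data/table2.csv`) transcribes a 27-listener study:
initial WRS, per-listener SNR, the 13 candidate scores (trailing cells empty
for the two listeners who stopped early, after 8 and 6 maps), the selected
map, and the final WRS. Consistency checks enforce that missing scores occur
only in trailing positions and that the selected map carries the row-maximum
score.

Two reporting quirks are handled deliberately:

- The dispersion printed as "±" in the source behaves as a **sample SD**
  (0.97 on n = 27; a standard error would be ≈ 0.19), even though the text
  declares standard errors. Summaries report both `sd` and `sem`; golden
  values target the SD.
- The source prints an initial median of 3.5 (range 2–5) that is
  inconsistent with its own table (median 4, range 3–6, which *does*
  reproduce the printed mean and SD exactly). The table is treated as
  authoritative; the initial median is therefore not a golden value.

### Wilcoxon signed-rank

Implemented in-package (scipy's version serves as an independent cross-check
in tests, never as the implementation). Zero differences are discarded by
default (classic Wilcoxon; Pratt's method is available), tied absolute
differences get mid-ranks. For effective n ≤ 12 the null distribution of the
positive-rank sum is enumerated exactly over all 2^n sign assignments
(correct under ties, where the classical tables are not); above that, a
normal approximation with tie-corrected variance and a 0.5 continuity
correction is used — the two branches agree to < 0.02 at the boundary. The
two-sided p is twice the smaller tail, capped at 1. All-zero differences are
degenerate: p = 1 with a warning.

## Problem sizes used in validation

The packaged validation runs use 200 paired seeded sessions for the
optimization-gain experiment (mean gains stabilize well below that), 1000
random sessions spread over the four shipped device profiles for the
constraint invariants, 10⁴ random vectors for repair idempotence, and 100
random instances for the Wilcoxon enumeration cross-check. The whole suite
runs in a few seconds on one CPU.

## Known limitations

- Shipped default band tables are representative (log-spaced, grid-aligned),
  not factory data; clinical use must supply the device's real table as a
  profile JSON.
- The 1.2× expansion of a truncated (deactivated-edge) array is taken
  relative to the re-chained active-array default, and the topmost band may
  mathematically exceed the device's default global maximum by up to 20%;
  whether vendor software accepts such values is device-specific.
- Loudness (T/M-level) fitting, coding-strategy simulation, and
  questionnaire instruments are out of scope.
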