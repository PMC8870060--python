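# eafit — evolutionary fitting of cochlear-implant frequency maps

Cochlear implants split the acoustic spectrum into contiguous analysis bands,
one per electrode (the frequency allocation map, or *fMAP*). Default maps are
factory settings; for users who combine an implant with acoustic hearing in
the other ear ("bimodal" listeners), the mismatch between the implant's
place-frequency coding and the acoustic ear can limit speech understanding in
noise. Because the space of admissible band allocations is huge and the only
trustworthy objective is the listener's own word recognition score (WRS),
this is a natural setting for an *interactive* evolutionary algorithm: the
human is the fitness function.

`eafit` implements that protocol as a library for audiology researchers and
methods developers:

- **Constraint model** — device profiles (electrode count, grid step,
  minimum band width, deactivated electrodes), contiguous non-overlapping
  band maps, and a deterministic repair operator. Each electrode's upper
  band edge `f_HIGH` explores `[f_LOW, 1.2 × f_HIGH]` around the default;
  lower edges follow by chaining, so overlaps and gaps cannot occur.
- **Search** — 4 random parent maps, then 3 generations of 3 children bred
  by size-2 tournament selection (with replacement), per-locus uniform
  crossover of upper edges, and Gaussian mutation (probability 0.2 per band,
  σ = 0.1 × band width). Survivor selection is elitist: each generation's
  breeding pool is the 4 best maps among *all* maps generated so far, and the
  final map is the best of all 13 candidates. Scores are WRS-in-noise out of
  ten, entered by a human (interactive callback, resumable JSONL session
  log) or produced by a simulated listener.
- **Simulated listener** — a synthetic oracle whose recognition probability
  falls logistically with the apically-weighted octave distance between a
  candidate's center frequencies and a hidden ideal map, with binomial
  10-word scoring noise. It exists to make the optimizer testable; no human
  data are fit by it.
- **Tonotopy** — the Greenwood place-frequency function
  `F = 165.4·(10^{2.1x} − 0.88)` (x = relative distance from the apex) for
  CT-measured electrode positions, and center-frequency comparisons between
  tonotopic, default, and optimized maps.
- **Statistics** — summaries of a packaged 27-listener study table (initial
  vs final WRS, which search stage produced the winning map, tie counts) and
  an internally implemented exact/approximate Wilcoxon signed-rank test.

## Worked example

```sh
python examples/session_table_statistics.py
```

```
listeners: 27
initial WRS: 4.17 +/- 0.97 /10 (41.67%), median 4
final WRS:   6.46 +/- 1.63 /10 (64.63%), median 7
selected map by stage: {'parents': 6, 'gen1': 7, 'gen2': 6, 'gen3': 8}
listeners with tied top scores: 9
Wilcoxon signed-rank (initial vs final): W = 13, p = 5.75e-05  (approx, n_eff = 25)
```

Initial scores are measured with the default map, final scores with the
evolutionary map 45–60 days after fitting, both on 20-word lists at each
listener's fixed SNR; the improvement is about 2.3 words out of ten. The
winning candidate appeared at every stage of the search — including the
random parents — and a third of listeners ended with several maps tied at
the top score, where the listener's sound-quality preference decides.

A full simulated fitting session:

```sh
python examples/simulated_fitting_session.py
```

prints the 13-map transcript, the selected map's band table, and its hidden
octave mismatch versus the best random parent. `examples/optimization_gain.py`
runs 100 paired sessions and reports the mean score gain of the search over
its own random initialization together with a one-sided sign test and the
mean reduction in hidden mismatch.

There is also a thin CLI: `eafit session start/score/next/best/export`
(stepwise human-in-the-loop sessions persisted as JSONL and resumable after
interruption), `eafit simulate`, `eafit greenwood`, `eafit table2-report`,
and `eafit validate-profile`.

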