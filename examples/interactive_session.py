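"""Scripted walk-through of the human-in-the-loop scoring protocol.

Uses the interactive fitness callback with a scripted input stream standing
in for the clinician typing word counts, so the whole session runs
unattended here.  With a real listener, run ``eafit session run`` (one
prompt per candidate map) or drive it stepwise across visits with
``eafit session start / score / next / best`` backed by a JSONL event log.
"""

import io

from eafit import EvolutionConfig, interactive_fitness, load_profile, run_session

profile = load_profile("cochlear22")

# thirteen word counts, one per candidate map, as a clinician would type them
scripted_scores = "4\n5\n3\n6\n6\n5\n7\n6\n8\n7\n7\n9\n8\n"
prompts = io.StringIO()
callback = interactive_fitness(io.StringIO(scripted_scores), prompts,
                               n_words=10, snr_db=5.0)

best, state = run_session(profile, EvolutionConfig(rng_seed=3), callback)

print(f"evaluated {state.evaluated_count} maps; "
      f"selected {best.id} with {best.score:g}/10 words correct")
print("first prompt shown to the operator:")
print("\n".join(prompts.getvalue().splitlines()[:6]))

# Each prompt prints the candidate's full band table and asks for an integer
# 0-10; invalid entries re-prompt and closing the input aborts the session
# with a resumable state (the two listeners who stopped early in practice).
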