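"""Event-sourced persistence for fitting sessions (JSONL).

A fitting session can span hours and may be interrupted (some listeners
abandon mid-protocol), so session state is persisted as an append-only JSONL
event log — one event per proposal, score entry, survivor-pool update and
final selection — and reconstructed by :func:`replay`.  Because the
evolutionary engine draws randomness from per-operation substreams of the
session seed, a replayed session proposes exactly the maps the live session
would have.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

from .evolution import EvolutionConfig, SessionState
from .fmap_core import DeviceProfile, FrequencyMap, make_exploration_domain

__all__ = ["LogError", "append_events", "replay", "write_log"]


class LogError(ValueError):
    """A session log is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


def _stamp(event: dict) -> dict:
    if "t" not in event:
        event = {"t": _dt.datetime.now(_dt.timezone.utc).isoformat(), **event}
    return event


def write_log(state: SessionState, path: str | Path) -> None:
    """Write the full event log of a session as JSONL."""
    lines = [json.dumps(_stamp(ev)) for ev in state.events]
    Path(path).write_text("\n".join(lines) + "\n")


def append_events(state: SessionState, path: str | Path, n_known: int) -> None:
    """Append the events created after the first ``n_known`` to the log."""
    new = state.events[n_known:]
    if not new:
        return
    with open(path, "a") as fh:
        for ev in new:
            fh.write(json.dumps(_stamp(ev)) + "\n")


def read_events(path: str | Path) -> list[dict]:
    events = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        try:
            events.append(json.loads(raw))
        except json.JSONDecodeError as e:
            raise LogError(f"corrupted event: {e.msg}", line=ln) from e
    return events


def replay(events_or_path) -> SessionState:
    """Rebuild a session from its event log.

    Accepts a path to a JSONL file or an in-memory event list.  The result is
    identical to the live session after its last event; a truncated log
    yields the corresponding resumable partial state.
    """
    if isinstance(events_or_path, (str, Path)):
        events = read_events(events_or_path)
    else:
        events = list(events_or_path)
    if not events or events[0].get("kind") != "init":
        raise LogError("log must start with an init event", line=1)
    init = events[0]
    profile = DeviceProfile.from_dict(init["profile"])
    config = EvolutionConfig.from_dict(init["config"])
    domain = make_exploration_domain(profile, expansion=config.domain_expansion)
    state = SessionState(profile=profile, config=config, domain=domain)
    state.events.append({k: v for k, v in init.items() if k != "t"})
    for ln, ev in enumerate(events[1:], start=2):
        kind = ev.get("kind")
        body = {k: v for k, v in ev.items() if k != "t"}
        if kind == "propose":
            fmap = FrequencyMap(
                electrodes=tuple(ev["electrodes"]),
                bands=tuple((lo, hi) for lo, hi in ev["bands"]),
                id=ev["id"],
                origin=ev["origin"],
                generation=int(ev["generation"]),
                creation_index=int(ev.get("creation_index", len(state.individuals))),
            )
            state.individuals.append(fmap)
            state.generation = max(state.generation, fmap.generation)
        elif kind == "score":
            state.get(ev["id"]).score = float(ev["score"])
        elif kind == "survivors":
            state.survivor_ids = list(ev["pool"])
        elif kind in ("select_best", "abort", "init"):
            pass
        else:
            raise LogError(f"unknown event kind: {kind!r}", line=ln)
        state.events.append(body)
    return state
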