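"""Session-table statistics and the Wilcoxon signed-rank test.

Works on a per-listener session table: initial word recognition score (WRS,
out of ten, 20-word list), the fixed per-listener SNR, the thirteen candidate
scores (four parents P1-P4 and nine children C1-C9, 10-word lists; trailing
cells empty for listeners who abandoned mid-protocol), the label of the
finally selected map, and the final WRS measured 45-60 days after fitting.
A transcription of the published 27-listener study table ships with the
package and is the default input.

The paired initial-vs-final comparison uses a Wilcoxon signed-rank test
implemented here: exact null by enumeration of sign assignments for small
effective n, normal approximation with tie-corrected variance and continuity
correction otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "CANDIDATE_COLUMNS",
    "GENERATION_OF",
    "WilcoxonResult",
    "best_generation_counts",
    "load_table2",
    "summarize_wrs",
    "table2_report",
    "tie_counts",
    "validate_table",
    "wilcoxon_signed_rank",
    "wrs_to_percent",
]

CANDIDATE_COLUMNS = ("P1", "P2", "P3", "P4",
                     "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "C9")

GENERATION_OF = {
    **{c: "parents" for c in ("P1", "P2", "P3", "P4")},
    **{c: "gen1" for c in ("C1", "C2", "C3")},
    **{c: "gen2" for c in ("C4", "C5", "C6")},
    **{c: "gen3" for c in ("C7", "C8", "C9")},
}


def load_table2(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged 27-listener session table (or a CSV in its schema)."""
    if path is None:
        with resources.as_file(
            resources.files("eafit").joinpath("data/table2.csv")
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return df


def validate_table(df: pd.DataFrame) -> list[str]:
    """Schema and consistency diagnostics for a session table.

    Checks that candidate scores are missing only in trailing positions (the
    abandon pattern) and that each row's selected map carries the row-maximum
    score among the maps that were actually tested.
    """
    problems = []
    needed = {"patient", "initial_wrs", "snr_db", "selected", "final_wrs",
              *CANDIDATE_COLUMNS}
    missing_cols = needed - set(df.columns)
    if missing_cols:
        return [f"missing columns: {sorted(missing_cols)}"]
    for _, row in df.iterrows():
        pid = row["patient"]
        scores = row[list(CANDIDATE_COLUMNS)].astype(float)
        isna = scores.isna().to_numpy()
        if isna.any() and not isna[np.argmax(isna):].all():
            problems.append(f"patient {pid}: interior missing candidate score")
        if not isna.all():
            sel = row["selected"]
            if sel not in CANDIDATE_COLUMNS:
                problems.append(f"patient {pid}: unknown selected label {sel!r}")
            elif not np.isclose(scores[sel], np.nanmax(scores.to_numpy())):
                problems.append(
                    f"patient {pid}: selected {sel} is not the row maximum"
                )
    return problems


def wrs_to_percent(score_out_of_ten: float) -> float:
    """A WRS out of ten as a percentage of words correct."""
    s = np.asarray(score_out_of_ten, dtype=float)
    if np.any(s < 0) or np.any(s > 10):
        raise ValueError("WRS out of ten must lie in [0, 10]")
    out = s * 10.0
    return float(out) if np.isscalar(score_out_of_ten) else out


def _column_summary(x: pd.Series) -> dict:
    x = x.astype(float)
    if x.empty or x.isna().any():
        raise ValueError("summary column is empty or has missing entries")
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "sem": float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0,
        "median": float(x.median()),
        "min": float(x.min()),
        "max": float(x.max()),
        "mean_percent": float(x.mean() * 10.0),
        "sd_percent": float(x.std(ddof=1) * 10.0) if x.size > 1 else 0.0,
    }


def summarize_wrs(df: pd.DataFrame) -> dict:
    """Initial and final WRS summaries (mean, sample SD, SEM, median, range).

    The plus/minus values in the source report behave as sample standard
    deviations (SEM on n=27 would be ~5x smaller), so ``sd`` is the headline
    dispersion; ``sem`` is reported alongside.
    """
    return {
        "initial": _column_summary(df["initial_wrs"]),
        "final": _column_summary(df["final_wrs"]),
    }


def best_generation_counts(df: pd.DataFrame) -> dict:
    """How many listeners' selected map came from each stage of the search."""
    counts = {"parents": 0, "gen1": 0, "gen2": 0, "gen3": 0}
    for _, row in df.iterrows():
        label = row["selected"]
        if label not in GENERATION_OF:
            raise ValueError(f"unknown selected-map label: {label!r}")
        counts[GENERATION_OF[label]] += 1
    return counts


def tie_counts(df: pd.DataFrame) -> int:
    """Listeners for whom several candidate maps share the maximum score."""
    n = 0
    for _, row in df.iterrows():
        scores = row[list(CANDIDATE_COLUMNS)].astype(float).dropna().to_numpy()
        if scores.size and (scores == scores.max()).sum() >= 2:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float        # min(W+, W-), the conventional report
    w_plus: float
    w_minus: float
    p_value: float          # two-sided
    n_effective: int
    method: str             # "exact" | "approx" | "degenerate"


def wilcoxon_signed_rank(
    x,
    y,
    zero_method: str = "wilcoxon",
    method: str = "auto",
    exact_threshold: int = 12,
) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are discarded (classic Wilcoxon; ``zero_method='pratt'``
    keeps them in the ranking but excludes their ranks from both sums).
    Tied absolute differences receive mid-ranks.  For effective n up to
    ``exact_threshold`` the null distribution of W+ is enumerated over all
    2^n sign assignments (exact even under ties); above it, a normal
    approximation with tie-corrected variance and continuity correction is
    used.  If every difference is zero the test is degenerate: p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length 1-d samples")
    d = x - y
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; Wilcoxon test is degenerate")
        return WilcoxonResult(0.0, 0.0, 0.0, 1.0, 0, "degenerate")
    if zero_method == "wilcoxon":
        d = d[d != 0]
        ranks = rankdata(np.abs(d))
    elif zero_method == "pratt":
        ranks_all = rankdata(np.abs(d))
        ranks = ranks_all[d != 0]
        d = d[d != 0]
    else:
        raise ValueError(f"unknown zero_method: {zero_method!r}")
    n = d.size
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())

    if method == "auto":
        method = "exact" if n <= exact_threshold else "approx"
    if method == "exact":
        p = _exact_two_sided_p(ranks, w_plus)
    elif method == "approx":
        p = _approx_two_sided_p(ranks, w_plus, n)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return WilcoxonResult(min(w_plus, w_minus), w_plus, w_minus,
                          float(min(p, 1.0)), n, method)


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by full enumeration of the 2^n sign assignments."""
    n = ranks.size
    # all subset sums of the rank vector: distribution of W+ under H0
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    tol = 1e-9
    p_le = np.mean(sums <= w_plus + tol)
    p_ge = np.mean(sums >= w_plus - tol)
    return 2.0 * min(p_le, p_ge)


def _approx_two_sided_p(ranks: np.ndarray, w_plus: float, n: int) -> float:
    """Normal approximation with tie-corrected variance and continuity correction."""
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_sizes = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_sizes**3 - tie_sizes) / 48.0
    if var <= 0:
        return 1.0
    dev = w_plus - mu
    # continuity correction shrinks the deviation by half a rank unit
    dev = np.sign(dev) * max(abs(dev) - 0.5, 0.0)
    z = dev / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


def table2_report(df: pd.DataFrame | None = None) -> dict:
    """Full summary of a session table: the package's headline statistics.

    Includes the WRS summaries, the selected-map generation counts, the
    tie count, and the paired initial-vs-final Wilcoxon signed-rank test.
    """
    if df is None:
        df = load_table2()
    problems = validate_table(df)
    if problems:
        raise ValueError("invalid session table: " + "; ".join(problems))
    wil = wilcoxon_signed_rank(df["initial_wrs"], df["final_wrs"])
    return {
        "n_patients": int(len(df)),
        "wrs": summarize_wrs(df),
        "best_generation_counts": best_generation_counts(df),
        "tie_count": tie_counts(df),
        "wilcoxon_initial_vs_final": {
            "statistic": wil.statistic,
            "p_value": wil.p_value,
            "n_effective": wil.n_effective,
            "method": wil.method,
        },
    }
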