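"""Peri-event behavioral selectivity of calcium traces.

For each cell and behavior, mean dF/F in the 2.5 s window before each behavior
onset is compared with the 2.5 s window after it by a paired t-test across
onsets, with Bonferroni correction over the behaviors tested for that cell.
Selectivity counts are then tabulated by assigned fluorophore identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EventSeries",
    "SelectivityResult",
    "peri_event_selectivity",
    "selectivity_table",
    "selectivity_counts",
]


@dataclass(frozen=True)
class EventSeries:
    """Onset times (seconds, sorted, nonnegative) of one behavior in one session."""

    behavior: str
    onsets: tuple[float, ...]
    session: str = ""

    def __post_init__(self):
        arr = np.asarray(self.onsets, dtype=float)
        if np.any(arr < 0):
            raise ValueError("onset times must be nonnegative")
        if np.any(np.diff(arr) < 0):
            raise ValueError("onset times must be sorted")


@dataclass
class SelectivityResult:
    """Per cell x behavior t-test outcome with Bonferroni-corrected decision."""

    cell_id: str
    behavior: str
    t_statistic: float
    p_value: float
    corrected_alpha: float
    selective: bool
    n_epochs: int
    n_dropped: int = 0
    n_overlapping: int = 0
    testable: bool = True


def _epoch_means(trace, fs, onsets, window):
    """(pre, post) mean dF/F per usable epoch; epochs without full windows dropped."""
    trace = np.asarray(trace, dtype=float)
    half = int(round(window * fs))
    pre, post, used = [], [], []
    for t in onsets:
        k = int(round(t * fs))
        if k - half < 0 or k + half > trace.size:
            continue
        pre.append(trace[k - half : k].mean())
        post.append(trace[k : k + half].mean())
        used.append(k)
    # epochs whose windows overlap a previous epoch are retained but counted
    overlapping = sum(
        1 for a, b in zip(used, used[1:]) if b - a < 2 * half
    )
    return np.array(pre), np.array(post), len(onsets) - len(used), overlapping


def peri_event_selectivity(
    trace,
    events: EventSeries,
    fs: float = 20.0,
    window: float = 2.5,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    cell_id: str = "",
    paired: bool = True,
) -> SelectivityResult:
    """Test whether a cell's activity differs before versus after behavior onsets.

    Each onset contributes a (pre, post) mean-activity pair over ``window``
    seconds; a two-sided paired t-test across epochs (Welch unpaired available
    via ``paired=False``) is compared against ``alpha / n_comparisons``
    (Bonferroni over the behaviors tested for this cell).  Onsets without full
    windows inside the trace are dropped and counted; with fewer than two
    usable epochs the result is flagged untestable rather than raising.
    """
    if fs <= 0 or window <= 0:
        raise ValueError("fs and window must be positive")
    pre, post, dropped, overlapping = _epoch_means(trace, fs, events.onsets, window)
    corrected = alpha / max(n_comparisons, 1)
    if pre.size < 2:
        return SelectivityResult(
            cell_id, events.behavior, float("nan"), float("nan"), corrected,
            False, int(pre.size), dropped, overlapping, testable=False,
        )
    if np.allclose(pre, post):
        t_stat, p_val = 0.0, 1.0
    elif paired:
        t_stat, p_val = stats.ttest_rel(post, pre)
    else:
        t_stat, p_val = stats.ttest_ind(post, pre, equal_var=False)
    return SelectivityResult(
        cell_id,
        events.behavior,
        float(t_stat),
        float(p_val),
        corrected,
        bool(p_val < corrected),
        int(pre.size),
        dropped,
        overlapping,
    )


def selectivity_table(
    traces: pd.DataFrame,
    event_series: list[EventSeries],
    fs: float = 20.0,
    window: float = 2.5,
    alpha: float = 0.05,
    paired: bool = True,
) -> list[SelectivityResult]:
    """Run the peri-event test for every cell column x behavior.

    ``traces`` holds one column per cell (a ``time`` column, if present, is
    ignored); the Bonferroni correction spans the behaviors tested per cell.
    """
    cells = [c for c in traces.columns if c != "time"]
    m = len(event_series)
    out = []
    for cell in cells:
        for ev in event_series:
            out.append(
                peri_event_selectivity(
                    traces[cell].to_numpy(), ev, fs=fs, window=window,
                    alpha=alpha, n_comparisons=m, cell_id=str(cell), paired=paired,
                )
            )
    return out


def selectivity_counts(
    results: list[SelectivityResult],
    identities: dict[str, str | None] | None = None,
) -> pd.DataFrame:
    """Per-cell count of selective behaviors, grouped by assigned identity.

    ``identities`` maps cell id -> primary fluorophore (``None`` -> grouped as
    ``"no match"``); omitted cells are likewise "no match".  Duplicate
    cell/behavior rows are an error.
    """
    seen = set()
    for r in results:
        key = (r.cell_id, r.behavior)
        if key in seen:
            raise ValueError(f"duplicate result for cell {r.cell_id!r} / {r.behavior!r}")
        seen.add(key)
    identities = identities or {}
    rows: dict[str, dict] = {}
    for r in results:
        row = rows.setdefault(
            r.cell_id,
            {
                "cell_id": r.cell_id,
                "identity": identities.get(r.cell_id) or "no match",
                "n_selective": 0,
                "behaviors": [],
            },
        )
        if r.selective:
            row["n_selective"] += 1
            row["behaviors"].append(r.behavior)
    df = pd.DataFrame(rows.values())
    if not df.empty:
        df["behaviors"] = df["behaviors"].map(";".join)
    return df
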