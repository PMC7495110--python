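"""State-sequence dynamics: dwell/fraction/visit/transition summaries,
group-pooled transition probabilities, and attractor extraction.

A *visit* is a maximal run of one state; a *transition* is any change of
label between consecutive windows.  Transition probabilities are defined over
state changes only (the diagonal is excluded); a diagonal-inclusive matrix is
also carried for completeness.  Mean dwell time is reported in windows, with
unvisited states marked NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .states import StateSequence

logger = logging.getLogger(__name__)


@dataclass
class StateMetrics:
    """Per-subject dynamics summary over k states (1-based labels)."""

    subject_id: str
    k: int
    ft: np.ndarray            # fraction of windows per state; sums to 1
    mdt: np.ndarray           # mean dwell time in windows; NaN if unvisited
    visits: np.ndarray        # number of maximal runs per state
    n_transitions: int        # label changes between consecutive windows
    specific: np.ndarray      # k x k off-diagonal a->b change counts
    n_windows: int


@dataclass
class TransitionModel:
    """Group-pooled transition structure over state changes."""

    group: str
    k: int
    counts: np.ndarray                 # k x k pooled off-diagonal counts
    probs: np.ndarray                  # rows normalized over off-diagonal; NaN rows undefined
    probs_with_self: np.ndarray        # diagonal-inclusive row-normalized matrix
    attractor: dict = field(default_factory=dict)


def state_metrics(seq: StateSequence, k: int) -> StateMetrics:
    """Summarize one subject's 1-based state sequence."""
    states = np.asarray(seq.states, dtype=int)
    n = states.size
    if n == 0:
        raise ValueError(f"subject {seq.subject_id}: empty state sequence")
    if states.min() < 1 or states.max() > k:
        raise ValueError(f"subject {seq.subject_id}: labels outside 1..{k}")
    counts = np.bincount(states, minlength=k + 1)[1:]
    ft = counts / n
    change = states[1:] != states[:-1]
    boundaries = np.flatnonzero(change)
    run_starts = np.concatenate([[0], boundaries + 1])
    run_lengths = np.diff(np.concatenate([run_starts, [n]]))
    run_states = states[run_starts]
    visits = np.bincount(run_states, minlength=k + 1)[1:]
    mdt = np.full(k, np.nan)
    for s in range(1, k + 1):
        if visits[s - 1]:
            mdt[s - 1] = run_lengths[run_states == s].mean()
    specific = np.zeros((k, k), dtype=int)
    np.add.at(specific, (states[:-1][change] - 1, states[1:][change] - 1), 1)
    return StateMetrics(
        subject_id=seq.subject_id,
        k=k,
        ft=ft,
        mdt=mdt,
        visits=visits,
        n_transitions=int(change.sum()),
        specific=specific,
        n_windows=n,
    )


def metrics_table(metrics: list[StateMetrics], tr_seconds: float | None = None) -> pd.DataFrame:
    """One row per subject: ft_1..k, mdt_1..k, visits_1..k, n_transitions and
    the k(k-1) specific-transition counts.  If ``tr_seconds`` is given, dwell
    times are additionally reported in seconds."""
    rows = []
    for m in metrics:
        row: dict[str, object] = {"subject_id": m.subject_id, "n_transitions": m.n_transitions}
        for s in range(m.k):
            row[f"ft_{s + 1}"] = m.ft[s]
            row[f"mdt_{s + 1}"] = m.mdt[s]
            if tr_seconds is not None:
                row[f"mdt_{s + 1}_seconds"] = m.mdt[s] * tr_seconds
            row[f"visits_{s + 1}"] = int(m.visits[s])
        for a in range(m.k):
            for b in range(m.k):
                if a != b:
                    row[f"trans_{a + 1}_to_{b + 1}"] = int(m.specific[a, b])
        rows.append(row)
    return pd.DataFrame(rows)


def pool_transitions(metrics: list[StateMetrics], k: int, group: str = "all") -> TransitionModel:
    """Sum subjects' specific-transition counts (never across subject
    boundaries) and row-normalize; rows with no outgoing change are NaN."""
    if not metrics:
        raise ValueError("no subjects to pool")
    counts = np.zeros((k, k), dtype=int)
    for m in metrics:
        counts += m.specific
    out_mass = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(out_mass > 0, counts / out_mass, np.nan)
    # diagonal-inclusive variant: a run of length L holds L-1 self-transitions
    self_counts = counts.astype(float)
    diag = np.zeros(k)
    for m in metrics:
        windows_per_state = np.round(np.asarray(m.ft) * m.n_windows)
        diag += np.maximum(windows_per_state - m.visits, 0)
    self_counts[np.diag_indices(k)] += diag
    mass = self_counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs_self = np.where(mass > 0, self_counts / mass, np.nan)
    model = TransitionModel(
        group=group, k=k, counts=counts, probs=probs, probs_with_self=probs_self
    )
    model.attractor = extract_attractor(model)
    return model


def extract_attractor(tm: TransitionModel) -> dict:
    """Cycles of the maximal-probability successor map.

    ``successor(s)`` is the argmax of row s of the change-only transition
    probabilities (ties toward the lower index).  The attractor is the set of
    cycles of this functional graph; off-cycle states are reported with their
    path into a cycle.  States with undefined rows are excluded.
    """
    successor: dict[int, int] = {}
    for s in range(tm.k):
        row = tm.probs[s]
        if np.isnan(row).all():
            logger.info("state %d has no outgoing transitions; excluded from attractor", s + 1)
            continue
        masked = np.where(np.isnan(row), -np.inf, row)
        masked[s] = -np.inf
        successor[s + 1] = int(masked.argmax()) + 1
    graph = nx.DiGraph(successor.items())
    cycles = [sorted(c) for c in nx.simple_cycles(graph)]
    on_cycle = {s for c in cycles for s in c}
    feeders: dict[int, list[int]] = {}
    for s in successor:
        if s in on_cycle:
            continue
        path = [s]
        cur = s
        while cur in successor and successor[cur] not in path:
            cur = successor[cur]
            path.append(cur)
            if cur in on_cycle:
                break
        feeders[s] = path
    return {"successor": successor, "cycles": sorted(cycles), "feeders": feeders}
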