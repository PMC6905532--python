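"""Group-level state transition matrices and most-probable itineraries.

Transition counts are pooled over a group's subjects (scan boundaries
contribute no transitions) and row-normalized.  An itinerary from a source
state repeatedly follows the most probable transition to a *new distinct*
state — the diagonal is excluded, and self-transition probabilities are
reported separately — until a previously visited state recurs.  The walk
then splits into a transient prefix and a closed periodic orbit; by
pigeonhole it closes within k distinct steps.  Argmax ties resolve to the
lowest state index, deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger("brainpolarity")


@dataclass
class TransitionModel:
    matrix: np.ndarray                 # (k, k) row-stochastic over defined rows
    self_transition_probs: np.ndarray  # (k,) diagonal of matrix
    counts: np.ndarray                 # (k, k) integer transition counts
    group: str = ""

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    @property
    def defined_rows(self) -> np.ndarray:
        """Boolean mask of states with at least one observed outgoing transition."""
        return self.counts.sum(axis=1) > 0


@dataclass
class Itinerary:
    transient: list            # ordered distinct states before orbit entry
    orbit: list                # ordered distinct states of the closed cycle
    absorbing: bool = False    # True when the walk dead-ends (no off-diagonal mass)

    @property
    def orbit_length(self) -> int:
        return len(self.orbit)


def estimate_transitions(
    label_sequences: Sequence[np.ndarray],
    n_states: int | None = None,
    group_mask: Sequence[bool] | None = None,
    group: str = "",
    method: str = "pooled",
) -> TransitionModel:
    """Group-level transition matrix from per-subject state sequences.

    ``method='pooled'`` (default) pools transition counts across the
    group's subjects before normalizing; ``method='mean'`` averages the
    per-subject row-normalized matrices instead.  No transition crosses a
    subject boundary.  Rows of states never observed as a source are left
    all-zero and flagged undefined.
    """
    seqs = [np.asarray(s, dtype=int) for s in label_sequences]
    if group_mask is not None:
        mask = np.asarray(group_mask, dtype=bool)
        seqs = [s for s, keep in zip(seqs, mask) if keep]
    if not seqs or any(s.size == 0 for s in seqs):
        raise ValueError("label sequences must be nonempty")
    if n_states is None:
        n_states = int(max(s.max() for s in seqs)) + 1
    counts = np.zeros((n_states, n_states), dtype=int)
    per_subject = []
    for s in seqs:
        c = np.zeros((n_states, n_states), dtype=int)
        np.add.at(c, (s[:-1], s[1:]), 1)
        counts += c
        per_subject.append(c)

    def _normalize(c: np.ndarray) -> np.ndarray:
        row = c.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(row > 0, c / row, 0.0)
        return m

    if method == "pooled":
        matrix = _normalize(counts)
    elif method == "mean":
        mats, weights = [], []
        for c in per_subject:
            mats.append(_normalize(c))
            weights.append((c.sum(axis=1) > 0).astype(float))
        w = np.sum(weights, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            matrix = np.where(
                w[:, None] > 0,
                np.sum([m * wt[:, None] for m, wt in zip(mats, weights)], axis=0)
                / np.maximum(w, 1)[:, None],
                0.0,
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    undefined = counts.sum(axis=1) == 0
    if undefined.any():
        logger.warning(
            "states %s never observed as source; rows undefined",
            np.flatnonzero(undefined).tolist(),
        )
    return TransitionModel(
        matrix=matrix,
        self_transition_probs=np.diag(matrix).copy(),
        counts=counts,
        group=group,
    )


def most_probable_itinerary(model: TransitionModel, source: int) -> Itinerary:
    """Follow argmax off-diagonal transitions from ``source`` until a repeat.

    Returns the transient prefix and the closed orbit of distinct states.
    A state whose off-diagonal mass is all zero terminates the walk with an
    empty orbit, flagged absorbing.
    """
    k = model.n_states
    if not 0 <= source < k:
        raise ValueError(f"source state {source} out of range [0, {k})")
    if not model.defined_rows[source]:
        raise ValueError(f"source state {source} has an undefined row")
    visited: list[int] = [int(source)]
    current = int(source)
    for _ in range(k + 1):
        row = model.matrix[current].copy()
        row[current] = 0.0              # itineraries step to distinct states
        if row.max() <= 0.0:
            logger.warning("state %d is absorbing (no off-diagonal mass)", current)
            return Itinerary(transient=visited, orbit=[], absorbing=True)
        nxt = int(np.argmax(row))       # ties -> lowest index
        if nxt in visited:
            entry = visited.index(nxt)
            return Itinerary(transient=visited[:entry], orbit=visited[entry:])
        visited.append(nxt)
        current = nxt
    raise AssertionError("itinerary failed to close within k steps")  # pragma: no cover


def compare_group_itineraries(
    model_a: TransitionModel,
    model_b: TransitionModel,
    sources: Sequence[int],
    polarity_class: Sequence[str] | None = None,
) -> dict:
    """Per-source itineraries for two groups, with orbit summaries.

    When a CoPP ``polarity_class`` list is given (from
    :func:`brainpolarity.copp.classify_copps`), the report also says whether
    each orbit visits a strongly polarized (non-neutral) state.
    """
    if model_a.n_states != model_b.n_states:
        raise ValueError("models are over different state sets")

    def _entry(model: TransitionModel, src: int) -> dict:
        it = most_probable_itinerary(model, src)
        entry = {
            "transient": it.transient,
            "orbit": it.orbit,
            "orbit_length": it.orbit_length,
            "absorbing": it.absorbing,
        }
        if polarity_class is not None:
            entry["orbit_polarized"] = any(
                polarity_class[s] != "neutral" for s in it.orbit
            )
        return entry

    report = {}
    for src in sources:
        report[int(src)] = {
            model_a.group or "a": _entry(model_a, src),
            model_b.group or "b": _entry(model_b, src),
        }
    return report
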