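"""Proximity-scored association indices and similarity networks.

Daily sightings are scored 2 (close, < 15 m, or interacting), 1 (medium,
15-100 m in the same cohesive unit) or 0 (not associated).  The per-dyad
edge weight is a proximity-weighted variant of the simple ratio index:

    E_AB = x_SUM / (2 * x_COUNT + y_AB + y_A + y_B)

where x_SUM is the summed daily scores, x_COUNT the number of days the dyad
was sighted together (daily score >= 1), y_AB the days both were observed
but not together, and y_A / y_B the days only one of them was seen.  When
every joint sighting scores 2 this collapses to the classic simple ratio
index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORY_SCORE = {"close": 2, "medium": 1, "far": 0, "seen": 0}


@dataclass
class DyadTally:
    """Raw per-dyad tallies behind the association index."""

    x_sum: int = 0
    x_count: int = 0
    y_ab: int = 0
    y_a: int = 0
    y_b: int = 0

    @property
    def denominator(self) -> int:
        return 2 * self.x_count + self.y_ab + self.y_a + self.y_b


@dataclass
class AssociationMatrix:
    """Symmetric dyadic edge weights E_AB in [0, 1]."""

    ids: list
    values: np.ndarray
    tallies: dict  # frozenset({a, b}) -> DyadTally
    undefined: set  # dyads with zero denominator, scored 0 and flagged

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def pair(self, a, b) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def _log_individuals(log: pd.DataFrame) -> list:
    ids = set(log["individual_a"])
    ids |= {b for b in log["individual_b"] if b}
    return sorted(ids)


def _observed_by_day(log: pd.DataFrame) -> dict:
    obs = {}
    for day, sub in log.groupby("day"):
        seen = set(sub["individual_a"])
        seen |= {b for b in sub["individual_b"] if b}
        obs[int(day)] = seen
    return obs


def daily_matrix(log: pd.DataFrame, day: int, ids: list | None = None) -> pd.DataFrame:
    """Symmetric integer score matrix {0,1,2} for one day.

    A dyad recorded more than once in a day takes its maximum score; far and
    not-co-sighted both score 0.
    """
    if day not in set(log["day"]):
        raise ValueError(f"day {day} not present in sighting log")
    ids = list(ids) if ids is not None else _log_individuals(log)
    known = set(ids)
    mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for _, row in log[log["day"] == day].iterrows():
        a, b = row["individual_a"], row["individual_b"]
        if a not in known or (b and b not in known):
            raise ValueError(f"unknown individual id in sighting log: {a!r}/{b!r}")
        if not b:
            continue
        score = CATEGORY_SCORE[row["category"]]
        if score > mat.at[a, b]:
            mat.at[a, b] = score
            mat.at[b, a] = score
    return mat


def association_index(log: pd.DataFrame, ids: list | None = None) -> AssociationMatrix:
    """Modified simple-ratio index over all days of a sighting log."""
    if len(log) == 0:
        raise ValueError("empty sighting log")
    ids = list(ids) if ids is not None else _log_individuals(log)
    index = {ind: k for k, ind in enumerate(ids)}
    observed = _observed_by_day(log)
    n = len(ids)
    tallies = {}
    values = np.zeros((n, n))
    daily = {day: daily_matrix(log, day, ids) for day in observed}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            t = DyadTally()
            for day, seen in observed.items():
                a_seen, b_seen = a in seen, b in seen
                if a_seen and b_seen:
                    score = int(daily[day].iat[i, j])
                    if score >= 1:
                        t.x_count += 1
                        t.x_sum += score
                    else:
                        t.y_ab += 1
                elif a_seen:
                    t.y_a += 1
                elif b_seen:
                    t.y_b += 1
            tallies[frozenset((a, b))] = t
    undefined = set()
    for key, t in tallies.items():
        a, b = sorted(key)
        if t.denominator == 0:
            undefined.add(key)
            e = 0.0
        else:
            e = t.x_sum / t.denominator
        values[index[a], index[b]] = values[index[b], index[a]] = e
    if undefined:
        logger.warning("%d dyads never observed; E set to 0", len(undefined))
    return AssociationMatrix(ids, values, tallies, undefined)


def similarity_network(dist) -> pd.DataFrame:
    """Microbiome similarity edges: 1/distance, mean-thresholded.

    Zero distances map to the largest finite similarity observed (flagged in
    the ``clamped`` column).  Edges with similarity strictly below the mean
    off-diagonal similarity are dropped.
    """
    ids, vals = dist.ids, dist.values
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    iu = np.triu_indices(n, k=1)
    d = vals[iu]
    with np.errstate(divide="ignore"):
        sim = 1.0 / d
    finite = sim[np.isfinite(sim)]
    if finite.size == 0:
        raise ValueError("all pairwise distances are zero")
    clamp = ~np.isfinite(sim)
    sim[clamp] = finite.max()
    mean_sim = sim.mean()
    rows = []
    for k, (i, j) in enumerate(zip(*iu)):
        if sim[k] >= mean_sim:
            rows.append(
                {"id_a": ids[i], "id_b": ids[j], "weight": sim[k],
                 "clamped": bool(clamp[k])}
            )
    return pd.DataFrame(rows, columns=["id_a", "id_b", "weight", "clamped"])


def association_edges(assoc: AssociationMatrix) -> pd.DataFrame:
    """Nonzero association-index edges as an edge list."""
    rows = []
    n = len(assoc.ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = assoc.values[i, j]
            if w > 0:
                rows.append({"id_a": assoc.ids[i], "id_b": assoc.ids[j], "weight": w})
    return pd.DataFrame(rows, columns=["id_a", "id_b", "weight"])


def to_graphml(edges: pd.DataFrame, path) -> None:
    """Export an edge list for external network-visualisation tools."""
    import networkx as nx

    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["id_a"], row["id_b"], weight=float(row["weight"]))
    nx.write_graphml(g, path)
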