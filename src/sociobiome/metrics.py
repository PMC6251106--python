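"""Core-microbiome extraction, pairwise dissimilarities, dyad categorisation.

Jensen-Shannon divergence is computed with natural logarithms, so values lie
in [0, ln 2 ~ 0.693]; its square root is a metric.  Bray-Curtis on
relative-abundance rows equals half the L1 distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import rel_entr

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with labelled axes."""

    ids: list
    values: np.ndarray
    metric_name: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.values) > 1e-12) or np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative with zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metric_name: str) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("square matrix required with matching index/columns")
        return cls(list(df.index), df.to_numpy(dtype=float), metric_name)

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric_name)

    def pair(self, a, b) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class CoreConfig:
    """Detection/prevalence thresholds for the core microbiome.

    A taxon is core when its relative abundance is at least ``detection``
    in at least ceil(prevalence * n_samples) samples.
    """

    detection: float = 1e-5   # 0.001 %
    prevalence: float = 0.999  # 99.9 %

    def __post_init__(self):
        if not 0 < self.detection < 1:
            raise ValueError("detection must be in (0, 1)")
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")


def core_microbiome(rel: pd.DataFrame, cfg: CoreConfig | None = None) -> tuple:
    """Core SV subset and the table restricted to it (NOT re-normalized)."""
    cfg = cfg or CoreConfig()
    n = rel.shape[0]
    required = math.ceil(cfg.prevalence * n)
    hits = (rel.to_numpy() >= cfg.detection).sum(axis=0)
    keep = rel.columns[hits >= required]
    if len(keep) == 0:
        logger.warning("core microbiome is empty at detection=%g prevalence=%g",
                       cfg.detection, cfg.prevalence)
    return list(keep), rel[keep]


def _check_normalized(rel: pd.DataFrame) -> np.ndarray:
    x = rel.to_numpy(dtype=float)
    if np.any(x < -1e-12):
        raise ValueError("negative abundances")
    sums = x.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = rel.index[np.abs(sums - 1.0) > 1e-6][:5].tolist()
        raise ValueError(f"rows not normalized to 1: {bad}")
    return np.clip(x, 0.0, None)


def bray_curtis(rel: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y) (= L1/2 on normalized rows).

    Rows need not sum to exactly 1: a core-subset table is deliberately not
    re-normalized after column filtering, and the formula handles it.
    """
    x = rel.to_numpy(dtype=float)
    if np.any(x < -1e-12):
        raise ValueError("negative abundances")
    if np.any(x.sum(axis=1) <= 0):
        raise ValueError("rows with zero total abundance")
    x = np.clip(x, 0.0, None)
    vals = squareform(pdist(x, metric="braycurtis"))
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(rel.index), vals, "bray_curtis")


def jsd_pair(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log) between two profiles."""
    m = 0.5 * (p + q)
    return float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())


def jensen_shannon(rel: pd.DataFrame) -> DistanceMatrix:
    """Pairwise JSD matrix, natural log, entries in [0, ln 2]."""
    x = _check_normalized(rel)
    n = x.shape[0]
    # entropy trick: JSD(P,Q) = H(M) - (H(P)+H(Q))/2 with natural-log entropy
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(x > 0, x * np.log(x), 0.0)
    h = -plogp.sum(axis=1)
    vals = np.zeros((n, n))
    for i in range(n):
        m = 0.5 * (x[i] + x[i:])
        with np.errstate(divide="ignore", invalid="ignore"):
            hm = -np.where(m > 0, m * np.log(m), 0.0).sum(axis=1)
        vals[i, i:] = hm - 0.5 * (h[i] + h[i:])
    vals = np.clip(vals + vals.T, 0.0, LN2)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(rel.index), vals, "jsd")


@dataclass
class DyadDistanceSet:
    """All dyads of one comparison family, ready for the mixed model/ANOVA.

    ``pairs`` columns: id_a, id_b, category, group, distance, focal, other,
    band.  ``focal``/``other`` are the two individuals behind the dyad (equal
    for within-individual sample pairs); both enter the mixed model as
    crossed random intercepts.  ``group`` refines the category where the
    ANOVA needs one cell per band or band pair (e.g. within_Aber,
    between_Aber-Marsh).
    """

    family: str
    pairs: pd.DataFrame = field(repr=False)

    @property
    def categories(self) -> list:
        return sorted(self.pairs["category"].unique())

    def mean_by_category(self) -> pd.Series:
        return self.pairs.groupby("category")["distance"].mean()


def _pair_row(a, b, category, group, dist, focal, other, band):
    return {
        "id_a": a, "id_b": b, "category": category, "group": group,
        "distance": dist, "focal": focal, "other": other, "band": band,
    }


def categorize_dyads_samples(
    dist: DistanceMatrix, metadata: pd.DataFrame
) -> DyadDistanceSet:
    """Sample-level dyads: within-individual vs between-individual (same band).

    Pairs of samples from different bands are excluded; the focal individual
    is the shared one for within-individual pairs, else the alphabetically
    first.
    """
    ids = dist.ids
    ind = metadata.loc[ids, "individual_id"]
    band = metadata.loc[ids, "band"]
    rows = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            if band.iloc[i] != band.iloc[j]:
                continue
            if ind.iloc[i] == ind.iloc[j]:
                cat = "within_individual"
                focal = other = ind.iloc[i]
            else:
                cat = "between_individual_within_band"
                focal = min(ind.iloc[i], ind.iloc[j])
                other = max(ind.iloc[i], ind.iloc[j])
            rows.append(
                _pair_row(a, b, cat, cat, dist.values[i, j], focal, other, band.iloc[i])
            )
    return DyadDistanceSet("individual", pd.DataFrame(rows))


def categorize_dyads_individuals(dist: DistanceMatrix, relmap) -> dict:
    """Individual-level dyad families over average-microbiome distances.

    Returns {"band": ..., "maternal": ..., "stallion": ...} DyadDistanceSets.
    band: within_band vs between_band (group = within_<band> /
    between_<b1>-<b2>).  maternal: mare x juvenile pairs within band,
    split into mother_offspring / nonmaternal_mare_juvenile /
    foalless_mare_juvenile ("juvenile" = foals and sub-adults combined).
    stallion: stallion_mare vs mare_mare within band.
    """
    ids = dist.ids
    missing_band = [i for i in ids if i not in relmap.band_of]
    if missing_band:
        logger.warning("individuals lacking band excluded: %s", missing_band)
        ids = [i for i in ids if i not in set(missing_band)]
    mothers_with_offspring = {
        m for j, m in relmap.mother_of.items() if j in set(ids)
    }
    band_rows, maternal_rows, stallion_rows = [], [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = dist.pair(a, b)
            ba, bb = relmap.band_of[a], relmap.band_of[b]
            focal, other = min(a, b), max(a, b)
            if ba == bb:
                band_rows.append(
                    _pair_row(a, b, "within_band", f"within_{ba}", d, focal, other, ba)
                )
            else:
                lo, hi = sorted((ba, bb))
                band_rows.append(
                    _pair_row(a, b, "between_band", f"between_{lo}-{hi}", d, focal, other, lo)
                )
                continue
            ra, rb = relmap.role_of[a], relmap.role_of[b]
            pair_roles = {ra, rb}
            if pair_roles == {"mare"}:
                stallion_rows.append(
                    _pair_row(a, b, "mare_mare", "mare_mare", d, focal, other, ba)
                )
            elif pair_roles == {"stallion", "mare"}:
                stallion_rows.append(
                    _pair_row(a, b, "stallion_mare", "stallion_mare", d, focal, other, ba)
                )
            juv, mare = None, None
            if ra in ("foal", "sub-adult") and rb == "mare":
                juv, mare = a, b
            elif rb in ("foal", "sub-adult") and ra == "mare":
                juv, mare = b, a
            if juv is not None:
                if relmap.mother_of.get(juv) == mare:
                    cat = "mother_offspring"
                elif mare in mothers_with_offspring:
                    cat = "nonmaternal_mare_juvenile"
                else:
                    cat = "foalless_mare_juvenile"
                maternal_rows.append(_pair_row(a, b, cat, cat, d, focal, other, ba))
    return {
        "band": DyadDistanceSet("band", pd.DataFrame(band_rows)),
        "maternal": DyadDistanceSet("maternal", pd.DataFrame(maternal_rows)),
        "stallion": DyadDistanceSet("stallion", pd.DataFrame(stallion_rows)),
    }
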