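"""Synthetic fixture generator for band-structured gut microbiome studies.

Emulates a population of group-living ponies: harem bands (one stallion,
several mares, their immature offspring), repeated faecal sampling per
individual over a field season, and daily proximity-based sightings.  The
generative model is a symmetric Dirichlet population baseline perturbed by
multiplicative lognormal effects at the band, individual, and sample level,
with convex mixing of expected profiles along bonded dyads (mother-offspring
and stallion-mare) and multinomial read sampling.

All randomness flows from ``SimConfig.seed`` through a single
``numpy.random.SeedSequence``; identical configs give byte-identical
fixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

RANKS = ["Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species"]

# Dominant anaerobic families of grass-eating hindgut fermenters; SVs are
# assigned round-robin so genus-level agglomeration is exercised downstream.
DEFAULT_FAMILIES = [
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
    ("Spirochaetae", "Spirochaetes", "Spirochaetales", "Spirochaetaceae"),
    ("Fibrobacteres", "Fibrobacteria", "Fibrobacterales", "Fibrobacteraceae"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Christensenellaceae"),
    ("Firmicutes", "Erysipelotrichia", "Erysipelotrichales", "Erysipelotrichaceae"),
    ("Firmicutes", "Negativicutes", "Selenomonadales", "Acidaminococcaceae"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidales_BS11"),
]


@dataclass(frozen=True)
class BandComposition:
    """Role counts for one band: exactly one stallion plus the rest."""

    mares: int
    subadult_f: int = 0
    subadult_m: int = 0
    foal_f: int = 0
    foal_m: int = 0

    @property
    def size(self) -> int:
        return 1 + self.mares + self.subadult_f + self.subadult_m + self.foal_f + self.foal_m


@dataclass
class SimConfig:
    """Generative parameters for a synthetic band-structured microbiome study.

    Variance components (``sigma_*``) are standard deviations of log-scale
    multiplicative perturbations; ``lambda_*`` are convex mixing weights in
    [0, 1] pulling offspring toward their mother and mares toward the band
    stallion.  Defaults emulate a population where roughly half of
    compositional variance is attributable to individual identity, ~15-20%
    to band membership, and ~25% to within-individual turnover.
    """

    band_names: list = field(default_factory=lambda: ["Aber", "Marsh", "Valley"])
    compositions: list = field(
        default_factory=lambda: [
            BandComposition(mares=6, subadult_m=1, foal_f=1),
            BandComposition(mares=7, subadult_f=1, foal_f=2, foal_m=2),
            BandComposition(mares=4, subadult_f=1, subadult_m=1, foal_m=1),
        ]
    )
    n_svs: int = 300
    base_concentration: float = 0.5
    sigma_band: float = 0.55
    sigma_ind: float = 0.7
    sigma_sample: float = 0.9
    foal_shift: float = 1.1
    lambda_mother: float = 0.25
    lambda_stallion: float = 0.15
    samples_per_individual: tuple = (3, 5)
    depth_range: tuple = (8000, 43000)
    n_days: int = 10
    p_band_cohesion: float = 0.8
    p_subset_inclusion: float = 0.7
    p_close_base: float = 0.2
    p_close_bonded: float = 0.9
    seed: int = 0

    def __post_init__(self):
        self.compositions = [
            c if isinstance(c, BandComposition) else BandComposition(**c)
            for c in self.compositions
        ]
        if len(self.band_names) != len(self.compositions):
            raise ValueError("band_names and compositions must have equal length")
        for p in (self.p_band_cohesion, self.p_subset_inclusion, self.p_close_base,
                  self.p_close_bonded):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for lam in (self.lambda_mother, self.lambda_stallion):
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"mixing weight {lam} outside [0, 1]")
        for s in (self.sigma_band, self.sigma_ind, self.sigma_sample, self.foal_shift):
            if s < 0:
                raise ValueError(f"negative variance component {s}")
        if self.n_svs < 1:
            raise ValueError("n_svs must be positive")
        if self.base_concentration <= 0:
            raise ValueError("base_concentration must be positive")
        lo, hi = self.samples_per_individual
        if lo < 1 or hi < lo:
            raise ValueError("invalid samples_per_individual range")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError("depth_range lower bound must be >= 1")

    @property
    def n_bands(self) -> int:
        return len(self.band_names)

    @property
    def band_sizes(self) -> list:
        return [c.size for c in self.compositions]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["compositions"] = [asdict(c) for c in self.compositions]
        d["samples_per_individual"] = list(self.samples_per_individual)
        d["depth_range"] = list(self.depth_range)
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("samples_per_individual", "depth_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RelationshipMap:
    """Kinship, role, and band structure of the simulated population."""

    band_of: dict
    role_of: dict  # stallion | mare | sub-adult | foal
    life_stage_of: dict  # foal | sub-adult | adult
    sex_of: dict  # F | M
    mother_of: dict  # juvenile -> mare (partial)
    stallion_of_band: dict

    @property
    def individuals(self) -> list:
        return list(self.band_of)

    def juveniles(self) -> list:
        """Foals and sub-adults combined, the unit of the maternal comparison."""
        return [i for i, s in self.life_stage_of.items() if s in ("foal", "sub-adult")]

    def bonded_pairs(self) -> set:
        """Mother-offspring and stallion-mare dyads, as frozensets."""
        pairs = {frozenset((j, m)) for j, m in self.mother_of.items()}
        for band, stallion in self.stallion_of_band.items():
            for ind, b in self.band_of.items():
                if b == band and self.role_of[ind] == "mare":
                    pairs.add(frozenset((stallion, ind)))
        return pairs

    def validate(self) -> None:
        for juv, mum in self.mother_of.items():
            if self.band_of[juv] != self.band_of[mum]:
                raise ValueError(f"mother {mum} and offspring {juv} in different bands")
        bands = set(self.band_of.values())
        if set(self.stallion_of_band) != bands:
            raise ValueError("every band must have exactly one stallion")


def build_relationship_map(config: SimConfig) -> RelationshipMap:
    """Lay out individuals, roles, sexes, and maternal links for a config.

    Mothers are assigned deterministically: juveniles of a band (foals
    first) are matched to distinct mares in order, so some mares are
    left without offspring ("foal-less mares").
    """
    band_of, role_of, stage_of, sex_of, mother_of, stallion_of = {}, {}, {}, {}, {}, {}
    for band, comp in zip(config.band_names, config.compositions):
        stallion = f"{band}_S1"
        stallion_of[band] = stallion
        band_of[stallion], role_of[stallion] = band, "stallion"
        stage_of[stallion], sex_of[stallion] = "adult", "M"
        mares = [f"{band}_M{i + 1}" for i in range(comp.mares)]
        for m in mares:
            band_of[m], role_of[m], stage_of[m], sex_of[m] = band, "mare", "adult", "F"
        juveniles = []
        for i in range(comp.foal_f):
            juveniles.append((f"{band}_F{i + 1}", "foal", "F"))
        for i in range(comp.foal_m):
            juveniles.append((f"{band}_F{comp.foal_f + i + 1}", "foal", "M"))
        for i in range(comp.subadult_f):
            juveniles.append((f"{band}_J{i + 1}", "sub-adult", "F"))
        for i in range(comp.subadult_m):
            juveniles.append((f"{band}_J{comp.subadult_f + i + 1}", "sub-adult", "M"))
        for k, (ind, stage, sex) in enumerate(juveniles):
            band_of[ind], stage_of[ind], sex_of[ind] = band, stage, sex
            role_of[ind] = stage
            if k < len(mares):
                mother_of[ind] = mares[k]
    relmap = RelationshipMap(band_of, role_of, stage_of, sex_of, mother_of, stallion_of)
    relmap.validate()
    return relmap


def _streams(config: SimConfig) -> dict:
    """Named independent generator streams fanned out from the single seed."""
    names = ["baseline", "band", "individual", "foal", "samples", "sightings", "days"]
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def simulate_profiles(config: SimConfig, relmap: RelationshipMap) -> pd.DataFrame:
    """Expected relative-abundance profile per individual (rows sum to 1).

    Baseline ~ symmetric Dirichlet(base_concentration); multiplicative
    exp(Normal(0, sigma)) effects shared within band, per individual, and an
    extra foal-specific shift; then convex mixing pulls each mare toward the
    band stallion and each offspring toward its mother's (mixed) profile.
    """
    relmap.validate()
    streams = _streams(config)
    k = config.n_svs
    baseline = streams["baseline"].dirichlet(np.full(k, config.base_concentration))
    band_eff = {
        b: np.exp(streams["band"].normal(0.0, config.sigma_band, k))
        for b in config.band_names
    }
    # one shared shift for all foals (a common milk-diet-like community),
    # so foals separate as a group in ordination
    foal_eff = np.exp(streams["foal"].normal(0.0, config.foal_shift, k))
    inds = relmap.individuals
    profiles = {}
    for ind in inds:
        eff = baseline * band_eff[relmap.band_of[ind]]
        eff = eff * np.exp(streams["individual"].normal(0.0, config.sigma_ind, k))
        if relmap.life_stage_of[ind] == "foal":
            eff = eff * foal_eff
        total = eff.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError(f"profile for {ind} failed to normalize")
        profiles[ind] = eff / total
    # mares first so offspring mix with the mother's final profile
    if config.lambda_stallion > 0:
        for ind in inds:
            if relmap.role_of[ind] == "mare":
                st = relmap.stallion_of_band[relmap.band_of[ind]]
                profiles[ind] = (
                    (1 - config.lambda_stallion) * profiles[ind]
                    + config.lambda_stallion * profiles[st]
                )
    if config.lambda_mother > 0:
        for juv, mum in relmap.mother_of.items():
            profiles[juv] = (
                (1 - config.lambda_mother) * profiles[juv]
                + config.lambda_mother * profiles[mum]
            )
    sv_ids = [f"SV{i + 1}" for i in range(k)]
    out = pd.DataFrame.from_dict(profiles, orient="index", dtype=float)
    out.columns = sv_ids
    out.index.name = "individual_id"
    return out


def simulate_counts(
    profiles: pd.DataFrame, config: SimConfig, relmap: RelationshipMap
) -> tuple:
    """Multinomial read counts per sample plus the sample metadata table.

    Each individual contributes a uniform number of samples in
    ``samples_per_individual``; each sample perturbs the individual profile
    by exp(Normal(0, sigma_sample)), renormalizes, and draws counts at a
    depth uniform in ``depth_range``.
    """
    if not np.allclose(profiles.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("profiles must be normalized")
    lo_s, hi_s = config.samples_per_individual
    lo_d, hi_d = config.depth_range
    if lo_d < 1:
        raise ValueError("depth_range lower bound must be >= 1")
    rng = _streams(config)["samples"]
    rows, meta = [], []
    sample_ids = []
    for ind in profiles.index:
        n_samp = int(rng.integers(lo_s, hi_s + 1))
        base = profiles.loc[ind].to_numpy()
        days = np.sort(rng.integers(1, config.n_days + 1, size=n_samp))
        for j in range(n_samp):
            p = base * np.exp(rng.normal(0.0, config.sigma_sample, base.size))
            p = p / p.sum()
            depth = int(rng.integers(lo_d, hi_d + 1))
            rows.append(rng.multinomial(depth, p))
            sid = f"{ind}_s{j + 1}"
            sample_ids.append(sid)
            meta.append(
                {
                    "sample_id": sid,
                    "individual_id": ind,
                    "band": relmap.band_of[ind],
                    "life_stage": relmap.life_stage_of[ind],
                    "sex": relmap.sex_of[ind],
                    "mother_id": relmap.mother_of.get(ind, ""),
                    "role": relmap.role_of[ind],
                    "day": int(days[j]),
                }
            )
    counts = pd.DataFrame(np.asarray(rows), index=sample_ids, columns=profiles.columns)
    counts.index.name = "sample_id"
    metadata = pd.DataFrame(meta).set_index("sample_id")
    return counts, metadata


def simulate_taxonomy(config: SimConfig) -> pd.DataFrame:
    """Round-robin taxonomy over dominant hindgut families, with SV lengths.

    About 30% of SVs are left unassigned at genus/species level (empty
    strings) so taxonomy back-fill is exercised; a small tail of SVs gets
    lengths above the usual amplicon length so the length filter removes
    something.
    """
    sv_ids = [f"SV{i + 1}" for i in range(config.n_svs)]
    n_genera_per_family = 6
    rows = []
    for i, sv in enumerate(sv_ids):
        phylum, cls, order, family = DEFAULT_FAMILIES[i % len(DEFAULT_FAMILIES)]
        if i % 10 < 7:
            genus = f"{family}_g{(i // len(DEFAULT_FAMILIES)) % n_genera_per_family + 1}"
            species = ""
        else:
            genus = ""
            species = ""
        rows.append(
            {
                "sv_id": sv,
                "Kingdom": "Bacteria",
                "Phylum": phylum,
                "Class": cls,
                "Order": order,
                "Family": family,
                "Genus": genus,
                "Species": species,
                "length": 253 if i % 97 != 0 or i == 0 else 265,
            }
        )
    return pd.DataFrame(rows).set_index("sv_id")


def simulate_sightings(relmap: RelationshipMap, config: SimConfig) -> pd.DataFrame:
    """Daily sighting log with proximity categories.

    Each day a band is observed as one cohesive unit with probability
    ``p_band_cohesion``, otherwise a random cohesive subset is observed.
    Within a co-sighted unit, bonded dyads (mother-offspring, stallion-mare)
    are close with probability ``p_close_bonded`` and other dyads with
    ``p_close_base``; non-close co-sighted dyads are medium.  Individuals
    sighted alone get a lone "seen" row.  Resampled until every individual
    is sighted on at least 5 days (requires n_days >= 5).
    """
    columns = ["day", "individual_a", "individual_b", "category"]
    if config.n_days < 0:
        raise ValueError("n_days must be non-negative")
    if config.n_days == 0:
        return pd.DataFrame(columns=columns)  # downstream builders reject this
    min_days = min(5, config.n_days)
    bonded = relmap.bonded_pairs()
    base_rng = _streams(config)["sightings"]
    for _attempt in range(200):
        rng = np.random.default_rng(base_rng.integers(2**31))
        records = []
        seen_days = {ind: 0 for ind in relmap.individuals}
        for day in range(1, config.n_days + 1):
            for band in relmap.stallion_of_band:
                members = [i for i, b in relmap.band_of.items() if b == band]
                if rng.random() < config.p_band_cohesion:
                    present = members
                else:
                    mask = rng.random(len(members)) < config.p_subset_inclusion
                    present = [m for m, keep in zip(members, mask) if keep]
                for ind in present:
                    seen_days[ind] += 1
                if len(present) == 1:
                    records.append((day, present[0], "", "seen"))
                    continue
                for a, b in itertools.combinations(sorted(present), 2):
                    p_close = (
                        config.p_close_bonded
                        if frozenset((a, b)) in bonded
                        else config.p_close_base
                    )
                    cat = "close" if rng.random() < p_close else "medium"
                    records.append((day, a, b, cat))
        if all(v >= min_days for v in seen_days.values()):
            break
    else:
        raise RuntimeError("could not satisfy minimum sighting days in 200 attempts")
    return pd.DataFrame(records, columns=columns)


def simulate_study(config: SimConfig) -> dict:
    """Run the full generator; returns all tables keyed by name."""
    relmap = build_relationship_map(config)
    profiles = simulate_profiles(config, relmap)
    counts, metadata = simulate_counts(profiles, config, relmap)
    taxonomy = simulate_taxonomy(config)
    sightings = simulate_sightings(relmap, config)
    return {
        "config": config,
        "relmap": relmap,
        "profiles": profiles,
        "counts": counts,
        "metadata": metadata,
        "taxonomy": taxonomy,
        "sightings": sightings,
    }


def write_fixture(tables: dict, directory) -> dict:
    """Write counts.tsv, taxonomy.tsv, metadata.tsv, sightings.csv, config.yaml.

    Round-trips losslessly through :func:`sociobiome.io.read_tables`.
    """
    counts = tables["counts"]
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("refusing to write an empty count table")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "taxonomy": directory / "taxonomy.tsv",
        "metadata": directory / "metadata.tsv",
        "sightings": directory / "sightings.csv",
        "config": directory / "config.yaml",
    }
    counts.to_csv(paths["counts"], sep="\t")
    tables["taxonomy"].to_csv(paths["taxonomy"], sep="\t")
    tables["metadata"].to_csv(paths["metadata"], sep="\t")
    tables["sightings"].to_csv(paths["sightings"], index=False)
    tables["config"].to_yaml(paths["config"])
    return paths


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced study layout for replicated Monte-Carlo experiments.

    Three bands of 7 (1 stallion, 3 mares, 1 sub-adult, 2 foals), 120 SVs,
    2-3 samples per individual at depth 2000-4000.  Effect-size defaults are
    inherited from :class:`SimConfig` unless overridden.
    """
    base = dict(
        band_names=["B1", "B2", "B3"],
        compositions=[
            BandComposition(mares=3, subadult_f=1, foal_f=1, foal_m=1)
            for _ in range(3)
        ],
        n_svs=120,
        samples_per_individual=(2, 3),
        depth_range=(2000, 4000),
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)
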