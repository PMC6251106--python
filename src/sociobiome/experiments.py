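"""Replicated Monte-Carlo experiments on synthetic studies.

These are the calibration experiments behind the package's statistical
guarantees: type-I error of the PERMANOVA band test on an exchangeable null,
power and variance-share recovery under planted band effects, and recovery
of the social signal (negative association-distance correlation; maternal
convergence) under the generator's default effect sizes.

All replicate seeds derive from one base seed through
``numpy.random.SeedSequence`` spawning, so a single integer reproduces every
experiment.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import io as sio
from .association import association_index
from .metrics import bray_curtis, categorize_dyads_individuals, jensen_shannon
from .ordination import nmds, ordination_distance
from .pipeline import relmap_from_metadata
from .simulate import BandComposition, SimConfig, simulate_study, small_config
from .stats import dyad_mixed_model, mantel_kendall, permanova


def replicate_seeds(base_seed: int, n: int) -> list:
    """n independent sub-seeds (< 2**31) fanned out from one base seed."""
    return [
        int(ss.generate_state(1)[0] % 2**31)
        for ss in np.random.SeedSequence(base_seed).spawn(n)
    ]


def null_band_config(seed: int) -> SimConfig:
    """Exchangeable no-band-effect null: one sample per individual, no
    shared structure (no band effect, no shared foal community, no dyadic
    mixing).

    With repeated samples per individual the unrestricted-permutation band
    test is anticonservative by construction (samples of one individual are
    correlated and share a band label), so the calibration null must be
    exchangeable at the sample level.
    """
    return small_config(
        seed=seed, sigma_band=0.0, foal_shift=0.0,
        lambda_mother=0.0, lambda_stallion=0.0,
        samples_per_individual=(1, 1),
    )


def maternal_power_config(seed: int, null: bool = False) -> SimConfig:
    """Calibrated fixture for the dyadic-convergence power oracle.

    Effect sizes are the generator defaults; power comes from replication:
    6 bands of 10 (1 stallion, 5 mares, 2 sub-adults, 2 foals), 3-4 samples
    per individual.  ``null`` zeroes the shared structure (band effect and
    dyadic mixing) for the type-I companion check.
    """
    kw = dict(
        band_names=[f"B{i + 1}" for i in range(6)],
        compositions=[
            BandComposition(mares=5, subadult_f=1, subadult_m=1, foal_f=1, foal_m=1)
            for _ in range(6)
        ],
        n_svs=150,
        samples_per_individual=(3, 4),
        depth_range=(3000, 5000),
        seed=seed,
    )
    if null:
        kw.update(sigma_band=0.0, lambda_mother=0.0, lambda_stallion=0.0)
    return SimConfig(**kw)


def band_test_rep(seed: int, n_perm: int = 99, **overrides) -> tuple:
    """One replicate of the PERMANOVA band test on a reduced study.

    Returns (permutation p, band R^2) for the single-term model
    distance ~ band on sample-level Bray-Curtis distances.
    """
    cfg = small_config(seed=seed, **overrides) if overrides else small_config(seed=seed)
    study = simulate_study(cfg)
    rel = sio.to_relative_abundance(study["counts"])
    res = permanova(bray_curtis(rel), study["metadata"], ["band"], n_perm=n_perm, seed=seed)
    return float(res.table.at["band", "p"]), float(res.table.at["band", "R2"])


def null_band_rejection_rate(base_seed: int, n_reps: int = 200, alpha: float = 0.05) -> float:
    """Type-I error of the band test over exchangeable null replicates."""
    rejections = 0
    for seed in replicate_seeds(base_seed, n_reps):
        cfg = null_band_config(seed)
        study = simulate_study(cfg)
        rel = sio.to_relative_abundance(study["counts"])
        res = permanova(
            bray_curtis(rel), study["metadata"], ["band"], n_perm=99, seed=seed
        )
        rejections += res.table.at["band", "p"] <= alpha
    return rejections / n_reps


def band_power_and_r2(base_seed: int, n_reps: int = 50, sigma_band: float | None = None) -> tuple:
    """(rejection rate, mean band R^2) under a planted band effect."""
    overrides = {} if sigma_band is None else {"sigma_band": sigma_band}
    ps, r2s = [], []
    for seed in replicate_seeds(base_seed, n_reps):
        p, r2 = band_test_rep(seed, **overrides)
        ps.append(p)
        r2s.append(r2)
    return float(np.mean([p <= 0.05 for p in ps])), float(np.mean(r2s))


def social_signal_rep(seed: int, null: bool = False) -> dict:
    """One replicate of the spatial/social-signal recovery experiment.

    Runs the individual-level path of the analysis on a reduced study:
    average microbiomes -> Bray-Curtis -> NMDS -> Euclidean distances,
    correlated (Kendall) with the sighting-derived association index; plus
    the maternal dyadic mixed-model contrast on average-microbiome JSD.

    Returns {"tau", "maternal_p", "maternal_ordered"}.
    """
    if null:
        tau_cfg = small_config(
            seed=seed, sigma_band=0.0, lambda_mother=0.0, lambda_stallion=0.0
        )
        mat_cfg = maternal_power_config(seed, null=True)
    else:
        tau_cfg = small_config(seed=seed)
        mat_cfg = maternal_power_config(seed)

    study = simulate_study(tau_cfg)
    merged = sio.merge_by_individual(study["counts"], study["metadata"])
    rel_ind = sio.to_relative_abundance(merged)
    ord_res = nmds(bray_curtis(rel_ind), n_starts=10, seed=seed)
    nmds_dist = ordination_distance(ord_res)
    assoc = association_index(study["sightings"], ids=nmds_dist.ids)
    tau = mantel_kendall(assoc, nmds_dist, n_perm=9, seed=seed).tau

    study_m = simulate_study(mat_cfg)
    relmap = relmap_from_metadata(study_m["metadata"])
    merged_m = sio.merge_by_individual(study_m["counts"], study_m["metadata"])
    jsd = jensen_shannon(sio.to_relative_abundance(merged_m))
    fams = categorize_dyads_individuals(jsd, relmap)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp = dyad_mixed_model(fams["maternal"])
    ordered = bool(
        comp.means.get("mother_offspring", np.inf)
        < comp.means.get("nonmaternal_mare_juvenile", -np.inf)
    )
    return {"tau": float(tau), "maternal_p": float(comp.p), "maternal_ordered": ordered}


def social_signal_rates(base_seed: int, n_reps: int = 50, null: bool = False) -> dict:
    """Aggregate rates over replicates of :func:`social_signal_rep`."""
    reps = [social_signal_rep(s, null=null) for s in replicate_seeds(base_seed, n_reps)]
    taus = np.array([r["tau"] for r in reps])
    return {
        "tau_negative_rate": float(np.mean(taus < 0)),
        "mean_tau": float(taus.mean()),
        "maternal_success_rate": float(
            np.mean([r["maternal_ordered"] and r["maternal_p"] < 0.05 for r in reps])
        ),
        "maternal_rejection_rate": float(
            np.mean([r["maternal_p"] < 0.05 for r in reps])
        ),
    }
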