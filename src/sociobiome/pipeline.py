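"""End-to-end pipeline: simulate/load -> preprocess -> metrics -> ordination
-> networks -> statistics, with a deterministic run manifest and a report.

Every stochastic stage draws its seed from the single global seed through a
named counter, so toggling stages never shifts another stage's stream, and
rerunning with the same inputs and seed reproduces all tabular outputs
bit-identically (the manifest carries their SHA-256 checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as sio
from .association import association_edges, association_index, similarity_network
from .metrics import (
    CoreConfig,
    DistanceMatrix,
    bray_curtis,
    categorize_dyads_individuals,
    categorize_dyads_samples,
    core_microbiome,
    jensen_shannon,
)
from .ordination import group_centroids, nmds, ordination_distance
from .simulate import RelationshipMap, SimConfig, simulate_study, write_fixture
from .stats import band_jsd_anova, dyad_mixed_model, indicator_analysis, mantel_kendall, permanova

logger = logging.getLogger(__name__)

STAGE_SEEDS = {"simulate": 0, "ordination": 1, "permanova": 2, "mantel": 3, "indval": 4}


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    out_dir: Path
    input_dir: Path | None = None  # read fixture from here instead of simulating
    sim: SimConfig | None = None
    core: CoreConfig = field(default_factory=CoreConfig)
    max_sv_length: int | None = 260
    nmds_k: int = 2
    nmds_starts: int = 20
    terms: list = field(default_factory=lambda: ["band", "life_stage", "sex"])
    n_perm: int = 999
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence([self.seed, STAGE_SEEDS[stage]]).generate_state(1)[0]
            % 2**31
        )


def relmap_from_metadata(metadata: pd.DataFrame) -> RelationshipMap:
    """Reconstruct the relationship map from per-sample metadata."""
    per_ind = metadata.drop_duplicates("individual_id").set_index("individual_id")
    band_of = per_ind["band"].to_dict()
    role_of = per_ind["role"].to_dict()
    stage_of = per_ind["life_stage"].to_dict()
    sex_of = per_ind["sex"].to_dict()
    mother_of = {i: m for i, m in per_ind["mother_id"].items() if m}
    stallion_of = {
        band_of[i]: i for i, r in role_of.items() if r == "stallion"
    }
    relmap = RelationshipMap(band_of, role_of, stage_of, sex_of, mother_of, stallion_of)
    relmap.validate()
    return relmap


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the in-memory outputs keyed by name.

    Writes filtered tables, distance matrices, ordination coordinates, the
    association matrix, network edge lists, PERMANOVA tables (total and
    core), the indicator table, dyad-comparison tables, the Mantel result,
    and ``manifest.json``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    outputs: dict = {}

    def save(name: str, df: pd.DataFrame, stage: str, index=True):
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        written[f"{stage}/{name}"] = path

    def run_stage(stage, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(stage, str(exc)) from exc

    # -- inputs -------------------------------------------------------------
    def load():
        if cfg.input_dir is not None:
            return sio.read_tables(cfg.input_dir)
        sim = cfg.sim or SimConfig()
        sim.seed = cfg.stage_seed("simulate")
        tables = simulate_study(sim)
        fixture_dir = out_dir / "fixture"
        write_fixture(tables, fixture_dir)
        return sio.read_tables(fixture_dir)

    table, taxonomy, metadata, sightings = run_stage("input", load)
    relmap = relmap_from_metadata(metadata)
    outputs["relmap"] = relmap

    # -- preprocess ---------------------------------------------------------
    def preprocess():
        t = table
        reports = {}
        if cfg.max_sv_length is not None and t.sv_lengths is not None:
            t, reports["length_filter"] = sio.filter_sv_length(t, cfg.max_sv_length)
        tax = sio.backfill_taxonomy(taxonomy)
        rel = sio.to_relative_abundance(t)
        return t, tax, rel, reports

    table_f, tax_full, rel, filter_reports = run_stage("preprocess", preprocess)
    save("relative_abundance", rel, "preprocess")
    outputs["filter_reports"] = filter_reports

    # -- sample-level distances and PERMANOVA -------------------------------
    def sample_stats():
        bc = bray_curtis(rel)
        jsd = jensen_shannon(rel)
        core_ids, rel_core = core_microbiome(rel, cfg.core)
        res = {
            "bray_curtis_samples": bc,
            "jsd_samples": jsd,
            "core_ids": core_ids,
        }
        seed = cfg.stage_seed("permanova")
        res["permanova_total_id"] = permanova(
            bc, metadata, ["individual_id"], cfg.n_perm, seed
        )
        res["permanova_total_terms"] = permanova(
            bc, metadata, cfg.terms, cfg.n_perm, seed
        )
        if core_ids:
            # core table is deliberately not re-normalized after filtering
            bc_core = bray_curtis(rel_core)
            res["permanova_core_id"] = permanova(
                bc_core, metadata, ["individual_id"], cfg.n_perm, seed
            )
            res["permanova_core_terms"] = permanova(
                bc_core, metadata, cfg.terms, cfg.n_perm, seed
            )
        return res

    sample_res = run_stage("sample_stats", sample_stats)
    outputs.update(sample_res)
    save("distance_bray_samples", sample_res["bray_curtis_samples"].to_frame(), "distance")
    save("distance_jsd_samples", sample_res["jsd_samples"].to_frame(), "distance")
    for key in ("permanova_total_id", "permanova_total_terms",
                "permanova_core_id", "permanova_core_terms"):
        if key in sample_res:
            save(key, sample_res[key].table, "stats")

    # -- within/between-individual dyad comparison --------------------------
    def individual_dyads():
        dyads = categorize_dyads_samples(sample_res["jsd_samples"], metadata)
        comparison = dyad_mixed_model(dyads)
        return dyads, comparison

    sample_dyads, within_between = run_stage("dyads_individual", individual_dyads)
    outputs["dyads_individual"] = sample_dyads
    outputs["comparison_individual"] = within_between
    save("dyads_individual", sample_dyads.pairs, "dyads", index=False)

    # -- average microbiome, band/maternal/stallion comparisons -------------
    def merged_stats():
        merged = sio.merge_by_individual(table_f, metadata)
        rel_ind = sio.to_relative_abundance(merged)
        jsd_ind = jensen_shannon(rel_ind)
        fams = categorize_dyads_individuals(jsd_ind, relmap)
        return merged, rel_ind, jsd_ind, fams

    merged, rel_ind, jsd_ind, families = run_stage("merged", merged_stats)
    outputs["jsd_individuals"] = jsd_ind
    outputs["dyad_families"] = families
    save("average_microbiome", merged, "merged")
    save("distance_jsd_individuals", jsd_ind.to_frame(), "distance")

    def comparisons():
        res = {
            "comparison_band": band_jsd_anova(families["band"]),
            "comparison_maternal": dyad_mixed_model(families["maternal"], pairwise=True),
            "comparison_stallion": dyad_mixed_model(families["stallion"]),
        }
        return res

    comp = run_stage("comparisons", comparisons)
    outputs.update(comp)
    for key, r in comp.items():
        summary = pd.DataFrame({"mean": r.means, "se": r.ses})
        summary.index.name = "category"
        save(key, summary, "stats")
        if r.pairwise is not None:
            save(f"{key}_pairwise", r.pairwise, "stats", index=False)

    # -- indicator analysis: foals vs sub-adults at genus level --------------
    def indval():
        keep = metadata["life_stage"].isin(["foal", "sub-adult"])
        sub = rel.loc[metadata.index[keep & metadata.index.isin(rel.index)]]
        genus = sio.agglomerate(sub, tax_full, "Genus")
        return indicator_analysis(
            genus, metadata["life_stage"], cfg.n_perm, cfg.stage_seed("indval")
        )

    outputs["indicator"] = run_stage("indicator", indval)
    save("indicator_genera", outputs["indicator"].table, "stats")

    # -- ordination of average microbiomes, networks, Mantel -----------------
    def ordination_stage():
        bc_ind = bray_curtis(rel_ind)
        ord_res = nmds(
            bc_ind, k=cfg.nmds_k, n_starts=cfg.nmds_starts,
            seed=cfg.stage_seed("ordination"),
        )
        return bc_ind, ord_res, ordination_distance(ord_res)

    bc_ind, ord_res, nmds_dist = run_stage("ordination", ordination_stage)
    outputs["ordination"] = ord_res
    outputs["nmds_distance"] = nmds_dist
    save("nmds_coordinates", ord_res.to_frame(), "ordination")
    save(
        "nmds_centroids_band",
        group_centroids(ord_res, relmap.band_of),
        "ordination",
    )

    def network_stage():
        assoc = association_index(sightings)
        common = [i for i in nmds_dist.ids if i in set(assoc.ids)]
        assoc_sub_frame = assoc.to_frame().loc[common, common]
        nmds_sub = nmds_dist.subset(common)
        assoc_sub = type(assoc)(
            common, assoc_sub_frame.to_numpy(), assoc.tallies, assoc.undefined
        )
        mantel = mantel_kendall(
            assoc_sub, nmds_sub, cfg.n_perm, cfg.stage_seed("mantel")
        )
        simnet = similarity_network(nmds_sub)
        return assoc, mantel, simnet

    assoc, mantel, simnet = run_stage("network", network_stage)
    outputs["association"] = assoc
    outputs["mantel"] = mantel
    outputs["similarity_network"] = simnet
    save("association_matrix", assoc.to_frame(), "network")
    save("association_edges", association_edges(assoc), "network", index=False)
    save("similarity_edges", simnet, "network", index=False)
    save(
        "mantel",
        pd.DataFrame(
            [{"tau": mantel.tau, "p": mantel.p_perm, "n_perm": mantel.n_perm}]
        ),
        "stats",
        index=False,
    )

    # -- manifest ------------------------------------------------------------
    manifest = {
        "package": "sociobiome",
        "version": __version__,
        "seed": cfg.seed,
        "n_permutations": cfg.n_perm,
        "n_samples": int(rel.shape[0]),
        "n_svs": int(rel.shape[1]),
        "n_individuals": int(len(relmap.individuals)),
        "checksums": {k: _sha256(p) for k, p in sorted(written.items())},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = manifest
    outputs["out_dir"] = out_dir
    return outputs


def make_report(outputs: dict, path: Path | None = None, figures: bool = True) -> str:
    """Render a markdown summary of a pipeline run.

    Sections: PERMANOVA tables, dyadic comparisons (the four families:
    individual, band, maternal, stallion-mare), indicator genera, Mantel
    correlation, ordination stress, and network sizes.  Missing outputs
    skip their section with a notice.  With ``figures`` and an output
    directory, bar charts with SE bars, the NMDS scatter, and network
    drawings are saved as PNGs alongside the report.
    """
    lines = ["# sociobiome run report", ""]

    def section(title):
        lines.extend([f"## {title}", ""])

    section("Variance partitioning (PERMANOVA)")
    any_perm = False
    for key, label in [
        ("permanova_total_id", "Total microbiome ~ individual"),
        ("permanova_total_terms", "Total microbiome ~ band + life stage + sex"),
        ("permanova_core_id", "Core microbiome ~ individual"),
        ("permanova_core_terms", "Core microbiome ~ band + life stage + sex"),
    ]:
        if key in outputs:
            any_perm = True
            tab = outputs[key].table.copy()
            tab["pct_variation"] = 100 * tab["R2"]
            lines.append(f"### {label}")
            lines.append("")
            lines.append(tab.round(4).to_markdown())
            lines.append("")
    if not any_perm:
        lines.append("_PERMANOVA outputs missing; section skipped._")
        lines.append("")

    section("Dyadic divergence comparisons")
    for key, label in [
        ("comparison_individual", "Within vs between individuals (JSD)"),
        ("comparison_band", "Within vs between bands (JSD, average microbiomes)"),
        ("comparison_maternal", "Mother-offspring vs other mare-juvenile dyads"),
        ("comparison_stallion", "Stallion-mare vs mare-mare dyads"),
    ]:
        if key not in outputs:
            lines.append(f"_{label}: missing; skipped._")
            lines.append("")
            continue
        r = outputs[key]
        lines.append(f"### {label}")
        lines.append("")
        summary = pd.DataFrame({"mean": r.means, "se": r.ses}).round(4)
        lines.append(summary.to_markdown())
        df_txt = (
            f"df = {r.df}" if not isinstance(r.df, tuple) else f"df = {r.df[0]},{r.df[1]}"
        )
        lines.append(
            f"\n{r.statistic_name} = {r.statistic:.3f}, {df_txt}, p = {r.p:.4g}"
        )
        if r.pairwise is not None:
            lines.append("")
            lines.append(r.pairwise.round(4).to_markdown(index=False))
        lines.append("")

    section("Indicator genera (foals vs sub-adults)")
    if "indicator" in outputs:
        sig = outputs["indicator"].significant()
        lines.append(f"{len(sig)} genera significant at p < 0.05 "
                     f"(of {len(outputs['indicator'].table)} tested).")
        if len(sig):
            lines.append("")
            lines.append(sig.round(4).to_markdown())
        lines.append("")
    else:
        lines.append("_Indicator output missing; skipped._")
        lines.append("")

    section("Spatial/social structuring")
    if "mantel" in outputs:
        m = outputs["mantel"]
        lines.append(
            f"Kendall matrix correlation between association index and "
            f"NMDS microbiome distance: tau = {m.tau:.3f}, p = {m.p_perm:.4g} "
            f"({m.n_perm} permutations)."
        )
        lines.append("")
    if "ordination" in outputs:
        lines.append(f"NMDS stress (Kruskal stress-1): {outputs['ordination'].stress:.4f}")
        lines.append("")
    if "similarity_network" in outputs and "association" in outputs:
        lines.append(
            f"Similarity network: {len(outputs['similarity_network'])} edges above "
            f"the population-mean similarity; association network over "
            f"{len(outputs['association'].ids)} individuals."
        )
        lines.append("")

    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
        if figures:
            try:
                _report_figures(outputs, Path(path).parent)
            except Exception as exc:  # noqa: BLE001 - figures are best-effort
                logger.warning("figure rendering failed: %s", exc)
    return text


def _report_figures(outputs: dict, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    for key in ("comparison_individual", "comparison_band",
                "comparison_maternal", "comparison_stallion"):
        if key not in outputs:
            continue
        r = outputs[key]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.bar(r.means.index, r.means.values, yerr=r.ses.values, capsize=4)
        ax.set_ylabel("Jensen-Shannon divergence")
        ax.tick_params(axis="x", rotation=30)
        fig.tight_layout()
        fig.savefig(out_dir / f"{key}.png", dpi=120)
        plt.close(fig)

    if "ordination" in outputs and "relmap" in outputs:
        coords = outputs["ordination"].to_frame()
        relmap = outputs["relmap"]
        fig, ax = plt.subplots(figsize=(5, 4.5))
        for band in sorted(set(relmap.band_of.values())):
            members = [i for i in coords.index if relmap.band_of.get(i) == band]
            sub = coords.loc[members]
            ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=band)
        ax.legend()
        ax.set_xlabel("NMDS1")
        ax.set_ylabel("NMDS2")
        fig.tight_layout()
        fig.savefig(out_dir / "nmds_bands.png", dpi=120)
        plt.close(fig)

    for key, fname in (("association", "network_association.png"),
                       ("similarity_network", "network_similarity.png")):
        if key not in outputs:
            continue
        if key == "association":
            edges = association_edges(outputs[key])
        else:
            edges = outputs[key]
        g = nx.Graph()
        for _, row in edges.iterrows():
            g.add_edge(row["id_a"], row["id_b"], weight=float(row["weight"]))
        if g.number_of_nodes() == 0:
            continue
        fig, ax = plt.subplots(figsize=(5, 4.5))
        pos = nx.spring_layout(g, seed=0)
        weights = [g[u][v]["weight"] for u, v in g.edges]
        wmax = max(weights) if weights else 1.0
        nx.draw_networkx(
            g, pos, ax=ax, node_size=120, font_size=5,
            width=[2.5 * w / wmax for w in weights],
        )
        ax.axis("off")
        fig.tight_layout()
        fig.savefig(out_dir / fname, dpi=120)
        plt.close(fig)
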