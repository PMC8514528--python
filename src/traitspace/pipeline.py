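"""End-to-end orchestration: score -> cluster -> network -> embed -> refine -> effects.

Stage order mirrors the analysis narrative: trait/subject clustergram,
partial-correlation graph, 2-D item embedding, embedding-based scale
refinement, a rerun of clustering and graph learning with the refined
scale, and (optionally) the factorial parental-bonding analysis.  All
artifacts are plain text (CSV/TSV/JSON/GraphML/Newick) with fixed
numeric formatting, so a rerun with the same configuration and inputs is
byte-identical; the run report records a SHA-256 hash of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import network as net
from .effects import dichotomize, pbi_average, tukey_hsd, two_way_anova
from .embedding import EmbedParams, mds_embed, tsne_embed
from .refine import prune_items, reassign_items
from .reliability import ReliabilityReport, cronbach_alpha, split_half
from .schema import QuestionnaireSchema
from .scoring import apply_key, exclude_subjects, load_responses, score_traits, zscore_columns
from .synthetic import build_schema, generate_cohort, generate_pbi, study_like_params

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

log = logging.getLogger(__name__)

_FLOAT = "%.10g"


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run.

    With ``responses_csv=None`` a synthetic cohort is generated from the
    default study-like preset using ``seed``; otherwise responses and a
    schema are loaded from the given paths.  ``stages`` toggles
    individual stages (dependencies are not auto-resolved: earlier
    stages feed later ones).
    """

    output_dir: str | Path = "traitspace_out"
    responses_csv: str | Path | None = None
    schema_path: str | Path | None = None
    external_corr_csv: str | Path | None = None
    pbi_csv: str | Path | None = None
    alpha_network: float = 0.01
    theta_refine: float = 0.05
    k_traits: int = 2
    k_subjects: int = 3
    refine_target: str = "SPS"
    embed: EmbedParams = field(default_factory=EmbedParams)
    seed: int = 0
    stages: tuple[str, ...] = ("score", "cluster", "network", "embed", "refine", "effects")

    def validate(self) -> None:
        for p in (self.responses_csv, self.schema_path, self.external_corr_csv, self.pbi_csv):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"configured path does not exist: {p}")
        if (self.responses_csv is None) != (self.schema_path is None):
            raise PipelineError("responses_csv and schema_path must be given together")


@dataclass
class RunReport:
    config: dict
    stages: dict[str, str] = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    summary: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format=_FLOAT, **kw)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages, writing all artifacts to ``output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={**{k: str(v) for k, v in asdict(config).items()}})
    artifacts: list[Path] = []

    def done(stage: str, *paths: Path) -> None:
        report.stages[stage] = "ok"
        artifacts.extend(paths)

    try:
        # ---- inputs ---------------------------------------------------
        truth = None
        if config.responses_csv is None:
            params = study_like_params(seed=config.seed)
            rm, truth = generate_cohort(params)
            schema = build_schema(params)
            rm.to_csv(out / "responses.csv")
            schema.to_yaml(out / "schema.yaml")
            artifacts += [out / "responses.csv", out / "schema.yaml"]
        else:
            schema = (
                QuestionnaireSchema.from_yaml(config.schema_path)
                if str(config.schema_path).endswith((".yml", ".yaml"))
                else QuestionnaireSchema.from_json(config.schema_path)
            )
            raw = load_responses(config.responses_csv)
            rm = apply_key(raw.values, schema, metadata=raw.metadata)
        rm = exclude_subjects(rm) if rm.metadata["excluded"].any() else rm

        # ---- score ----------------------------------------------------
        scores = score_traits(rm, schema)
        trait_z = zscore_columns(scores.traits).values
        item_z = zscore_columns(rm).values
        if "score" in config.stages:
            _write_csv(scores.traits, out / "trait_scores.csv", index_label="subject")
            _write_csv(trait_z, out / "trait_zscores.csv", index_label="subject")
            target_inst = schema.instrument_for_trait(config.refine_target)
            target_items = rm.values[list(target_inst.item_ids)].to_numpy()
            raw_sh, corr_sh = split_half(target_items)
            ReliabilityReport(
                scale=config.refine_target,
                alpha=cronbach_alpha(target_items),
                split_half_raw=raw_sh,
                split_half_corrected=corr_sh,
                k=target_items.shape[1],
                n=target_items.shape[0],
            ).to_json(out / "reliability.json")
            done(
                "score",
                out / "trait_scores.csv",
                out / "trait_zscores.csv",
                out / "reliability.json",
            )

        # ---- cluster --------------------------------------------------
        trait_assign = subj_assign = None
        if "cluster" in config.stages:
            dt = cl.correlation_distance(trait_z, axis="columns")
            dend_t = cl.wpgma_linkage(dt)
            trait_assign = cl.cut_tree(dend_t, config.k_traits)
            ds = cl.correlation_distance(trait_z, axis="rows")
            dend_s = cl.wpgma_linkage(ds)
            subj_assign = cl.cut_tree(dend_s, config.k_subjects)
            comps = cl.composite_scores(trait_z, trait_assign)
            (out / "trait_dendrogram.nwk").write_text(dend_t.to_newick())
            dend_t.to_json(out / "trait_dendrogram.json")
            (out / "subject_dendrogram.nwk").write_text(dend_s.to_newick())
            _write_csv(
                pd.Series(trait_assign.mapping, name="cluster").rename_axis("trait").to_frame(),
                out / "trait_clusters.csv",
            )
            _write_csv(
                pd.Series(subj_assign.mapping, name="group").rename_axis("subject").to_frame(),
                out / "subject_groups.csv",
            )
            _write_csv(comps, out / "composites.csv", index_label="subject")
            gstats = []
            for g in range(1, config.k_subjects + 1):
                members = subj_assign.members(g)
                t, dfree, p = cl.paired_ttest(
                    comps.loc[members, "cluster_1"], comps.loc[members, "cluster_2"]
                )
                gstats.append({"group": g, "n": len(members), "t": t, "df": dfree, "p": p})
            gc = cl.group_correlation(comps["cluster_1"], comps["cluster_2"], subj_assign)
            (out / "group_stats.json").write_text(
                json.dumps(
                    {"paired_t": gstats, "within_group_r": gc.reset_index().to_dict("records")},
                    indent=2,
                    sort_keys=True,
                )
            )
            report.summary["trait_clusters"] = {
                str(c): trait_assign.members(c) for c in range(1, config.k_traits + 1)
            }
            report.summary["subject_group_sizes"] = {
                str(g): len(subj_assign.members(g)) for g in range(1, config.k_subjects + 1)
            }
            done(
                "cluster",
                out / "trait_dendrogram.nwk",
                out / "trait_dendrogram.json",
                out / "subject_dendrogram.nwk",
                out / "trait_clusters.csv",
                out / "subject_groups.csv",
                out / "composites.csv",
                out / "group_stats.json",
            )

        # ---- network --------------------------------------------------
        if "network" in config.stages:
            graph, records = net.pc_stable_skeleton(trait_z, alpha=config.alpha_network)
            graph = net.assign_edge_weights(graph, records)
            graph.write_graphml(out / "trait_graph.graphml")
            graph.write_edge_tsv(out / "trait_graph_edges.tsv")
            _write_csv(
                pd.DataFrame(
                    [
                        {
                            "node1": r.pair[0],
                            "node2": r.pair[1],
                            "cond_set": "|".join(r.cond_set),
                            "rho": r.rho_hat,
                            "z": r.z,
                            "p": r.p,
                            "significant": r.significant,
                        }
                        for r in records
                    ]
                ),
                out / "ci_tests.csv",
                index=False,
            )
            report.summary["edges"] = [
                {"pair": list(e.pair), "sign": e.sign, "weight": round(e.weight, 6)}
                for e in graph.edges
            ]
            report.summary["centrality"] = {
                k: round(v, 6) for k, v in graph.centrality.items()
            }
            done(
                "network",
                out / "trait_graph.graphml",
                out / "trait_graph_edges.tsv",
                out / "ci_tests.csv",
            )

        # ---- embed ----------------------------------------------------
        emb = None
        if "embed" in config.stages:
            d_items = cl.correlation_distance(item_z, axis="columns")
            mds0 = mds_embed(d_items)
            mds0.metadata = pd.DataFrame(
                {
                    "trait": [schema.trait_of_item(i) for i in d_items.labels],
                    "subdomain": [schema.item(i).subdomain for i in d_items.labels],
                },
                index=list(d_items.labels),
            )
            emb = tsne_embed(d_items, mds0, config.embed)
            emb.to_csv(out / "item_embedding.csv")
            done("embed", out / "item_embedding.csv")

        # ---- refine ---------------------------------------------------
        if "refine" in config.stages and emb is not None:
            target = config.refine_target
            neighbors = [t for t in schema.traits if t != target]
            rep = prune_items(
                emb, schema, target, neighbors, theta=config.theta_refine, responses=rm
            )
            rep.to_json(out / "refinement.json")
            mod_schema = rep.schema_variant
            mod_schema.to_yaml(out / "schema_modified.yaml")
            if len(schema.instrument_for_trait(target).subdomains) >= 2:
                mapping, _ = reassign_items(emb, schema, target)
                (out / "subdomain_reassignment.json").write_text(
                    json.dumps(mapping, indent=2, sort_keys=True)
                )
            # rerun clustering and graph with the modified scale
            mod_scores = score_traits(rm, mod_schema)
            mod_tz = zscore_columns(mod_scores.traits).values
            mod_assign = cl.cut_tree(
                cl.wpgma_linkage(cl.correlation_distance(mod_tz, axis="columns")),
                config.k_traits,
            )
            _write_csv(
                pd.Series(mod_assign.mapping, name="cluster").rename_axis("trait").to_frame(),
                out / "trait_clusters_modified.csv",
            )
            g2, r2 = net.pc_stable_skeleton(mod_tz, alpha=config.alpha_network)
            g2 = net.assign_edge_weights(g2, r2)
            g2.write_edge_tsv(out / "trait_graph_edges_modified.tsv")
            report.summary["refinement"] = {
                "removed": list(rep.removed),
                "alpha_before": rep.alpha_before,
                "alpha_after": rep.alpha_after,
            }
            done(
                "refine",
                out / "refinement.json",
                out / "schema_modified.yaml",
                out / "trait_clusters_modified.csv",
                out / "trait_graph_edges_modified.tsv",
            )

        # ---- effects --------------------------------------------------
        if "effects" in config.stages:
            pbi = None
            if config.pbi_csv is not None:
                pbi = pd.read_csv(config.pbi_csv, index_col="subject")
            elif truth is not None:
                pbi = generate_pbi(study_like_params(seed=config.seed))
            if pbi is not None:
                avg = pbi_average(
                    pbi[["mother_care", "mother_overprotection"]].rename(
                        columns=lambda c: c.replace("mother_", "")
                    ),
                    pbi[["father_care", "father_overprotection"]].rename(
                        columns=lambda c: c.replace("father_", "")
                    ),
                )
                common = scores.traits.index.intersection(avg.index)
                sps_lv = dichotomize(scores.traits.loc[common, config.refine_target])
                care_lv = dichotomize(avg.loc[common, "care"])
                neg = (
                    cl.composite_scores(trait_z.loc[common], trait_assign)["cluster_2"]
                    if trait_assign is not None
                    else trait_z.loc[common].mean(axis=1)
                )
                tab = two_way_anova(neg, sps_lv, care_lv)
                _write_csv(tab.table, out / "anova_sps_care.csv", index_label="term")
                cells = sps_lv + "/" + care_lv
                tk = tukey_hsd(neg, cells)
                _write_csv(tk, out / "tukey_sps_care.csv", index=False)
                done("effects", out / "anova_sps_care.csv", out / "tukey_sps_care.csv")
            else:
                report.stages["effects"] = "skipped (no parental-bonding scores)"

    except Exception as exc:
        stage = next(
            (s for s in config.stages if s not in report.stages), "input"
        )
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    for p in artifacts:
        report.artifacts[p.name] = _sha256(p)
    report.to_json(out / "report.json")
    return report
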