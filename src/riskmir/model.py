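"""Model/Results surface over the full miRNA-mRNA-pathway analysis.

:class:`MirnaPathwayModel` holds the input data (one or more mRNA
case/control studies, one miRNA study, a pathway collection, a validated
miRNA-target map, a PPI network, optionally a rat miRNA study) together
with an :class:`AnalysisConfig` of thresholds.  ``fit()`` runs the stages
in order -- differential expression and Fisher meta-analysis, GSEA and
consensus risk-pathway selection, core-gene/risk-gene extraction,
hypergeometric miRNA-pathway pairing, triple and network assembly with
topology ranking, cross-validated single-feature AUC, and the cross-species
comparison -- and returns a :class:`MirnaPathwayResults` carrying every
stage table, the summary counts, and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections.abc import Sequence
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import biomarker, crossspecies, de, gsea, network
from .enrich import test_mirna_pathways
from .errors import ConfigError
from .io import (
    ExpressionStudy,
    GeneSetCollection,
    PpiNetwork,
    TargetMap,
    write_network,
)
from .simulate import SimulationBundle, SimulationConfig, TruthRecord, simulate_bundle

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Thresholds and stage parameters; defaults follow the analysis'
    published rule set."""

    de_p: float = 0.05                # human DE rule: raw p strictly below
    gsea_p: float = 0.1               # per-dataset enrichment threshold
    dataset_fraction: float = 0.5     # risk pathway: significant in > this fraction
    pair_p: float = 0.05              # miRNA-pathway pair significance (BH-adjusted)
    rat_fc: float = 2.0               # rat rule: linear |fold change| >= this
    rat_p: float = 0.05               # rat rule: p <= this
    n_perm: int = 1000
    gsea_weight: float = 1.0
    cv_k: int = 5
    de_method: str = "welch"          # "welch" | "moderated"
    pair_use_raw_p: bool = False
    topology_mode: str = "mixed"      # "mixed" | "composite" | "ppi"
    hub_k: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("de_p", "gsea_p", "dataset_fraction", "pair_p", "rat_p"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.rat_fc < 1:
            raise ConfigError("rat_fc must be >= 1")
        if self.de_method not in ("welch", "moderated"):
            raise ConfigError("de_method must be 'welch' or 'moderated'")
        if self.topology_mode not in ("mixed", "composite", "ppi"):
            raise ConfigError("topology_mode must be mixed, composite or ppi")


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Fan a single global seed out into deterministic per-stage seeds."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n).astype(np.int64) % (2**31)]


def _de_table(study: ExpressionStudy, method: str) -> pd.DataFrame:
    return de.moderated_t_table(study) if method == "moderated" else de.welch_t_table(study)


class MirnaPathwayModel:
    """The full analysis as a fittable model over an input bundle."""

    def __init__(
        self,
        mrna_studies: Sequence[ExpressionStudy],
        mirna_study: ExpressionStudy,
        pathways: GeneSetCollection,
        targets: TargetMap,
        ppi: PpiNetwork | None = None,
        rat_study: ExpressionStudy | None = None,
        config: AnalysisConfig | None = None,
        truth: TruthRecord | None = None,
    ) -> None:
        if not mrna_studies:
            raise ConfigError("need at least one mRNA study")
        self.mrna_studies = list(mrna_studies)
        self.mirna_study = mirna_study
        self.pathways = pathways
        self.targets = targets
        self.ppi = ppi
        self.rat_study = rat_study
        self.config = config or AnalysisConfig()
        self.config.validate()
        self.truth = truth

    @classmethod
    def from_simulation(
        cls,
        sim_config: SimulationConfig | None = None,
        config: AnalysisConfig | None = None,
    ) -> "MirnaPathwayModel":
        bundle = simulate_bundle(sim_config)
        return cls.from_bundle(bundle, config=config)

    @classmethod
    def from_bundle(cls, bundle: SimulationBundle, config: AnalysisConfig | None = None) -> "MirnaPathwayModel":
        return cls(
            mrna_studies=bundle.mrna_studies,
            mirna_study=bundle.mirna_study,
            pathways=bundle.pathways,
            targets=bundle.targets,
            ppi=bundle.ppi,
            rat_study=bundle.rat_study,
            config=config,
            truth=bundle.truth,
        )

    # ------------------------------------------------------------------

    def fit(self, seed: int | None = None) -> "MirnaPathwayResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        seeds = _stage_seeds(seed)

        # 1. per-study DE + meta-analysis (mRNA)
        per_study = {s.study_id: _de_table(s, cfg.de_method) for s in self.mrna_studies}
        meta = (
            de.fisher_combine(per_study)
            if len(per_study) > 1
            else next(iter(per_study.values()))
        )
        degs = de.call_de(meta, p_threshold=cfg.de_p)
        logger.info("DE: %d of %d genes called at p<%g", len(degs), len(meta), cfg.de_p)

        # 2. miRNA DE (single study)
        mirna_table = _de_table(self.mirna_study, cfg.de_method)
        demirs = de.call_de(mirna_table, p_threshold=cfg.de_p)
        logger.info("DE: %d of %d miRNAs called at p<%g", len(demirs), len(mirna_table), cfg.de_p)

        # 3. GSEA per mRNA dataset + consensus risk pathways
        gsea_results = {
            s.study_id: gsea.gsea_study(
                s, self.pathways,
                weight_exponent=cfg.gsea_weight, n_perm=cfg.n_perm,
                seed=seeds[0] + i,
            )
            for i, s in enumerate(self.mrna_studies)
        }
        sig_table = gsea.select_sig_pathways(gsea_results, cfg.gsea_p, cfg.dataset_fraction)
        risk_pathways = list(sig_table.index[sig_table["risk"]]) if len(sig_table) else []
        logger.info("GSEA: %d of %d pathways flagged risk", len(risk_pathways), len(sig_table))

        # 4. core genes and risk genes
        core_by_pathway = gsea.core_genes_by_pathway(gsea_results, risk_pathways)
        core = gsea.core_genes(gsea_results, risk_pathways)
        deg_dirs = de.directions_of(degs)
        risk_genes = network.identify_risk_genes(
            core, deg_dirs, {n: self.pathways[n] for n in risk_pathways}
        )

        # 5. hypergeometric miRNA-pathway pairs
        measured = set(self.mrna_studies[0].feature_ids)
        for s in self.mrna_studies[1:]:
            measured &= set(s.feature_ids)
        background = measured & (self.targets.genes | self.pathways.universe)
        demir_dirs = de.directions_of(demirs)
        if risk_pathways and demir_dirs and background:
            pairs = test_mirna_pathways(
                sorted(demir_dirs), self.targets, risk_pathways, self.pathways,
                background, alpha=cfg.pair_p, use_raw_p=cfg.pair_use_raw_p,
            )
        else:
            logger.warning("empty DEmiR set, risk-pathway set or background; no pair tests run")
            pairs = pd.DataFrame(columns=["mirna", "pathway", "x", "K", "M", "N", "p", "p_adj", "significant", "I"])

        # 6. triples, network, topology
        triples = network.build_triples(demir_dirs, risk_genes, risk_pathways, self.targets, self.pathways)
        net = network.build_network(triples, self.ppi)
        topology = self._topology(net)
        hubs = network.hub_nodes(topology[topology["node_type"] != "pathway"] if len(topology) else topology,
                                 k=cfg.hub_k)
        n_opposite, n_same = network.classify_concordance(triples)

        # 7. cross-validated single-feature AUC on network members
        auc_tables = []
        gene_nodes = sorted(triples["gene"].unique()) if len(triples) else []
        mirna_nodes = sorted(triples["mirna"].unique()) if len(triples) else []
        if gene_nodes:
            pooled = _pool_studies(self.mrna_studies)
            auc_tables.append(biomarker.evaluate_features(pooled, gene_nodes, k=cfg.cv_k, seed=seeds[1]))
        if mirna_nodes:
            auc_tables.append(biomarker.evaluate_features(self.mirna_study, mirna_nodes, k=cfg.cv_k, seed=seeds[2]))
        auc_table = (
            pd.concat(auc_tables, ignore_index=True).sort_values(["auc", "feature"], ascending=[False, True]).reset_index(drop=True)
            if auc_tables
            else pd.DataFrame(columns=["feature", "auc", "orientation", "k", "seed"])
        )

        # 8. optional cross-species comparison
        rat_table = shared = None
        if self.rat_study is not None:
            rat_de_table = de.welch_t_table(self.rat_study)
            rat_table = de.call_de(rat_de_table, p_threshold=cfg.rat_p, fc_threshold=cfg.rat_fc)
            shared = crossspecies.shared_demirs(demirs, rat_table, suffixes=("_human", "_rat"))
            logger.info("cross-species: %d rat DEmiRs, %d shared families", len(rat_table), len(shared))

        manifest = {
            "seed": seed,
            "config": asdict(cfg),
            "n_mrna_studies": len(self.mrna_studies),
            "input_digests": self._digests(),
        }
        return MirnaPathwayResults(
            model=self,
            per_study_de=per_study,
            meta_de=meta,
            degs=degs,
            mirna_de=mirna_table,
            demirs=demirs,
            gsea_results=gsea_results,
            sig_pathways=sig_table,
            risk_pathways=risk_pathways,
            core_genes=core,
            core_genes_by_pathway=core_by_pathway,
            risk_genes=risk_genes,
            pairs=pairs,
            triples=triples,
            network=net,
            topology=topology,
            hubs=hubs,
            n_opposite=n_opposite,
            n_same=n_same,
            auc_table=auc_table,
            rat_demirs=rat_table,
            shared_mirnas=shared,
            manifest=manifest,
        )

    # ------------------------------------------------------------------

    def _topology(self, net: nx.Graph) -> pd.DataFrame:
        """Topology table per the configured mode.

        ``composite``: all metrics on the tripartite network.  ``ppi``: gene
        metrics on the whole PPI network only.  ``mixed`` (default): gene
        nodes measured in the whole PPI network, miRNA/pathway nodes in the
        composite network.
        """
        mode = self.config.topology_mode
        composite = network.node_topology(net)
        if mode == "composite" or self.ppi is None or len(composite) == 0:
            return composite
        gene_nodes = [n for n, d in net.nodes(data=True) if d.get("node_type") == "gene"]
        ppi_graph = self.ppi.to_networkx()
        ppi_topo = network.node_topology(ppi_graph, nodes=[g for g in gene_nodes if g in ppi_graph])
        ppi_topo["node_type"] = "gene"
        if mode == "ppi":
            return ppi_topo
        other = composite[composite["node_type"] != "gene"]
        mixed = pd.concat([ppi_topo, other], ignore_index=True)
        mixed = mixed.sort_values(["degree", "node"], ascending=[False, True], kind="stable")
        return mixed.reset_index(drop=True)

    def _digests(self) -> dict[str, str]:
        def h(text: str) -> str:
            return hashlib.sha256(text.encode()).hexdigest()[:12]

        digests = {
            "pathways": h(";".join(f"{n}:{','.join(sorted(s))}" for n, s in sorted(self.pathways.sets.items()))),
            "targets": h(";".join(f"{m},{g}" for m, g in sorted(self.targets.pairs))),
        }
        for s in self.mrna_studies + [self.mirna_study]:
            digests[s.study_id] = h(np.array2string(np.round(s.values, 6)))
        return digests


def _pool_studies(studies: Sequence[ExpressionStudy]) -> ExpressionStudy:
    """Pool samples of several studies over their shared features (the
    paper-style combined 18 vs 18 cohort)."""
    if len(studies) == 1:
        return studies[0]
    common = [f for f in studies[0].feature_ids if all(f in set(s.feature_ids) for s in studies[1:])]
    frames = [s.to_frame().loc[common] for s in studies]
    values = np.hstack([f.to_numpy() for f in frames])
    sample_ids = [sid for s in studies for sid in s.sample_ids]
    labels = np.concatenate([s.labels for s in studies])
    return ExpressionStudy(
        "+".join(s.study_id for s in studies), studies[0].platform, common, sample_ids, values, labels
    )


@dataclass
class MirnaPathwayResults:
    """Fitted-analysis container: every stage table plus summary counts."""

    model: MirnaPathwayModel
    per_study_de: dict[str, pd.DataFrame]
    meta_de: pd.DataFrame
    degs: pd.DataFrame
    mirna_de: pd.DataFrame
    demirs: pd.DataFrame
    gsea_results: dict[str, list]
    sig_pathways: pd.DataFrame
    risk_pathways: list[str]
    core_genes: frozenset[str]
    core_genes_by_pathway: dict[str, frozenset[str]]
    risk_genes: pd.DataFrame
    pairs: pd.DataFrame
    triples: pd.DataFrame
    network: nx.Graph
    topology: pd.DataFrame
    hubs: list[str]
    n_opposite: int
    n_same: int
    auc_table: pd.DataFrame
    manifest: dict
    rat_demirs: pd.DataFrame | None = None
    shared_mirnas: pd.DataFrame | None = None

    # -- summary -------------------------------------------------------

    @property
    def counts(self) -> dict[str, int]:
        c = {
            "n_degs": len(self.degs),
            "n_demirs": len(self.demirs),
            "n_risk_pathways": len(self.risk_pathways),
            "n_core_genes": len(self.core_genes),
            "n_risk_genes": len(self.risk_genes),
            "n_sig_pairs": int(self.pairs["significant"].sum()) if len(self.pairs) else 0,
            "n_pairs_tested": len(self.pairs),
            "n_triples": len(self.triples),
            "n_opposite_pairs": self.n_opposite,
            "n_same_pairs": self.n_same,
            "n_network_nodes": self.network.number_of_nodes(),
            "n_network_edges": self.network.number_of_edges(),
        }
        if self.rat_demirs is not None:
            c["n_rat_demirs"] = len(self.rat_demirs)
            c["n_shared_demirs"] = len(self.shared_mirnas) if self.shared_mirnas is not None else 0
        return c

    def summary(self) -> str:
        lines = [
            "miRNA-mRNA-pathway risk analysis",
            "=" * 48,
            f"mRNA studies: {len(self.per_study_de)}   seed: {self.manifest['seed']}",
            "-" * 48,
        ]
        for key, value in self.counts.items():
            lines.append(f"{key:<24s} {value}")
        if len(self.auc_table):
            best = self.auc_table.iloc[0]
            lines.append("-" * 48)
            lines.append(f"best biomarker: {best['feature']} (CV AUC = {best['auc']:.3f})")
        if self.hubs:
            lines.append(f"hub nodes (degree): {', '.join(self.hubs)}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------

    def save(self, out_dir) -> Path:
        """Write every stage table, the network exports and the manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.meta_de.to_csv(out / "meta_de_genes.tsv", sep="\t")
        self.degs.to_csv(out / "degs.tsv", sep="\t")
        self.mirna_de.to_csv(out / "mirna_de.tsv", sep="\t")
        self.demirs.to_csv(out / "demirs.tsv", sep="\t")
        self.sig_pathways.to_csv(out / "sig_pathways.tsv", sep="\t")
        gsea_rows = [
            {
                "dataset": ds, "pathway": r.pathway, "es": r.es, "p": r.p,
                "n_core": len(r.leading_edge), "core_genes": ";".join(sorted(r.leading_edge)),
            }
            for ds, results in self.gsea_results.items()
            for r in results
        ]
        pd.DataFrame(gsea_rows).to_csv(out / "gsea_results.tsv", sep="\t", index=False)
        self.risk_genes.to_csv(out / "risk_genes.tsv", sep="\t", index=False)
        self.pairs.to_csv(out / "mirna_pathway_pairs.tsv", sep="\t", index=False)
        self.triples.to_csv(out / "triples.tsv", sep="\t", index=False)
        self.topology.to_csv(out / "topology.tsv", sep="\t", index=False)
        self.auc_table.to_csv(out / "cv_auc.tsv", sep="\t", index=False)
        if self.rat_demirs is not None:
            self.rat_demirs.to_csv(out / "rat_demirs.tsv", sep="\t")
        if self.shared_mirnas is not None:
            self.shared_mirnas.to_csv(out / "shared_demirs.tsv", sep="\t", index=False)
        write_network(self.network, out / "network.sif", "SIF")
        write_network(self.network, out / "network.graphml", "GraphML")
        payload = dict(self.manifest)
        payload["counts"] = self.counts
        with open(out / "manifest.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
        return out

    # -- plotting -------------------------------------------------------

    def plot_roc(self, features: Sequence[str], path=None):
        """ROC curves for selected network features (pooled out-of-fold
        scores); returns the matplotlib figure."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        seeds = _stage_seeds(self.manifest["seed"])
        fig, ax = plt.subplots(figsize=(5, 5))
        for f in features:
            if f in self.model.mirna_study.feature_ids:
                study = self.model.mirna_study
                seed = seeds[2]
            else:
                study = _pool_studies(self.model.mrna_studies)
                seed = seeds[1]
            res = biomarker.cv_feature_auc(study, f, k=self.model.config.cv_k, seed=seed)
            ax.plot(res.roc[:, 0], res.roc[:, 1], label=f"{f} (AUC={res.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
        return fig
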