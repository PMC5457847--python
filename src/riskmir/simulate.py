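"""Fully in-silico inputs with planted, machine-readable ground truth.

The generator emulates the structure of the public chronic-pancreatitis
cohorts the analysis is designed for: two mRNA case/control studies of
9 vs 9 samples, one miRNA study of 33 vs 58, a validated miRNA-target map,
a pathway collection, a scale-free PPI network, and (optionally) a small
rat miRNA experiment of 2 vs 2 arrays sharing a handful of up-regulated
miRNA families with the human study.

Expression values are Gaussian log2 intensities: control samples are drawn
around per-feature baselines, case samples are shifted additively by the
planted signed effect.  Planted risk structure: each planted (miRNA,
pathway) pair consists of a pathway whose members all share a common
case-shift (so set-level enrichment is detectable) and a differentially
expressed miRNA whose target set covers most of that pathway, far above the
background target density.  Null pathways are drawn (with overlap among
themselves) from genes that are neither planted-DE nor members of planted
pathways, and background targets avoid planted-pathway genes; this keeps
the planted truth uniquely recoverable, at the cost of some realism (see
the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConfigError
from .io import ExpressionStudy, GeneSetCollection, PpiNetwork, TargetMap

_DIR_NAME = {1: "up", -1: "down"}


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic bundle.

    Defaults mirror the cohort designs the analysis targets (two 9v9 mRNA
    studies, one 33v58 miRNA study, a 2v2 rat experiment) with desk-scale
    feature counts; effect sizes are log2 shifts.
    """

    n_genes: int = 2000
    n_mirnas: int = 150
    mrna_design: tuple[tuple[int, int], ...] = ((9, 9), (9, 9))
    mirna_design: tuple[int, int] = (33, 58)
    n_pathways: int = 15
    pathway_size_range: tuple[int, int] = (12, 18)
    fraction_de_genes: float = 0.10
    fraction_de_mirnas: float = 0.10
    effect_size: float = 1.0
    noise_sd: float = 0.5
    n_planted_risk_pairs: int = 2
    target_density: float = 20.0
    planted_target_fraction: float = 0.8
    ppi_attachment: int = 2
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    # rat arm
    include_rat: bool = True
    rat_design: tuple[int, int] = (2, 2)
    n_rat_mirnas: int = 100
    n_shared_de: int = 4
    n_rat_only_de: int = 8
    rat_effect_size: float = 2.5
    rat_noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_pathways", "n_planted_risk_pairs", "ppi_attachment"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("fraction_de_genes", "fraction_de_mirnas"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigError(f"{name} must lie in [0, 1)")
        if self.effect_size <= 0:
            raise ConfigError("effect_size must be positive")
        if self.noise_sd <= 0 or self.rat_noise_sd <= 0:
            raise ConfigError("noise standard deviations must be positive")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ConfigError("pathway_size_range must be an increasing pair of positive counts")
        if self.n_planted_risk_pairs > self.n_pathways:
            raise ConfigError("cannot plant more risk pairs than pathways")
        if self.n_planted_risk_pairs * hi > self.n_genes:
            raise ConfigError("planted pathways would exceed the gene universe")
        if not (0 < self.planted_target_fraction <= 1):
            raise ConfigError("planted_target_fraction must lie in (0, 1]")
        if self.ppi_attachment >= self.n_genes:
            raise ConfigError("ppi_attachment must be smaller than n_genes")


@dataclass
class TruthRecord:
    """Planted ground truth, checkable against the generated inputs."""

    de_genes: dict[str, int]
    de_mirnas: dict[str, int]
    planted_pathways: tuple[str, ...]
    risk_pairs: tuple[tuple[str, str], ...]
    triples: frozenset[tuple[str, str, str]]
    risk_genes: frozenset[str]
    rat_de_mirnas: dict[str, int] = field(default_factory=dict)
    shared_families: tuple[str, ...] = ()

    def validate(self, targets: TargetMap, pathways: GeneSetCollection) -> None:
        """Consistency of the planted triples with the generated inputs."""
        for mirna, gene, pathway in self.triples:
            if gene not in pathways[pathway]:
                raise ConfigError(f"truth triple gene {gene} not in pathway {pathway}")
            if (mirna, gene) not in targets.pairs:
                raise ConfigError(f"truth triple pair ({mirna}, {gene}) not in target map")
            if mirna not in self.de_mirnas or gene not in self.de_genes:
                raise ConfigError("truth triple member not planted DE")
        for _, pathway in self.risk_pairs:
            if pathway not in self.planted_pathways:
                raise ConfigError("risk pair pathway not planted")


@dataclass
class SimulationBundle:
    mrna_studies: list[ExpressionStudy]
    mirna_study: ExpressionStudy
    pathways: GeneSetCollection
    targets: TargetMap
    ppi: PpiNetwork
    truth: TruthRecord
    config: SimulationConfig
    rat_study: ExpressionStudy | None = None


def simulate_expression_study(
    feature_ids,
    effects,
    design: tuple[int, int],
    *,
    noise_sd: float,
    baselines=None,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
    study_id: str = "study",
    platform: str = "mRNA",
) -> ExpressionStudy:
    """One case/control study: control ~ N(baseline, sd), cases shifted by
    the signed effect of each DE feature.  Deterministic for a fixed seed."""
    if noise_sd <= 0:
        raise ConfigError("noise_sd must be positive")
    feature_ids = list(feature_ids)
    unknown = set(effects) - set(feature_ids)
    if unknown:
        raise ConfigError(f"effects defined for features not in the study: {sorted(unknown)[:5]}")
    n_case, n_control = design
    rng = np.random.default_rng(seed)
    if baselines is None:
        baselines = rng.normal(baseline_mean, baseline_sd, len(feature_ids))
    baselines = np.asarray(baselines, dtype=float)
    shift = np.array([effects.get(f, 0.0) for f in feature_ids])

    noise = rng.normal(0.0, noise_sd, (len(feature_ids), n_case + n_control))
    values = baselines[:, None] + noise
    values[:, :n_case] += shift[:, None]

    sample_ids = [f"{study_id}_case_{i + 1}" for i in range(n_case)] + [
        f"{study_id}_ctrl_{i + 1}" for i in range(n_control)
    ]
    labels = np.array(["case"] * n_case + ["control"] * n_control, dtype=object)
    return ExpressionStudy(study_id, platform, feature_ids, sample_ids, values, labels)


def simulate_scale_free_ppi(n_nodes: int, attachment: int, seed: int = 0, node_ids=None) -> PpiNetwork:
    """Preferential-attachment (Barabasi-Albert) PPI network: connected,
    undirected, heavy-tailed degree distribution."""
    if not (n_nodes > attachment >= 1):
        raise ConfigError("need n_nodes > attachment >= 1")
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=int(seed) % 2**31)
    if node_ids is None:
        node_ids = [f"G{i + 1:04d}" for i in range(n_nodes)]
    node_ids = list(node_ids)
    if len(node_ids) != n_nodes:
        raise ConfigError("node_ids length must equal n_nodes")
    return PpiNetwork(frozenset((node_ids[a], node_ids[b]) for a, b in g.edges))


def _mirna_number(name: str) -> int:
    return int(name.rsplit("-", 1)[-1])


def simulate_bundle(cfg: SimulationConfig | None = None) -> SimulationBundle:
    """Generate the full input bundle plus its truth record.

    Planted structure (per risk pair j): pathway A_j, all members shifted by
    a common signed effect; miRNA m_j, planted DE, targeting
    ``planted_target_fraction`` of A_j on top of its background targets.
    The truth triples are every (DEmiR, DE gene, planted pathway) relation
    realized in the generated target map and pathway collection.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(16).astype(np.int64) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])

    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    mirnas = [f"hsa-miR-{i + 1}" for i in range(cfg.n_mirnas)]

    n_pairs = cfg.n_planted_risk_pairs
    lo, hi = cfg.pathway_size_range

    # --- planted pathways: disjoint member sets, coherent direction -------
    planted_sizes = rng.integers(lo, hi + 1, n_pairs)
    planted_gene_pool = rng.permutation(genes)
    planted_sets: list[list[str]] = []
    cursor = 0
    for size in planted_sizes:
        planted_sets.append(sorted(str(g) for g in planted_gene_pool[cursor:cursor + size]))
        cursor += size
    planted_members = {g for s in planted_sets for g in s}
    pathway_dirs = [1 if j % 2 == 0 else -1 for j in range(n_pairs)]

    # --- scattered DE genes: outside every pathway ------------------------
    n_de_genes = round(cfg.fraction_de_genes * cfg.n_genes)
    n_scatter = max(0, n_de_genes - len(planted_members))
    scatter_pool = [g for g in genes if g not in planted_members]
    scatter_genes = [str(g) for g in rng.choice(scatter_pool, size=min(n_scatter, len(scatter_pool)), replace=False)]
    scatter_dirs = rng.choice([1, -1], size=len(scatter_genes))

    de_genes: dict[str, int] = {}
    for members, d in zip(planted_sets, pathway_dirs):
        for g in members:
            de_genes[g] = d
    for g, d in zip(scatter_genes, scatter_dirs):
        de_genes[g] = int(d)

    # --- pathway collection: null sets avoid planted and DE genes --------
    null_pool = [g for g in genes if g not in planted_members and g not in de_genes]
    sets: dict[str, frozenset[str]] = {}
    for j, members in enumerate(planted_sets):
        sets[f"PW{j + 1:02d}"] = frozenset(members)
    for j in range(n_pairs, cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if size > len(null_pool):
            raise ConfigError("gene universe too small for the requested pathway collection")
        sets[f"PW{j + 1:02d}"] = frozenset(str(g) for g in rng.choice(null_pool, size=size, replace=False))
    pathways = GeneSetCollection(sets, "synthetic")
    planted_names = tuple(f"PW{j + 1:02d}" for j in range(n_pairs))

    # --- DE miRNAs --------------------------------------------------------
    n_demirs = max(round(cfg.fraction_de_mirnas * cfg.n_mirnas),
                   n_pairs + (cfg.n_shared_de if cfg.include_rat else 0))
    if n_demirs > cfg.n_mirnas:
        raise ConfigError("fraction_de_mirnas too small for the requested plants")
    # shared families must exist on the rat platform (family number in range)
    eligible_shared = [m for m in mirnas if _mirna_number(m) <= cfg.n_rat_mirnas]
    demir_ids = [str(m) for m in rng.choice(mirnas, size=n_demirs, replace=False)]
    pair_mirnas = demir_ids[:n_pairs]
    shared: list[str] = []
    if cfg.include_rat:
        shared = [m for m in demir_ids[n_pairs:] if m in eligible_shared][: cfg.n_shared_de]
        missing = cfg.n_shared_de - len(shared)
        if missing > 0:
            extra = [m for m in eligible_shared if m not in demir_ids][:missing]
            demir_ids.extend(extra)
            shared.extend(extra)
        if len(shared) < cfg.n_shared_de:
            raise ConfigError("not enough miRNA families shared with the rat platform")

    de_mirnas: dict[str, int] = {}
    for j, m in enumerate(pair_mirnas):
        # canonical repression (opposite trend) for even pairs, same for odd
        de_mirnas[m] = -pathway_dirs[j] if j % 2 == 0 else pathway_dirs[j]
    for m in shared:
        de_mirnas.setdefault(m, 1)
        de_mirnas[m] = 1  # shared families are up-regulated in both species
    for m in demir_ids:
        if m not in de_mirnas:
            de_mirnas[m] = int(rng.choice([1, -1]))

    # --- target map: background avoids planted pathways ------------------
    bg_pool = np.array([g for g in genes if g not in planted_members], dtype=object)
    pairs: set[tuple[str, str]] = set()
    for m in mirnas:
        k = int(rng.poisson(cfg.target_density))
        k = min(k, len(bg_pool))
        if k > 0:
            for g in rng.choice(bg_pool, size=k, replace=False):
                pairs.add((m, str(g)))
    for j, m in enumerate(pair_mirnas):
        members = planted_sets[j]
        n_in = max(1, math.ceil(cfg.planted_target_fraction * len(members)))
        for g in rng.choice(np.array(members, dtype=object), size=n_in, replace=False):
            pairs.add((m, str(g)))
    targets = TargetMap(frozenset(pairs), "validated")

    # --- PPI --------------------------------------------------------------
    ppi = simulate_scale_free_ppi(cfg.n_genes, cfg.ppi_attachment, seed=int(seeds[0]), node_ids=genes)

    # --- expression studies ----------------------------------------------
    gene_effects = {g: d * cfg.effect_size for g, d in de_genes.items()}
    mirna_effects = {m: d * cfg.effect_size for m, d in de_mirnas.items()}
    gene_baselines = np.random.default_rng(int(seeds[1])).normal(
        cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes
    )
    mrna_studies = [
        simulate_expression_study(
            genes, gene_effects, design,
            noise_sd=cfg.noise_sd, baselines=gene_baselines,
            seed=int(seeds[2 + i]), study_id=f"mrna_{i + 1}", platform="mRNA",
        )
        for i, design in enumerate(cfg.mrna_design)
    ]
    mirna_study = simulate_expression_study(
        mirnas, mirna_effects, cfg.mirna_design,
        noise_sd=cfg.noise_sd, baseline_mean=cfg.baseline_mean, baseline_sd=cfg.baseline_sd,
        seed=int(seeds[10]), study_id="mirna_1", platform="miRNA",
    )

    # --- rat study --------------------------------------------------------
    rat_study = None
    rat_de: dict[str, int] = {}
    if cfg.include_rat:
        rat_features = [f"rno-miR-{i + 1}" for i in range(cfg.n_rat_mirnas)]
        human_de_numbers = {_mirna_number(m) for m in de_mirnas}
        for m in shared:
            rat_de[f"rno-miR-{_mirna_number(m)}"] = 1
        rat_only_pool = [f for f in rat_features if _mirna_number(f) not in human_de_numbers]
        rat_rng = np.random.default_rng(int(seeds[11]))
        rat_only = [str(f) for f in rat_rng.choice(rat_only_pool, size=min(cfg.n_rat_only_de, len(rat_only_pool)), replace=False)]
        for i, f in enumerate(rat_only):
            rat_de[f] = -1 if i < 2 else 1  # mostly up, as in DBTC-model arrays
        rat_effects = {f: d * cfg.rat_effect_size for f, d in rat_de.items()}
        rat_study = simulate_expression_study(
            rat_features, rat_effects, cfg.rat_design,
            noise_sd=cfg.rat_noise_sd, baseline_mean=cfg.baseline_mean, baseline_sd=cfg.baseline_sd,
            seed=int(seeds[12]), study_id="rat_1", platform="miRNA",
        )

    # --- truth record -----------------------------------------------------
    by_mirna = targets.by_mirna()
    triples: set[tuple[str, str, str]] = set()
    for m in de_mirnas:
        tg = by_mirna.get(m, frozenset())
        for name in planted_names:
            for g in tg & pathways[name]:
                if g in de_genes:
                    triples.add((m, g, name))
    truth = TruthRecord(
        de_genes=de_genes,
        de_mirnas=de_mirnas,
        planted_pathways=planted_names,
        risk_pairs=tuple(zip(pair_mirnas, planted_names)),
        triples=frozenset(triples),
        risk_genes=frozenset(planted_members),
        rat_de_mirnas=rat_de,
        shared_families=tuple(sorted(f"mir-{_mirna_number(m)}" for m in shared)),
    )
    truth.validate(targets, pathways)

    return SimulationBundle(
        mrna_studies=mrna_studies,
        mirna_study=mirna_study,
        pathways=pathways,
        targets=targets,
        ppi=ppi,
        truth=truth,
        config=cfg,
        rat_study=rat_study,
    )
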