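"""Gene set enrichment analysis with leading-edge ("core gene") extraction.

All genes are ranked by the signal-to-noise metric

    (mu_case - mu_control) / (sigma_case + sigma_control),

each group standard deviation floored at max(0.2 * |mu|, 0.2).  A gene set
is scored by the weighted Kolmogorov-Smirnov running sum: hits advance by
|metric|^w normalized over the set's hits, misses retreat by
1 / (N - N_hits); the enrichment score (ES) is the signed extremum of the
walk.  Nominal significance comes from phenotype permutation: labels are
shuffled, the list re-ranked and re-scored, and the observed |ES| referred
to the same-sign permutation null,

    p = (1 + #{|ES_perm| >= |ES_obs|, same sign}) / (1 + #{same-sign perms}).

The leading edge (the pathway's "core genes") is the set members at or
before the walk's maximum for ES > 0, and strictly after the minimum for
ES < 0.

A pathway is a *risk pathway* when its nominal enrichment p falls below the
threshold (default .1) in strictly more than half of the analyzed datasets.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError
from .io import ExpressionStudy, GeneSetCollection

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 0.2


@dataclass
class GseaResult:
    """Per-dataset, per-pathway enrichment result."""

    dataset_id: str
    pathway: str
    es: float
    walk: np.ndarray
    p: float
    leading_edge: frozenset[str]
    n_perm: int
    n_members: int = 0
    direction: str = ""  # up if ES > 0 (case-enriched), down otherwise

    def __post_init__(self) -> None:
        if not self.direction:
            self.direction = "up" if self.es >= 0 else "down"


def signal_to_noise(study: ExpressionStudy) -> pd.Series:
    """Per-feature signal-to-noise metric (unsorted, indexed by feature)."""
    case = study.case_values()
    ctrl = study.control_values()
    if case.shape[1] < 3 or ctrl.shape[1] < 3:
        raise DesignError("signal-to-noise ranking needs >=3 samples per group")
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    s1 = np.maximum(case.std(axis=1, ddof=1), np.maximum(SIGMA_FLOOR * np.abs(m1), SIGMA_FLOOR))
    s2 = np.maximum(ctrl.std(axis=1, ddof=1), np.maximum(SIGMA_FLOOR * np.abs(m2), SIGMA_FLOOR))
    return pd.Series((m1 - m2) / (s1 + s2), index=study.feature_ids, name="metric")


def rank_by_signal_to_noise(study: ExpressionStudy) -> pd.Series:
    """Ranked list: metric values sorted descending, ties broken by feature id."""
    metric = signal_to_noise(study)
    ids = np.asarray(metric.index, dtype=object)
    order = np.lexsort((ids, -metric.to_numpy()))
    return metric.iloc[order]


def _walk_stats(walk: np.ndarray) -> tuple[float, int]:
    """Signed extremum of the running sum and its (first) position."""
    wmax = float(walk.max())
    wmin = float(walk.min())
    if wmax >= -wmin:
        return wmax, int(np.argmax(walk))
    return wmin, int(np.argmin(walk))


def enrichment_score(
    ranked: pd.Series,
    pathway: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, frozenset[str]]:
    """Weighted KS running sum for one gene set over a ranked list.

    Returns ``(ES, walk, leading_edge)``.  Raises :class:`ConfigError` when
    the set does not intersect the ranked universe (callers skip and log).
    """
    ids = np.asarray(ranked.index, dtype=object)
    metric = ranked.to_numpy(dtype=float)
    members = frozenset(pathway)
    hit = np.fromiter((g in members for g in ids), dtype=bool, count=len(ids))
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ConfigError("gene set does not intersect the ranked list")
    n = len(ids)

    weights = np.abs(metric[hit]) ** weight_exponent
    total = weights.sum()
    if total <= 0:
        weights = np.full(n_hits, 1.0 / n_hits)
    else:
        weights = weights / total

    steps = np.empty(n)
    steps[~hit] = -1.0 / (n - n_hits) if n > n_hits else 0.0
    steps[hit] = weights
    walk = np.cumsum(steps)

    es, idx = _walk_stats(walk)
    hit_positions = np.flatnonzero(hit)
    if es >= 0:
        lead = hit_positions[hit_positions <= idx]
    else:
        lead = hit_positions[hit_positions > idx]
    leading_edge = frozenset(ids[lead])
    return es, walk, leading_edge


def _es_from_positions(hit_pos: np.ndarray, hit_abs_metric: np.ndarray, n: int, weight: float) -> float:
    """ES from sorted hit positions only (no full walk); used in permutations."""
    m = len(hit_pos)
    misses = n - m
    w = hit_abs_metric**weight
    total = w.sum()
    w = (w / total) if total > 0 else np.full(m, 1.0 / m)
    cw = np.cumsum(w)
    if misses == 0:
        return 1.0
    dec = 1.0 / misses
    after = cw - (hit_pos + 1 - np.arange(1, m + 1)) * dec
    before = np.concatenate(([0.0], cw[:-1])) - (hit_pos - np.arange(m)) * dec
    wmax = max(float(after.max()), 0.0)
    wmin = min(float(before.min()), 0.0)
    return wmax if wmax >= -wmin else wmin


def _ranked_order(values: np.ndarray, case_mask: np.ndarray, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(order, metric) for a label assignment; ties broken by feature id."""
    case = values[:, case_mask]
    ctrl = values[:, ~case_mask]
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    s1 = np.maximum(case.std(axis=1, ddof=1), np.maximum(SIGMA_FLOOR * np.abs(m1), SIGMA_FLOOR))
    s2 = np.maximum(ctrl.std(axis=1, ddof=1), np.maximum(SIGMA_FLOOR * np.abs(m2), SIGMA_FLOOR))
    metric = (m1 - m2) / (s1 + s2)
    order = np.lexsort((ids, -metric))
    return order, metric


def _count_distinct_assignments(n: int, k: int) -> int:
    return math.comb(n, k)


def gsea_study(
    study: ExpressionStudy,
    collection: GeneSetCollection,
    *,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[GseaResult]:
    """Run GSEA for every pathway of a collection on one dataset.

    Phenotype permutations are shared across pathways (one re-ranking per
    permutation scores every set), matching the standard implementation.
    Pathways that do not intersect the measured features are skipped with a
    logged warning.
    """
    if n_perm < 10:
        raise ConfigError("n_perm must be >= 10")
    ids = np.asarray(study.feature_ids, dtype=object)
    id_to_idx = {g: i for i, g in enumerate(ids)}
    values = study.values
    case_mask = study.case_mask.astype(bool)

    if _count_distinct_assignments(len(study.sample_ids), int(case_mask.sum())) < n_perm:
        logger.warning(
            "study %s admits fewer than %d distinct label assignments; permutations sampled with replacement",
            study.study_id, n_perm,
        )

    member_idx: dict[str, np.ndarray] = {}
    for name in collection.names:
        idx = np.array(sorted(id_to_idx[g] for g in collection[name] if g in id_to_idx), dtype=int)
        if idx.size == 0:
            logger.warning("pathway %s does not intersect study %s; skipped", name, study.study_id)
            continue
        member_idx[name] = idx

    # observed ranking and scores
    order, metric = _ranked_order(values, case_mask, ids)
    ranked = pd.Series(metric[order], index=ids[order])
    observed: dict[str, tuple[float, np.ndarray, frozenset[str]]] = {}
    for name, idx in member_idx.items():
        observed[name] = enrichment_score(ranked, ids[idx], weight_exponent)

    # permutation null, shared across pathways
    rng = np.random.default_rng(seed)
    labels = case_mask.copy()
    n_same_sign = {name: 0 for name in member_idx}
    n_extreme = {name: 0 for name in member_idx}
    pos_of = np.empty(len(ids), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        p_order, p_metric = _ranked_order(values, perm, ids)
        pos_of[p_order] = np.arange(len(ids))
        abs_metric = np.abs(p_metric)
        for name, idx in member_idx.items():
            hit_pos = np.sort(pos_of[idx])
            es_p = _es_from_positions(hit_pos, abs_metric[idx][np.argsort(pos_of[idx])], len(ids), weight_exponent)
            es_o = observed[name][0]
            if (es_p >= 0) == (es_o >= 0):
                n_same_sign[name] += 1
                if abs(es_p) >= abs(es_o):
                    n_extreme[name] += 1

    results = []
    for name, idx in member_idx.items():
        es, walk, lead = observed[name]
        p = (1 + n_extreme[name]) / (1 + n_same_sign[name])
        results.append(
            GseaResult(
                dataset_id=study.study_id,
                pathway=name,
                es=es,
                walk=walk,
                p=p,
                leading_edge=lead,
                n_perm=n_perm,
                n_members=int(idx.size),
            )
        )
    return results


def gsea_permutation_p(
    study: ExpressionStudy,
    pathway: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    *,
    weight_exponent: float = 1.0,
) -> float:
    """Sign-aware phenotype-permutation nominal p for a single gene set."""
    members = frozenset(pathway)
    collection = GeneSetCollection({"_set": members}, "adhoc")
    [res] = gsea_study(study, collection, weight_exponent=weight_exponent, n_perm=n_perm, seed=seed)
    return res.p


def select_sig_pathways(
    results_by_dataset: Mapping[str, Iterable[GseaResult]],
    p_threshold: float = 0.1,
    dataset_fraction: float = 0.5,
) -> pd.DataFrame:
    """Consensus risk-pathway selection across datasets.

    A pathway is flagged ``risk`` when its nominal p is below ``p_threshold``
    in strictly more than ``dataset_fraction`` of the datasets.  A pathway
    absent from a dataset counts as not significant there (logged).
    """
    if not results_by_dataset:
        raise ConfigError("need at least one dataset of GSEA results")
    datasets = list(results_by_dataset)
    p_by_ds: dict[str, dict[str, float]] = {
        ds: {r.pathway: r.p for r in results} for ds, results in results_by_dataset.items()
    }
    all_pathways = sorted(set().union(*[set(d) for d in p_by_ds.values()]))

    rows = []
    for name in all_pathways:
        ps = {}
        n_sig = 0
        for ds in datasets:
            p = p_by_ds[ds].get(name)
            if p is None:
                logger.info("pathway %s absent from dataset %s; counted not significant", name, ds)
            elif p < p_threshold:
                n_sig += 1
            ps[f"p_{ds}"] = np.nan if p is None else p
        frac = n_sig / len(datasets)
        rows.append({"pathway": name, **ps, "n_sig": n_sig, "n_datasets": len(datasets),
                     "fraction": frac, "risk": frac > dataset_fraction})
    table = pd.DataFrame(rows).set_index("pathway") if rows else pd.DataFrame(
        columns=["n_sig", "n_datasets", "fraction", "risk"]
    )
    return table


def core_genes(
    results_by_dataset: Mapping[str, Iterable[GseaResult]],
    risk_pathways: Iterable[str],
) -> frozenset[str]:
    """Union of leading-edge genes of the risk pathways across datasets."""
    risk = set(risk_pathways)
    out: set[str] = set()
    for results in results_by_dataset.values():
        for r in results:
            if r.pathway in risk:
                out |= r.leading_edge
    return frozenset(out)


def core_genes_by_pathway(
    results_by_dataset: Mapping[str, Iterable[GseaResult]],
    risk_pathways: Iterable[str],
) -> dict[str, frozenset[str]]:
    risk = set(risk_pathways)
    acc: dict[str, set[str]] = {name: set() for name in risk}
    for results in results_by_dataset.values():
        for r in results:
            if r.pathway in risk:
                acc[r.pathway] |= r.leading_edge
    return {name: frozenset(genes) for name, genes in acc.items()}
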