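"""Per-pathway K-means clustering of samples: gap-statistic K selection,
replica-based stability, and cross-pathway consensus blocks.

For each pathway with more than five expressed genes, samples are clustered
on the standardized log-CPM of the pathway's genes.  The optimal K comes from
the gap statistic (uniform reference over per-feature ranges, first-SE rule);
stability repeats K-means (default 500 replicas) and scores the fraction of
replicas whose partition equals — up to label permutation — the
lowest-dispersion reference partition.  Pathways with stability >= 0.95 vote
on a per-sample consensus block named after anchor tissue classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .datatypes import CountMatrix, ValidationError
from .de import effective_library_sizes

log = logging.getLogger(__name__)


def load_gene_sets(path: str | Path) -> dict[str, frozenset[str]]:
    """Parse a GMT file (name, description, genes...) into a pathway dict.

    Duplicate pathway names or lines with fewer than 3 fields raise an error
    naming the offending line; duplicate genes within a line are collapsed.
    """
    db: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"malformed GMT line {lineno}: fewer than 3 fields")
        name = fields[0]
        if name in db:
            raise ValidationError(f"duplicate pathway name {name!r} at line {lineno}")
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise ValidationError(f"empty pathway {name!r} at line {lineno}")
        db[name] = genes
    return db


def write_gene_sets(db: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in db.items():
            fh.write("\t".join([name, name, *sorted(genes)]) + "\n")


def filter_pathways(
    db: Mapping[str, frozenset[str]],
    expressed_genes: Iterable[str],
    min_expressed: int = 5,
) -> dict[str, frozenset[str]]:
    """Keep pathways with strictly more than ``min_expressed`` expressed genes."""
    expressed = set(expressed_genes)
    if not expressed:
        raise ValidationError("expressed gene list is empty")
    return {
        name: genes
        for name, genes in db.items()
        if len(genes & expressed) > min_expressed
    }


def pathway_feature_matrix(
    counts: CountMatrix, pathway_genes: Iterable[str]
) -> np.ndarray:
    """Samples x genes feature matrix: standardized log2-CPM of the pathway's
    expressed genes (constant genes dropped)."""
    genes = [g for g in counts.gene_ids if g in set(pathway_genes)]
    if not genes:
        raise ValidationError("pathway has no expressed genes in the matrix")
    x = counts.counts.loc[genes].to_numpy(dtype=float)
    eff = effective_library_sizes(counts).to_numpy()
    logcpm = np.log2(x / eff * 1e6 + 1.0)
    sd = logcpm.std(axis=1)
    keep = sd > 0
    z = (logcpm[keep] - logcpm[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return z.T  # samples x genes


def _within_dispersion(data: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared distances to centroids."""
    w = 0.0
    for lab in np.unique(labels):
        pts = data[labels == lab]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def _kmeans(data: np.ndarray, k: int, rs: int) -> KMeans:
    return KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=100, random_state=rs).fit(data)


def gap_statistic_profile(
    data: np.ndarray, k_max: int, n_reference: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Gap-statistic profile for k = 1..k_max.

    gap(k) = mean_ref log W_k,ref - log W_k with W the within-cluster
    dispersion; reference datasets are uniform over each feature's observed
    range.  ``sk`` is the reference standard deviation scaled by
    sqrt(1 + 1/B).
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < k_max + 1:
        raise ValidationError("need at least k_max + 1 samples")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(2)[0])
    km_seeds = np.random.default_rng(ss.spawn(2)[1]).integers(0, 2**31 - 1, size=(n_reference + 1) * k_max)
    lo, hi = data.min(axis=0), data.max(axis=0)
    refs = [rng.uniform(lo, hi, size=data.shape) for _ in range(n_reference)]

    eps = 1e-12
    rows = []
    si = 0
    for k in range(1, k_max + 1):
        if k == 1:
            w = _within_dispersion(data, np.zeros(n, dtype=int))
            w_refs = [_within_dispersion(r, np.zeros(n, dtype=int)) for r in refs]
            si += 1
        else:
            w = _kmeans(data, k, int(km_seeds[si])).inertia_
            si += 1
            w_refs = []
            for r in refs:
                w_refs.append(_kmeans(r, k, int(km_seeds[si])).inertia_)
                si += 1
        logw_refs = np.log(np.maximum(w_refs, eps))
        gap = float(logw_refs.mean() - np.log(max(w, eps)))
        sk = float(logw_refs.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_reference))
        rows.append({"k": k, "logW": float(np.log(max(w, eps))), "gap": gap, "sk": sk})
    return pd.DataFrame(rows)


def gap_statistic_k(
    data: np.ndarray, k_max: int, n_reference: int = 50, seed: int = 0
) -> int:
    """Optimal K by the first-SE rule: smallest k with
    gap(k) >= gap(k+1) - sk(k+1); k_max if none qualifies."""
    data = np.asarray(data, dtype=float)
    if np.allclose(data, data[0]):
        return 1
    prof = gap_statistic_profile(data, k_max, n_reference, seed)
    gaps = prof["gap"].to_numpy()
    sks = prof["sk"].to_numpy()
    for i in range(k_max - 1):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            return i + 1
    return k_max


def canonical_labels(labels: Sequence[int]) -> tuple[int, ...]:
    """Relabel a partition by order of first appearance; two partitions are
    identical up to label permutation iff their canonical forms are equal."""
    mapping: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return tuple(out)


def partitions_equal(a: Sequence[int], b: Sequence[int]) -> bool:
    if len(a) != len(b):
        return False
    return canonical_labels(a) == canonical_labels(b)


@dataclass
class StabilityResult:
    pathway_id: str
    k_optimal: int
    replica_count: int
    stability_fraction: float
    stable: bool
    reference_partition: dict[str, int]  # sample id -> cluster label


def cluster_stability(
    data: np.ndarray,
    k: int,
    sample_ids: Sequence[str] | None = None,
    n_replicas: int = 500,
    conservation_threshold: float = 0.95,
    seed: int = 0,
    pathway_id: str = "",
    relaxed_rand: bool = False,
) -> StabilityResult:
    """Replica stability of K-means at fixed k.

    The reference partition is the replica with the lowest within-cluster
    dispersion; a replica conserves composition when its partition equals the
    reference up to label permutation (or, with ``relaxed_rand``, when the
    adjusted Rand index is >= 0.99).
    """
    data = np.asarray(data, dtype=float)
    if k < 2:
        raise ValidationError("stability requires k >= 2")
    n_distinct = np.unique(data, axis=0).shape[0]
    if n_distinct < k:
        raise ValidationError(f"only {n_distinct} distinct points for k={k}")
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(data.shape[0])]
    rs = np.random.default_rng(np.random.SeedSequence(seed)).integers(
        0, 2**31 - 1, size=n_replicas
    )
    labels = []
    inertias = np.empty(n_replicas)
    for r in range(n_replicas):
        km = _kmeans(data, k, int(rs[r]))
        labels.append(canonical_labels(km.labels_))
        inertias[r] = km.inertia_
    ref_idx = int(np.argmin(inertias))
    ref = labels[ref_idx]
    if relaxed_rand:
        from sklearn.metrics import adjusted_rand_score

        conserved = sum(1 for lab in labels if adjusted_rand_score(ref, lab) >= 0.99)
    else:
        conserved = sum(1 for lab in labels if lab == ref)
    frac = conserved / n_replicas
    return StabilityResult(
        pathway_id=pathway_id,
        k_optimal=k,
        replica_count=n_replicas,
        stability_fraction=frac,
        stable=frac >= conservation_threshold,
        reference_partition=dict(zip(sample_ids, ref)),
    )


@dataclass
class ConsensusAssignment:
    sample_id: str
    block_votes: dict[str, int]
    majority_block: str
    vote_string: str
    tie: bool = False


def consensus_assignment(
    stable_results: Sequence[StabilityResult], anchor_classes: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample consensus block across stable pathways.

    In each stable pathway every cluster is named by the majority anchor
    tissue class of its members (ties broken to the lexicographically
    smallest class); each sample then votes with its cluster's block name.
    Returns a table with the vote tally, the majority block, a "votes/total"
    string and a tie flag.
    """
    if not stable_results:
        raise ValidationError("no stable pathways to build a consensus from")
    classes = anchor_classes.set_index("sample_id")["tissue_class"]
    votes: dict[str, dict[str, int]] = {}
    for res in stable_results:
        part = res.reference_partition
        members_by_cluster: dict[int, list[str]] = {}
        for sid, lab in part.items():
            members_by_cluster.setdefault(lab, []).append(sid)
        block_name = {}
        for lab, members in members_by_cluster.items():
            tally = pd.Series([classes.get(s, "NA") for s in members]).value_counts()
            top = tally[tally == tally.max()]
            block_name[lab] = sorted(top.index)[0]
        for sid, lab in part.items():
            votes.setdefault(sid, {})
            block = block_name[lab]
            votes[sid][block] = votes[sid].get(block, 0) + 1
    total = len(stable_results)
    rows = []
    for sid in sorted(votes):
        tally = votes[sid]
        best = max(tally.values())
        winners = sorted(b for b, v in tally.items() if v == best)
        rows.append(
            {
                "sample_id": sid,
                "tissue_class": classes.get(sid, "NA"),
                "majority_block": winners[0],
                "votes": best,
                "total": total,
                "vote_string": f"{best}/{total}",
                "tie": len(winners) > 1,
                "block_votes": dict(sorted(tally.items())),
            }
        )
    return pd.DataFrame(rows)
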