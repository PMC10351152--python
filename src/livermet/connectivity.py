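"""Connectivity-map-style screening of a gene signature against compound
perturbation profiles.

Each compound-context profile ranks all reference genes by their differential
response; the query signature's enrichment at the extremes of that ranking is
scored with a weighted Kolmogorov-Smirnov running sum, scaled to [-100, 100].
A strongly negative score means the compound pushes the signature's up genes
to the bottom of its ranking, i.e. it inverts the signature.  Hits are
compounds scoring below a cutoff (default -95, strict) in every required
context, mirroring a "global plus liver plus colon cell line" selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import PerturbationReference, SignatureSet, ValidationError

log = logging.getLogger(__name__)

MIN_QUERY_GENES = 10
MAX_QUERY_GENES = 150

GLOBAL_CONTEXT = "global"


@dataclass
class QuerySignature:
    """Up/down query gene lists, size-bounded to 10..150 genes in total."""

    up: tuple[str, ...]
    down: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.up = tuple(dict.fromkeys(str(g).upper() for g in self.up))
        self.down = tuple(dict.fromkeys(str(g).upper() for g in self.down))
        if set(self.up) & set(self.down):
            raise ValidationError("query up and down lists overlap")

    @property
    def size(self) -> int:
        return len(self.up) + len(self.down)

    @classmethod
    def from_signature(cls, sig: SignatureSet) -> "QuerySignature":
        return cls(up=sig.up, down=sig.down)


def validate_query(
    sig: QuerySignature, reference: PerturbationReference | frozenset[str]
) -> tuple[QuerySignature, list[str]]:
    """Drop query genes absent from the reference universe and enforce the
    10..150 size bound on what remains.

    Returns the filtered query and the list of dropped genes.
    """
    universe = (
        frozenset(g.upper() for g in reference)
        if isinstance(reference, (frozenset, set))
        else frozenset(g.upper() for g in reference.gene_ids)
    )
    up = tuple(g for g in sig.up if g in universe)
    down = tuple(g for g in sig.down if g in universe)
    dropped = [g for g in (*sig.up, *sig.down) if g not in universe]
    if dropped:
        log.info("query genes dropped (not in reference): %s", dropped)
    n = len(up) + len(down)
    if not MIN_QUERY_GENES <= n <= MAX_QUERY_GENES:
        raise ValidationError(
            f"query has {n} genes after filtering; must have "
            f"{MIN_QUERY_GENES}-{MAX_QUERY_GENES}"
        )
    return QuerySignature(up=up, down=down), dropped


def _enrichment_score(ranked_genes: list[str], hits: set[str]) -> float:
    """Signed maximum deviation of the KS running sum (uniform hit weights)."""
    n = len(ranked_genes)
    n_hits = len(hits)
    if n_hits == 0 or n_hits == n:
        return 0.0
    step_hit = 1.0 / n_hits
    step_miss = 1.0 / (n - n_hits)
    running = 0.0
    best = 0.0
    for g in ranked_genes:
        running += step_hit if g in hits else -step_miss
        if abs(running) > abs(best):
            best = running
    return best


def connectivity_score(query: QuerySignature, profile: pd.Series) -> float:
    """Score one compound-context profile against the query, in [-100, 100].

    Genes are ranked by profile value descending (ties broken by gene id);
    ES(up) and ES(down) are the signed KS maximum deviations of the up and
    down sets, combined as (ES_up - ES_down)/2 when both are present.  A
    constant profile carries no ranking information and scores 0.
    """
    values = profile.to_numpy(dtype=float)
    if np.all(values == values[0]):
        log.warning("constant profile; connectivity score set to 0")
        return 0.0
    order = sorted(range(len(values)), key=lambda i: (-values[i], str(profile.index[i])))
    ranked = [str(profile.index[i]).upper() for i in order]
    es_up = _enrichment_score(ranked, set(query.up)) if query.up else None
    es_dn = _enrichment_score(ranked, set(query.down)) if query.down else None
    if es_up is not None and es_dn is not None:
        s = (es_up - es_dn) / 2.0
    elif es_up is not None:
        s = es_up
    elif es_dn is not None:
        s = -es_dn
    else:
        raise ValidationError("query has no genes")
    return 100.0 * s


def screen(query: QuerySignature, reference: PerturbationReference) -> pd.DataFrame:
    """Score every compound in every context plus a "global" mean summary.

    Returns a tidy table (compound, context, score, rank) where ranks are
    dense within context, best (most negative) score first; ties broken by
    compound id.
    """
    rows = []
    for compound in reference.compounds:
        for ctx in reference.contexts:
            score = connectivity_score(query, reference.profile(compound, ctx))
            rows.append({"compound": compound, "context": ctx, "score": score})
    df = pd.DataFrame(rows)
    glob = (
        df.groupby("compound", sort=False)["score"]
        .mean()
        .reset_index()
        .assign(context=GLOBAL_CONTEXT)
    )
    df = pd.concat([df, glob[["compound", "context", "score"]]], ignore_index=True)
    df = df.sort_values(["context", "score", "compound"], kind="mergesort").reset_index(drop=True)
    df["rank"] = df.groupby("context")["score"].rank(method="dense").astype(int)
    return df


def select_hits(
    results: pd.DataFrame,
    cutoff: float = -95.0,
    contexts_required: list[str] | None = None,
) -> list[str]:
    """Compounds scoring strictly below ``cutoff`` in every required context.

    Defaults to all contexts present in ``results`` (including "global").
    Compounds missing a required context are excluded and logged.  Output is
    sorted by global score ascending (most inverting first).
    """
    if contexts_required is None:
        contexts_required = sorted(results["context"].unique())
    missing_ctx = set(contexts_required) - set(results["context"].unique())
    if missing_ctx:
        raise ValidationError(f"results lack required contexts: {sorted(missing_ctx)}")
    wide = results.pivot(index="compound", columns="context", values="score")
    hits = []
    for compound, row in wide.iterrows():
        vals = row[contexts_required]
        if vals.isna().any():
            log.info("compound %s missing a required context; excluded", compound)
            continue
        if (vals < cutoff).all():
            hits.append(compound)
    key = GLOBAL_CONTEXT if GLOBAL_CONTEXT in wide.columns else contexts_required[0]
    hits.sort(key=lambda c: (wide.loc[c, key], c))
    return hits


def summarize_classes(
    hits: list[str],
    compound_meta: pd.DataFrame,
    results: pd.DataFrame | None = None,
    score_band: tuple[float, float] = (-100.0, -50.0),
) -> pd.DataFrame:
    """Mechanism-class composition of hits inside a connectivity-score band.

    The band applies to the global score when ``results`` is given (both ends
    inclusive); without ``results`` all hits are counted.  Hits without
    metadata are assigned class "unknown".  Proportions sum to 1.
    """
    lo, hi = min(score_band), max(score_band)
    selected = []
    for c in hits:
        if results is not None:
            sub = results[(results["compound"] == c) & (results["context"] == GLOBAL_CONTEXT)]
            if len(sub) and not (lo <= float(sub["score"].iloc[0]) <= hi):
                continue
        selected.append(c)
    classes = [
        compound_meta.loc[c, "mechanism_class"] if c in compound_meta.index else "unknown"
        for c in selected
    ]
    if not classes:
        return pd.DataFrame(columns=["mechanism_class", "count", "proportion"])
    tab = pd.Series(classes).value_counts().rename_axis("mechanism_class").reset_index(name="count")
    tab["proportion"] = tab["count"] / tab["count"].sum()
    return tab
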