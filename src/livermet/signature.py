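"""Signature derivation: set intersections, tissue-enrichment classification,
and hypergeometric over-representation.

The core colon-to-liver metastasis signature is the intersection of the
up-regulated genes from the matched-patient contrast, the unmatched contrast,
and any external cohorts, with full provenance of which inputs produced it.
Genes are classified against a Protein-Atlas-style tissue-enrichment table as
liver-only / intestine-only / both / neither.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetPair, SignatureSet, ValidationError
from .de import adjust_pvalues_bh

log = logging.getLogger(__name__)


@dataclass
class TissueClassCounts:
    liver_only: int
    intestine_only: int
    both: int
    neither: int

    @property
    def total(self) -> int:
        return self.liver_only + self.intestine_only + self.both + self.neither


def _parse_levels(text: str) -> dict[str, float | None]:
    """Parse "liver: 442.2;intestine: 224.8" into a tissue -> level map."""
    out: dict[str, float | None] = {}
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            tissue, _, level = part.partition(":")
            try:
                out[tissue.strip().lower()] = float(level.strip())
            except ValueError:
                out[tissue.strip().lower()] = None
        else:
            out[part.lower()] = None
    return out


def load_annotation(path: str | Path, tissue_column: str | None = None) -> pd.DataFrame:
    """Read a tissue-enrichment TSV into an annotation table.

    The first column is the gene symbol; the enrichment column (auto-detected
    among ``enriched_tissues`` / ``rna_tissue_enrichment`` unless named) holds
    semicolon-separated "tissue: level" entries.  Returns a DataFrame indexed
    by upper-cased gene symbol with columns ``tissues`` (frozenset) and
    ``levels`` (dict).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_col = df.columns[0]
    if tissue_column is None:
        for cand in ("enriched_tissues", "rna_tissue_enrichment"):
            if cand in df.columns:
                tissue_column = cand
                break
    if tissue_column is None:
        raise ValidationError("no tissue-enrichment column found")
    if df[gene_col].str.upper().duplicated().any():
        raise ValidationError("duplicate gene ids in annotation")
    rows = []
    for _, r in df.iterrows():
        levels = _parse_levels(r[tissue_column]) if pd.notna(r[tissue_column]) else {}
        rows.append(
            {
                "gene_id": str(r[gene_col]).upper(),
                "tissues": frozenset(levels),
                "levels": levels,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def intersect_gene_sets(sets: Sequence[GeneSetPair], direction: str = "up") -> tuple[str, ...]:
    """Exact intersection of the requested direction across >= 2 sets, sorted."""
    if len(sets) < 2:
        raise ValidationError("need at least two gene sets to intersect")
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    acc: set[str] | None = None
    for s in sets:
        members = set(getattr(s, direction))
        acc = members if acc is None else acc & members
    return tuple(sorted(acc or ()))


def classify_tissue_enrichment(
    genes: Iterable[str],
    annotation: pd.DataFrame,
    tissues: tuple[str, str] = ("liver", "intestine"),
) -> tuple[TissueClassCounts, pd.Series]:
    """Label each gene liver_only / intestine_only / both / neither.

    A gene absent from the annotation is "neither" (logged).  Counts form a
    partition of the input set.
    """
    t1, t2 = tissues
    labels = {}
    for g in dict.fromkeys(str(g).upper() for g in genes):
        if g not in annotation.index:
            log.info("gene %s not annotated; classified neither", g)
            labels[g] = "neither"
            continue
        ts = annotation.loc[g, "tissues"]
        has1, has2 = t1 in ts, t2 in ts
        if has1 and has2:
            labels[g] = "both"
        elif has1:
            labels[g] = f"{t1}_only"
        elif has2:
            labels[g] = f"{t2}_only"
        else:
            labels[g] = "neither"
    s = pd.Series(labels, dtype=object)
    counts = TissueClassCounts(
        liver_only=int((s == f"{t1}_only").sum()),
        intestine_only=int((s == f"{t2}_only").sum()),
        both=int((s == "both").sum()),
        neither=int((s == "neither").sum()),
    )
    return counts, s


def derive_core_signature(
    own_matched: GeneSetPair,
    own_unmatched: GeneSetPair,
    external: Sequence[GeneSetPair] = (),
    name: str = "core",
) -> SignatureSet:
    """Core signature = intersection of all provided up-sets (down likewise).

    Provenance records every input with its contrast label, so alternative
    intersection semantics can be reproduced by re-running with a different
    input list.
    """
    inputs = [own_matched, own_unmatched, *external]
    up = intersect_gene_sets(inputs, "up")
    down = intersect_gene_sets(inputs, "down")
    provenance = [
        {
            "dataset": "own_matched" if i == 0 else "own_unmatched" if i == 1 else f"external_{i - 1}",
            "contrast": s.contrast_label,
            "operation": "intersection(up), intersection(down)",
            "n_up": len(s.up),
            "n_down": len(s.down),
        }
        for i, s in enumerate(inputs)
    ]
    return SignatureSet(name=name, up=up, down=down, provenance=provenance)


def enrichment_test(
    gene_set: Iterable[str],
    pathway_db: Mapping[str, frozenset[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``gene_set`` in each
    pathway, BH-adjusted across pathways.

    ``p = P(X >= overlap)`` where X is hypergeometric with the pathway's
    in-universe size, the query size and the universe size.
    """
    universe = set(str(g).upper() for g in universe)
    query = set(str(g).upper() for g in gene_set)
    outside = query - universe
    if outside:
        raise ValidationError(f"genes outside universe: {sorted(outside)[:10]}")
    n_u = len(universe)
    n_q = len(query)
    rows = []
    for pid, members in pathway_db.items():
        mem = {str(g).upper() for g in members} & universe
        k = len(query & mem)
        m = len(mem)
        # upper tail at the observed overlap
        p = float(stats.hypergeom.sf(k - 1, n_u, m, n_q)) if m else 1.0
        expected = n_q * m / n_u if n_u else 0.0
        fold = k / expected if expected > 0 else np.nan
        rows.append({"pathway": pid, "overlap": k, "size": m, "fold": fold, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = adjust_pvalues_bh(out["p"].to_numpy())
        out = out.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# packaged fixtures

def _data_path(name: str) -> Path:
    return Path(resources.files("livermet").joinpath("data", name))


def load_signature_table(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged 22-gene colon-to-liver signature table (symbol, name,
    Ensembl id, tissue enrichment with nTPM-like levels)."""
    if path is None:
        path = _data_path("colon_liver_signature.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["gene"] = df["gene"].str.upper()
    if df["gene"].duplicated().any():
        raise ValidationError("duplicate symbols in signature table")
    return df


def core_signature_from_table(path: str | Path | None = None) -> SignatureSet:
    """The 22-gene up-regulated metastasis signature as a SignatureSet."""
    df = load_signature_table(path)
    return SignatureSet(
        name="colon_liver_metastasis_22",
        up=tuple(df["gene"]),
        down=(),
        provenance=[
            {
                "dataset": "packaged",
                "contrast": "LM vs CC",
                "operation": "matched-core ∩ unmatched ∩ two external cohorts",
            }
        ],
    )


def load_reference_universe(path: str | Path | None = None) -> frozenset[str]:
    """Gene universe of the packaged perturbation annotation (synthetic
    stand-in for a perturbation database's annotated-gene list; one signature
    gene, SLC13A5, is deliberately absent from it)."""
    if path is None:
        path = _data_path("reference_universe_synthetic.txt")
    genes = [
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return frozenset(genes)
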