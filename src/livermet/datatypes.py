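"""Core containers shared by the pipeline stages.

Conventions used throughout the package:

* expression matrices are genes (rows) x samples (columns);
* gene identity is by symbol, upper-cased;
* tissue classes follow the cohort labels ``CC`` (primary colon cancer),
  ``LM1``/``LM2``/``LM3`` (first/second/third-wave liver metastasis),
  ``AL`` (adjacent uninvolved liver) and ``NC`` (normal colon).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TISSUE_CLASSES = ("CC", "LM1", "LM2", "LM3", "AL", "NC")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class CountMatrix:
    """Integer expression counts, genes x samples.

    ``counts`` is a DataFrame indexed by gene id with sample ids as columns.
    Identifiers must be unique and every cell a non-negative integer.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        keep = [g for g in self.counts.index if g in set(genes)]
        return CountMatrix(self.counts.loc[keep])

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(samples)])


def validate_metadata(metadata: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Check a sample-metadata table (sample_id, patient_id, tissue_class, matched).

    Every sample of ``counts`` (when given) must have exactly one metadata row.
    """
    required = {"sample_id", "patient_id", "tissue_class"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    if metadata["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad = set(metadata["tissue_class"]) - set(TISSUE_CLASSES)
    if bad:
        raise ValidationError(f"unknown tissue classes: {sorted(bad)}")
    if counts is not None:
        have = set(metadata["sample_id"])
        need = set(counts.sample_ids)
        if have != need:
            raise ValidationError(
                f"metadata/sample mismatch: missing={sorted(need - have)[:5]} "
                f"extra={sorted(have - need)[:5]}"
            )
    return metadata


@dataclass
class GeneSetPair:
    """Up/down gene lists for one group contrast."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    contrast_label: str = ""

    def __post_init__(self) -> None:
        self.up = tuple(dict.fromkeys(self.up))
        self.down = tuple(dict.fromkeys(self.down))
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValidationError(f"up/down sets overlap: {sorted(overlap)[:5]}")


@dataclass
class SignatureSet:
    """A named signature with provenance of the intersections that produced it."""

    name: str
    up: tuple[str, ...]
    down: tuple[str, ...] = ()
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.up = tuple(dict.fromkeys(self.up))
        self.down = tuple(dict.fromkeys(self.down))
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValidationError(f"up/down sets overlap: {sorted(overlap)[:5]}")

    @property
    def size(self) -> int:
        return len(self.up) + len(self.down)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "up": list(self.up),
            "down": list(self.down),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureSet":
        d = json.loads(Path(path).read_text())
        return cls(d["name"], tuple(d["up"]), tuple(d.get("down", ())), d.get("provenance", []))


@dataclass
class GroundTruth:
    """Planted truth emitted by the simulators; the oracle for recovery tests."""

    de_up_genes: frozenset[str] = frozenset()
    de_down_genes: frozenset[str] = frozenset()
    liver_enriched: frozenset[str] = frozenset()
    intestine_enriched: frozenset[str] = frozenset()
    reverter_compounds: frozenset[str] = frozenset()
    synergy_pairs: dict[str, float] = field(default_factory=dict)
    rs_effect: float | None = None

    def __post_init__(self) -> None:
        self.de_up_genes = frozenset(self.de_up_genes)
        self.de_down_genes = frozenset(self.de_down_genes)
        self.liver_enriched = frozenset(self.liver_enriched)
        self.intestine_enriched = frozenset(self.intestine_enriched)
        self.reverter_compounds = frozenset(self.reverter_compounds)
        if self.de_up_genes & self.de_down_genes:
            raise ValidationError("planted up and down gene sets overlap")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_up_genes": sorted(self.de_up_genes),
            "de_down_genes": sorted(self.de_down_genes),
            "liver_enriched": sorted(self.liver_enriched),
            "intestine_enriched": sorted(self.intestine_enriched),
            "reverter_compounds": sorted(self.reverter_compounds),
            "synergy_pairs": self.synergy_pairs,
            "rs_effect": self.rs_effect,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            frozenset(d["de_up_genes"]),
            frozenset(d["de_down_genes"]),
            frozenset(d["liver_enriched"]),
            frozenset(d["intestine_enriched"]),
            frozenset(d["reverter_compounds"]),
            d.get("synergy_pairs", {}),
            d.get("rs_effect"),
        )


@dataclass
class PerturbationReference:
    """Compound perturbation profiles: genes x (compound, context) scores.

    ``profiles`` carries a two-level column index (compound, context);
    ``compound_meta`` is indexed by compound id with columns ``name`` and
    ``mechanism_class``.
    """

    profiles: pd.DataFrame
    compound_meta: pd.DataFrame
    contexts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.profiles.columns.nlevels != 2:
            raise ValidationError("profiles need (compound, context) columns")
        if self.profiles.isna().any().any():
            raise ValidationError("profiles contain missing values")
        self.contexts = tuple(self.contexts)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def compounds(self) -> list[str]:
        return list(dict.fromkeys(self.profiles.columns.get_level_values(0)))

    def profile(self, compound: str, context: str) -> pd.Series:
        return self.profiles[(compound, context)]
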