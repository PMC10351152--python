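"""Readers and writers for the pipeline's tabular formats.

All tables are TSV with a header row; structured outputs are JSON.  Count
matrices have gene ids in the first column and sample ids as the header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, PerturbationReference, ValidationError
from .organoid import DoseResponseMatrix


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Strictly parse a counts TSV: integer cells, unique gene/sample ids."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dups = [h for h in header if h in seen or seen.add(h)]
    if dups:
        raise ValidationError(f"duplicate sample header(s): {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"duplicate gene id(s): {dups}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(f"non-integer count at gene {gene!r}, sample {col!r}")
    return CountMatrix(df.astype(np.int64))


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_perturbation_reference(ref: PerturbationReference, path: str | Path, meta_path: str | Path) -> None:
    """Profiles as TSV with "compound|context" columns; metadata alongside."""
    flat = ref.profiles.copy()
    flat.columns = [f"{c}|{x}" for c, x in flat.columns]
    flat.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.6g")
    ref.compound_meta.rename_axis("compound").to_csv(meta_path, sep="\t")


def read_perturbation_reference(path: str | Path, meta_path: str | Path) -> PerturbationReference:
    flat = pd.read_csv(path, sep="\t", index_col=0)
    pairs = []
    for col in flat.columns:
        if "|" not in col:
            raise ValidationError(f"reference column {col!r} is not 'compound|context'")
        compound, _, ctx = col.partition("|")
        pairs.append((compound, ctx))
    flat.columns = pd.MultiIndex.from_tuples(pairs, names=["compound", "context"])
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    contexts = tuple(dict.fromkeys(p[1] for p in pairs))
    return PerturbationReference(flat, meta, contexts)


def read_dose_matrix(path: str | Path) -> DoseResponseMatrix:
    """Dose grid TSV: first row/column are doses, body is inhibition fractions."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DoseResponseMatrix(
        doses_a=df.index.to_numpy(dtype=float),
        doses_b=df.columns.to_numpy(dtype=float),
        inhibition=df.to_numpy(dtype=float),
    )


def write_dose_matrix(m: DoseResponseMatrix, path: str | Path) -> None:
    pd.DataFrame(m.inhibition, index=m.doses_a, columns=m.doses_b).rename_axis(
        "dose_a"
    ).to_csv(path, sep="\t", float_format="%.6g")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
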