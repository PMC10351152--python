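"""Synthetic cohorts, annotations, perturbation references and organoid assays.

Every generator plants a known ground truth so that each downstream stage can
be scored against what was actually put in.  The cohort model mirrors the
biology the pipeline assumes: a liver expression program high in adjacent
liver and low in primary colon tumors, a colon program with the opposite
orientation, and liver-metastasis samples whose log-scale expected expression
is a convex mixture ``(1-w)*CC + w*AL`` of the two tissue programs, so that
metastases sit between tumor and liver in any low-dimensional embedding.

Counts are negative binomial with variance ``mu + phi*mu**2`` (``phi`` shared
across genes by default) and per-sample library sizes drawn log-uniformly, so
the normalization step downstream has real work to do.  All randomness flows
from a single ``numpy.random.SeedSequence``; per-operation substreams are
spawned deterministically, hence identical configs and seeds give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CountMatrix,
    GroundTruth,
    PerturbationReference,
    SignatureSet,
    ValidationError,
)
from .organoid import DoseResponseMatrix, OrganoidTimepoint, bliss_expected

DEFAULT_GROUPS: dict[str, int] = {"CC": 9, "LM1": 25, "LM2": 7, "LM3": 3, "AL": 6}

MECHANISM_CLASSES = (
    "cox_inhibitor",
    "dopamine_antagonist",
    "histamine_antagonist",
    "adrenergic_antagonist",
    "serotonin_antagonist",
    "pde_inhibitor",
    "egfr_inhibitor",
    "tki",
)


@dataclass
class CohortConfig:
    """Parameters of the simulated colon/liver cohort.

    ``groups`` maps tissue class to the number of samples; ``mixture_weight``
    is the fraction of the liver program adopted by metastasis samples;
    ``planted_logfc`` is the CC-vs-AL separation of the program genes in log2
    units; ``nb_dispersion`` is the shared NB dispersion phi.
    """

    n_patients: int = 9
    groups: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    n_genes: int = 2000
    n_liver_program: int = 40
    n_colon_program: int = 40
    mixture_weight: float = 0.8
    planted_logfc: float = 6.0
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (1e6, 2e7)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_liver_program + self.n_colon_program > self.n_genes:
            raise ValidationError("program genes exceed n_genes")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValidationError("mixture_weight must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be non-negative")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValidationError("library_size_range must be positive and ordered")
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValidationError("n_patients and n_genes must be positive")
        bad = set(self.groups) - {"CC", "LM1", "LM2", "LM3", "AL", "NC"}
        if bad:
            raise ValidationError(f"unknown tissue classes in groups: {sorted(bad)}")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, var = mu + phi mu^2) sample; Poisson when phi == 0."""
    if phi == 0:
        return rng.poisson(mu)
    size = 1.0 / phi
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _tissue_log_means(cfg: CohortConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, list[str]]:
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    liver_idx = np.arange(cfg.n_liver_program)
    colon_idx = np.arange(cfg.n_liver_program, cfg.n_liver_program + cfg.n_colon_program)

    cc = base.copy()
    al = base.copy()
    al[liver_idx] += cfg.planted_logfc       # liver program: high in AL
    cc[colon_idx] += cfg.planted_logfc       # colon program: high in CC
    w = cfg.mixture_weight
    lm = (1.0 - w) * cc + w * al             # metastasis = convex mixture in log space
    means = pd.DataFrame(
        {"CC": cc, "LM1": lm, "LM2": lm, "LM3": lm, "AL": al, "NC": cc}, index=genes
    )
    return means, genes


def expected_group_log_means(cfg: CohortConfig) -> pd.DataFrame:
    """Per-tissue expected log2 relative expression (deterministic given seed)."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(3)[0])
    means, _ = _tissue_log_means(cfg, rng)
    return means


def simulate_cohort(cfg: CohortConfig) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a cohort of NB counts with planted tissue programs.

    Returns the count matrix, a sample-metadata table (sample_id, patient_id,
    tissue_class, matched) and the planted :class:`GroundTruth`.  Metastasis
    log-means are the convex mixture of the CC and AL programs, so with
    ``mixture_weight = 0`` the LM groups are distributionally identical to CC.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    s_means, s_libs, s_counts = ss.spawn(3)
    means, genes = _tissue_log_means(cfg, np.random.default_rng(s_means))

    # sample bookkeeping: CC samples take patients P01.., LM waves cycle over
    # patients so that min(n_patients, n_CC, n_LM1) patients are matched
    rows = []
    for tissue, n in cfg.groups.items():
        for i in range(n):
            patient = f"P{(i % cfg.n_patients) + 1:02d}"
            rows.append((f"{tissue}_{i + 1:02d}", patient, tissue))
    meta = pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue_class"])
    cc_patients = set(meta.loc[meta.tissue_class == "CC", "patient_id"])
    lm1_patients = set(meta.loc[meta.tissue_class == "LM1", "patient_id"])
    matched = cc_patients & lm1_patients
    meta["matched"] = meta["patient_id"].isin(matched)

    rng_lib = np.random.default_rng(s_libs)
    lo, hi = cfg.library_size_range
    lib = np.exp(rng_lib.uniform(np.log(lo), np.log(hi), len(meta)))

    rng_counts = np.random.default_rng(s_counts)
    counts = np.empty((cfg.n_genes, len(meta)), dtype=np.int64)
    for j, (_, row) in enumerate(meta.iterrows()):
        log_mu = means[row.tissue_class].to_numpy()
        prop = np.exp2(log_mu)
        prop = prop / prop.sum()
        counts[:, j] = _nb_draw(rng_counts, prop * lib[j], cfg.nb_dispersion)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=meta["sample_id"].tolist()))
    liver = frozenset(genes[: cfg.n_liver_program])
    colon = frozenset(genes[cfg.n_liver_program : cfg.n_liver_program + cfg.n_colon_program])
    effect = cfg.mixture_weight * cfg.planted_logfc
    truth = GroundTruth(
        de_up_genes=liver if effect > 0 else frozenset(),
        de_down_genes=colon if effect > 0 else frozenset(),
        liver_enriched=liver,
        intestine_enriched=colon,
    )
    return cm, meta, truth


def simulate_annotation(
    truth: GroundTruth, noise_fraction: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Tissue-enrichment annotation consistent with the planted programs.

    One row per annotated gene with columns ``gene_id``, ``enriched_tissues``
    (semicolon-separated) and ``levels`` (tissue:value pairs).  A seeded
    ``round(noise_fraction * n)`` subset of rows is corrupted (re-labelled
    "other"), emulating imperfect atlas annotation.
    """
    if not 0.0 <= noise_fraction < 0.5:
        raise ValidationError("noise_fraction must lie in [0, 0.5)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = sorted(truth.liver_enriched | truth.intestine_enriched)
    rows = []
    for g in genes:
        tissues = []
        if g in truth.liver_enriched:
            tissues.append("liver")
        if g in truth.intestine_enriched:
            tissues.append("intestine")
        levels = {t: float(np.round(rng.uniform(50, 2000), 1)) for t in tissues}
        rows.append((g, tissues, levels))
    n_flip = int(round(noise_fraction * len(rows)))
    flip_idx = set(rng.choice(len(rows), size=n_flip, replace=False)) if n_flip else set()
    out = []
    for i, (g, tissues, levels) in enumerate(rows):
        if i in flip_idx:
            tissues, levels = ["other"], {"other": levels[next(iter(levels))]}
        out.append(
            {
                "gene_id": g,
                "enriched_tissues": ";".join(tissues),
                "levels": ";".join(f"{t}: {levels[t]}" for t in tissues),
            }
        )
    return pd.DataFrame(out, columns=["gene_id", "enriched_tissues", "levels"])


def simulate_perturbation_reference(
    signature: SignatureSet,
    n_compounds: int = 50,
    n_reverters: int = 2,
    contexts: Sequence[str] = ("HEPG2", "HT29", "A549"),
    seed: int = 0,
    n_genes: int = 500,
    reverter_strength: float = 8.0,
) -> tuple[PerturbationReference, GroundTruth]:
    """Perturbation profiles with planted signature-reverting compounds.

    Non-reverter compounds receive exchangeable standard-normal gene scores in
    every context.  Reverters push the signature's up genes strongly negative
    (and down genes positive) in every context, so a rank-based connectivity
    score places them near -100.
    """
    if signature.size == 0:
        raise ValidationError("signature is empty")
    if n_reverters > n_compounds:
        raise ValidationError("n_reverters exceeds n_compounds")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    sig_genes = list(signature.up) + list(signature.down)
    n_bg = max(0, n_genes - len(sig_genes))
    genes = sig_genes + [f"BG{i:05d}" for i in range(n_bg)]

    compounds = [f"CPD{i + 1:03d}" for i in range(n_compounds)]
    reverters = sorted(rng.choice(compounds, size=n_reverters, replace=False).tolist())
    up_pos = [genes.index(g) for g in signature.up]
    dn_pos = [genes.index(g) for g in signature.down]

    cols = {}
    for c in compounds:
        for ctx in contexts:
            prof = rng.normal(0.0, 1.0, len(genes))
            if c in reverters:
                prof[up_pos] = -reverter_strength + rng.normal(0.0, 0.1, len(up_pos))
                prof[dn_pos] = reverter_strength + rng.normal(0.0, 0.1, len(dn_pos))
            cols[(c, ctx)] = prof
    profiles = pd.DataFrame(cols, index=genes)
    profiles.columns = pd.MultiIndex.from_tuples(profiles.columns, names=["compound", "context"])

    meta = pd.DataFrame(
        {
            "name": [c.lower() for c in compounds],
            "mechanism_class": rng.choice(MECHANISM_CLASSES, size=n_compounds),
        },
        index=pd.Index(compounds, name="compound"),
    )
    ref = PerturbationReference(profiles, meta, tuple(contexts))
    truth = GroundTruth(reverter_compounds=frozenset(reverters))
    return ref, truth


def simulate_pathways(
    gene_ids: Sequence[str],
    n_pathways: int = 151,
    size_range: tuple[int, int] = (10, 80),
    planted: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> dict[str, frozenset[str]]:
    """Synthetic pathway collection over a gene universe (GMT-shaped dict).

    ``planted`` pathways (e.g. the liver/colon programs) are included first;
    the remainder are random draws, emulating a curated pathway database.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    db: dict[str, frozenset[str]] = {}
    if planted:
        for name, members in planted.items():
            db[name] = frozenset(members)
    i = 0
    while len(db) < n_pathways:
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(gene_ids))
        members = rng.choice(gene_ids, size=size, replace=False)
        db[f"PW{i:05d}"] = frozenset(members.tolist())
        i += 1
    return db


def simulate_organoid_experiment(
    rs_effect: float = 4.0,
    bliss_excess: float = 0.2,
    doses_a: Sequence[float] = (0.0, 12.5, 25.0, 50.0, 100.0),
    doses_b: Sequence[float] = (0.0, 1.5625, 3.125, 6.25, 12.5),
    noise_sd: float = 0.02,
    seed: int = 0,
    max_inhibition: tuple[float, float] = (0.45, 0.45),
) -> tuple[tuple[OrganoidTimepoint, OrganoidTimepoint], DoseResponseMatrix, GroundTruth]:
    """Organoid assay with a planted response score and Bliss excess.

    Single-agent margins follow saturating Hill-type curves capped at
    ``max_inhibition``; combination inhibition is the Bliss expectation plus
    ``bliss_excess`` plus Gaussian noise, clipped to [0, 1].  Margins are kept
    noise-free so the planted excess is identifiable from the combination
    cells alone.  The paired timepoints are scaled so the true RS equals
    ``rs_effect`` exactly when ``noise_sd == 0``.
    """
    if rs_effect <= 0:
        raise ValidationError("rs_effect must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    da = np.asarray(doses_a, dtype=float)
    db_ = np.asarray(doses_b, dtype=float)
    if da[0] != 0 or db_[0] != 0:
        raise ValidationError("dose grids must include zero-dose margins")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def hill(d: np.ndarray, cap: float) -> np.ndarray:
        ref = np.median(d[d > 0]) if (d > 0).any() else 1.0
        return cap * d / (d + ref)

    ya = hill(da, max_inhibition[0])
    yb = hill(db_, max_inhibition[1])
    inhib = np.empty((len(da), len(db_)))
    for i in range(len(da)):
        for j in range(len(db_)):
            exp = bliss_expected(ya[i], yb[j])
            if i > 0 and j > 0:
                exp = exp + bliss_excess + rng.normal(0.0, noise_sd)
            inhib[i, j] = np.clip(exp, 0.0, 1.0)
    inhib[0, 0] = 0.0
    matrix = DoseResponseMatrix(doses_a=da, doses_b=db_, inhibition=inhib)

    t0 = OrganoidTimepoint(n_organoids=100, mean_max_diameter=150.0, viability=0.9)
    jitter = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
    t72 = OrganoidTimepoint(
        n_organoids=100,
        mean_max_diameter=150.0 / rs_effect * jitter,
        viability=0.9,
    )
    truth = GroundTruth(
        synergy_pairs={"planted_excess_x100": 100.0 * bliss_excess},
        rs_effect=rs_effect,
    )
    return (t0, t72), matrix, truth
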