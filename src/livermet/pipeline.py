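"""End-to-end orchestration of the synthetic analysis pipeline.

``run_pipeline`` executes the requested stages in dependency order
(simulate -> de -> signature -> cluster -> connect -> organoid) on a
synthetic cohort, writing each stage's outputs plus a manifest recording
parameters, seeds and output hashes, so identical configurations reproduce
byte-identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as lio
from .clustering import (
    cluster_stability,
    consensus_assignment,
    filter_pathways,
    gap_statistic_k,
    pathway_feature_matrix,
    write_gene_sets,
)
from .connectivity import QuerySignature, screen, select_hits, summarize_classes, validate_query
from .datatypes import SignatureSet, ValidationError
from .de import (
    PRESETS,
    DECallThresholds,
    call_de,
    compute_sample_embedding,
    filter_low_expression,
    test_differential_expression,
)
from .organoid import bliss_synergy_score, response_score
from .signature import classify_tissue_enrichment, derive_core_signature, load_annotation
from .simulate import (
    CohortConfig,
    simulate_annotation,
    simulate_cohort,
    simulate_organoid_experiment,
    simulate_pathways,
    simulate_perturbation_reference,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "de", "signature", "cluster", "connect", "organoid")


@dataclass
class PipelineConfig:
    """Declarative configuration of a pipeline run.

    ``preset`` selects the DE thresholds: "paper" (BH-adjusted p < 0.01,
    |logFC| > 4) or the public-cohort variants "public1" (raw p < 1e-3) and
    "public2" (raw p < 0.01).
    """

    out_dir: str | Path = "livermet_run"
    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    preset: str = "paper"
    cohort: CohortConfig | None = None
    n_pathways: int = 20
    cluster_replicas: int = 500
    conservation_threshold: float = 0.95
    connectivity_cutoff: float = -95.0
    n_compounds: int = 50
    n_reverters: int = 2

    def thresholds(self) -> DECallThresholds:
        if self.preset not in PRESETS:
            raise ValidationError(f"unknown preset {self.preset!r}")
        return PRESETS[self.preset]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    seed = int(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "preset": config.preset,
        "stages": list(stages),
        "outputs": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": path.name, "sha256": _sha256(path)}

    cfg = config.cohort or CohortConfig(seed=seed)
    counts = meta = truth = None

    if "simulate" in stages:
        counts, meta, truth = simulate_cohort(cfg)
        annotation = simulate_annotation(truth, noise_fraction=0.0, seed=seed)
        lio.write_count_matrix(counts, out / "counts.tsv")
        lio.write_metadata(meta, out / "metadata.tsv")
        truth.to_json(out / "truth.json")
        annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
        for name in ("counts.tsv", "metadata.tsv", "truth.json", "annotation.tsv"):
            record(name, out / name)

    def _require_cohort():
        nonlocal counts, meta
        if counts is None:
            if not (out / "counts.tsv").exists():
                raise ValidationError("missing upstream output of stage 'simulate'")
            counts = lio.read_count_matrix(out / "counts.tsv")
            meta = lio.read_metadata(out / "metadata.tsv")
        return counts, meta

    filtered = None
    sets: dict[str, object] = {}

    if "de" in stages:
        counts, meta = _require_cohort()
        filtered = filter_low_expression(counts)
        thr = config.thresholds()
        matched_patients = meta.loc[meta["matched"] == True, "patient_id"]  # noqa: E712
        matched_samples = meta[
            meta["patient_id"].isin(matched_patients)
            & meta["tissue_class"].isin(["CC", "LM1"])
        ]["sample_id"].tolist()
        tbl_matched = test_differential_expression(
            filtered.subset_samples(matched_samples), meta, ("LM1", "CC")
        )
        tbl_unmatched = test_differential_expression(filtered, meta, ("LM1", "CC"))
        lio.write_de_table(tbl_matched, out / "de_matched.tsv")
        lio.write_de_table(tbl_unmatched, out / "de_unmatched.tsv")
        sets["matched"] = call_de(tbl_matched, thr, "LM1 vs CC (matched)")
        sets["unmatched"] = call_de(tbl_unmatched, thr, "LM1 vs CC (unmatched)")
        emb = compute_sample_embedding(filtered)
        emb.rename_axis("sample_id").to_csv(out / "embedding.tsv", sep="\t", float_format="%.6g")
        lio.write_json(
            {
                label: {"up": list(gs.up), "down": list(gs.down)}
                for label, gs in sets.items()
            },
            out / "de_sets.json",
        )
        for name in ("de_matched.tsv", "de_unmatched.tsv", "embedding.tsv", "de_sets.json"):
            record(name, out / name)

    signature = None
    if "signature" in stages:
        if "matched" not in sets:
            raise ValidationError("missing upstream output of stage 'de'")
        # two extra simulated cohorts stand in for the external public datasets
        externals = []
        for i, preset in enumerate(("public1", "public2")):
            ext_cfg = CohortConfig(
                **{**cfg.__dict__, "seed": seed + 1000 + i, "groups": {"CC": 5, "LM1": 5}}
            )
            ec, em, _ = simulate_cohort(ext_cfg)
            ef = filter_low_expression(ec)
            et = test_differential_expression(ef, em, ("LM1", "CC"))
            externals.append(call_de(et, PRESETS[preset], f"LM vs CC ({preset})"))
        signature = derive_core_signature(sets["matched"], sets["unmatched"], externals)
        signature.to_json(out / "signature.json")
        ann = load_annotation(out / "annotation.tsv") if (out / "annotation.tsv").exists() else None
        if ann is not None and signature.up:
            counts_cls, labels = classify_tissue_enrichment(signature.up, ann)
            labels.rename("tissue_class").rename_axis("gene_id").to_csv(
                out / "signature_tissue_classes.tsv", sep="\t"
            )
            record("signature_tissue_classes.tsv", out / "signature_tissue_classes.tsv")
        record("signature.json", out / "signature.json")

    if "cluster" in stages:
        counts, meta = _require_cohort()
        if filtered is None:
            filtered = filter_low_expression(counts)
        truth_path = out / "truth.json"
        planted = {}
        if truth_path.exists():
            from .datatypes import GroundTruth

            t = GroundTruth.from_json(truth_path)
            planted = {
                "LIVER_PROGRAM": set(t.liver_enriched),
                "COLON_PROGRAM": set(t.intestine_enriched),
            }
        db = simulate_pathways(
            filtered.gene_ids, n_pathways=config.n_pathways, planted=planted, seed=seed
        )
        write_gene_sets(db, out / "pathways.gmt")
        db = filter_pathways(db, filtered.gene_ids)
        rows = []
        stable_results = []
        for i, (pid, genes) in enumerate(sorted(db.items())):
            data = pathway_feature_matrix(filtered, genes)
            k = gap_statistic_k(data, k_max=min(6, data.shape[0] - 1), seed=seed + i)
            if k < 2:
                rows.append({"pathway": pid, "k": k, "stability": np.nan, "stable": False})
                continue
            res = cluster_stability(
                data,
                k,
                sample_ids=filtered.sample_ids,
                n_replicas=config.cluster_replicas,
                conservation_threshold=config.conservation_threshold,
                seed=seed + 10_000 + i,
                pathway_id=pid,
            )
            rows.append(
                {"pathway": pid, "k": k, "stability": res.stability_fraction, "stable": res.stable}
            )
            if res.stable:
                stable_results.append(res)
        pd.DataFrame(rows).to_csv(out / "pathway_stability.tsv", sep="\t", index=False)
        record("pathway_stability.tsv", out / "pathway_stability.tsv")
        if stable_results:
            cons = consensus_assignment(stable_results, meta)
            cons.drop(columns=["block_votes"]).to_csv(out / "consensus.tsv", sep="\t", index=False)
            record("consensus.tsv", out / "consensus.tsv")

    if "connect" in stages:
        if signature is None:
            sig_path = out / "signature.json"
            if not sig_path.exists():
                raise ValidationError("missing upstream output of stage 'signature'")
            signature = SignatureSet.from_json(sig_path)
        ref, ref_truth = simulate_perturbation_reference(
            signature,
            n_compounds=config.n_compounds,
            n_reverters=config.n_reverters,
            seed=seed,
        )
        lio.write_perturbation_reference(ref, out / "reference.tsv", out / "compound_meta.tsv")
        query, dropped = validate_query(QuerySignature.from_signature(signature), ref)
        results = screen(query, ref)
        results.to_csv(out / "connectivity_scores.tsv", sep="\t", index=False, float_format="%.6g")
        hits = select_hits(results, cutoff=config.connectivity_cutoff)
        lio.write_json(
            {
                "hits": hits,
                "dropped_query_genes": dropped,
                "planted_reverters": sorted(ref_truth.reverter_compounds),
            },
            out / "hits.json",
        )
        classes = summarize_classes(hits, ref.compound_meta, results)
        classes.to_csv(out / "hit_classes.tsv", sep="\t", index=False, float_format="%.6g")
        for name in ("connectivity_scores.tsv", "hits.json", "hit_classes.tsv"):
            record(name, out / name)

    if "organoid" in stages:
        (t0, t72), matrix, otruth = simulate_organoid_experiment(seed=seed)
        rs = response_score(t0, t72)
        syn = bliss_synergy_score(matrix)
        lio.write_dose_matrix(matrix, out / "dose_matrix.tsv")
        lio.write_json(
            {
                "rs": rs.rs,
                "rs_planted": otruth.rs_effect,
                "bliss_score": syn.bliss_score,
                "bliss_classification": syn.classification,
                "bliss_planted_x100": otruth.synergy_pairs,
            },
            out / "organoid.json",
        )
        for name in ("dose_matrix.tsv", "organoid.json"):
            record(name, out / name)

    lio.write_json(manifest, out / "manifest.json")
    return manifest
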