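"""Count normalization, NB differential expression and sample embedding.

The testing model is a negative-binomial Wald test on normalized group means:
counts are library-size corrected with trimmed-mean-of-M-values (TMM)
factors, per-gene dispersions are method-of-moments estimates shrunk toward
the across-gene median, and the Wald statistic compares log2 group means with
delta-method standard errors.  DE calls use strict thresholds on |logFC| and
on the (raw or BH-adjusted) p-value; the default "paper" preset is
BH-adjusted p < 0.01 and |logFC| > 4.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, GeneSetPair, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DECallThresholds:
    """Cutoffs for calling a gene differentially expressed.

    Inequalities are strict: |logFC| must exceed ``min_abs_logfc`` and the
    selected p-value must fall below ``p_cutoff``.
    """

    min_abs_logfc: float = 4.0
    p_mode: str = "adjusted"  # "adjusted" | "raw"
    p_cutoff: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cutoff < 1.0:
            raise ValidationError("p_cutoff must lie in (0, 1)")
        if self.p_mode not in ("adjusted", "raw"):
            raise ValidationError("p_mode must be 'adjusted' or 'raw'")
        if self.min_abs_logfc <= 0:
            raise ValidationError("min_abs_logfc must be positive")


#: the printed threshold presets: own cohort, then the two public comparators
PRESETS: dict[str, DECallThresholds] = {
    "paper": DECallThresholds(4.0, "adjusted", 0.01),
    "public1": DECallThresholds(4.0, "raw", 1e-3),
    "public2": DECallThresholds(4.0, "raw", 0.01),
}


def filter_low_expression(
    counts: CountMatrix, min_count: int = 10, min_sample_fraction: float = 0.10
) -> CountMatrix:
    """Keep genes with count > ``min_count`` in at least
    ``ceil(min_sample_fraction * n_samples)`` samples."""
    x = counts.counts.to_numpy()
    n_samples = x.shape[1]
    need = math.ceil(min_sample_fraction * n_samples)
    keep = (x > min_count).sum(axis=1) >= need
    if not keep.any():
        log.warning("low-expression filter removed every gene")
    log.info("low-expression filter: %d -> %d genes", len(keep), int(keep.sum()))
    return CountMatrix(counts.counts.loc[keep])


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    do_weighting: bool = True,
) -> float:
    """Trimmed mean of M-values between one sample and the reference."""
    mask = (obs > 0) & (ref > 0)
    o = obs[mask] / lib_obs
    r = ref[mask] / lib_ref
    if o.size == 0:
        return 1.0
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    # asymptotic binomial variance of M (delta method)
    w = (lib_obs - obs[mask]) / (lib_obs * obs[mask]) + (lib_ref - ref[mask]) / (
        lib_ref * ref[mask]
    )
    n = m.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    if do_weighting:
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    else:
        f = np.mean(m[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def normalization_factors(counts: CountMatrix) -> pd.Series:
    """TMM normalization factors, scaled to geometric mean 1.

    Effective library size = column total x factor.  The reference sample is
    the one whose 75th count-fraction quantile is closest to the mean across
    samples; M-values are 30%-trimmed and A-values 5%-trimmed, with
    inverse-variance weighting.
    """
    x = counts.counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    zero = np.where(lib == 0)[0]
    if zero.size:
        raise ValidationError(
            f"all-zero sample(s): {[counts.sample_ids[j] for j in zero]}"
        )
    if x.shape[1] == 1:
        return pd.Series([1.0], index=counts.sample_ids)
    f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    if np.median(f75) < 1e-20:
        ref_j = int(np.argmax(np.sqrt(x).sum(axis=0)))
    else:
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref_j], lib[j], lib[ref_j])
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids)


def effective_library_sizes(counts: CountMatrix) -> pd.Series:
    return counts.counts.sum(axis=0) * normalization_factors(counts)


def _normalized(counts: CountMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Counts rescaled to the geometric-mean effective library size."""
    x = counts.counts.to_numpy(dtype=float)
    eff = effective_library_sizes(counts).to_numpy()
    s_bar = float(np.exp(np.mean(np.log(eff))))
    return x / eff * s_bar, eff, s_bar


def estimate_dispersion(
    counts: CountMatrix,
    groups: pd.Series | dict,
    shrink_weight: float = 0.3,
) -> pd.Series:
    """Per-gene NB dispersion phi (var = mu + phi mu^2), method of moments.

    Moments are pooled across groups with >= 2 samples on normalized counts;
    raw estimates are clipped at 0 and shrunk toward the across-gene median
    with weight ``shrink_weight``.
    """
    groups = pd.Series(groups)
    y, eff, s_bar = _normalized(counts)
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    used = 0
    sample_ids = counts.sample_ids
    for g in groups.unique():
        members = [i for i, s in enumerate(sample_ids) if groups.get(s) == g]
        if len(members) < 2:
            continue
        used += len(members)
        yg = y[:, members]
        kappa = float(np.mean(s_bar / eff[members]))
        ybar = yg.mean(axis=1)
        s2 = yg.var(axis=1, ddof=1)
        w = len(members) - 1
        num += w * (s2 - kappa * ybar)
        den += w * ybar**2
    if used == 0:
        raise ValidationError("no group has at least two samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    phi = np.clip(phi, 0.0, None)
    med = float(np.median(phi))
    phi = (1.0 - shrink_weight) * phi + shrink_weight * med
    return pd.Series(phi, index=counts.gene_ids)


def adjust_pvalues_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def test_differential_expression(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    contrast: tuple[str, str],
    dispersion: pd.Series | None = None,
    pseudo_count: float = 0.5,
    method: str = "t",
) -> pd.DataFrame:
    """Per-gene NB Wald test of tissue class A vs B (logFC = A minus B).

    Returns a DataFrame with columns ``gene_id``, ``logFC``, ``PValue`` and
    ``FDR`` (Benjamini-Hochberg).  ``method`` selects the reference
    distribution of the Wald statistic: "t" (default; Student t with
    n_A + n_B - 2 df, the finite-sample choice that keeps small-group tests
    calibrated), "wald" (asymptotic normal) or "consensus" (per-gene maximum
    of the two p-values, i.e. a gene is significant only under both
    variants).
    """
    class_a, class_b = contrast
    groups = metadata.set_index("sample_id")["tissue_class"]
    idx_a = [j for j, s in enumerate(counts.sample_ids) if groups.get(s) == class_a]
    idx_b = [j for j, s in enumerate(counts.sample_ids) if groups.get(s) == class_b]
    for name, idx in ((class_a, idx_a), (class_b, idx_b)):
        if len(idx) < 2:
            raise ValidationError(f"contrast class {name!r} has fewer than 2 samples")
    if method not in ("wald", "t", "consensus"):
        raise ValidationError("method must be 'wald', 't' or 'consensus'")

    y, eff, s_bar = _normalized(counts)
    if dispersion is None:
        sub = counts.subset_samples(
            [counts.sample_ids[j] for j in idx_a + idx_b]
        )
        dispersion = estimate_dispersion(sub, groups)
    phi = dispersion.reindex(counts.gene_ids).to_numpy()

    def group_stats(idx: list[int]) -> tuple[np.ndarray, np.ndarray]:
        mu = y[:, idx].mean(axis=1)
        inv = np.mean(s_bar / eff[idx])
        n = len(idx)
        m = mu + pseudo_count
        # var(mean of normalized counts): Poisson part m * mean(S/s_j) / n plus
        # overdispersion phi * m^2 / n
        var_mu = (m * inv + phi * m**2) / n
        var_log2 = var_mu / (m**2 * np.log(2.0) ** 2)
        return m, var_log2

    m_a, v_a = group_stats(idx_a)
    m_b, v_b = group_stats(idx_b)
    logfc = np.log2(m_a) - np.log2(m_b)
    se = np.sqrt(v_a + v_b)
    z = np.where(se > 0, logfc / se, 0.0)
    df = len(idx_a) + len(idx_b) - 2
    p_norm = 2.0 * stats.norm.sf(np.abs(z))
    p_t = 2.0 * stats.t.sf(np.abs(z), df)
    if method == "wald":
        p = p_norm
    elif method == "t":
        p = p_t
    else:
        p = np.maximum(p_norm, p_t)
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "logFC": logfc,
            "PValue": p,
            "FDR": adjust_pvalues_bh(p),
        }
    )


def call_de(table: pd.DataFrame, thresholds: DECallThresholds, contrast_label: str = "") -> GeneSetPair:
    """Call up/down genes at strict |logFC| and p cutoffs, ordered by gene id."""
    if len(table) == 0:
        raise ValidationError("DE table is empty")
    pcol = "FDR" if thresholds.p_mode == "adjusted" else "PValue"
    sig = table[pcol] < thresholds.p_cutoff
    up = table.loc[sig & (table["logFC"] > thresholds.min_abs_logfc), "gene_id"]
    down = table.loc[sig & (table["logFC"] < -thresholds.min_abs_logfc), "gene_id"]
    return GeneSetPair(tuple(sorted(up)), tuple(sorted(down)), contrast_label)


def compute_sample_embedding(
    counts: CountMatrix, top_n: int = 2000, n_dims: int = 2
) -> pd.DataFrame:
    """2-D (by default) principal-coordinate embedding of samples.

    Uses the ``top_n`` most variable genes on log2-CPM (pseudo-count 1,
    TMM-effective library sizes), centers genes, and projects samples onto the
    leading principal axes.  The sign of each axis is fixed so that its
    largest-magnitude gene loading is positive.
    """
    if counts.shape[1] < 3:
        raise ValidationError("need at least 3 samples for an embedding")
    x = counts.counts.to_numpy(dtype=float)
    eff = effective_library_sizes(counts).to_numpy()
    logcpm = np.log2(x / eff * 1e6 + 1.0)
    if top_n > logcpm.shape[0]:
        log.info("top_n=%d exceeds gene count %d; using all genes", top_n, logcpm.shape[0])
        top_n = logcpm.shape[0]
    var = logcpm.var(axis=1)
    top = np.argsort(var, kind="mergesort")[::-1][:top_n]
    z = logcpm[top] - logcpm[top].mean(axis=1, keepdims=True)
    # samples x genes SVD; coordinates = U * S
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    n_dims = min(n_dims, len(s))
    coords = u[:, :n_dims] * s[:n_dims]
    for d in range(n_dims):
        loading = vt[d]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, d] = -coords[:, d]
    return pd.DataFrame(
        coords, index=counts.sample_ids, columns=[f"dim{d + 1}" for d in range(n_dims)]
    )
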