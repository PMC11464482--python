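"""Two-group differential expression and valve-bias classification.

Counts are normalized with median-of-ratios size factors; each gene is
tested with a negative-binomial Wald test on the log2 fold change between
the flat- and round-valve groups. Gene-wise dispersions are estimated by
the method of moments and shrunk halfway toward the across-gene mean, which
stabilises the n = 3 designs typical of mantle studies. Significant genes
are classified as side-specific (the other valve is essentially silent) or
side-biased, mirroring the four-class coloring of valve-resolved MA plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import ExpressionPanel, FormatError

__all__ = [
    "DERecord",
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "classify_valve_bias",
    "classify_panel",
    "fpkm",
    "de_table",
]

BIAS_CLASSES = ("flat_specific", "flat_biased", "round_specific", "round_biased", "ns")


@dataclass
class DERecord:
    """Per-gene differential-expression result (flat over round)."""

    gene_id: str
    base_mean: float
    log2fc: float
    p: float
    padj: float = float("nan")
    mean_flat: float = float("nan")
    mean_round: float = float("nan")
    bias_class: str = "ns"


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive factor per sample).

    factor_s = median over genes g of count_gs / geometric-mean_g, taken
    over genes with all-positive counts.
    """
    if counts.shape[1] < 2:
        raise FormatError("size_factors requires at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise FormatError(
            "no gene has positive counts in every sample; cannot form the "
            "reference (pseudo-reference fallback is off)"
        )
    sub = arr[positive]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise FormatError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_moments(norm: np.ndarray, idx: np.ndarray):
    sub = norm[:, idx]
    mean = sub.mean(axis=1)
    var = sub.var(axis=1, ddof=1)
    return mean, var


def nb_wald_test(
    panel: ExpressionPanel,
    group_a: Sequence[str],
    group_b: Sequence[str],
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Negative-binomial Wald test of group A over group B, per gene.

    Counts are normalized by median-of-ratios factors. The gene-wise
    dispersion is the moment estimate ``alpha_g = max(0, (s2 - mu) / mu^2)``
    from pooled within-group variances, shrunk toward the across-gene mean
    with weight ``shrink_weight``. The Wald statistic is the log2 fold
    change (pseudo-count 0.5 on normalized group means) over its
    delta-method standard error under the NB variance ``mu + alpha mu^2``.

    Returns a DataFrame indexed by gene with columns base_mean, mean_a,
    mean_b, log2fc, se, p, padj.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise FormatError("each group needs at least 2 replicates")
    if panel.unit != "counts":
        raise FormatError("nb_wald_test requires raw counts")
    cols = list(panel.values.columns)
    use = list(group_a) + list(group_b)
    missing = [s for s in use if s not in cols]
    if missing:
        raise FormatError(f"samples not in panel: {missing}")
    sub = panel.values[use]
    sf = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    na, nb = len(group_a), len(group_b)
    ia = np.arange(na)
    ib = np.arange(na, na + nb)

    mean_a, var_a = _group_moments(norm, ia)
    mean_b, var_b = _group_moments(norm, ib)
    base_mean = norm.mean(axis=1)

    # Moment dispersion from pooled within-group variance around the grand mean
    pooled_var = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    grand = (mean_a + mean_b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(grand > 0, (pooled_var - grand) / grand**2, 0.0)
    alpha_hat = np.clip(alpha_hat, 0.0, None)
    expressed = grand > 0
    trend = alpha_hat[expressed].mean() if expressed.any() else 0.0
    alpha = shrink_weight * trend + (1.0 - shrink_weight) * alpha_hat

    log2fc = np.log2(mean_a + 0.5) - np.log2(mean_b + 0.5)
    ln2 = np.log(2.0)
    var_mean_a = (mean_a + alpha * mean_a**2) / na
    var_mean_b = (mean_b + alpha * mean_b**2) / nb
    se2 = var_mean_a / ((mean_a + 0.5) ** 2 * ln2**2) + var_mean_b / (
        (mean_b + 0.5) ** 2 * ln2**2
    )
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    # Degenerate rule: a gene with no counts anywhere carries no signal
    allzero = (mean_a == 0) & (mean_b == 0)
    p = np.where(allzero, 1.0, p)
    log2fc = np.where(allzero, 0.0, log2fc)
    p = np.clip(p, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "se": se,
            "p": p,
        },
        index=panel.values.index,
    )
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def classify_valve_bias(
    padj: float,
    log2fc: float,
    mean_flat: float,
    mean_round: float,
    floor: float = 1.0,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> str:
    """Assign one of the four valve-bias classes, or 'ns'.

    A significant gene (padj < alpha, |log2fc| >= lfc_min) is flat-sided if
    log2fc > 0, round-sided otherwise; it is *specific* when the opposite
    valve's normalized mean falls below ``floor`` and *biased* otherwise.
    """
    if not np.isfinite(padj) or padj >= alpha or abs(log2fc) < lfc_min:
        return "ns"
    if log2fc > 0:
        return "flat_specific" if mean_round < floor else "flat_biased"
    return "round_specific" if mean_flat < floor else "round_biased"


def classify_panel(
    panel: ExpressionPanel,
    floor: float = 1.0,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> list[DERecord]:
    """Run the flat-vs-round test on a mantle panel and classify every gene.

    Groups are taken from sample metadata (valve == flat vs round); flat is
    group A, so log2fc > 0 means flat-enriched.
    """
    flat = panel.select(valve="flat")
    rnd = panel.select(valve="round")
    res = nb_wald_test(panel, flat, rnd)
    records = []
    for gid, row in res.iterrows():
        rec = DERecord(
            gene_id=gid,
            base_mean=row["base_mean"],
            log2fc=row["log2fc"],
            p=row["p"],
            padj=row["padj"],
            mean_flat=row["mean_a"],
            mean_round=row["mean_b"],
        )
        rec.bias_class = classify_valve_bias(
            rec.padj, rec.log2fc, rec.mean_flat, rec.mean_round,
            floor=floor, alpha=alpha, lfc_min=lfc_min,
        )
        records.append(rec)
    return records


def de_table(records: Sequence[DERecord]) -> pd.DataFrame:
    """DERecords as a DataFrame (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "base_mean": [r.base_mean for r in records],
            "log2fc": [r.log2fc for r in records],
            "p": [r.p for r in records],
            "padj": [r.padj for r in records],
            "mean_flat": [r.mean_flat for r in records],
            "mean_round": [r.mean_round for r in records],
            "bias_class": [r.bias_class for r in records],
        }
    ).set_index("gene_id")


def fpkm(panel: ExpressionPanel, gene_lengths: pd.Series) -> ExpressionPanel:
    """Fragments per kilobase per million: count * 1e9 / (length * library).

    ``gene_lengths`` is in bp, indexed by gene id; every panel gene must be
    present with positive length.
    """
    if panel.unit != "counts":
        raise FormatError("fpkm expects raw counts")
    lengths = gene_lengths.reindex(panel.values.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:3]
        raise FormatError(f"genes missing lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise FormatError("gene lengths must be positive")
    lib = panel.values.sum(axis=0).to_numpy(dtype=float)
    if (lib == 0).any():
        raise FormatError("a sample has zero total counts")
    vals = (
        panel.values.to_numpy(dtype=float)
        * 1e9
        / (lengths.to_numpy(dtype=float)[:, None] * lib[None, :])
    )
    df = pd.DataFrame(vals, index=panel.values.index, columns=panel.values.columns)
    return ExpressionPanel(df, panel.samples, unit="FPKM")
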