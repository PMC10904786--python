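"""Pool-normalized enrichment analysis of barcode count tables.

Counts are first turned into within-sample fractions (pseudocount
stabilized), then divided by the barcode's fraction in the uninjected pool
("basemean" normalization).  Per (barcode, organ) the normalized
accumulations across mice are tested with a two-sided Wilcoxon rank-sum
test (exact permutation distribution for small tie-free samples, normal
approximation with tie and continuity correction otherwise), adjusted with
Benjamini-Hochberg within each organ, and classified as enriched /
depleted / neutral.  Organ-tropic candidates are barcodes enriched in the
organ of interest and not enriched in any off-target organ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lnpscreen.quantify import CountTable
from lnpscreen.simulate import ORGANS

__all__ = [
    "NormalizedTable",
    "normalize_within_sample",
    "normalize_to_pool",
    "build_normalized_table",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "enrichment_analysis",
    "classify_tropism",
    "heatmap_matrix",
]

CALL_ENRICHED = "enriched"
CALL_DEPLETED = "depleted"
CALL_NEUTRAL = "neutral"

DEFAULT_NAKED_IDS = ("naked",)


def normalize_within_sample(
    counts: pd.DataFrame | CountTable, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Within-sample fractions: ``(count + pc) / sum(count + pc)`` per column.

    All-zero samples are excluded with a warning.  The naked-control
    barcode, if present, stays in the denominator (it is flagged downstream,
    not removed here).
    """
    if isinstance(counts, CountTable):
        counts = counts.counts
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    zero_cols = [c for c in counts.columns if counts[c].sum() == 0]
    if zero_cols:
        warnings.warn(f"excluding all-zero samples: {zero_cols}", stacklevel=2)
        counts = counts.drop(columns=zero_cols)
    shifted = counts.astype(float) + pseudocount
    return shifted / shifted.sum(axis=0)


def normalize_to_pool(
    fractions: pd.DataFrame | pd.Series, pool_fractions: pd.Series
) -> pd.DataFrame | pd.Series:
    """Normalized accumulation: tissue fraction over pool ("basemean") fraction."""
    if (pool_fractions <= 0).any():
        raise ValueError("pool fractions must be > 0 (use a positive pseudocount)")
    if isinstance(fractions, pd.Series):
        return fractions / pool_fractions.reindex(fractions.index)
    return fractions.div(pool_fractions.reindex(fractions.index), axis=0)


@dataclass
class NormalizedTable:
    """Fractions, pool fractions, and pool-normalized accumulation with metadata.

    ``accumulation`` covers tissue samples only (columns); ``samples`` maps
    sample_id -> (mouse, organ, role); ``naked_ids`` flags the naked-control
    barcode(s), which stay in denominators but are excluded from enrichment
    records and candidate calling.
    """

    fractions: pd.DataFrame
    pool_fractions: pd.Series
    accumulation: pd.DataFrame
    samples: pd.DataFrame
    naked_ids: tuple = ()
    pool_sample_ids: tuple = ()
    pseudocount: float = 0.5

    def tissue_samples(self) -> pd.DataFrame:
        s = self.samples
        return s[(s["role"] == "tissue") & s["sample_id"].isin(self.accumulation.columns)]

    def organ_matrix(self, organ: str) -> pd.DataFrame:
        """Barcode x mouse matrix of normalized accumulation for one organ."""
        tis = self.tissue_samples()
        sel = tis[tis["organ"] == organ]
        if sel.empty:
            raise KeyError(f"no tissue samples for organ {organ!r}")
        mat = self.accumulation[list(sel["sample_id"])]
        mat.columns = list(sel["mouse"])
        return mat

    @property
    def organs(self) -> list[str]:
        present = set(self.tissue_samples()["organ"])
        ordered = [o for o in ORGANS if o in present]
        return ordered + sorted(present - set(ORGANS))


def build_normalized_table(
    counts: CountTable,
    pseudocount: float = 0.5,
    naked_ids: Sequence[str] = DEFAULT_NAKED_IDS,
) -> NormalizedTable:
    """Run both normalization steps on a CountTable.

    Pool fractions are computed from the sample(s) with role ``pool``
    (averaged when replicated).  Samples with role ``naked`` are reference
    lanes for QC and are excluded from fractions/accumulation.
    """
    samples = counts.samples
    analysis_ids = list(samples.loc[samples["role"] != "naked", "sample_id"])
    fractions = normalize_within_sample(counts.counts[analysis_ids], pseudocount)
    pool_ids = [
        s for s in samples.loc[samples["role"] == "pool", "sample_id"] if s in fractions.columns
    ]
    if not pool_ids:
        raise ValueError("no uninjected-pool sample available for normalization")
    pool_fractions = fractions[pool_ids].mean(axis=1)
    tissue_ids = [
        s for s in samples.loc[samples["role"] == "tissue", "sample_id"] if s in fractions.columns
    ]
    accumulation = normalize_to_pool(fractions[tissue_ids], pool_fractions)
    return NormalizedTable(
        fractions=fractions,
        pool_fractions=pool_fractions,
        accumulation=accumulation,
        samples=samples,
        naked_ids=tuple(i for i in naked_ids if i in counts.counts.index),
        pool_sample_ids=tuple(pool_ids),
        pseudocount=pseudocount,
    )


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation distribution when ``len(x) + len(y) <= 20`` with no
    ties; otherwise the normal approximation with tie and continuity
    correction.  Two-sided probability is twice the smaller tail, capped
    at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and len(pooled) <= 20:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    ``q_(i) = min_{j >= i} min(1, p_(j) * m / j)`` over sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def _call(log2fc: float, q: float, fc_threshold: float, q_threshold: float) -> str:
    if q <= q_threshold and log2fc >= fc_threshold:
        return CALL_ENRICHED
    if q <= q_threshold and log2fc <= -fc_threshold:
        return CALL_DEPLETED
    return CALL_NEUTRAL


def enrichment_analysis(
    table: NormalizedTable,
    comparison: str = "one_vs_rest",
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    bh_scope: str = "organ",
) -> pd.DataFrame:
    """Per-(barcode, organ) enrichment records.

    ``one_vs_rest`` (default): for barcode *b* in organ *o*, x = b's
    per-mouse normalized accumulations, y = every other barcode's per-mouse
    values in *o*.  ``vs_pool_replicates``: x = b's tissue fractions across
    mice, y = b's fractions across >= 3 uninjected-pool replicates.

    BH adjustment is applied within each organ (``bh_scope="organ"``) or
    over all records (``"global"``).  The log2 fold-change is the median
    over mice of log2 normalized accumulation.  Naked-control barcodes are
    excluded from the records.

    Returns a DataFrame with columns barcode_id, organ, log2fc, p_value,
    q_value, call.
    """
    if comparison not in ("one_vs_rest", "vs_pool_replicates"):
        raise ValueError(f"unknown comparison {comparison!r}")
    if bh_scope not in ("organ", "global"):
        raise ValueError(f"bh_scope must be 'organ' or 'global', got {bh_scope!r}")
    if comparison == "vs_pool_replicates" and len(table.pool_sample_ids) < 3:
        raise ValueError(
            f"vs_pool_replicates needs >= 3 pool replicates "
            f"(have {len(table.pool_sample_ids)}); use comparison='one_vs_rest'"
        )
    records = []
    for organ in table.organs:
        mat = table.organ_matrix(organ)
        if mat.shape[1] < 2:
            raise ValueError(f"need >= 2 mice per organ, organ {organ!r} has {mat.shape[1]}")
        barcodes = [b for b in mat.index if b not in table.naked_ids]
        values = mat.to_numpy()
        idx_of = {b: i for i, b in enumerate(mat.index)}
        for b in barcodes:
            i = idx_of[b]
            x = values[i]
            if comparison == "one_vs_rest":
                y = np.delete(values, i, axis=0).ravel()
            else:
                tis = table.tissue_samples()
                sel = tis[tis["organ"] == organ]
                x = table.fractions.loc[b, list(sel["sample_id"])].to_numpy()
                y = table.fractions.loc[b, list(table.pool_sample_ids)].to_numpy()
            records.append(
                {
                    "barcode_id": b,
                    "organ": organ,
                    "log2fc": float(np.median(np.log2(values[i]))),
                    "p_value": wilcoxon_rank_sum(x, y),
                }
            )
    df = pd.DataFrame(records)
    if bh_scope == "organ":
        df["q_value"] = np.nan
        for organ in df["organ"].unique():
            mask = df["organ"] == organ
            df.loc[mask, "q_value"] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
    else:
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    df["call"] = [
        _call(fc, q, fc_threshold, q_threshold) for fc, q in zip(df["log2fc"], df["q_value"])
    ]
    df.attrs["comparison"] = comparison
    df.attrs["bh_scope"] = bh_scope
    df.attrs["fc_threshold"] = fc_threshold
    df.attrs["q_threshold"] = q_threshold
    return df


def classify_tropism(
    records: pd.DataFrame,
    organ_of_interest: str = "lung",
    off_targets: Sequence[str] = ("liver", "spleen"),
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> list[str]:
    """Candidate barcodes: enriched in the organ of interest, not enriched off-target.

    A barcode qualifies when log2 FC >= ``fc_threshold`` and q <=
    ``q_threshold`` in ``organ_of_interest``, and in every off-target organ
    it is *not* enriched (log2 FC < threshold or q > threshold).
    """
    present = set(records["organ"])
    missing = [o for o in (organ_of_interest, *off_targets) if o not in present]
    if missing:
        raise KeyError(f"organs missing from records: {missing}")

    def enriched_in(organ: str) -> set[str]:
        sub = records[records["organ"] == organ]
        mask = (sub["log2fc"] >= fc_threshold) & (sub["q_value"] <= q_threshold)
        return set(sub.loc[mask, "barcode_id"])

    candidates = enriched_in(organ_of_interest)
    for organ in off_targets:
        candidates -= enriched_in(organ)
    order = {b: i for i, b in enumerate(records["barcode_id"].unique())}
    return sorted(candidates, key=lambda b: order[b])


def heatmap_matrix(table: NormalizedTable, row_scale: bool = False) -> pd.DataFrame:
    """Barcode x organ matrix of mouse-median normalized accumulation.

    Rows follow the count-table barcode order, columns the fixed organ
    order.  With ``row_scale`` each row is divided by its maximum, mapping
    the row max to 1.
    """
    cols = {}
    for organ in table.organs:
        cols[organ] = table.organ_matrix(organ).median(axis=1)
    mat = pd.DataFrame(cols, index=table.accumulation.index)
    if row_scale:
        mat = mat.div(mat.max(axis=1), axis=0)
    return mat
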