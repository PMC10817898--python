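"""Quality control, identifier mapping, normalization, balanced downsampling,
fold partitioning and count-thinning augmentation.

The pipeline mirrors the standard single-cell conventions: per-cell QC on
totals / detected genes / mitochondrial fraction / top-gene fraction,
Seurat-style log-normalization, and train-statistics-only standardization.
Balancing uses hierarchically readjusted weights: every occupied group at a
hierarchy level shares its parent's weight equally, so rare species or cell
classes are not drowned out by abundant ones when downsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "QCThresholds",
    "PreprocessParams",
    "compute_qc_metrics",
    "qc_filter",
    "load_mapping_table",
    "map_gene_ids",
    "lognormalize",
    "fit_standardizer",
    "apply_standardizer",
    "hierarchical_weights",
    "shannon_entropy",
    "weighted_downsample",
    "partition_folds",
    "augment_counts",
]


@dataclass
class QCThresholds:
    """Per-cell QC band. Boundaries are inclusive: the rules read
    "less than" / "greater than" strictly, so a cell exactly at a boundary
    passes."""

    min_counts: int = 5000
    max_counts: int = 50000
    min_genes: int = 1000
    max_mito_frac: float = 0.10
    max_top_gene_frac: float = 0.10

    def __post_init__(self):
        if self.min_counts >= self.max_counts:
            raise ValueError("min_counts must be < max_counts")


@dataclass
class PreprocessParams:
    """Frozen preprocessing state estimated on training data only."""

    feature_order: list
    mean: np.ndarray  # per-gene mean of log-normalized expression
    sd: np.ndarray  # per-gene SD; zero-SD genes flagged and given z = 0
    scale_factor: float = 1e4
    zero_sd_genes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def compute_qc_metrics(counts: CountMatrix, mito_genes=None, mito_prefix="mt-"):
    """Per-cell totals, genes detected, mito fraction and top-gene fraction."""
    x = counts.dense()
    if x.shape[1] == 0:
        raise ValueError("empty count matrix")
    total = x.sum(axis=0)
    detected = (x > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        top_frac = np.where(total > 0, x.max(axis=0) / np.maximum(total, 1), 0.0)
    if mito_genes is None:
        mito_genes = [g for g in counts.gene_ids if g.lower().startswith(mito_prefix.lower())]
    mito_idx = [i for i, g in enumerate(counts.gene_ids) if g in set(mito_genes)]
    if mito_idx:
        mito_frac = x[mito_idx, :].sum(axis=0) / np.maximum(total, 1)
    else:
        mito_frac = np.full(x.shape[1], np.nan)
    return pd.DataFrame(
        {
            "total_counts": total,
            "genes_detected": detected,
            "mito_frac": mito_frac,
            "top_gene_frac": top_frac,
        },
        index=counts.cell_ids,
    )


def qc_filter(counts: CountMatrix, mito_genes=None, thresholds: QCThresholds | None = None,
              mito_prefix="mt-"):
    """Return (keep_mask, metrics). A cell is kept iff its total counts,
    detected genes, mitochondrial fraction and single-gene dominance all lie
    within the inclusive QC band."""
    thresholds = thresholds or QCThresholds()
    metrics = compute_qc_metrics(counts, mito_genes=mito_genes, mito_prefix=mito_prefix)
    t = thresholds
    keep = (
        (metrics["total_counts"] >= t.min_counts)
        & (metrics["total_counts"] <= t.max_counts)
        & (metrics["genes_detected"] >= t.min_genes)
        & (metrics["top_gene_frac"] <= t.max_top_gene_frac)
    )
    if metrics["mito_frac"].isna().all():
        warnings.warn("no mitochondrial genes found; mito-fraction rule skipped")
    else:
        keep &= metrics["mito_frac"] <= t.max_mito_frac
    return keep.to_numpy(), metrics


# ---------------------------------------------------------------------------
# Identifier mapping
# ---------------------------------------------------------------------------


def load_mapping_table(path_or_df, source_col="source", target_col="target") -> pd.DataFrame:
    """Load a one-to-one orthology/identifier table; rejects any row whose
    source or target appears more than once."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(
        path_or_df, sep=None, engine="python"
    )
    df = df[[source_col, target_col]].rename(
        columns={source_col: "source", target_col: "target"}
    )
    if df["source"].duplicated().any() or df["target"].duplicated().any():
        raise ValueError("mapping table is not one-to-one")
    return df


def map_gene_ids(ids, mapping_table: pd.DataFrame):
    """Map `ids` through a validated one-to-one table.

    Returns (mapped_ids, kept_source_ids, unmapped_ids); the input order is
    preserved for genes that map.
    """
    lut = dict(zip(mapping_table["source"], mapping_table["target"]))
    mapped, kept, unmapped = [], [], []
    for g in ids:
        if g in lut:
            mapped.append(lut[g])
            kept.append(g)
        else:
            unmapped.append(g)
    if len(set(mapped)) != len(mapped):
        raise ValueError("duplicate target IDs after mapping")
    return mapped, kept, unmapped


# ---------------------------------------------------------------------------
# Normalization / standardization
# ---------------------------------------------------------------------------


def lognormalize(counts: CountMatrix, feature_order=None, scale_factor: float = 1e4):
    """Seurat-style log-normalization: y = ln(1 + scale * x / T) where T is the
    cell's total over the model's feature universe only.

    Returns (normalized genes-by-cells ndarray over feature_order, totals).
    """
    if feature_order is None:
        feature_order = counts.gene_ids
    sub = counts.subset_genes(feature_order)
    x = sub.dense().astype(float)
    totals = x.sum(axis=0)
    bad = np.flatnonzero(totals == 0)
    if bad.size:
        raise ValueError(
            "cells with zero counts over the feature universe: "
            + ", ".join(str(sub.cell_ids[i]) for i in bad[:20])
        )
    return np.log1p(scale_factor * x / totals), totals


def fit_standardizer(normalized: np.ndarray, feature_order, scale_factor: float = 1e4
                     ) -> PreprocessParams:
    """Estimate per-gene mean/SD of log-normalized expression (training data
    only; for cross-validation call this without the held-out fold)."""
    if normalized.shape[1] < 2:
        raise ValueError("need at least 2 training cells")
    mean = normalized.mean(axis=1)
    sd = normalized.std(axis=1)
    zero = sd == 0
    return PreprocessParams(
        feature_order=list(feature_order),
        mean=mean,
        sd=np.where(zero, 1.0, sd),
        scale_factor=scale_factor,
        zero_sd_genes=[g for g, z in zip(feature_order, zero) if z],
    )


def apply_standardizer(normalized: np.ndarray, params: PreprocessParams) -> np.ndarray:
    """z = (y - mean)/sd with training statistics; zero-SD genes give z = 0."""
    if normalized.shape[0] != len(params.feature_order):
        raise ValueError("matrix rows do not match the fitted feature order")
    z = (normalized - params.mean[:, None]) / params.sd[:, None]
    if params.zero_sd_genes:
        idx = [params.feature_order.index(g) for g in params.zero_sd_genes]
        z[idx, :] = 0.0
    return z


# ---------------------------------------------------------------------------
# Hierarchical balancing
# ---------------------------------------------------------------------------


def _bin_labels(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning, returning integer bin labels."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        return np.zeros(len(v), dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.searchsorted(edges, v, side="right") - 1, 0, n_bins - 1)


def hierarchical_weights(metadata: pd.DataFrame, hierarchy, leaf_cols=None,
                         n_bins=(10, 10)) -> np.ndarray:
    """Per-cell balancing weights over a label hierarchy.

    Moving root to leaf, the weight mass of each group is split equally among
    its *occupied* child groups; within the final leaf group, cells share the
    leaf's mass equally. The optional `leaf_cols` pair (a technical and a
    biological covariate, e.g. log10 total counts and target-gene PC1) is
    two-dimensionally binned and appended as the last level. Weights sum to 1.
    """
    n = len(metadata)
    levels = [metadata[c].astype(str).to_numpy() for c in hierarchy]
    if leaf_cols is not None:
        b1 = _bin_labels(metadata[leaf_cols[0]].to_numpy(), n_bins[0])
        b2 = _bin_labels(metadata[leaf_cols[1]].to_numpy(), n_bins[1])
        levels.append(np.char.add(np.char.add(b1.astype(str), "x"), b2.astype(str)))
    w = np.ones(n)
    parent = np.zeros(n, dtype=int)  # group index of the parent level
    for labels in levels:
        key = np.char.add(np.char.add(parent.astype(str), "\x1f"), labels.astype(str))
        codes, _ = pd.factorize(key)
        # occupied children per parent
        df = pd.DataFrame({"parent": parent, "child": codes})
        n_child = df.groupby("parent")["child"].transform("nunique").to_numpy()
        w /= n_child
        parent = codes
    leaf_size = pd.Series(parent).groupby(parent).transform("size").to_numpy()
    return w / leaf_size


def shannon_entropy(labels) -> float:
    """Shannon entropy of the label distribution, in nats."""
    counts = pd.Series(list(labels)).value_counts().to_numpy()
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def weighted_downsample(weights, n: int, seed: int, cell_ids=None):
    """Weighted sampling without replacement of `n` cells."""
    w = np.asarray(weights, dtype=float)
    if n > len(w):
        raise ValueError(f"cannot sample {n} from {len(w)} cells")
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(w), size=n, replace=False, p=w / w.sum())
    idx = np.sort(idx)
    if cell_ids is not None:
        return [cell_ids[i] for i in idx]
    return idx


# ---------------------------------------------------------------------------
# Fold partitioning
# ---------------------------------------------------------------------------


def partition_folds(metadata: pd.DataFrame, k: int = 5, test_fraction: float = 0.0,
                    cat_col: str | None = None, num_col: str | None = None,
                    id_col: str | None = None, seed: int = 0) -> pd.Series:
    """Grouped, balanced fold assignment.

    Every `id_col` group lands entirely in one fold (or the test split), so a
    held-out fold contains whole subclasses the model never saw. Groups are
    assigned greedily, largest first, to the bin that minimizes an imbalance
    objective combining bin-size deviation from target, `cat_col` proportion
    deviation from the global proportions, and `num_col` mean deviation.

    Returns a Series indexed like `metadata` with values 'fold1'..'foldk'
    and optionally 'test'.
    """
    n = len(metadata)
    ids = metadata[id_col].astype(str) if id_col else pd.Series(
        np.arange(n).astype(str), index=metadata.index
    )
    groups = list(ids.groupby(ids).groups.items())
    if len(groups) < 2:
        raise ValueError("cannot partition a single id group")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    groups = [groups[i] for i in order]
    groups.sort(key=lambda kv: -len(kv[1]))  # stable: largest first, seeded ties

    bins = [f"fold{i+1}" for i in range(k)] + (["test"] if test_fraction > 0 else [])
    target = {b: (1 - test_fraction) / k * n for b in bins if b != "test"}
    if test_fraction > 0:
        target["test"] = test_fraction * n

    cats = sorted(metadata[cat_col].astype(str).unique()) if cat_col else []
    global_prop = (
        metadata[cat_col].astype(str).value_counts(normalize=True) if cat_col else None
    )
    nums = metadata[num_col].to_numpy(dtype=float) if num_col else None
    global_mean = float(np.mean(nums)) if num_col else 0.0
    global_sd = float(np.std(nums)) or 1.0 if num_col else 1.0

    state = {b: {"size": 0, "cat": {c: 0 for c in cats}, "num_sum": 0.0} for b in bins}
    assignment = pd.Series(index=metadata.index, dtype=object)
    pos = {lab: i for i, lab in enumerate(metadata.index)}

    for gid, members in groups:
        g_size = len(members)
        g_cat = (
            metadata.loc[members, cat_col].astype(str).value_counts() if cat_col else None
        )
        g_num = (
            float(np.sum([nums[pos[m]] for m in members])) if num_col else 0.0
        )
        best, best_obj = None, np.inf
        for b in bins:
            s = state[b]
            new_size = s["size"] + g_size
            # proportional fill keeps bins of unequal target size comparable
            obj = new_size / max(target[b], 1.0)
            if cat_col:
                for c in cats:
                    cnt = s["cat"][c] + int(g_cat.get(c, 0))
                    obj += (cnt / new_size - global_prop.get(c, 0.0)) ** 2
            if num_col:
                mean_b = (s["num_sum"] + g_num) / new_size
                obj += ((mean_b - global_mean) / global_sd) ** 2
            if obj < best_obj:
                best, best_obj = b, obj
        s = state[best]
        s["size"] += g_size
        s["num_sum"] += g_num
        if cat_col:
            for c, cnt in (g_cat.items() if g_cat is not None else []):
                s["cat"][c] += int(cnt)
        assignment.loc[members] = best
    return assignment


# ---------------------------------------------------------------------------
# Augmentation by count thinning
# ---------------------------------------------------------------------------


def augment_counts(counts: CountMatrix, metadata: pd.DataFrame | None = None,
                   group_cols=None, target_totals=(1e3, 10 ** 3.25, 10 ** 3.5),
                   seed: int = 0):
    """Create shallow-depth companions of each cell by downsampling its reads.

    Within each group (e.g. species x subclass), cells are split evenly among
    the target totals; each cell's reads are thinned without replacement
    (multivariate hypergeometric), so the augmented total hits the target
    exactly and no gene exceeds its source count. Cells whose total is below
    their assigned target are skipped with a warning.

    Returns (augmented CountMatrix, provenance DataFrame with columns
    augmented_id, source_id, target_total).
    """
    x = counts.dense().astype(np.int64)
    totals = x.sum(axis=0)
    rng = np.random.default_rng(seed)
    n = counts.n_cells
    if metadata is not None and group_cols:
        key = metadata[list(group_cols)].astype(str).agg("|".join, axis=1).to_numpy()
    else:
        key = np.zeros(n, dtype=int)
    targets = np.empty(n)
    for g in pd.unique(key):
        idx = np.flatnonzero(key == g)
        perm = rng.permutation(idx)
        per = np.array_split(perm, len(target_totals))
        for t, chunk in zip(target_totals, per):
            targets[chunk] = t

    cols, aug_ids, prov = [], [], []
    skipped = 0
    for j in range(n):
        t = int(round(targets[j]))
        if t > totals[j]:
            skipped += 1
            continue
        thinned = rng.multivariate_hypergeometric(x[:, j], t)
        cols.append(thinned)
        aug_ids.append(f"{counts.cell_ids[j]}_aug{t}")
        prov.append((aug_ids[-1], counts.cell_ids[j], t))
    if skipped:
        warnings.warn(f"{skipped} cells skipped: assigned target exceeds cell total")
    values = np.column_stack(cols) if cols else np.zeros((counts.n_genes, 0), dtype=int)
    aug = CountMatrix(values, counts.gene_ids, aug_ids)
    provenance = pd.DataFrame(prov, columns=["augmented_id", "source_id", "target_total"])
    return aug, provenance
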