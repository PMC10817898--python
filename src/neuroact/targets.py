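"""Selection of activity-dependent target genes.

Candidate immediate-early-gene markers are the intersection of independent
stimulus-response gene lists; candidates failing cross-species identifier
mapping or a detection-rate filter are excluded. The surviving candidates are
screened for robust coexpression: PC1 loadings of the observed data are
compared against an outlier threshold built from a null PCA on per-gene
shuffled data, and the comparison is repeated over bootstrap subsamples of
cells. Genes whose loadings exceed the null threshold in at least 5% of
permutations form the final target set.

`TARGET_GENES` ships the canonical 22-gene activity-dependent set used when
scoring real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TARGET_GENES",
    "CandidateSet",
    "SelectionResult",
    "intersect_candidates",
    "detection_filter",
    "observed_pc1",
    "null_pc1",
    "mad_outlier_threshold",
    "bootstrap_select",
]

# Canonical activity-dependent target set (mouse symbols), ordered.
TARGET_GENES = (
    "Arc", "Btg2", "Coq10b", "Crem", "Dusp1", "Dusp5", "Egr1", "Egr3",
    "Fbxo33", "Fos", "Fosl2", "Gadd45g", "Gmeb2", "Grasp", "Junb", "Nr4a1",
    "Nr4a2", "Nr4a3", "Per1", "Rgs2", "Sertad1", "Tiparp",
)


@dataclass
class CandidateSet:
    genes: list
    provenance: dict  # gene -> list of source-list names containing it
    excluded: dict = field(default_factory=dict)  # gene -> reason

    def exclude(self, genes, reason: str):
        keep = [g for g in self.genes if g not in set(genes)]
        for g in genes:
            if g in self.provenance:
                self.excluded[g] = reason
        self.genes = keep
        return self


@dataclass
class SelectionResult:
    genes: list
    observed_loadings: np.ndarray
    scaling_factor: float  # var(observed PC1) / var(null PC1)
    threshold: tuple  # (low, high) from the null loadings
    pass_rate: np.ndarray  # per-gene fraction of permutations beyond threshold
    selected: list


def intersect_candidates(lists: dict | list) -> CandidateSet:
    """Genes present in every input list, with per-gene provenance."""
    if not isinstance(lists, dict):
        lists = {f"list{i+1}": lst for i, lst in enumerate(lists)}
    if len(lists) < 2 or any(len(v) == 0 for v in lists.values()):
        raise ValueError("need at least two nonempty gene lists")
    sets = {k: set(v) for k, v in lists.items()}
    common = set.intersection(*sets.values())
    if not common:
        warnings.warn("candidate intersection is empty")
    first = list(lists.values())[0]
    genes = [g for g in first if g in common]  # preserve first list's order
    prov = {g: [k for k, s in sets.items() if g in s] for g in genes}
    return CandidateSet(genes=genes, provenance=prov)


def detection_filter(counts, group_labels, min_rate: float = 0.01,
                     max_failing_groups: int = 1, expected_groups=None):
    """Exclude genes detected in < `min_rate` of cells in more than
    `max_failing_groups` of the groups (e.g. the four species-by-class
    groups). Returns (retained_genes, excluded_genes). Passing
    `expected_groups` asserts that each configured group has cells."""
    x = counts.dense()
    labels = np.asarray(group_labels)
    groups = pd.unique(labels) if expected_groups is None else list(expected_groups)
    fails = np.zeros(x.shape[0], dtype=int)
    for g in groups:
        idx = labels == g
        if idx.sum() == 0:
            raise ValueError(f"group {g!r} has no cells")
        rate = (x[:, idx] > 0).mean(axis=1)
        fails += rate < min_rate
    excluded = [g for g, f in zip(counts.gene_ids, fails) if f > max_failing_groups]
    retained = [g for g in counts.gene_ids if g not in set(excluded)]
    return retained, excluded


def _pc1(x: np.ndarray):
    """Centered PCA; x is cells x genes. Returns (loadings, pc1_variance),
    loadings sign-oriented so most are positive."""
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0):
        raise ValueError("zero-variance input")
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    loadings = vt[0]
    if (loadings > 0).sum() < (loadings < 0).sum():
        loadings = -loadings
    var = s[0] ** 2 / (x.shape[0] - 1)
    return loadings, float(var)


def observed_pc1(expr: np.ndarray):
    """PC1 loadings and variance of candidate expression (cells x genes)."""
    if expr.shape[1] < 2 or expr.shape[0] < 3:
        raise ValueError("need >= 2 genes and >= 3 cells")
    return _pc1(expr)


def null_pc1(expr: np.ndarray, seed=None, rng: np.random.Generator | None = None):
    """PC1 of a null matrix in which each gene's values are independently
    permuted across cells — covariance destroyed, margins preserved."""
    if expr.shape[1] < 2 or expr.shape[0] < 3:
        raise ValueError("need >= 2 genes and >= 3 cells")
    rng = rng or np.random.default_rng(seed)
    null = expr.copy()
    for j in range(null.shape[1]):
        rng.shuffle(null[:, j])
    return _pc1(null)


def mad_outlier_threshold(null_loadings: np.ndarray):
    """(low, high) = median(null) -/+ 3 * MAD(null); raw MAD, no consistency
    constant. A zero MAD yields a degenerate threshold and a warning."""
    null_loadings = np.asarray(null_loadings, dtype=float)
    if null_loadings.size < 3:
        raise ValueError("need at least 3 null loadings")
    med = np.median(null_loadings)
    mad = np.median(np.abs(null_loadings - med))
    if mad == 0:
        warnings.warn("MAD of null loadings is 0; threshold is degenerate")
    return med - 3 * mad, med + 3 * mad


def _outliers(obs_loadings, obs_var, null_loadings, null_var, side="positive"):
    """Scaled-loading outlier calls for one (observed, null) PCA pair.

    The variance ratio makes the unit-norm loading vectors comparable: an
    observed loading is put on the null's scale by multiplying with
    sqrt(var_obs / var_null) (loading x sqrt(variance) is the gene's
    covariance with the component). Selection targets genes with extreme
    *positive* loadings (loadings are majority-positive oriented, so this is
    invariant to a global sign flip); `side="both"` also counts the negative
    tail."""
    scaling = obs_var / null_var
    low, high = mad_outlier_threshold(null_loadings)
    scaled = obs_loadings * np.sqrt(scaling)
    out = scaled > high
    if side == "both":
        out = out | (scaled < low)
    return out, scaling, (low, high)


def bootstrap_select(expr: np.ndarray, gene_ids, n_perm: int = 1000,
                     cells_per_perm: int = 10000, pass_rate_min: float = 0.05,
                     seed: int = 0, replace: bool = False,
                     side: str = "positive") -> SelectionResult:
    """Bootstrap the observed-vs-null PC1 outlier analysis.

    Each permutation subsamples `cells_per_perm` cells (without replacement by
    default), computes observed and per-gene-shuffled null PC1, and flags
    genes whose scaled loadings fall outside the null MAD threshold. Genes
    flagged in at least `pass_rate_min` of permutations are selected.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    expr = np.asarray(expr, dtype=float)
    n_cells, n_genes = expr.shape
    if n_cells < cells_per_perm and not replace:
        cells_per_perm = n_cells
    rng = np.random.default_rng(seed)
    hits = np.zeros(n_genes)
    for _ in range(n_perm):
        idx = rng.choice(n_cells, size=cells_per_perm, replace=replace)
        sub = expr[idx]
        try:
            obs_l, obs_v = observed_pc1(sub)
            null_l, null_v = null_pc1(sub, rng=rng)
        except ValueError:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, _, _ = _outliers(obs_l, obs_v, null_l, null_v, side=side)
        hits += out
    pass_rate = hits / n_perm

    obs_l, obs_v = observed_pc1(expr)
    null_l, null_v = null_pc1(expr, rng=np.random.default_rng(seed + 1))
    _, scaling, thr = _outliers(obs_l, obs_v, null_l, null_v, side=side)
    selected = [g for g, r in zip(gene_ids, pass_rate) if r >= pass_rate_min]
    return SelectionResult(
        genes=list(gene_ids),
        observed_loadings=obs_l,
        scaling_factor=scaling,
        threshold=thr,
        pass_rate=pass_rate,
        selected=selected,
    )
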