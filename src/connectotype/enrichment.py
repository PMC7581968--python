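"""Cell-type and gene-list enrichment.

Expression-weighted cell-type enrichment (EWCE) asks whether a target gene
list's mean cell-type specificity exceeds that of random gene lists matched
on transcript length and GC content. Specificity of gene g for cell type c
is g's mean expression in c divided by the sum of its mean expression over
all cell types, so each gene's specificities sum to one.

Gene-list overlaps (e.g. with disease risk-gene lists) use an upper-tail
hypergeometric test. Annotation-set enrichment is a plain hypergeometric +
Benjamini-Hochberg procedure (labelled as such in outputs); it does not
reimplement service-specific corrections such as g:SCS.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .group_stats import bh_fdr

__all__ = [
    "build_specificity",
    "ewce",
    "hypergeom_overlap",
    "annotation_enrichment",
]


def build_specificity(cell_by_gene: pd.DataFrame, cell_labels: pd.Series) -> pd.DataFrame:
    """Genes x cell-types specificity matrix from single-cell expression.

    ``cell_by_gene`` has one row per cell, one column per gene;
    ``cell_labels`` assigns each cell to a major cell-type class. Each cell
    is first normalised to relative abundance (so the result is invariant
    to per-cell library size), expression is averaged per type, then each
    gene's row is normalised to sum to one. Genes expressed nowhere are
    dropped.
    """
    labels = cell_labels.loc[cell_by_gene.index]
    if labels.nunique() < 2:
        raise ValueError("need at least 2 cell types")
    if (cell_by_gene.to_numpy() < 0).any():
        raise ValueError("expression must be nonnegative")
    lib = cell_by_gene.sum(axis=1)
    rel = cell_by_gene.div(lib.where(lib > 0, 1.0), axis=0)
    mean_per_type = rel.groupby(labels).mean()               # types x genes
    totals = mean_per_type.sum(axis=0)
    dead = totals.index[totals == 0]
    if len(dead):
        warnings.warn(f"dropping {len(dead)} genes expressed in no cell")
        mean_per_type = mean_per_type.drop(columns=dead)
        totals = totals.drop(dead)
    spec = (mean_per_type / totals).T                        # genes x types
    spec.index.name = "gene"
    return spec


def _strata(meta: pd.DataFrame, target: list, n_bins: int = 5) -> pd.Series:
    """Joint transcript-length x GC quantile strata, merged when sparse.

    Starts from ``n_bins`` x ``n_bins`` quantile bins; if any stratum's
    candidate pool is too small to support sampling the target's count from
    it, falls back to length-only bins, then to a single stratum.
    """
    length_bin = pd.qcut(meta["length"].rank(method="first"), n_bins, labels=False)
    gc_bin = pd.qcut(meta["gc"].rank(method="first"), n_bins, labels=False)
    for strata in (
        length_bin.astype(str) + "x" + gc_bin.astype(str),
        length_bin.astype(str),
        pd.Series("all", index=meta.index),
    ):
        counts = strata.loc[target].value_counts()
        pools = strata.value_counts()
        if all(pools[s] >= 2 * k for s, k in counts.items()):
            if strata.nunique() < n_bins * n_bins:
                warnings.warn("sparse strata merged for EWCE bootstrap")
            return strata
    raise ValueError("target list too large for any stratification")


def ewce(
    target: list,
    spec: pd.DataFrame,
    meta: pd.DataFrame,
    n_boot: int = 100_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Expression-weighted cell-type enrichment with controlled bootstrap.

    The observed statistic per cell type is the mean specificity of the
    target genes. ``n_boot`` random gene lists are drawn (without
    replacement, within joint transcript-length x GC quantile strata
    matching the target's stratum counts) from the genes shared by ``spec``
    and ``meta``; the empirical upper-tail p per cell type is
    ``(1 + #{bootstrap mean >= observed}) / (1 + n_boot)``, BH-corrected
    across cell types. ``sd_from_mean`` is the observed statistic's distance
    from the bootstrap mean in bootstrap SDs.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    universe = spec.index.intersection(meta.index)
    target = list(dict.fromkeys(target))
    missing = set(target) - set(universe)
    if missing:
        raise ValueError(
            f"{len(missing)} target genes lack specificity or metadata"
        )
    meta = meta.loc[universe]
    if (meta["length"] <= 0).any() or ((meta["gc"] <= 0) | (meta["gc"] >= 1)).any():
        raise ValueError("transcript length must be > 0 and GC in (0, 1)")
    spec_arr = spec.loc[universe].to_numpy(float)
    pos = pd.Series(np.arange(len(universe)), index=universe)

    strata = _strata(meta, target)
    rng = np.random.default_rng(seed)
    n_target = len(target)
    boot_sum = np.zeros((n_boot, spec.shape[1]))
    for s, k in strata.loc[target].value_counts().items():
        pool = pos[strata.index[strata == s]].to_numpy()
        pool_spec = spec_arr[pool]                     # pool x types
        chunk = max(1, int(5e6 // max(len(pool), 1)))
        for start in range(0, n_boot, chunk):
            stop = min(start + chunk, n_boot)
            r = rng.random((stop - start, len(pool)))
            sel = np.argpartition(r, k - 1, axis=1)[:, :k]
            boot_sum[start:stop] += pool_spec[sel].sum(axis=1)
    boot = boot_sum / n_target                          # n_boot x types

    obs = spec.loc[target].mean(axis=0).to_numpy()
    ge = (boot >= obs[None, :]).sum(axis=0)
    p = (1 + ge) / (1 + n_boot)
    bmean = boot.mean(axis=0)
    bsd = boot.std(axis=0, ddof=1)
    out = pd.DataFrame({
        "observed": obs,
        "boot_mean": bmean,
        "boot_sd": bsd,
        "sd_from_mean": (obs - bmean) / bsd,
        "p": p,
        "q": bh_fdr(p),
    }, index=spec.columns)
    out.index.name = "cell_type"
    out["significant"] = out["q"] < alpha
    return out


def hypergeom_overlap(list_a, list_b, background: int) -> tuple[int, float]:
    """Upper-tail hypergeometric test of overlap between two gene lists.

    Returns the overlap count and P(X >= overlap) for X hypergeometric with
    ``background`` genes, ``|a|`` of which are in list a, drawing ``|b|``.
    """
    a, b = set(list_a), set(list_b)
    if len(a) > background or len(b) > background:
        raise ValueError("lists larger than the background universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, background, len(a), len(b)))
    return k, min(p, 1.0)


def annotation_enrichment(
    target,
    annotation_sets: dict,
    background,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric + BH enrichment of a gene list in annotation sets.

    ``background`` may be an integer universe size or the universe gene
    collection itself (sets and the target are then intersected with it).
    Per set: B = set size in the universe, b = intersection with the target,
    N = target size, upper-tail hypergeometric p, BH q across sets.
    """
    target = set(target)
    if isinstance(background, int):
        m = background
        universe = None
    else:
        universe = set(background)
        m = len(universe)
        target = target & universe
    rows = []
    for name, genes in annotation_sets.items():
        genes = set(genes) if universe is None else set(genes) & universe
        k = len(target & genes)
        p = float(stats.hypergeom.sf(k - 1, m, len(genes), len(target)))
        rows.append({"set": name, "B": len(genes), "b": k, "N": len(target),
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    out["method"] = "hypergeometric+BH"
    return out.sort_values("q")
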