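"""Cis effects of lincRNA-locus perturbations across clonal cell lines.

Clonal lines carrying a ribozyme insertion or genomic deletion at a
lincRNA locus are compared with non-targeted lines: after per-gene batch
centring in log space, the absolute difference in median expression of
each neighbouring gene (targeted vs control lines) is tested by Monte-
Carlo label permutation with an add-one p-value, Bonferroni-corrected over
all (locus, gene) tests.  A chi-squared test quantifies overlap between
up-regulated gene sets.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def center_batches(log_matrix: pd.DataFrame, batch_labels: pd.Series,
                   statistic: str = "median") -> pd.DataFrame:
    """Per gene, subtract the batch statistic and add the grand statistic.

    ``log_matrix`` is genes x lines (log-space expression); within-batch
    gene differences are preserved exactly.  ``statistic`` is "median"
    (neighbour analysis) or "mean" (PCA use-case).
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    stat = (lambda df: df.median(axis=1)) if statistic == "median" \
        else (lambda df: df.mean(axis=1))
    grand = stat(log_matrix)
    out = log_matrix.copy()
    for batch in batch_labels.unique():
        cols = batch_labels.index[batch_labels == batch]
        cols = [c for c in cols if c in out.columns]
        out[cols] = out[cols].sub(stat(out[cols]), axis=0).add(grand, axis=0)
    return out


def neighbor_genes(locus_span: tuple[str, int, int], annotations: pd.DataFrame,
                   max_distance: float = 500e3,
                   exclude: Sequence[str] = ()) -> pd.DataFrame:
    """Genes within ``max_distance`` nt (edge-to-edge) of the locus span.

    ``annotations`` is indexed by gene id with columns chrom/start/end.
    Genes overlapping the locus span are flagged ``overlaps_locus`` and
    meant to be excluded from testing (a deletion removes them); genes in
    ``exclude`` (e.g. the targeted lincRNA itself) are omitted.
    """
    chrom, lstart, lend = locus_span
    rows = []
    for gid, row in annotations.iterrows():
        if gid in exclude or row["chrom"] != chrom:
            continue
        gap = max(row["start"] - lend, lstart - row["end"], 0)
        overlaps = row["start"] < lend and lstart < row["end"]
        if gap <= max_distance:
            rows.append({"gene_id": gid, "distance": float(gap),
                         "overlaps_locus": bool(overlaps)})
    return pd.DataFrame(rows, columns=["gene_id", "distance", "overlaps_locus"])


def mc_test(values_targeted: np.ndarray, values_control: np.ndarray,
            n_perm: int = 10_000, seed: int = 0,
            rng: Optional[np.random.Generator] = None) -> tuple[float, float]:
    """Two-sided Monte-Carlo test on the difference of group medians.

    Observed statistic: |median(targeted) - median(control)|.  Labels are
    permuted preserving group sizes; p = (1 + #{permuted >= observed}) /
    (n_perm + 1), so p is never 0 and at least 1/(n_perm+1).

    Returns (observed difference, p).
    """
    t = np.asarray(values_targeted, dtype=float)
    c = np.asarray(values_control, dtype=float)
    if len(t) < 2 or len(c) < 2:
        raise ValueError("need at least 2 lines per group")
    if rng is None:
        rng = np.random.default_rng(seed)
    pooled = np.concatenate([t, c])
    nt = len(t)
    observed = abs(np.median(t) - np.median(c))
    # vectorised permutations: one argsort of uniforms per permutation
    order = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    perm = pooled[order]
    diffs = np.abs(np.median(perm[:, :nt], axis=1) - np.median(perm[:, nt:], axis=1))
    p = (1 + int((diffs >= observed).sum())) / (n_perm + 1)
    return float(observed), float(p)


def bonferroni(results: pd.DataFrame, p_col: str = "mc_p") -> pd.DataFrame:
    """Add ``p_bonf`` = min(1, m * p) with m = number of rows tested."""
    out = results.copy()
    m = len(out)
    out["p_bonf"] = np.minimum(1.0, m * out[p_col])
    return out


def neighbor_effect_screen(
    log_matrix: pd.DataFrame,
    line_meta: pd.DataFrame,
    loci: dict[str, tuple[str, int, int]],
    annotations: pd.DataFrame,
    max_distance: float = 500e3,
    n_perm: int = 10_000,
    seed: int = 0,
    batch_correct: bool = True,
) -> pd.DataFrame:
    """Full neighbour-gene screen across perturbed loci.

    ``line_meta`` is indexed by line id with columns ``group`` (control /
    deletion:<locus> / ribozyme:<locus>) and ``batch``.  Deletion and
    ribozyme lines of a locus are tested as separate groups against all
    control lines.  Tests with fewer than 2 lines per side are skipped
    (logged).  Bonferroni correction spans every performed test.
    """
    meta = line_meta.loc[[c for c in log_matrix.columns if c in line_meta.index]]
    mat = log_matrix[meta.index]
    if batch_correct:
        mat = center_batches(mat, meta["batch"], statistic="median")
    control_cols = meta.index[meta["group"] == "control"]
    rng = np.random.default_rng(seed)

    rows = []
    for locus, span in loci.items():
        nb = neighbor_genes(span, annotations, max_distance, exclude=(locus,))
        for kind in ("deletion", "ribozyme"):
            cols = meta.index[meta["group"] == f"{kind}:{locus}"]
            if len(cols) == 0:
                continue
            if len(cols) < 2 or len(control_cols) < 2:
                logger.info("locus %s (%s): <2 lines per side, skipped", locus, kind)
                continue
            for _, g in nb.iterrows():
                if g["overlaps_locus"]:
                    continue
                gid = g["gene_id"]
                if gid not in mat.index:
                    continue
                tvals = mat.loc[gid, cols].to_numpy()
                cvals = mat.loc[gid, control_cols].to_numpy()
                obs, p = mc_test(tvals, cvals, n_perm=n_perm, rng=rng)
                rows.append({"locus": locus, "kind": kind, "gene": gid,
                             "distance": g["distance"],
                             "median_targeted": float(np.median(tvals)),
                             "median_control": float(np.median(cvals)),
                             "observed_diff": obs, "mc_p": p})
    results = pd.DataFrame(rows, columns=["locus", "kind", "gene", "distance",
                                          "median_targeted", "median_control",
                                          "observed_diff", "mc_p"])
    return bonferroni(results) if len(results) else results


def upregulated_genes(counts_a: pd.Series, counts_b: pd.Series,
                      fold: float = 1.5, pseudocount: float = 8.0) -> list[str]:
    """Genes with (a + pc)/(b + pc) fold change above ``fold``."""
    fc = (counts_a + pseudocount) / (counts_b + pseudocount)
    return list(fc.index[fc > fold])


def overlap_chisq(set_a: Sequence[str], set_b: Sequence[str],
                  universe: Sequence[str],
                  yates: bool = False) -> tuple[float, float, np.ndarray]:
    """Chi-squared test of overlap between two gene sets over a universe.

    Builds the 2x2 membership table; no continuity correction by default.
    Returns (chi2, p, table); raises when either set is empty.
    """
    sa = set(set_a) & set(universe)
    sb = set(set_b) & set(universe)
    if not sa or not sb:
        raise ValueError("both sets must be non-empty within the universe")
    n = len(set(universe))
    both = len(sa & sb)
    only_a = len(sa) - both
    only_b = len(sb) - both
    neither = n - both - only_a - only_b
    table = np.array([[both, only_a], [only_b, neither]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p), table
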