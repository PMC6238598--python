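"""Single-cell expression heterogeneity and cis co-expression analysis.

Cells pass QC on capture annotation, mapped-read depth and mitochondrial
fraction; counts are normalised by median-of-ratios size factors.  The
module then provides: PCA-loading-based variable-gene selection; the
distance-to-median (DM) variability statistic — the residual of log10 CV^2
from a running median over genes of similar mean expression within
gene-length strata; jackpot scoring (90th percentile vs median across
cells); marker-panel cell-cycle assignment; a lincRNA-vs-mRNA correlation
screen with Benjamini-Hochberg control; and the cis co-expression test,
which calls a proximal gene pair co-expressed when the Euclidean distance
between the two genes' standardised expression profiles falls below the
first percentile of distances among distant ("null") same-chromosome pairs.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .decay import NormalizationModel, size_factors_median_of_ratios

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------- cell QC

def qc_cells(records: pd.DataFrame, min_mapped: float = 0.5e6,
             max_mito: float = 0.10) -> pd.DataFrame:
    """Flag cells passing QC; failure reasons recorded.

    ``records`` is indexed by cell id with columns ``mapped_reads``,
    ``mito_fraction``, optional ``capture_annotation`` (pass requires
    "ok") and optional boolean ``external_quality_flag`` (pass requires
    True).
    """
    df = records.copy()
    reasons = []
    for cell, row in df.iterrows():
        r = []
        if "capture_annotation" in df.columns and row["capture_annotation"] != "ok":
            r.append("capture")
        if "external_quality_flag" in df.columns and not bool(row["external_quality_flag"]):
            r.append("external_flag")
        if row["mapped_reads"] < min_mapped:
            r.append("mapped_reads")
        if row["mito_fraction"] > max_mito:
            r.append("mito_fraction")
        reasons.append(",".join(r))
    df["fail_reasons"] = reasons
    df["passed"] = df["fail_reasons"] == ""
    return df


def cell_size_factors(matrix: pd.DataFrame) -> NormalizationModel:
    """Median-of-ratios size factors over all genes (genes x cells)."""
    return size_factors_median_of_ratios(matrix)


def normalize_cells(matrix: pd.DataFrame) -> pd.DataFrame:
    return cell_size_factors(matrix).normalize(matrix)


# ------------------------------------------------------------ variable genes

def variable_genes_pca(matrix: pd.DataFrame, n_pcs: int = 7,
                       top_per_pc: int = 300,
                       log_transform: bool = True) -> list[str]:
    """Union of the genes with largest |loading| on each leading PC.

    ``matrix`` is normalised genes x cells; cells are observations and
    genes variables, so loadings are per-gene.  At most
    ``n_pcs * top_per_pc`` genes are returned.
    """
    X = np.log2(matrix.to_numpy(dtype=float) + 1.0).T if log_transform \
        else matrix.to_numpy(dtype=float).T
    n_pcs = min(n_pcs, min(X.shape) - 1)
    if matrix.shape[0] <= top_per_pc:
        logger.warning("fewer genes (%d) than top_per_pc (%d); returning all",
                       matrix.shape[0], top_per_pc)
        return list(matrix.index)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    pca.fit(X)
    genes = matrix.index.to_numpy()
    selected: set[str] = set()
    for pc in range(n_pcs):
        order = np.argsort(-np.abs(pca.components_[pc]))[:top_per_pc]
        selected.update(genes[order])
    return sorted(selected)


# ------------------------------------------------------------- DM statistic

def dm_statistic(matrix: pd.DataFrame, gene_lengths: Optional[pd.Series] = None,
                 n_length_bins: int = 3, window: int = 50) -> pd.DataFrame:
    """Distance-to-median expression variability per gene.

    CV^2 = var/mean^2 of normalised counts across cells; within each
    gene-length stratum (terciles by default; one stratum when no lengths
    are given) genes are ordered by mean expression and the expected
    log10 CV^2 is a centred running median of ``window`` genes; DM is the
    residual.  Scale-free: rescaling the whole matrix leaves DM unchanged.
    """
    X = matrix.to_numpy(dtype=float)
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    ok = mean > 0
    if not ok.all():
        logger.info("%d genes with zero mean excluded from DM", int((~ok).sum()))
    genes = matrix.index.to_numpy()[ok]
    mean = mean[ok]
    cv2 = var[ok] / mean ** 2
    log_cv2 = np.log10(np.where(cv2 > 0, cv2, np.nan))

    if gene_lengths is not None:
        lengths = gene_lengths.loc[genes].to_numpy(dtype=float)
        qs = np.quantile(lengths, np.linspace(0, 1, n_length_bins + 1))
        bins = np.clip(np.searchsorted(qs, lengths, side="right") - 1,
                       0, n_length_bins - 1)
    else:
        bins = np.zeros(len(genes), dtype=int)

    expected = np.full(len(genes), np.nan)
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        w = min(window, len(idx))
        if w < window:
            logger.info("length bin %d has %d genes; window shrunk", b, len(idx))
        order = idx[np.argsort(mean[idx], kind="stable")]
        vals = log_cv2[order]
        half = w // 2
        for i, gi in enumerate(order):
            lo = max(0, i - half)
            hi = min(len(order), i + half + 1)
            expected[gi] = np.nanmedian(vals[lo:hi])
    dm = log_cv2 - expected
    return pd.DataFrame({"mean_expr": mean, "cv2": cv2,
                         "expected_log_cv2": expected, "dm": dm}, index=genes)


# ------------------------------------------------------------ jackpot / cycle

def jackpot_score(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene median and 90th percentile across cells (linear interpolation)."""
    X = matrix.to_numpy(dtype=float)
    return pd.DataFrame({
        "median": np.median(X, axis=1),
        "p90": np.percentile(X, 90, axis=1),
    }, index=matrix.index)


def assign_cell_cycle(matrix: pd.DataFrame,
                      marker_panels: dict[str, Sequence[str]]) -> pd.Series:
    """Assign each cell the stage whose marker panel scores highest.

    Panel score = mean normalised expression of the panel's genes present
    in the matrix; ties (including all-zero cells) are left "unassigned".
    """
    scores = {}
    for stage, panel in marker_panels.items():
        present = [g for g in panel if g in matrix.index]
        if not present:
            raise ValueError(f"no marker genes of panel {stage!r} in matrix")
        scores[stage] = matrix.loc[present].mean(axis=0)
    sc = pd.DataFrame(scores)
    best = sc.max(axis=1)
    n_best = (sc.values == best.values[:, None]).sum(axis=1)
    labels = sc.idxmax(axis=1)
    labels[(n_best > 1) | (best <= 0)] = "unassigned"
    return labels.rename("cell_cycle_stage")


# -------------------------------------------------------- correlation screen

def correlation_screen(matrix: pd.DataFrame, lincrna_ids: Sequence[str],
                       mrna_ids: Optional[Sequence[str]] = None,
                       fdr: float = 0.05,
                       method: str = "spearman") -> pd.DataFrame:
    """Test every lincRNA x mRNA expression correlation across cells.

    Benjamini-Hochberg is applied over all tested pairs; pairs at FDR <=
    ``fdr`` are returned with their coefficient and q-value.  Spearman by
    default (robust to jackpot outliers); Pearson by flag.
    """
    lincs = [g for g in lincrna_ids if g in matrix.index]
    mrnas = [g for g in (mrna_ids if mrna_ids is not None else
                         matrix.index.difference(lincs))]
    n = matrix.shape[1]
    if n < 4:
        raise ValueError("need at least 4 cells")
    A = matrix.loc[lincs].to_numpy(dtype=float)
    B = matrix.loc[mrnas].to_numpy(dtype=float)
    if method == "spearman":
        A = np.apply_along_axis(stats.rankdata, 1, A)
        B = np.apply_along_axis(stats.rankdata, 1, B)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A ** 2).sum(axis=1))
    sb = np.sqrt((B ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A @ B.T) / np.outer(sa, sb)
    r = np.clip(r, -1, 1)
    # two-sided p from the t transform of the coefficient
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(p), 1.0, np.where(np.abs(r) >= 1, 0.0, p))

    flat_p = p.ravel()
    reject, qvals, _, _ = multipletests(flat_p, alpha=fdr, method="fdr_bh")
    li, mi = np.divmod(np.flatnonzero(reject), len(mrnas))
    out = pd.DataFrame({
        "lincRNA": np.asarray(lincs)[li],
        "gene": np.asarray(mrnas)[mi],
        "coefficient": r[li, mi],
        "p_value": p[li, mi],
        "q_value": qvals.reshape(p.shape)[li, mi],
    })
    return out.sort_values("q_value", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------- cis co-expression

def standardize_profiles(matrix: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """log2(x+1) then per-gene centring/scaling; constant genes dropped."""
    X = matrix.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        logger.info("%d constant genes dropped before distance computation",
                    int((~keep).sum()))
    Z = (X[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(Z, index=matrix.index[keep], columns=matrix.columns)


def cis_coexpression(
    matrix: pd.DataFrame,
    positions: pd.DataFrame,
    lincrna_ids: Optional[Sequence[str]] = None,
    near_min: float = 20e3,
    near_max: float = 1e6,
    null_range: tuple[float, float] = (20e6, 40e6),
    bin_size: float = 200e3,
    threshold_percentile: float = 1.0,
    min_null_pairs: int = 100,
    standardized: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Cis co-expression test against a distant-pair null.

    ``positions`` is indexed by gene id with columns ``chrom`` and ``mid``
    (genomic midpoint).  Same-chromosome pairs at genomic distance within
    ``null_range`` define the null; the co-expression threshold is the
    ``threshold_percentile``-th percentile of their expression-profile
    Euclidean distances.  Proximal pairs (``near_min`` <= d < ``near_max``;
    closer pairs are excluded as possible single transcription units) are
    flagged ``below_threshold`` and summarised as a below-threshold
    fraction per ``bin_size`` genomic-distance bin.  When ``lincrna_ids``
    is given, only pairs involving at least one lincRNA are considered.

    Returns (pairs frame, per-bin summary, threshold).
    """
    genes = [g for g in matrix.index if g in positions.index]
    Z = matrix.loc[genes] if standardized else standardize_profiles(matrix.loc[genes])
    genes = list(Z.index)
    D = squareform(pdist(Z.to_numpy(dtype=float), metric="euclidean"))
    pos = positions.loc[genes]
    chrom = pos["chrom"].to_numpy()
    mid = pos["mid"].to_numpy(dtype=float)
    is_linc = (np.isin(genes, list(lincrna_ids)) if lincrna_ids is not None
               else np.ones(len(genes), dtype=bool))

    iu, ju = np.triu_indices(len(genes), k=1)
    same = chrom[iu] == chrom[ju]
    gdist = np.abs(mid[iu] - mid[ju])
    involves_linc = is_linc[iu] | is_linc[ju]
    euclid = D[iu, ju]

    null_mask = same & involves_linc & (gdist >= null_range[0]) & (gdist < null_range[1])
    if null_mask.sum() < min_null_pairs:
        raise ValueError(f"only {int(null_mask.sum())} null pairs; "
                         f"threshold unreliable (need >= {min_null_pairs})")
    threshold = float(np.percentile(euclid[null_mask], threshold_percentile))

    prox_mask = same & involves_linc & (gdist >= near_min) & (gdist < near_max)
    pairs = pd.DataFrame({
        "gene_a": np.asarray(genes)[iu[prox_mask]],
        "gene_b": np.asarray(genes)[ju[prox_mask]],
        "genomic_distance": gdist[prox_mask],
        "euclid": euclid[prox_mask],
    })
    pairs["below_threshold"] = pairs["euclid"] < threshold

    bin_idx = (pairs["genomic_distance"] // bin_size).astype(int)
    summary = pairs.groupby(bin_idx).agg(
        n_pairs=("below_threshold", "size"),
        n_below=("below_threshold", "sum"),
    )
    summary["fraction_below"] = summary["n_below"] / summary["n_pairs"]
    summary.index = summary.index * bin_size
    summary.index.name = "bin_start"
    return pairs, summary, threshold
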