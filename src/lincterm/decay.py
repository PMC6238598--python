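"""Spike-in normalisation and two-point RNA half-life estimation.

After transcription shut-off, a gene's abundance decays as
N(t) = N(0) * 2**(-t / t_half).  With external spike-ins used to derive
per-sample size factors (median-of-ratios restricted to spike rows with
mean count above a floor), the half-life follows in closed form from the
spike-normalised median counts at t = 0 and t = 240 min:

    t_half = t * log(2) / log(med0 / med240)

The t = 30 / 90 min samples and the mock are normalised for QC but do not
enter the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NormalizationModel:
    """Per-sample median-of-ratios size factors and the reference used."""

    sample_ids: tuple[str, ...]
    size_factors: np.ndarray
    reference: pd.Series           # per-feature geometric means (usable features)
    features_used: tuple[str, ...]

    def normalize(self, counts: pd.DataFrame) -> pd.DataFrame:
        return counts / self.size_factors


@dataclass
class DecayEstimate:
    gene_id: str
    med0: float
    med240: float
    t_half: Optional[float]       # minutes; None when no decay is observed
    flag: str = "ok"


def size_factors_median_of_ratios(
    counts: pd.DataFrame,
    feature_subset: Optional[Sequence[str]] = None,
    min_mean: float = 0.0,
) -> NormalizationModel:
    """Median-of-ratios size factors (genes x samples count matrix).

    The reference is the per-feature geometric mean across samples over
    ``feature_subset`` (e.g. spike-in rows) restricted to features with
    cross-sample mean > ``min_mean``; features with any zero count are
    excluded (their log geometric mean is undefined).  Each sample's
    factor is the median of count/reference over usable features (median
    taken in log space), rescaled so the factors have unit geometric mean
    — normalising an already-normalised matrix therefore returns factors
    of exactly 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    sub = counts.loc[list(feature_subset)] if feature_subset is not None else counts
    if min_mean > 0:
        sub = sub[sub.mean(axis=1) > min_mean]
    sub = sub[(sub > 0).all(axis=1)]
    if sub.empty:
        raise ValueError("no usable reference features (all filtered or contain zeros)")
    log_geo = np.log(sub).mean(axis=1)
    log_factors = (np.log(sub) - log_geo.values[:, None]).median(axis=0)
    factors = np.exp(log_factors - log_factors.mean())
    return NormalizationModel(
        sample_ids=tuple(counts.columns),
        size_factors=factors.values.astype(float),
        reference=np.exp(log_geo),
        features_used=tuple(sub.index),
    )


def half_life(med0: float, med240: float, t: float = 240.0) -> Optional[float]:
    """Closed-form half-life in minutes; None when no decay is measurable.

    Undefined (None) when med240 >= med0 (no apparent decay) or when the
    t = 240 median is zero.
    """
    if med0 < 0 or med240 < 0:
        raise ValueError("median counts must be non-negative")
    if med240 <= 0 or med240 >= med0:
        return None
    return t * np.log(2) / np.log(med0 / med240)


def estimate_halflives(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    spike_ids: Sequence[str],
    min_spike_mean: float = 50.0,
    t: float = 240.0,
) -> pd.DataFrame:
    """Spike-normalise a decay time course and estimate per-gene half-lives.

    ``sample_meta`` is indexed by sample id with a ``timepoint`` column in
    minutes and a boolean ``is_mock`` column.  Medians at t=0 and t=240 are
    taken across replicate libraries.  Genes without measurable decay get
    ``t_half`` = NaN and a flag.  The mock drift diagnostic (mock / t=0
    median ratio) is included as a column when a mock sample exists.
    """
    model = size_factors_median_of_ratios(counts, feature_subset=spike_ids,
                                          min_mean=min_spike_mean)
    norm = model.normalize(counts)
    meta = sample_meta.loc[list(counts.columns)]
    is_mock = meta["is_mock"].astype(bool) if "is_mock" in meta else pd.Series(False, index=meta.index)
    s0 = meta.index[(meta["timepoint"] == 0) & ~is_mock]
    s240 = meta.index[(meta["timepoint"] == t) & ~is_mock]
    smock = meta.index[is_mock]
    genes = [g for g in counts.index if g not in set(spike_ids)]

    rows = []
    for g in genes:
        med0 = float(norm.loc[g, s0].median())
        med240 = float(norm.loc[g, s240].median())
        th = half_life(med0, med240, t)
        flag = "ok" if th is not None else ("no_decay" if med240 >= med0 else "zero_at_t")
        row = {"gene_id": g, "med0": med0, "med240": med240,
               "t_half": th if th is not None else np.nan, "flag": flag}
        if len(smock):
            mock_med = float(norm.loc[g, smock].median())
            row["mock_ratio"] = mock_med / med0 if med0 > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def compare_halflives(
    estimates: pd.DataFrame,
    biotypes: pd.Series,
    expression_threshold: float = 40.0,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of lincRNA vs mRNA half-lives by stratum.

    Strata: low (med0 < threshold), high (med0 > threshold), all.  Genes
    exactly at the threshold belong to neither expression stratum (strict
    inequalities).  Only genes with defined half-lives are compared.
    """
    est = estimates.dropna(subset=["t_half"])
    bt = biotypes.loc[est.index]
    strata = {
        "low": est["med0"] < expression_threshold,
        "high": est["med0"] > expression_threshold,
        "all": pd.Series(True, index=est.index),
    }
    rows = []
    for name, mask in strata.items():
        linc = est.loc[mask & (bt == "lincRNA"), "t_half"]
        mrna = est.loc[mask & (bt == "mRNA"), "t_half"]
        if len(linc) and len(mrna):
            stat, p = stats.ranksums(linc, mrna)
        else:
            stat, p = np.nan, np.nan
        rows.append({"stratum": name, "n_lincRNA": len(linc), "n_mRNA": len(mrna),
                     "median_lincRNA": float(linc.median()) if len(linc) else np.nan,
                     "median_mRNA": float(mrna.median()) if len(mrna) else np.nan,
                     "statistic": stat, "p_value": p})
    return pd.DataFrame(rows).set_index("stratum")
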