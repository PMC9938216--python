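"""SILAM-style quantification post-processing.

Implements the light/heavy-ratio analysis chain used to call dysregulated
proteins between genotypes:

1. quality filter on the peptide-fit correlation (r² > 0.5, strict);
2. peptide→protein aggregation (median of retained ratios);
3. iterative two-sided Grubbs outlier removal per protein (α = 0.01);
4. replicate-coverage filter (≥ 3 quantified samples per genotype);
5. per-replicate standardization
       Z_(P,i) = (P_i − Mean_i) / SD_i
   where Mean_i/SD_i are taken over the proteins quantified in biological
   replicate i (sample SD, n−1), by default on log2-transformed ratios;
6. the between-genotype Z-ratio
       Zratio_p = (Z_(p,dup)_Avg − Z_(p,wt)_Avg) / SD[Z_diff(p1…pn)]
   where the denominator is the standard deviation, over all quantified
   proteins, of the difference of genotype-averaged Z-scores;
7. dysregulation calls at |Z-ratio| > 1.96 (strict).

The long-format quantification table has columns
``protein_id, replicate_id, genotype, ratio, r2`` with ratio > 0 and
r2 ∈ [0, 1]; genotype labels are ``WT`` and ``DUP``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_quality",
    "aggregate_peptides",
    "grubbs_critical_value",
    "grubbs_filter",
    "grubbs_filter_table",
    "coverage_filter",
    "zscore_replicates",
    "zratio",
    "classify",
    "quantify",
    "ZScoreMatrix",
    "GrubbsResult",
]

REQUIRED_COLUMNS = ("protein_id", "replicate_id", "genotype", "ratio", "r2")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"quant table missing columns: {missing}")


def filter_quality(table: pd.DataFrame, r2_min: float = 0.5) -> pd.DataFrame:
    """Keep entries whose peptide-fit r² strictly exceeds ``r2_min``.

    Emits a warning (not an error) if nothing survives.
    """
    _check_table(table)
    if not 0.0 <= r2_min <= 1.0:
        raise ValueError("r2_min must be in [0, 1]")
    out = table[table["r2"] > r2_min].reset_index(drop=True)
    if out.empty:
        warnings.warn("quality filter removed every entry", stacklevel=2)
    return out


def aggregate_peptides(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple peptide rows per (protein, replicate) to their median ratio."""
    _check_table(table)
    return (
        table.groupby(["protein_id", "replicate_id", "genotype"], as_index=False)
        .agg(ratio=("ratio", "median"), r2=("r2", "median"))
    )


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit for sample size n at level alpha."""
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


@dataclass
class GrubbsResult:
    retained: np.ndarray
    removed: list[float]
    skipped: bool  # True when n < 3 and the test could not run


def grubbs_filter(values, alpha: float = 0.01) -> GrubbsResult:
    """Iterative two-sided Grubbs outlier removal.

    Repeatedly removes the single most extreme value while
    G = max|x − mean| / sd exceeds the critical value at ``alpha``
    (sample SD; test requires n ≥ 3 — smaller inputs are returned
    unchanged with ``skipped=True``).  A zero SD (all values equal) leaves
    the data untouched: G is undefined, so nothing can be declared extreme.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    x = np.asarray(values, dtype=float).copy()
    removed: list[float] = []
    if x.size < 3:
        return GrubbsResult(retained=x, removed=removed, skipped=True)
    while x.size >= 3:
        sd = x.std(ddof=1)
        if sd == 0.0 or not np.isfinite(sd):
            break
        dev = np.abs(x - x.mean())
        idx = int(np.argmax(dev))
        g = dev[idx] / sd
        if g > grubbs_critical_value(x.size, alpha):
            removed.append(float(x[idx]))
            x = np.delete(x, idx)
        else:
            break
    return GrubbsResult(retained=x, removed=removed, skipped=False)


def grubbs_filter_table(table: pd.DataFrame, alpha: float = 0.01,
                        log_transform: bool = True) -> pd.DataFrame:
    """Apply the Grubbs filter per protein across its replicate ratio values.

    Outliers are judged on the log2 scale when ``log_transform`` (ratios are
    multiplicative); the surviving rows are returned unchanged otherwise.
    """
    _check_table(table)
    keep_mask = np.ones(len(table), dtype=bool)
    values = np.log2(table["ratio"].to_numpy()) if log_transform else table["ratio"].to_numpy()
    for _, idx in table.groupby("protein_id").indices.items():
        res = grubbs_filter(values[idx], alpha=alpha)
        if res.removed:
            vals = values[idx]
            for r in res.removed:
                # drop the first row matching each removed value
                j = int(np.flatnonzero(np.isclose(vals, r) & keep_mask[idx])[0])
                keep_mask[idx[j]] = False
    return table[keep_mask].reset_index(drop=True)


def coverage_filter(table: pd.DataFrame, min_per_genotype: int = 3) -> pd.DataFrame:
    """Keep proteins quantified in at least ``min_per_genotype`` samples of each genotype."""
    _check_table(table)
    if min_per_genotype <= 0:
        return table
    counts = table.groupby(["protein_id", "genotype"])["ratio"].count().unstack(fill_value=0)
    genotypes = counts.columns
    ok = counts.index[(counts[genotypes] >= min_per_genotype).all(axis=1)]
    return table[table["protein_id"].isin(ok)].reset_index(drop=True)


@dataclass
class ZScoreMatrix:
    """Per-replicate standardized protein values.

    ``z`` is protein × replicate (NaN where unquantified); ``mean_i`` and
    ``sd_i`` are the per-replicate summary statistics; ``genotype`` maps
    replicate id to its genotype label.
    """

    z: pd.DataFrame
    mean_i: pd.Series
    sd_i: pd.Series
    genotype: pd.Series


def zscore_replicates(table: pd.DataFrame, log_transform: bool = True) -> ZScoreMatrix:
    """Standardize each biological replicate across its quantified proteins.

    Z_(P,i) = (P_i − Mean_i)/SD_i with Mean_i and SD_i (sample SD) computed
    over the proteins quantified in replicate i, on log2(ratio) by default.
    """
    _check_table(table)
    wide = table.pivot(index="protein_id", columns="replicate_id", values="ratio")
    if log_transform:
        wide = np.log2(wide)
    counts = wide.notna().sum(axis=0)
    too_few = counts[counts < 2]
    if len(too_few):
        raise ValueError(f"replicates with < 2 quantified proteins: {list(too_few.index)}")
    mean_i = wide.mean(axis=0)
    sd_i = wide.std(axis=0, ddof=1)
    degenerate = sd_i[sd_i == 0.0]
    if len(degenerate):
        raise ValueError(f"zero variance in replicate(s): {list(degenerate.index)}")
    z = (wide - mean_i) / sd_i
    genotype = (
        table.drop_duplicates("replicate_id").set_index("replicate_id")["genotype"]
    ).reindex(z.columns)
    return ZScoreMatrix(z=z, mean_i=mean_i, sd_i=sd_i, genotype=genotype)


def zratio(zmat: ZScoreMatrix) -> pd.DataFrame:
    """Between-genotype Z-ratio per protein.

    Averages each protein's Z-scores within genotype over its available
    replicates, takes the DUP − WT difference, and standardizes it by the
    sample SD of that difference across all proteins (shared denominator).

    Returns a DataFrame with columns ``z_wt_avg, z_dup_avg, z_ratio`` and
    the shared ``sd_zdiff`` both as a column and in ``DataFrame.attrs``.
    """
    for g in ("WT", "DUP"):
        if g not in set(zmat.genotype.dropna()):
            raise ValueError(f"genotype {g!r} absent from the z-score matrix")
    wt_cols = zmat.genotype[zmat.genotype == "WT"].index
    dup_cols = zmat.genotype[zmat.genotype == "DUP"].index
    z_wt = zmat.z[wt_cols].mean(axis=1)
    z_dup = zmat.z[dup_cols].mean(axis=1)
    diff = (z_dup - z_wt).dropna()
    if len(diff) < 2:
        raise ValueError("need >= 2 proteins with both genotype averages for SD[Z_diff]")
    sd_zdiff = float(diff.std(ddof=1))
    if sd_zdiff == 0.0:
        raise ValueError("SD of Z-differences is zero; Z-ratio undefined")
    out = pd.DataFrame(
        {
            "z_wt_avg": z_wt.loc[diff.index],
            "z_dup_avg": z_dup.loc[diff.index],
            "z_ratio": diff / sd_zdiff,
            "sd_zdiff": sd_zdiff,
        }
    )
    out.index.name = "protein_id"
    out.attrs["sd_zdiff"] = sd_zdiff
    return out


def classify(results: pd.DataFrame, threshold: float = 1.96) -> pd.DataFrame:
    """Partition proteins into up / down / null at strict |Z-ratio| > threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = results.copy()
    z = out["z_ratio"]
    out["call"] = np.where(z > threshold, "up", np.where(z < -threshold, "down", "null"))
    out.attrs["n_up"] = int((out["call"] == "up").sum())
    out.attrs["n_down"] = int((out["call"] == "down").sum())
    out.attrs["n_null"] = int((out["call"] == "null").sum())
    return out


def quantify(
    table: pd.DataFrame,
    r2_min: float = 0.5,
    grubbs_alpha: float = 0.01,
    min_per_genotype: int = 3,
    threshold: float = 1.96,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Full chain: quality → aggregation → Grubbs → coverage → Z-scores → Z-ratios → calls."""
    t = filter_quality(table, r2_min=r2_min)
    t = aggregate_peptides(t)
    t = grubbs_filter_table(t, alpha=grubbs_alpha, log_transform=log_transform)
    t = coverage_filter(t, min_per_genotype=min_per_genotype)
    zmat = zscore_replicates(t, log_transform=log_transform)
    res = zratio(zmat)
    return classify(res, threshold=threshold)
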