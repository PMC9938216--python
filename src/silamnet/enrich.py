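"""Gene-set over-representation profiling and interactome calling.

Enrichment of a query gene list in a named set is assessed with the
hypergeometric test against a declared background universe (every list is
first restricted to the background so membrane-detectability cannot
masquerade as disease association).  Results report the observed overlap k,
its chance expectation nK/N, the fold over chance and the percent increase
in enrichment over chance, with Benjamini–Hochberg adjustment across each
direction's family of sets.

Interactors of a bait are called from bait-vs-IgG spectral counts: mean
count ≥ 2-fold higher in the bait purification and a one-tailed Welch
t-test p < 0.1; proteins absent from the IgG control pass the fold
criterion outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "restrict_to_background",
    "hypergeom_enrich",
    "disease_profile",
    "call_interactome",
    "cross_dataset_overlap",
    "OverlapComparison",
]


@dataclass
class EnrichmentResult:
    """Over-representation of a query list in one gene set."""

    set_name: str
    k: int  # observed overlap
    n_query: int
    K_set: int
    N_universe: int
    expected: float  # chance expectation n_query * K_set / N_universe
    fold: float  # k / expected
    pct_enrichment: float  # (fold - 1) * 100
    p: float  # hypergeometric tail probability (upper tail unless two_sided)
    p_adj: float | None = None
    two_sided: bool = False

    def as_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "k": self.k,
            "n_query": self.n_query,
            "K_set": self.K_set,
            "N_universe": self.N_universe,
            "expected": self.expected,
            "fold": self.fold,
            "pct_enrichment": self.pct_enrichment,
            "p": self.p,
            "p_adj": self.p_adj,
        }


def restrict_to_background(sets: dict[str, Iterable[str]],
                           universe: Iterable[str]) -> GeneSetCollection:
    """Intersect every set with the background universe.

    Genes not detected in the background cannot contribute to enrichment;
    sets that become empty are kept (flagged) so downstream tables stay
    aligned with the input collection.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be nonempty")
    restricted = {name: set(s) & uni for name, s in sets.items()}
    empty = {name for name, s in restricted.items() if not s}
    return GeneSetCollection(sets=restricted, universe=uni, empty_after_restriction=empty)


def hypergeom_enrich(query: Iterable[str], target: Iterable[str],
                     universe: Iterable[str], set_name: str = "",
                     two_sided: bool = False) -> EnrichmentResult:
    """Hypergeometric over-representation of ``query`` in ``target``.

    p = P(X ≥ k) for X ~ Hypergeometric(N, K, n) (the observed overlap is
    included in the tail).  With ``two_sided`` the doubled smaller tail is
    reported, capped at 1.
    """
    uni = set(universe)
    q = set(query) & uni
    t = set(target) & uni
    if not q or not t:
        raise ValueError("query and target must be nonempty within the universe")
    N, K, n = len(uni), len(t), len(q)
    k = len(q & t)
    expected = n * K / N
    upper = float(stats.hypergeom.sf(k - 1, N, K, n))
    if two_sided:
        lower = float(stats.hypergeom.cdf(k, N, K, n))
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        p = upper
    fold = k / expected
    return EnrichmentResult(
        set_name=set_name, k=k, n_query=n, K_set=K, N_universe=N,
        expected=expected, fold=fold, pct_enrichment=(fold - 1.0) * 100.0,
        p=p, two_sided=two_sided,
    )


def disease_profile(up: Iterable[str], down: Iterable[str],
                    collections: GeneSetCollection,
                    universe: Iterable[str] | None = None,
                    two_sided: bool = False) -> pd.DataFrame:
    """Enrichment profile of up- and down-regulated lists across a collection.

    One row per (direction, set); BH adjustment is applied within each
    direction's family.  Sets empty after background restriction are
    skipped.  ``up`` and ``down`` must be disjoint.
    """
    uni = set(universe) if universe is not None else collections.universe
    up_set, down_set = set(up), set(down)
    if up_set & down_set:
        raise ValueError("up and down lists must be disjoint")
    rows: list[dict] = []
    for direction, genes in (("up", up_set), ("down", down_set)):
        fam: list[EnrichmentResult] = []
        for name, members in collections.sets.items():
            if not members or not (genes & uni):
                continue
            fam.append(hypergeom_enrich(genes, members, uni, set_name=name,
                                        two_sided=two_sided))
        if fam:
            _, p_adj, _, _ = multipletests([r.p for r in fam], method="fdr_bh")
            for r, pa in zip(fam, p_adj):
                r.p_adj = float(pa)
                rows.append({"direction": direction, **r.as_dict()})
    return pd.DataFrame(rows)


def call_interactome(counts: pd.DataFrame, fold_min: float = 2.0,
                     p_max: float = 0.1) -> pd.DataFrame:
    """Call bait interactors from spectral counts.

    ``counts`` is indexed by protein with bait replicate columns prefixed
    ``bait`` and control columns prefixed ``igg`` (≥ 2 replicates each).
    A protein is called when mean(bait) ≥ fold_min × mean(IgG) and a
    one-tailed Welch t-test (bait > IgG) gives p < p_max.  A zero IgG mean
    passes the fold criterion whenever the bait mean is positive
    (``not_in_control`` is flagged instead of an infinite fold).
    """
    bait_cols = [c for c in counts.columns if c.lower().startswith("bait")]
    igg_cols = [c for c in counts.columns if c.lower().startswith("igg")]
    if len(bait_cols) < 2 or len(igg_cols) < 2:
        raise ValueError("need >= 2 replicate columns per arm (prefixes 'bait', 'igg')")
    vals = counts[bait_cols + igg_cols].to_numpy()
    if not np.allclose(vals, np.round(vals)) or (vals < 0).any():
        raise ValueError("spectral counts must be nonnegative integers")
    bait = counts[bait_cols].to_numpy(float)
    igg = counts[igg_cols].to_numpy(float)
    mean_bait = bait.mean(axis=1)
    mean_igg = igg.mean(axis=1)
    not_in_control = mean_igg == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(not_in_control, np.inf, mean_bait / np.where(mean_igg == 0, 1, mean_igg))
    fold_ok = np.where(not_in_control, mean_bait > 0, mean_bait >= fold_min * mean_igg)

    p = np.ones(len(counts))
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # near-constant arms
        for i in range(len(counts)):
            b, g = bait[i], igg[i]
            if b.std(ddof=1) == 0.0 and g.std(ddof=1) == 0.0:
                # degenerate: no within-arm variability, decide by the means
                p[i] = 0.0 if b.mean() > g.mean() else 1.0
            else:
                p[i] = stats.ttest_ind(b, g, equal_var=False, alternative="greater").pvalue
    out = pd.DataFrame(
        {
            "mean_bait": mean_bait,
            "mean_igg": mean_igg,
            "fold": fold,
            "not_in_control": not_in_control,
            "p": p,
            "called": fold_ok & (p < p_max),
        },
        index=counts.index,
    )
    return out


@dataclass
class OverlapComparison:
    """Cross-dataset overlap with optional effect-size correlation."""

    overlap: set[str]
    enrichment: EnrichmentResult
    pearson_r: float | None = None
    r_squared: float | None = None
    p_correlation: float | None = None
    correlation_skipped: bool = False


def cross_dataset_overlap(list_a: Iterable[str], list_b: Iterable[str],
                          universe: Iterable[str],
                          effects_a: dict[str, float] | None = None,
                          effects_b: dict[str, float] | None = None,
                          exclude: Iterable[str] | None = None) -> OverlapComparison:
    """Overlap two hit lists over a shared background.

    Reports hypergeometric enrichment of the overlap and, when paired
    effect sizes are supplied, the Pearson r / R² / p of the overlapping
    genes' effects.  ``exclude`` removes a gene list (e.g. the duplicated
    locus itself, whose cis dosage effects would correlate trivially)
    before any computation.  Correlation requires ≥ 3 overlapping genes;
    smaller overlaps set ``correlation_skipped``.
    """
    uni = set(universe)
    excl = set(exclude) if exclude else set()
    a = (set(list_a) & uni) - excl
    b = (set(list_b) & uni) - excl
    enr = hypergeom_enrich(a, b, uni - excl, set_name="overlap")
    ov = a & b
    res = OverlapComparison(overlap=ov, enrichment=enr)
    if effects_a is not None and effects_b is not None:
        paired = sorted(g for g in ov if g in effects_a and g in effects_b)
        if len(paired) < 3:
            res.correlation_skipped = True
        else:
            x = np.array([effects_a[g] for g in paired])
            y = np.array([effects_b[g] for g in paired])
            r, p = stats.pearsonr(x, y)
            res.pearson_r = float(r)
            res.r_squared = float(r * r)
            res.p_correlation = float(p)
    return res
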