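"""Permutation statistics for genotype and drug comparisons.

The workflow mirrors rigorous MEA group comparison: per-plate normalization
of every feature to the plate's WT mean (per DIV), a two-sided Mann-Whitney
U test on per-well values, an empirical permutation p-value obtained by
shuffling well labels, and Fisher's method to combine per-plate p-values.

The MWU p-value uses the tie-corrected normal approximation with continuity
correction (an exact enumeration is used when both groups have at most
``exact_max_n`` wells and the data are tie-free); the same statistic is
evaluated, vectorised, for every label permutation, and the permutation
p-value is the add-one rank of the observed p within the permuted ones:
``p_perm = (1 + #{p_pi <= p_obs}) / (n_perm + 1)``.  When the number of
distinct label assignments is at most ``n_perm``, the full assignment set is
enumerated instead of sampled and the plain rank over all assignments is
reported (the identity assignment makes it strictly positive).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import FeatureTable, PlateMap


@dataclass(frozen=True)
class StatsParams:
    n_perm: int = 1000
    #: how per-well values are combined across the chosen DIVs:
    #: "well_mean" (one value per well, the default) or "pool"
    #: (every well x DIV observation enters; wells stop being the unit)
    div_combine: str = "well_mean"
    exact_max_n: int = 8

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.div_combine not in ("well_mean", "pool"):
            raise ValueError("div_combine must be 'well_mean' or 'pool'")


# ---------------------------------------------------------------------------
# Mann-Whitney machinery


def _rank_and_tie_term(pooled: np.ndarray) -> tuple[np.ndarray, float]:
    ranks = sps.rankdata(pooled)
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    return ranks, tie_term


def _asymptotic_p(u1: np.ndarray, n1: int, n2: int, tie_term: float) -> np.ndarray:
    """Two-sided tie-corrected normal-approximation p for U statistics."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values tied
        return np.ones_like(np.asarray(u1, float))
    # continuity correction as in the standard asymptotic MWU test
    z = (np.abs(np.asarray(u1, float) - mu) - 0.5) / math.sqrt(var)
    z = np.clip(z, 0.0, None)
    return np.minimum(2.0 * sps.norm.sf(z), 1.0)


def mwu_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 8) -> tuple[float, float]:
    """(U1, two-sided p) of the Mann-Whitney test of x vs y.

    Exact p when both groups have <= ``exact_max_n`` observations and no
    ties are present; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks, tie_term = _rank_and_tie_term(pooled)
    u1 = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    no_ties = tie_term == 0.0
    if x.size <= exact_max_n and y.size <= exact_max_n and no_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return u1, float(res.pvalue)
    return u1, float(_asymptotic_p(np.array([u1]), x.size, y.size, tie_term)[0])


def permuted_mwu(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    exact_max_n: int = 8,
) -> tuple[float, float, float]:
    """(U, p_raw, p_perm) of the label-permutation Mann-Whitney test.

    ``values`` holds one number per well; ``labels`` its two group labels.
    NaN values are removed with their labels; each group must keep at least
    two wells.  Deterministic given the seed.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"need exactly two groups, got {groups.tolist()}")
    is_a = labels == groups[0]
    n1, n2 = int(is_a.sum()), int((~is_a).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two non-missing wells")

    # observed values, group A first so ranks[:n1] always belongs to group A
    pooled = np.concatenate([values[is_a], values[~is_a]])
    ranks, tie_term = _rank_and_tie_term(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    no_ties = tie_term == 0.0
    exact = n1 <= exact_max_n and n2 <= exact_max_n and no_ties

    # p for an arbitrary rank-subset sum, matching mwu_p's method choice
    def p_from_ranksum(r1: np.ndarray) -> np.ndarray:
        u1 = np.asarray(r1, float) - n1 * (n1 + 1) / 2.0
        if exact:
            dist = _exact_u_sf_table(n1, n2)
            u1i = np.rint(u1).astype(int)
            u_hi = np.maximum(u1i, n1 * n2 - u1i)
            return np.minimum(2.0 * dist[u_hi], 1.0)
        return _asymptotic_p(u1, n1, n2, tie_term)

    p_raw = float(p_from_ranksum(np.array([ranks[:n1].sum()]))[0])

    n = n1 + n2
    n_assign = math.comb(n, n1)
    if n_assign <= n_perm:
        idx = np.array(list(itertools.combinations(range(n), n1)))
        r1 = ranks[idx].sum(axis=1)
        p_all = p_from_ranksum(r1)
        p_perm = float(np.sum(p_all <= p_raw * (1 + 1e-12)) / n_assign)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perm = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
        r1 = ranks[perm].sum(axis=1)
        p_all = p_from_ranksum(r1)
        p_perm = float((1 + np.sum(p_all <= p_raw * (1 + 1e-12))) / (n_perm + 1))
    return u_obs, p_raw, p_perm


_EXACT_SF_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _exact_u_sf_table(n1: int, n2: int) -> np.ndarray:
    """P(U >= u) for the tie-free null distribution of U1, u = 0..n1*n2.

    Built by enumerating every rank subset; only used for small groups
    (both sizes <= ``exact_max_n``), where the enumeration is tiny.
    """
    key = (n1, n2)
    if key in _EXACT_SF_CACHE:
        return _EXACT_SF_CACHE[key]
    n = n1 + n2
    subsets = np.array(list(itertools.combinations(range(1, n + 1), n1)))
    u = subsets.sum(axis=1) - n1 * (n1 + 1) // 2
    counts = np.bincount(u, minlength=n1 * n2 + 1).astype(float)
    probs = counts / counts.sum()
    sf = np.cumsum(probs[::-1])[::-1]
    _EXACT_SF_CACHE[key] = sf
    return sf


def fisher_combine(pvalues) -> float:
    """Fisher's method: -2 sum(ln p) vs chi-square with 2k df (upper tail)."""
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.sum(np.log(p))
    return float(sps.chi2.sf(x, 2 * p.size))


# ---------------------------------------------------------------------------
# Table-level operations


def normalize_to_wt(table: FeatureTable, pmap: PlateMap) -> FeatureTable:
    """Divide every value by the mean over WT wells of its (plate, DIV).

    After normalization the WT mean is exactly 1 per (plate, DIV, feature).
    A WT mean of zero, or a (plate, DIV) with no non-missing WT value, sets
    the normalized values to missing with a warning.
    """
    geno = pmap.genotype_series()
    df = table.data.copy()
    wells = df.index.get_level_values("well")
    is_wt = geno.reindex(wells).to_numpy() == "WT"
    out = df.copy()
    for (plate, div), sub in df.groupby(level=["plate", "div"]):
        mask = (df.index.get_level_values("plate") == plate) & (
            df.index.get_level_values("div") == div
        )
        wt_mask = mask & is_wt
        for feat in df.columns:
            wt_vals = df.loc[wt_mask, feat]
            m = wt_vals.mean(skipna=True)
            if pd.isna(m) or m == 0:
                warnings.warn(
                    f"plate {plate} DIV {div} feature {feat}: WT mean missing or zero; "
                    "normalized values set missing",
                    stacklevel=2,
                )
                out.loc[mask, feat] = np.nan
            else:
                out.loc[mask, feat] = df.loc[mask, feat] / m
    return FeatureTable(data=out, normalized=True)


def combine_divs(
    table: FeatureTable, divs: list[int] | None = None, mode: str = "well_mean"
) -> pd.DataFrame:
    """Collapse a feature table over DIVs to one row per (plate, well).

    ``well_mean`` (default) averages each well's values across the selected
    DIVs, keeping the well as the independent unit; ``pool`` keeps every
    (well, DIV) observation as a separate row.
    """
    df = table.data
    if divs is not None:
        df = df[df.index.get_level_values("div").isin(divs)]
    if mode == "pool":
        return df.reset_index().drop(columns="div")
    if mode != "well_mean":
        raise ValueError("mode must be 'well_mean' or 'pool'")
    return df.groupby(level=["plate", "well"]).mean().reset_index()


def genotype_comparison(
    table: FeatureTable,
    pmap: PlateMap,
    divs: list[int] | None = None,
    features: list[str] | None = None,
    params: StatsParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature permuted MWU of WT vs K78R wells of one plate.

    Returns a frame with feature, n per group, U, p_raw, p_perm and the
    direction of the effect (mean of mutant minus mean of WT values).
    """
    if params is None:
        params = StatsParams()
    per_well = combine_divs(table, divs, mode=params.div_combine)
    geno = pmap.genotype_series()
    labels = geno.reindex(per_well["well"]).to_numpy()
    if features is None:
        features = [c for c in per_well.columns if c not in ("plate", "well")]
    rows = []
    rng = np.random.default_rng(seed)
    for feat in features:
        values = per_well[feat].to_numpy(float)
        keep = ~np.isnan(values)
        lab = labels[keep]
        u, p_raw, p_perm = permuted_mwu(
            values[keep], lab, n_perm=params.n_perm, seed=rng, exact_max_n=params.exact_max_n
        )
        mut = values[keep][lab == "K78R"]
        wt = values[keep][lab == "WT"]
        rows.append(
            {
                "feature": feat,
                "n_wt": int((lab == "WT").sum()),
                "n_mut": int((lab == "K78R").sum()),
                "U": u,
                "p_raw": p_raw,
                "p_perm": p_perm,
                "direction": float(np.mean(mut) - np.mean(wt)),
            }
        )
    return pd.DataFrame(rows)


def drug_ratio(baseline: FeatureTable, drug: FeatureTable) -> FeatureTable:
    """Per-well, per-feature ratio drug/baseline (baseline condition = 1).

    Wells present in only one table are an error; a baseline of zero makes
    the ratio missing.
    """
    b = baseline.data
    d = drug.data
    if not b.index.equals(d.index):
        only_b = b.index.difference(d.index).tolist()
        only_d = d.index.difference(b.index).tolist()
        raise ValueError(
            f"tables cover different wells: baseline-only {only_b[:4]}, drug-only {only_d[:4]}"
        )
    denom = b.replace(0, np.nan)
    return FeatureTable(data=d / denom, normalized=baseline.normalized)


def compare_drug_response(
    ratios: FeatureTable,
    pmap: PlateMap,
    features: list[str] | None = None,
    params: StatsParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Permuted MWU per feature on drug/baseline ratios, Bonferroni-adjusted.

    ``p_adjusted = min(1, p_perm x number of features tested)``, with the
    multiplier equal to the number of features actually tested in this call.
    """
    out = genotype_comparison(ratios, pmap, features=features, params=params, seed=seed)
    k = len(out)
    out["p_adjusted"] = np.minimum(1.0, out["p_perm"] * k)
    return out
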