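"""Fertility comparisons across karyotype categories.

Males and females from a two-race hybrid colony fall into five
categories: the parental races (CHBU, CHHN), F1 hybrids, and backcross
offspring grouped by diploid number (BC.23 = hybrid karyotype,
BC.24 = restored parental karyotype).  Chain-of-fifteen carriers (F1 and
BC.23) are the group of interest.

Inference is deliberately design-based rather than model-based: sibling
structure (several animals per parent pair) is respected by permuting or
resampling whole families.  Contrast effects are covariate-adjusted
category mean differences from an ordinary least-squares fit; their null
distribution comes from permuting category labels across family clusters,
with a max-T step-down standing in for parametric multiple-comparison
adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("CHBU", "CHHN", "F1", "BC.23", "BC.24")
CHAIN_CARRIER_CATEGORIES = frozenset({"F1", "BC.23"})

#: The standard contrast family: each category against the backcross race,
#: plus the two chain-carrier groups against each other.
CONTRASTS = (
    ("CHBU", "CHHN"),
    ("F1", "CHHN"),
    ("BC.23", "CHHN"),
    ("BC.24", "CHHN"),
    ("BC.23", "F1"),
)


class FertilityError(ValueError):
    """Raised for invalid analysis inputs (empty groups, single clusters)."""


# -- sperm counting ----------------------------------------------------------


def sperm_count_from_hemocytometer(
    sperm_seen: float,
    n_squares: int = 10,
    square_area_mm2: float = 0.04,
    depth_mm: float = 0.1,
    dilution_ml: float = 2.0,
) -> float:
    """Total sperm in one cauda epididymis from a haemocytometer count.

    The count over ``n_squares`` chamber squares is divided by the counted
    volume (area × depth, in ml) and multiplied by the dilution volume.
    With the default geometry (ten 0.04 mm² squares, 0.1 mm depth, 2 ml),
    340 sperm seen gives 1.7e7.  When no sperm are visible the whole 9 mm²
    chamber is scanned (``n_squares=1, square_area_mm2=9.0``).
    """
    if n_squares <= 0 or square_area_mm2 <= 0 or depth_mm <= 0 or dilution_ml <= 0:
        raise FertilityError("hemocytometer geometry must be positive")
    if sperm_seen < 0:
        raise FertilityError("sperm_seen must be nonnegative")
    volume_ml = n_squares * square_area_mm2 * depth_mm / 1000.0  # mm^3 -> ml
    return sperm_seen / volume_ml * dilution_ml


def average_chambers(counts: Iterable[float]) -> float:
    """Mean of replicate chamber estimates for one male."""
    counts = list(counts)
    if not counts:
        raise FertilityError("no chamber estimates supplied")
    return float(np.mean(counts))


# -- sperm presence (Fisher's exact test) ------------------------------------


@dataclass(frozen=True)
class FisherExactResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def sperm_presence_table(records: pd.DataFrame) -> tuple[tuple[int, int], tuple[int, int]]:
    """2×2 table of sperm presence by expected chain carriage."""
    carriers = records["category"].isin(CHAIN_CARRIER_CATEGORIES)
    has_sperm = records["sperm_count"] > 0
    if carriers.sum() == 0 or (~carriers).sum() == 0:
        raise FertilityError("both carrier and non-carrier males are required")
    return (
        (int((carriers & has_sperm).sum()), int((carriers & ~has_sperm).sum())),
        (int((~carriers & has_sperm).sum()), int((~carriers & ~has_sperm).sum())),
    )


def sperm_presence_test(records: pd.DataFrame) -> FisherExactResult:
    """Two-sided Fisher's exact test: sperm presence in chain carriers
    (F1, BC.23) versus the sperm-producing categories (CHBU, CHHN, BC.24)."""
    table = sperm_presence_table(records)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return FisherExactResult(table=table, odds_ratio=float(odds), p_value=float(p))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for an arbitrary 2×2 count table."""
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# -- cluster permutation machinery -------------------------------------------


class ClusteredComparisonResults:
    """Contrast estimates with raw and max-T-adjusted permutation p-values."""

    def __init__(self, contrasts, effects, p_raw, p_adj, n_permutations, response):
        self.contrasts = list(contrasts)
        self.effects = dict(zip(self.contrasts, effects))
        self.pvalues = dict(zip(self.contrasts, p_raw))
        self.pvalues_adjusted = dict(zip(self.contrasts, p_adj))
        self.n_permutations = n_permutations
        self.response = response

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b) in self.contrasts:
            rows.append(
                {
                    "contrast": f"{a}-{b}",
                    "estimate": self.effects[(a, b)],
                    "p_perm": self.pvalues[(a, b)],
                    "p_adjusted": self.pvalues_adjusted[(a, b)],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        header = (
            f"Cluster-permutation contrasts for {self.response} "
            f"({self.n_permutations} permutations, max-T adjustment)"
        )
        return header + "\n" + self.to_frame().to_string(index=False)


class ClusteredComparison:
    """Covariate-adjusted category contrasts with family-level permutation.

    Parameters
    ----------
    data : records with one row per animal.
    response : response column (e.g. ``"testis_mass"``).
    category : categorical column; clusters must be nested within it.
    cluster : family identifier (parent pair) permuted as a unit.
    covariate : optional numeric covariate (e.g. body mass); effects are
        category coefficient differences from an OLS fit including it.
    log10_response : analyse the response on the common-log scale
        (positive values required), as is conventional for sperm counts.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        category: str = "category",
        cluster: str = "parent_pair_id",
        covariate: str | None = None,
        contrasts: Sequence[tuple[str, str]] = CONTRASTS,
        log10_response: bool = False,
    ):
        df = data.dropna(subset=[response]).copy()
        if log10_response:
            if (df[response] <= 0).any():
                raise FertilityError(
                    "log10 response requires strictly positive values; "
                    "exclude zero-sperm categories first"
                )
            df[response] = np.log10(df[response])
        self.data = df
        self.response = response
        self.category = category
        self.cluster = cluster
        self.covariate = covariate
        present = set(df[category].unique())
        self.contrasts = [c for c in contrasts if c[0] in present and c[1] in present]
        if not self.contrasts:
            raise FertilityError("no requested contrast has both categories present")
        # clusters must be nested in categories and replicated
        nested = df.groupby(cluster)[category].nunique()
        if (nested > 1).any():
            bad = nested[nested > 1].index.tolist()
            raise FertilityError(f"clusters span multiple categories: {bad}")
        per_cat = df.drop_duplicates([cluster])[category].value_counts()
        singles = per_cat[per_cat < 2].index.tolist()
        if singles:
            raise FertilityError(
                f"categories with a single cluster: {singles}; "
                "pool these families or drop the category"
            )

    # internal: design pieces that do not change under permutation
    def _prepare(self):
        df = self.data
        cats = sorted(df[self.category].unique())
        cat_code = {c: i for i, c in enumerate(cats)}
        clusters = df[self.cluster].to_numpy()
        uniq_clusters, cluster_idx = np.unique(clusters, return_inverse=True)
        cluster_cat = np.array(
            [
                cat_code[df[self.category].iloc[np.flatnonzero(cluster_idx == j)[0]]]
                for j in range(len(uniq_clusters))
            ]
        )
        y = df[self.response].to_numpy(float)
        x = (
            df[self.covariate].to_numpy(float)
            if self.covariate is not None
            else None
        )
        return cats, cat_code, cluster_idx, cluster_cat, y, x

    @staticmethod
    def _effects(y, row_cat, n_cats, x, contrast_codes):
        """Category coefficients from OLS of y on dummies (+ covariate)."""
        n = len(y)
        cols = [np.ones(n)]
        for c in range(1, n_cats):
            cols.append((row_cat == c).astype(float))
        if x is not None:
            cols.append(x)
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        coef = np.zeros(n_cats)
        coef[1:] = beta[1:n_cats]
        return np.array([coef[a] - coef[b] for a, b in contrast_codes])

    def fit(
        self, n_permutations: int = 999, seed: int = 0
    ) -> ClusteredComparisonResults:
        cats, cat_code, cluster_idx, cluster_cat, y, x = self._prepare()
        n_cats = len(cats)
        contrast_codes = [(cat_code[a], cat_code[b]) for a, b in self.contrasts]
        obs = self._effects(y, cluster_cat[cluster_idx], n_cats, x, contrast_codes)
        rng = np.random.default_rng(seed)
        B = n_permutations
        perm = np.empty((B, len(obs)))
        for b in range(B):
            shuffled = rng.permutation(cluster_cat)
            perm[b] = self._effects(
                y, shuffled[cluster_idx], n_cats, x, contrast_codes
            )
        if B > 0:
            exceed = (np.abs(perm) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)
            p_raw = (1.0 + exceed) / (1.0 + B)
            sd = perm.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, np.inf)
            t_obs = np.abs(obs) / sd
            t_perm_max = (np.abs(perm) / sd[None, :]).max(axis=1)
            p_adj = np.array(
                [
                    (1.0 + (t_perm_max >= t - 1e-12).sum()) / (1.0 + B)
                    for t in t_obs
                ]
            )
        else:  # identity permutation only
            p_raw = np.ones(len(obs))
            p_adj = np.ones(len(obs))
        return ClusteredComparisonResults(
            self.contrasts, obs, p_raw, p_adj, B, self.response
        )


def clustered_group_compare(
    records: pd.DataFrame,
    response: str,
    covariate: str | None = "body_mass",
    cluster: str = "parent_pair_id",
    contrasts: Sequence[tuple[str, str]] = CONTRASTS,
    n_permutations: int = 999,
    seed: int = 0,
    log10_response: bool = False,
) -> ClusteredComparisonResults:
    """Functional wrapper over :class:`ClusteredComparison`."""
    model = ClusteredComparison(
        records,
        response,
        cluster=cluster,
        covariate=covariate,
        contrasts=contrasts,
        log10_response=log10_response,
    )
    return model.fit(n_permutations=n_permutations, seed=seed)


def litter_size_compare(
    records: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]] = CONTRASTS,
    n_permutations: int = 999,
    seed: int = 0,
) -> ClusteredComparisonResults:
    """First-litter-size contrasts among females that reproduced."""
    reproduced = records[records["first_litter_size"].fillna(0) >= 1]
    model = ClusteredComparison(
        reproduced,
        "first_litter_size",
        covariate=None,
        contrasts=contrasts,
    )
    return model.fit(n_permutations=n_permutations, seed=seed)


# -- scars and timing --------------------------------------------------------


def scar_excess_summary(records: pd.DataFrame) -> dict:
    """Per-category summary of implantation scars versus total offspring.

    A scar excess (scars > offspring) indicates post-implantation loss;
    a deficit is biologically impossible and flags an undercount.
    """
    df = records.dropna(subset=["scar_count"]).copy()
    df["excess"] = df["scar_count"] - df["total_offspring"]
    per_cat = (
        df.groupby("category")
        .agg(
            n=("excess", "size"),
            n_excess=("excess", lambda e: int((e > 0).sum())),
            mean_excess=("excess", "mean"),
        )
        .reset_index()
    )
    per_cat["fraction_excess"] = per_cat["n_excess"] / per_cat["n"]
    n = len(df)
    return {
        "n_examined": n,
        "n_excess": int((df["excess"] > 0).sum()),
        "fraction_excess": float((df["excess"] > 0).mean()) if n else math.nan,
        "n_undercount_flagged": int((df["excess"] < 0).sum()),
        "per_category": per_cat,
        "excess": df[["female_id", "category", "excess"]].reset_index(drop=True),
    }


def weeks_to_first_litter_test(
    records: pd.DataFrame, category_a: str, category_b: str
) -> tuple[float, float]:
    """Exact Wilcoxon-Mann-Whitney rank-sum test on weeks to first litter.

    Returns (W, p) where W is the rank-sum statistic for ``category_a``.
    """
    df = records.dropna(subset=["weeks_to_first_litter"])
    a = df.loc[df["category"] == category_a, "weeks_to_first_litter"].to_numpy(float)
    b = df.loc[df["category"] == category_b, "weeks_to_first_litter"].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise FertilityError("both categories need observations")
    method = "exact" if (len(a) < 25 and len(b) < 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def plot_scars_vs_offspring(records: pd.DataFrame, ax=None):
    """Scatter of total offspring vs uterine scars, diagonal = no loss."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = records.dropna(subset=["scar_count"])
    for cat, sub in df.groupby("category"):
        ax.scatter(sub["total_offspring"], sub["scar_count"], label=str(cat), alpha=0.7)
    lim = max(df["scar_count"].max(), df["total_offspring"].max(), 1)
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("total offspring")
    ax.set_ylabel("uterine scars")
    ax.legend()
    return ax
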