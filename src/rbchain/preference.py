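"""Two-choice female mate-preference analysis.

Each trial places one female between two caged males — one of each race,
CHHN and CHBU — behind mesh, and records the time she spends within
nose distance of each mesh over a 30-minute scoring window.  The
preference index is

    P = t_CHHN / (t_CHHN + t_CHBU),

analysed on the logit scale.  The per-race null test asks whether mean
logit P differs from zero (no preference); the covariate model regresses
logit P on female race and the centred/scaled between-male differences
(body mass, age, time at mesh, each CHHN − CHBU), with inference by
cluster bootstrap over male pairs since pairs are reused across trials.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_TRIAL_DURATION = 1800.0  # seconds

#: Δ-covariates: between-male differences, CHHN − CHBU.
DELTA_COVARIATES = ("delta_body_mass", "delta_age", "delta_male_time")


class PreferenceError(ValueError):
    """Raised for invalid trial data."""


class CollinearityWarning(UserWarning):
    """Emitted when the covariate design is ill-conditioned."""


def preference_index(t_chhn: float, t_chbu: float) -> float:
    """P = time at CHHN mesh / total mesh time; NaN if both times are zero."""
    if t_chhn < 0 or t_chbu < 0:
        raise PreferenceError("mesh times must be nonnegative")
    total = t_chhn + t_chbu
    if total == 0:
        return math.nan
    return t_chhn / total


def default_epsilon(trial_duration: float = DEFAULT_TRIAL_DURATION) -> float:
    """Boundary clamp: half of one time-resolution unit (1 s) as a fraction."""
    return 1.0 / (2.0 * trial_duration)


def logit_transform(
    p: float | np.ndarray,
    epsilon: float | None = None,
    trial_duration: float = DEFAULT_TRIAL_DURATION,
):
    """log(p/(1−p)) with boundary values clamped into (ε, 1−ε)."""
    if epsilon is None:
        epsilon = default_epsilon(trial_duration)
    p = np.clip(np.asarray(p, dtype=float), epsilon, 1.0 - epsilon)
    out = np.log(p / (1.0 - p))
    return float(out) if out.ndim == 0 else out


def trial_preferences(trials: pd.DataFrame, epsilon: float | None = None) -> pd.DataFrame:
    """Attach P and logit P per trial; drop trials with no mesh time.

    Returns a copy with ``preference_p`` and ``logit_p`` columns; trials
    where the female never approached either mesh are excluded (flagged
    in the ``n_excluded`` attribute of the returned frame's attrs).
    """
    df = trials.copy()
    total = df["t_CHHN"] + df["t_CHBU"]
    df["preference_p"] = np.where(total > 0, df["t_CHHN"] / total, np.nan)
    n_excluded = int(df["preference_p"].isna().sum())
    df = df.dropna(subset=["preference_p"]).copy()
    duration = (
        float(df["trial_duration"].iloc[0])
        if "trial_duration" in df and len(df)
        else DEFAULT_TRIAL_DURATION
    )
    df["logit_p"] = logit_transform(
        df["preference_p"].to_numpy(), epsilon, trial_duration=duration
    )
    df.attrs["n_excluded"] = n_excluded
    return df


# -- per-race null test ------------------------------------------------------


@dataclass(frozen=True)
class NullPreferenceResult:
    race: str
    n_trials: int
    mean_logit: float
    t_stat: float
    p_value: float


def null_preference_test(
    trials: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    epsilon: float | None = None,
) -> dict[str, NullPreferenceResult]:
    """Per-race test of mean logit P = 0 with male-pair cluster bootstrap.

    Positive statistics indicate time spent toward the CHHN male.
    """
    df = trial_preferences(trials, epsilon)
    rng = np.random.default_rng(seed)
    out: dict[str, NullPreferenceResult] = {}
    for race, sub in df.groupby("female_race"):
        if len(sub) < 3:
            raise PreferenceError(f"race {race}: fewer than 3 usable trials")
        y = sub["logit_p"].to_numpy(float)
        pairs = sub["male_pair_id"].to_numpy()
        uniq = np.unique(pairs)
        groups = [y[pairs == u] for u in uniq]
        mean = float(y.mean())
        sd = y.std(ddof=1)
        t = mean / (sd / math.sqrt(len(y))) if sd > 0 else 0.0
        if sd == 0:
            p = 1.0
        else:
            boot_means = np.empty(n_boot)
            m = len(groups)
            for b in range(n_boot):
                take = rng.integers(0, m, size=m)
                boot_means[b] = np.concatenate([groups[i] for i in take]).mean()
            centred = boot_means - mean  # null distribution of the mean
            p = float(
                (1.0 + (np.abs(centred) >= abs(mean)).sum()) / (1.0 + n_boot)
            )
        out[str(race)] = NullPreferenceResult(
            race=str(race), n_trials=len(sub), mean_logit=mean, t_stat=float(t),
            p_value=p,
        )
    return out


# -- covariate model ---------------------------------------------------------


def standardize(values: np.ndarray) -> np.ndarray:
    """Centre and scale to unit variance (sample SD); constant columns -> 0."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        return values - values.mean()
    return (values - values.mean()) / sd


class PreferenceResults:
    """OLS coefficients for logit P with cluster-bootstrap uncertainty."""

    def __init__(self, names, params, boot, ci_level, n_boot, n_trials, n_pairs):
        self.names = list(names)
        self.params = dict(zip(self.names, params))
        self.boot_params = boot  # (n_boot, k)
        self.ci_level = ci_level
        self.n_boot = n_boot
        self.n_trials = n_trials
        self.n_pairs = n_pairs
        alpha = (1.0 - ci_level) / 2.0
        self.bse = dict(zip(self.names, boot.std(axis=0, ddof=1)))
        lo = np.quantile(boot, alpha, axis=0)
        hi = np.quantile(boot, 1.0 - alpha, axis=0)
        self.ci = {n: (float(l), float(h)) for n, l, h in zip(self.names, lo, hi)}
        signs = (boot <= 0).mean(axis=0)
        p = 2.0 * np.minimum(signs, 1.0 - signs)
        p = np.clip(p, 1.0 / (n_boot + 1.0), 1.0)
        self.pvalues = dict(zip(self.names, p))

    def conf_int(self) -> dict[str, tuple[float, float]]:
        return self.ci

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.names:
            lo, hi = self.ci[n]
            rows.append(
                {
                    "term": n,
                    "estimate": self.params[n],
                    "boot_se": self.bse[n],
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "p_boot": self.pvalues[n],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = (
            f"Preference covariate model: logit P on {self.n_trials} trials, "
            f"{self.n_pairs} male pairs, {self.n_boot} cluster-bootstrap draws, "
            f"{self.ci_level:.0%} CIs"
        )
        return head + "\n" + self.to_frame().to_string(index=False)


class PreferenceModel:
    """Linear model of logit P on female race and standardised Δ covariates.

    Design: intercept (CHHN female baseline), CHBU-female indicator, the
    three standardised between-male differences, and a side indicator
    (CHHN male on the right).  Uncertainty by resampling male pairs with
    replacement, which respects the reuse of pairs across trials.
    """

    _COND_LIMIT = 1e8

    def __init__(self, trials: pd.DataFrame, epsilon: float | None = None):
        df = trial_preferences(trials, epsilon)
        missing = [c for c in DELTA_COVARIATES if c not in df.columns]
        if missing:
            raise PreferenceError(f"missing covariate columns: {missing}")
        self.data = df
        y = df["logit_p"].to_numpy(float)
        cols = [np.ones(len(df))]
        names = ["intercept(CHHN)"]
        cols.append((df["female_race"] == "CHBU").to_numpy(float))
        names.append("female_race[CHBU]")
        for cov in DELTA_COVARIATES:
            cols.append(standardize(df[cov].to_numpy(float)))
            names.append(cov)
        if "side_of_CHHN" in df.columns:
            cols.append((df["side_of_CHHN"] == "right").to_numpy(float))
            names.append("side[CHHN right]")
        X = np.column_stack(cols)
        cond = np.linalg.cond(X)
        if cond > self._COND_LIMIT:
            warnings.warn(
                f"design condition number {cond:.2e}: covariates are "
                "collinear; coefficients are not separately identified",
                CollinearityWarning,
                stacklevel=2,
            )
        self.X, self.y, self.names = X, y, names
        self.pairs = df["male_pair_id"].to_numpy()

    @staticmethod
    def _ols(X, y):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta

    def fit(
        self, n_boot: int = 1000, ci_level: float = 0.99, seed: int = 0
    ) -> PreferenceResults:
        params = self._ols(self.X, self.y)
        uniq = np.unique(self.pairs)
        idx_by_pair = [np.flatnonzero(self.pairs == u) for u in uniq]
        m = len(uniq)
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, self.X.shape[1]))
        for b in range(n_boot):
            take = rng.integers(0, m, size=m)
            rows = np.concatenate([idx_by_pair[i] for i in take])
            boot[b] = self._ols(self.X[rows], self.y[rows])
        return PreferenceResults(
            self.names,
            params,
            boot,
            ci_level=ci_level,
            n_boot=n_boot,
            n_trials=len(self.y),
            n_pairs=m,
        )


def covariate_model(
    trials: pd.DataFrame,
    n_boot: int = 1000,
    ci_level: float = 0.99,
    seed: int = 0,
) -> PreferenceResults:
    """Functional wrapper over :class:`PreferenceModel`."""
    return PreferenceModel(trials).fit(n_boot=n_boot, ci_level=ci_level, seed=seed)


def plot_preference(trials: pd.DataFrame, ax=None):
    """Per-race strip plot of preference indices around the 0.5 line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = trial_preferences(trials)
    races = sorted(df["female_race"].unique())
    rng = np.random.default_rng(0)
    for i, race in enumerate(races):
        p = df.loc[df["female_race"] == race, "preference_p"]
        x = i + rng.uniform(-0.12, 0.12, size=len(p))
        ax.scatter(x, p, alpha=0.6)
    ax.axhline(0.5, ls="--", c="k", lw=1)
    ax.set_xticks(range(len(races)), races)
    ax.set_ylabel("P (time fraction near CHHN male)")
    ax.set_xlabel("female race")
    return ax
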