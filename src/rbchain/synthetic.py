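"""Synthetic colony, fertility and preference data.

The generator emulates the statistical structure of a two-race hybrid
breeding colony — per-category organ masses and sperm counts with a
body-mass covariate and sibling clusters, per-category litter-size and
implantation-scar distributions, and 30-minute two-male preference
trials with male-pair reuse — so every analysis stage can be exercised
end to end without animal data.  Default location/spread parameters are
the published category summaries for the CHBU/CHHN system; sample sizes
default to the study's.  See docs/methods.md for what the generator
deliberately does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .karyotype import Karyotype
from .meiosis import configurations_from_cross
from .races import BUILTIN, get_race
from .segregation import (
    SegregationModel,
    backcross_karyotype_distribution,
    enumerate_balanced_gametes,
    simulate_breeding,
)

# -- defaults ----------------------------------------------------------------

#: per-category (mean, sd) male summaries; sperm on the absolute scale.
MALE_STATS = {
    "CHHN": dict(n=23, body_mass=(25.0, 1.9), sperm=(17_019e3, 5_074e3),
                 testis=(93.22, 9.75), epididymis=(28.24, 3.93),
                 sv_cg=(91.23, 22.87), preputial=(47.39, 16.64)),
    "CHBU": dict(n=24, body_mass=(22.1, 3.0), sperm=(12_935e3, 3_594e3),
                 testis=(84.77, 12.11), epididymis=(25.04, 4.40),
                 sv_cg=(65.60, 19.46), preputial=(36.12, 21.45)),
    "F1": dict(n=42, body_mass=(23.7, 3.0), sperm=(0.0, 0.0),
               testis=(34.56, 6.59), epididymis=(16.27, 2.25),
               sv_cg=(78.64, 15.65), preputial=(54.22, 23.11)),
    "BC.23": dict(n=6, body_mass=(26.3, 1.3), sperm=(0.0, 0.0),
                  testis=(30.95, 3.33), epididymis=(17.02, 0.61),
                  sv_cg=(99.10, 9.49), preputial=(43.8, 10.35)),
    "BC.24": dict(n=15, body_mass=(23.6, 2.4), sperm=(15_247e3, 5_018e3),
                  testis=(90.91, 10.79), epididymis=(28.43, 3.99),
                  sv_cg=(88.28, 25.19), preputial=(48.84, 28.64)),
}

#: organ-mass slope on body mass, mg per g.
BODY_MASS_SLOPES = {"testis": 1.5, "epididymis": 0.5, "sv_cg": 4.0, "preputial": 2.0}

#: per-category female parameters: sample size, first-litter (mean, sd) and
#: admissible range, weeks to first litter, mean parametric scar excess.
FEMALE_STATS = {
    "CHHN": dict(n=12, litter=(6.3, 1.5), litter_range=(1, 12),
                 weeks=(3.5, 0.8), scar_excess=0.0),
    "CHBU": dict(n=12, litter=(6.1, 1.4), litter_range=(1, 12),
                 weeks=(3.5, 0.8), scar_excess=0.0),
    "F1": dict(n=31, litter=(1.1, 0.3), litter_range=(1, 3),
               weeks=(8.0, 5.0), scar_excess=6.0),
    "BC.23": dict(n=4, litter=(1.8, 1.0), litter_range=(1, 4),
                  weeks=(8.5, 2.1), scar_excess=4.0),
    "BC.24": dict(n=8, litter=(7.5, 0.9), litter_range=(1, 12),
                  weeks=(3.5, 0.8), scar_excess=0.3),
}

PREFERENCE_DEFAULTS = dict(
    n_females={"CHBU": 30, "CHHN": 28},
    n_male_pairs=36,
    n_pairs_reused=22,        # pairs used once with a female of each race
    trial_duration=1800.0,
    mesh_fraction=(0.345, 0.119),  # total mesh time as fraction of the trial
    race_intercepts={"CHHN": -0.07, "CHBU": 0.31},  # logit scale
    effects={"delta_body_mass": 0.0, "delta_age": -0.24, "delta_male_time": 0.18},
    covariate_scales={"delta_body_mass": 3.0, "delta_age": 20.0,
                      "delta_male_time": 120.0},
    side_effect=0.0,
    pair_re_sd=0.25,
    resid_sd=0.7,
    pre_epoch_mean=60.0,      # neutral-zone epoch before scoring starts, s
)


class GeneratorError(ValueError):
    """Raised for invalid generator configurations or crossing schemes."""


@dataclass
class GeneratorConfig:
    """All tunable generator parameters with study-scale defaults."""

    male_stats: dict = field(default_factory=lambda: {k: dict(v) for k, v in MALE_STATS.items()})
    body_mass_slopes: dict = field(default_factory=lambda: dict(BODY_MASS_SLOPES))
    female_stats: dict = field(default_factory=lambda: {k: dict(v) for k, v in FEMALE_STATS.items()})
    f1_reproduce_prob: float = 0.48
    nonreproducer_scar_prob: float = 0.3
    nonreproducer_scar_mean: float = 4.0
    scar_undercount_prob: float = 0.0
    siblings_per_pair: int = 2
    segregation: SegregationModel = field(default_factory=SegregationModel)
    breeding_cycles: int = 5
    weeks_per_cycle: float = 4.0
    preference: dict = field(default_factory=lambda: {
        k: (dict(v) if isinstance(v, dict) else v)
        for k, v in PREFERENCE_DEFAULTS.items()
    })

    def __post_init__(self) -> None:
        if not 0.0 <= self.f1_reproduce_prob <= 1.0:
            raise GeneratorError("f1_reproduce_prob outside [0, 1]")
        for cat, st in self.male_stats.items():
            for key in ("body_mass", "sperm", "testis", "epididymis", "sv_cg", "preputial"):
                if st[key][1] < 0:
                    raise GeneratorError(f"negative SD for {cat}/{key}")


def _pair_ids(category: str, n: int, per_pair: int) -> list[str]:
    return [f"{category}-p{i // per_pair:03d}" for i in range(n)]


def _lognormal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Log-normal draws moment-matched to (mean, sd) on the natural scale."""
    if mean <= 0:
        return np.zeros(size)
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def gen_male_fertility(
    config: GeneratorConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-male fertility records across the five karyotype categories.

    Sperm counts are log-normal in the fertile categories and exactly
    zero for chain carriers (F1, BC.23); organ masses co-vary positively
    with body mass; siblings share a ``parent_pair_id``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    frames = []
    for cat, st in config.male_stats.items():
        n = st["n"]
        body = rng.normal(*st["body_mass"], size=n)
        row = {
            "male_id": [f"{cat}-m{i:03d}" for i in range(n)],
            "category": cat,
            "parent_pair_id": _pair_ids(cat, n, config.siblings_per_pair),
            "body_mass": body,
        }
        if cat in ("F1", "BC.23"):
            row["sperm_count"] = np.zeros(n)
        else:
            row["sperm_count"] = _lognormal(rng, *st["sperm"], n)
        for organ, col in (("testis", "testis_mass"), ("epididymis", "epididymis_mass"),
                           ("sv_cg", "sv_cg_mass"), ("preputial", "preputial_mass")):
            mean, sd = st[organ]
            slope = config.body_mass_slopes[organ]
            resid_sd = np.sqrt(
                max(sd**2 - (slope * st["body_mass"][1]) ** 2, (0.3 * sd) ** 2)
            )
            vals = mean + slope * (body - st["body_mass"][0]) + rng.normal(0, resid_sd, n)
            row[col] = np.maximum(vals, 0.05 * mean if mean else 0.1)
        row["age_days"] = np.round(rng.normal(63, 3, size=n))
        frames.append(pd.DataFrame(row))
    return pd.concat(frames, ignore_index=True)


def _draw_litters(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Discretised normal litter sizes, truncated to [lo, hi]."""
    raw = np.round(rng.normal(mean, sd, size=size))
    return np.clip(raw, lo, hi).astype(int)


def gen_female_fertility(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    use_segregation: bool = False,
) -> pd.DataFrame:
    """Per-female breeding outcomes (first litter, total offspring, scars).

    Parametric mode draws category litter-size distributions directly;
    with ``use_segregation=True`` the chain-carrier categories (F1,
    BC.23) are driven mechanistically through
    :func:`rbchain.segregation.simulate_breeding` instead.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    frames = []
    for cat, st in config.female_stats.items():
        n = st["n"]
        pair_ids = _pair_ids(cat, n, config.siblings_per_pair)
        ids = [f"{cat}-f{i:03d}" for i in range(n)]
        if use_segregation and cat in ("F1", "BC.23"):
            frames.append(_mechanistic_females(config, cat, n, ids, pair_ids, rng))
            continue
        reproduces = (
            rng.random(n) < config.f1_reproduce_prob
            if cat == "F1"
            else np.ones(n, dtype=bool)
        )
        lo, hi = st["litter_range"]
        litter = np.where(
            reproduces, _draw_litters(rng, *st["litter"], lo, hi, n), 0
        )
        weeks = np.where(
            reproduces, np.maximum(rng.normal(*st["weeks"], size=n), 1.0), np.nan
        )
        total = litter.copy()
        excess = rng.poisson(st["scar_excess"], size=n)
        scars = total + excess
        # some non-reproducing chain carriers still implant and lose embryos
        if cat in ("F1", "BC.23"):
            lost = (~reproduces) & (rng.random(n) < config.nonreproducer_scar_prob)
            scars = np.where(
                lost, rng.poisson(config.nonreproducer_scar_mean, size=n), scars
            )
        if config.scar_undercount_prob > 0:
            under = rng.random(n) < config.scar_undercount_prob
            scars = np.maximum(scars - under.astype(int), 0)
        frames.append(
            pd.DataFrame(
                {
                    "female_id": ids,
                    "category": cat,
                    "parent_pair_id": pair_ids,
                    "first_litter_size": litter,
                    "weeks_to_first_litter": weeks,
                    "total_offspring": total,
                    "scar_count": scars,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _mechanistic_females(config, cat, n, ids, pair_ids, rng) -> pd.DataFrame:
    """Chain-carrier females simulated through the segregation model."""
    configs = configurations_from_cross(get_race("CHBU"), get_race("CHHN"), "XX")
    records = simulate_breeding(
        configs,
        get_race("CHHN"),
        config.segregation,
        n_females=n,
        cycles_per_female=config.breeding_cycles,
        category=cat,
        seed=rng,
    )
    per = records.groupby("female_id", sort=True)
    first_litter = []
    weeks = []
    for _, sub in per:
        hit = sub.loc[sub["litter_size"] > 0, ["cycle", "litter_size"]]
        if len(hit):
            first_litter.append(int(hit.iloc[0]["litter_size"]))
            weeks.append(float(hit.iloc[0]["cycle"]) * config.weeks_per_cycle)
        else:
            first_litter.append(0)
            weeks.append(np.nan)
    total = per["litter_size"].sum().to_numpy()
    scars = per["scars"].sum().to_numpy()
    return pd.DataFrame(
        {
            "female_id": ids,
            "category": cat,
            "parent_pair_id": pair_ids,
            "first_litter_size": first_litter,
            "weeks_to_first_litter": weeks,
            "total_offspring": total,
            "scar_count": scars,
        }
    )


TRIAL_COLUMNS = [
    "female_id", "female_race", "male_pair_id", "side_of_CHHN",
    "t_CHHN", "t_CHBU", "trial_duration",
    "delta_body_mass", "delta_age", "delta_male_time", "pre_epoch_s",
]


def gen_preference_trials(
    config: GeneratorConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Two-male choice trials with male-pair reuse and side randomisation.

    A reused pair is tested once with a female of each race, so the
    cluster structure the analysis must respect is actually present.
    The ``pre_epoch_s`` column is the pre-scoring neutral-zone epoch;
    mesh times are measured after it and analyses must ignore it.
    """
    config = config or GeneratorConfig()
    p = config.preference
    rng = np.random.default_rng(seed)
    n_by_race = dict(p["n_females"])
    races = sorted(n_by_race)
    total_trials = sum(n_by_race.values())
    if total_trials == 0:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    n_pairs = p["n_male_pairs"]
    reused = min(p["n_pairs_reused"], n_pairs)
    # pair-level latent quantities
    scales = p["covariate_scales"]
    pair_z = {
        name: rng.normal(size=n_pairs) for name in ("delta_body_mass", "delta_age")
    }
    pair_re = rng.normal(0.0, p["pair_re_sd"], size=n_pairs)
    # assignment: reused pairs get one trial per race; singles fill the rest
    assignments: list[tuple[int, str]] = []
    for j in range(reused):
        for race in races:
            assignments.append((j, race))
    leftovers: list[str] = []
    for race in races:
        used = min(reused, n_by_race[race])
        leftovers += [race] * (n_by_race[race] - used)
    next_pair = reused
    for race in leftovers:
        assignments.append((next_pair % max(n_pairs, 1), race))
        next_pair += 1
    assignments = assignments[:total_trials]
    rows = []
    counter = {r: 0 for r in races}
    for pair_idx, race in assignments:
        z_time = rng.normal()
        z = {
            "delta_body_mass": pair_z["delta_body_mass"][pair_idx],
            "delta_age": pair_z["delta_age"][pair_idx],
            "delta_male_time": z_time,
        }
        side = "right" if rng.random() < 0.5 else "left"
        logit_p = (
            p["race_intercepts"][race]
            + sum(p["effects"][k] * z[k] for k in z)
            + p["side_effect"] * (side == "right")
            + pair_re[pair_idx]
            + rng.normal(0.0, p["resid_sd"])
        )
        prob = float(expit(logit_p))
        frac = float(np.clip(rng.normal(*p["mesh_fraction"]), 0.02, 0.95))
        total_mesh = frac * p["trial_duration"]
        i = counter[race]
        counter[race] += 1
        rows.append(
            {
                "female_id": f"{race}-q{i:03d}",
                "female_race": race,
                "male_pair_id": f"pair{pair_idx:03d}",
                "side_of_CHHN": side,
                "t_CHHN": round(prob * total_mesh, 1),
                "t_CHBU": round((1.0 - prob) * total_mesh, 1),
                "trial_duration": p["trial_duration"],
                "delta_body_mass": z["delta_body_mass"] * scales["delta_body_mass"],
                "delta_age": z["delta_age"] * scales["delta_age"],
                "delta_male_time": z["delta_male_time"] * scales["delta_male_time"],
                "pre_epoch_s": round(float(rng.exponential(p["pre_epoch_mean"])), 1),
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# -- colony simulation -------------------------------------------------------

DEFAULT_SCHEME = (
    ("P", "CHBU", "CHHN"),
    ("BC1", "P", "CHHN"),
    ("BC2", "BC1", "CHHN"),
    ("BC3", "BC2", "CHHN"),
)


def _validate_scheme(scheme) -> None:
    defined: set[str] = set()
    for name, mother, father in scheme:
        if name in BUILTIN:
            raise GeneratorError(f"generation name {name!r} shadows a race")
        if name in defined:
            raise GeneratorError(f"duplicate generation name {name!r}")
        for src in (mother, father):
            if src not in BUILTIN and src not in defined:
                raise GeneratorError(
                    f"cross {name!r} references {src!r} before it is defined "
                    "(scheme must be acyclic and forward-defined)"
                )
        defined.add(name)


def gen_colony(
    config: GeneratorConfig | None = None,
    scheme=DEFAULT_SCHEME,
    n_mothers=(14, 31, 10, 2),
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate a crossing scheme with karyotype transmission.

    Each scheme entry is ``(name, mother_source, father_source)``: the
    father source is a race, the mother source a race or an earlier
    generation.  A generation source supplies its chain-carrier
    (hybrid-karyotype) daughters for backcrossing; carrier gamete classes
    come from the founder-race configuration via alternate segregation.
    Returns ``animals``, ``crosses`` and a per-generation
    ``karyotype_counts`` table of expected vs observed diploid numbers.
    """
    config = config or GeneratorConfig()
    _validate_scheme(scheme)
    rng = np.random.default_rng(seed)
    first_name, first_mother, first_father = scheme[0]
    if first_mother not in BUILTIN:
        raise GeneratorError("the first cross must be between races")
    founder_mother, founder_father = get_race(first_mother), get_race(first_father)
    hybrid_colony = founder_mother.fusions != founder_father.fusions
    carrier_configs = (
        configurations_from_cross(founder_mother, founder_father, "XX")
        if hybrid_colony
        else None
    )
    animals: list[dict] = []
    crosses: list[dict] = []
    counts: list[dict] = []
    generations: set[str] = set()
    aid = 0
    for (name, mother_src, father_src), n_m in zip(scheme, n_mothers):
        if father_src not in BUILTIN:
            raise GeneratorError("father source must be a race")
        father = get_race(father_src)
        if mother_src in BUILTIN:
            dist = {
                get_race(mother_src).haploid_count() + father.haploid_count(): 1.0
            }
            reproduce_p, litter_key = 1.0, "CHHN"
        elif carrier_configs is not None:
            gametes = enumerate_balanced_gametes(carrier_configs)
            dist = backcross_karyotype_distribution(gametes, father)
            reproduce_p, litter_key = config.f1_reproduce_prob, "F1"
        else:  # within-race colony: daughters are homozygous race females
            dist = {father.diploid_number: 1.0}
            reproduce_p, litter_key = 1.0, "CHHN"
        litter_mean, litter_sd = config.female_stats[litter_key]["litter"]
        lo, hi = config.female_stats[litter_key]["litter_range"]
        two_ns = np.array(sorted(dist))
        weights = np.array([dist[t] for t in two_ns])
        offspring_2n: list[int] = []
        for m in range(n_m):
            if rng.random() >= reproduce_p:
                continue
            litter = int(_draw_litters(rng, litter_mean, litter_sd, lo, hi, 1)[0])
            crosses.append({"cross": name, "mother_index": m, "litter_size": litter})
            for _ in range(litter):
                two_n = int(rng.choice(two_ns, p=weights))
                sex = "XY" if rng.random() < 0.5 else "XX"
                animals.append(
                    {
                        "animal_id": f"a{aid:05d}",
                        "generation": name,
                        "sex": sex,
                        "diploid_number": two_n,
                        "category": _category_for(two_n, name, father, hybrid_colony),
                    }
                )
                offspring_2n.append(two_n)
                aid += 1
        for t in two_ns:
            counts.append(
                {
                    "generation": name,
                    "diploid_number": int(t),
                    "expected_fraction": float(dist[t]),
                    "observed": int(sum(o == t for o in offspring_2n)),
                }
            )
        generations.add(name)
    return {
        "animals": pd.DataFrame(animals),
        "crosses": pd.DataFrame(crosses),
        "karyotype_counts": pd.DataFrame(counts),
    }


def _category_for(
    two_n: int, generation: str, father: Karyotype, hybrid_colony: bool
) -> str:
    if not hybrid_colony:
        return father.name
    if generation == "P":
        return "F1"
    return "BC.23" if two_n != father.diploid_number else f"BC.{two_n}"
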