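"""Gamete segregation, backcross karyotype prediction and breeding simulation.

Balanced gametes arise from **alternate segregation**: a chain or ring
sends its alternating members to opposite poles, each bivalent sends one
homolog, so every autosomal arm ends up exactly once in the gamete.  A
hybrid with *m* multivalents therefore produces at most ``2**m``
karyotypically distinct balanced gamete classes — exactly two when a
single chain is present, as in the CHBU×CHHN F1.

Unbalanced (nondisjoined) gametes produce monosomic or trisomic zygotes
after fertilisation.  Monosomics die before implantation and leave no
trace; trisomics usually implant and die later, leaving a visible uterine
scar.  A live birth also leaves a scar, so the per-female excess of scars
over offspring measures post-implantation loss and carries the signal of
the nondisjunction rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from collections import Counter
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .karyotype import ALL_ARMS, Karyotype, Metacentric
from .meiosis import (
    BIVALENT,
    CHAIN,
    RING,
    ChromosomeCopy,
    MeioticConfigurationSet,
    MeiosisError,
    configurations_from_cross,
)

Content = object  # Metacentric | int | str


class SegregationError(ValueError):
    """Raised for impossible segregation inputs (odd rings, unbalanced sets)."""


@dataclass(frozen=True)
class GameteClass:
    """A karyotypically distinct balanced gamete: a haploid chromosome set."""

    chromosomes: frozenset

    @property
    def haploid_count(self) -> int:
        return len(self.chromosomes)

    @property
    def sex_chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(c for c in self.chromosomes if isinstance(c, str)))

    @property
    def n_metacentrics(self) -> int:
        return sum(1 for c in self.chromosomes if isinstance(c, Metacentric))

    def arm_counts(self) -> Counter:
        counts: Counter = Counter()
        for c in self.chromosomes:
            if isinstance(c, Metacentric):
                counts.update(c.arms)
            elif isinstance(c, int):
                counts[c] += 1
        return counts

    @property
    def is_balanced(self) -> bool:
        counts = self.arm_counts()
        return (
            set(counts) == set(ALL_ARMS)
            and all(v == 1 for v in counts.values())
            and len(self.sex_chromosomes) == 1
        )

    def autosome_contents(self) -> frozenset:
        return frozenset(c for c in self.chromosomes if not isinstance(c, str))

    def _sort_key(self):
        return (self.haploid_count, sorted(str(c) for c in self.chromosomes))

    def __str__(self) -> str:
        metas = sorted(
            (c for c in self.chromosomes if isinstance(c, Metacentric))
        )
        acros = sorted(c for c in self.chromosomes if isinstance(c, int))
        parts = [str(m) for m in metas] + [str(a) for a in acros]
        parts += list(self.sex_chromosomes)
        return " ".join(parts)


def _config_options(config) -> list[frozenset]:
    """The balanced segregation products of one configuration."""
    contents = [m.content for m in config.members]
    if config.kind == BIVALENT:
        opts = [frozenset([contents[0]]), frozenset([contents[1]])]
    elif config.kind in (CHAIN, RING):
        if config.kind == RING and config.length % 2:
            raise SegregationError(f"odd ring of {config.length} chromosomes")
        opts = [frozenset(contents[0::2]), frozenset(contents[1::2])]
    else:  # pragma: no cover - kinds are closed
        raise SegregationError(f"unknown configuration kind {config.kind!r}")
    # collapse content-identical products (homozygous bivalents)
    unique: list[frozenset] = []
    for o in opts:
        if o not in unique:
            unique.append(o)
    return unique


def enumerate_balanced_gametes(
    configs: MeioticConfigurationSet,
) -> list[GameteClass]:
    """All karyotypically distinct balanced gamete classes of a carrier.

    Cartesian product of per-configuration alternate-segregation products,
    collapsed by content; the sex pair contributes one sex chromosome
    (two classes per autosomal class for an XY carrier).
    """
    option_lists = [_config_options(c) for c in configs.configurations]
    sex_options = sorted(set(configs.sex_pair))
    seen: set[frozenset] = set()
    classes: list[GameteClass] = []
    for combo in product(*option_lists) if option_lists else [()]:
        autosomes = frozenset().union(*combo) if combo else frozenset()
        for sex in sex_options:
            chroms = frozenset(set(autosomes) | {sex})
            if chroms in seen:
                continue
            seen.add(chroms)
            g = GameteClass(chroms)
            if not g.is_balanced:
                raise SegregationError(
                    f"alternate segregation produced an unbalanced gamete: {g}"
                )
            classes.append(g)
    classes.sort(key=GameteClass._sort_key)
    return classes


def haploid_gamete(k: Karyotype, sex: str = "X") -> GameteClass:
    """The single balanced gamete class of a structurally homozygous animal."""
    contents = set(k.fusions) | set(k.acrocentric_arms) | {sex}
    return GameteClass(frozenset(contents))


def backcross_karyotype_distribution(
    f1_gametes: Sequence[GameteClass], mate: Karyotype
) -> dict[int, float]:
    """Expected offspring 2n distribution under equal gamete-class weights.

    The null expectation gives every balanced gamete class the same
    transmission probability; offspring 2n is the gamete's haploid count
    plus the mate's haploid count.
    """
    if not f1_gametes:
        raise SegregationError("no gamete classes supplied")
    mate_haploid = mate.haploid_count()
    dist: dict[int, float] = {}
    w = 1.0 / len(f1_gametes)
    for g in f1_gametes:
        if not g.is_balanced:
            raise SegregationError(f"unbalanced gamete class: {g}")
        two_n = g.haploid_count + mate_haploid
        dist[two_n] = dist.get(two_n, 0.0) + w
    return dict(sorted(dist.items()))


# -- sterility rule ---------------------------------------------------------

DEFAULT_STERILITY_CHAIN_LENGTH = 4
_DEMONSTRATED_CHAIN_LENGTH = 15  # male sterility is established for this length


def sterility_rule(
    configs: MeioticConfigurationSet,
    sex: str,
    min_chain: int = DEFAULT_STERILITY_CHAIN_LENGTH,
) -> bool:
    """Return True if the animal is fertile under the empirical rule.

    Males carrying a meiotic chain of ``min_chain`` or more chromosomes
    are classified sterile (sperm count zero); all other males, and all
    females, are classified fertile — female carriers are subfertile, not
    sterile, and their output emerges from the breeding simulation.
    Applying the rule to chains shorter than fifteen extrapolates beyond
    the length for which male sterility has been demonstrated; a warning
    is emitted in that case.
    """
    if sex not in ("XX", "XY", "M", "F", "male", "female"):
        raise SegregationError(f"unrecognised sex label {sex!r}")
    is_male = sex in ("XY", "M", "male")
    if not is_male:
        return True
    longest = configs.longest_chain()
    if longest >= min_chain:
        if longest < _DEMONSTRATED_CHAIN_LENGTH:
            warnings.warn(
                f"classifying a male with a chain of {longest} as sterile "
                f"extrapolates the rule demonstrated for chains of "
                f"{_DEMONSTRATED_CHAIN_LENGTH}",
                stacklevel=2,
            )
        return False
    return True


# -- nondisjunction / breeding model ----------------------------------------


@dataclass(frozen=True)
class ZygoteFate:
    """Outcome of one zygote: whether it implants (scar) and is born."""

    kind: str  # balanced_live, balanced_lost, trisomic_scar, monosomic_lost
    scar: bool
    born: bool


BALANCED_LIVE = ZygoteFate("balanced_live", scar=True, born=True)
BALANCED_LOST = ZygoteFate("balanced_lost", scar=True, born=False)
TRISOMIC_SCAR = ZygoteFate("trisomic_scar", scar=True, born=False)
MONOSOMIC_LOST = ZygoteFate("monosomic_lost", scar=False, born=False)


@dataclass(frozen=True)
class SegregationModel:
    """Stochastic model of oogenesis and early loss in a multivalent carrier.

    Parameters
    ----------
    nondisjunction_rate : probability that a meiosis with a multivalent
        malsegregates, producing an unbalanced gamete (monosomic or
        trisomic zygote with equal probability).  Carriers without a
        multivalent are unaffected by this parameter.
    ovulation_count : mean ovulated eggs per cycle (Poisson).
    fertilization_prob : per-egg fertilisation probability.
    baseline_loss : probability that a balanced zygote dies between
        implantation and birth (it still leaves a scar).
    """

    nondisjunction_rate: float = 0.82
    ovulation_count: float = 7.0
    fertilization_prob: float = 0.95
    baseline_loss: float = 0.05

    def __post_init__(self) -> None:
        for name in ("nondisjunction_rate", "fertilization_prob", "baseline_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SegregationError(f"{name}={v} outside [0, 1]")
        if self.ovulation_count <= 0:
            raise SegregationError("ovulation_count must be positive")


def expected_scar_excess_per_fertilized(
    model: SegregationModel, multivalent: bool = True
) -> float:
    """E[scars − litter] per fertilised egg, in closed form.

    A malsegregated zygote is trisomic (scar, no birth) with probability
    rate/2; a balanced zygote leaves a scar but no birth with probability
    baseline_loss.
    """
    r = model.nondisjunction_rate if multivalent else 0.0
    return r / 2.0 + (1.0 - r) * model.baseline_loss


def expected_litter_size(model: SegregationModel, multivalent: bool = True) -> float:
    """E[births] per cycle."""
    r = model.nondisjunction_rate if multivalent else 0.0
    return (
        model.ovulation_count
        * model.fertilization_prob
        * (1.0 - r)
        * (1.0 - model.baseline_loss)
    )


BREEDING_COLUMNS = [
    "female_id",
    "category",
    "cycle",
    "eggs",
    "fertilized",
    "balanced",
    "trisomic",
    "monosomic",
    "litter_size",
    "scars",
]


def simulate_breeding(
    configs: MeioticConfigurationSet,
    mate: Karyotype,
    model: SegregationModel,
    n_females: int,
    cycles_per_female: int = 1,
    category: str = "F1",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate per-cycle breeding records for carrier females.

    One row per female×cycle with egg, zygote-fate and outcome counts;
    identical seeds give identical records.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    multivalent = bool(configs.multivalents())
    rate = model.nondisjunction_rate if multivalent else 0.0
    n = n_females * cycles_per_female
    eggs = rng.poisson(model.ovulation_count, size=n)
    fertilized = rng.binomial(eggs, model.fertilization_prob)
    balanced = rng.binomial(fertilized, 1.0 - rate)
    unbalanced = fertilized - balanced
    trisomic = rng.binomial(unbalanced, 0.5)
    monosomic = unbalanced - trisomic
    born = rng.binomial(balanced, 1.0 - model.baseline_loss)
    scars = balanced + trisomic  # every implanted zygote scars, born or not
    female_ids = np.repeat(
        [f"{category}-f{i:04d}" for i in range(n_females)], cycles_per_female
    )
    cycles = np.tile(np.arange(1, cycles_per_female + 1), n_females)
    return pd.DataFrame(
        {
            "female_id": female_ids,
            "category": category,
            "cycle": cycles,
            "eggs": eggs,
            "fertilized": fertilized,
            "balanced": balanced,
            "trisomic": trisomic,
            "monosomic": monosomic,
            "litter_size": born,
            "scars": scars,
        },
        columns=BREEDING_COLUMNS,
    )


# -- nondisjunction-rate estimation (method of moments + cluster bootstrap) --


class NondisjunctionResults:
    """Estimated nondisjunction rate with a female-level bootstrap interval."""

    def __init__(
        self,
        estimate: float,
        ci: tuple[float, float],
        boot: np.ndarray,
        n_females: int,
        ci_level: float,
        undefined: bool,
        baseline_loss: float,
    ):
        self.estimate = estimate
        self.ci_lower, self.ci_upper = ci
        self.boot_estimates = boot
        self.n_females = n_females
        self.ci_level = ci_level
        self.undefined = undefined
        self.baseline_loss = baseline_loss

    def conf_int(self) -> tuple[float, float]:
        return (self.ci_lower, self.ci_upper)

    def summary(self) -> str:
        lines = [
            "Nondisjunction rate (method of moments on scar excess)",
            f"  females: {self.n_females}   assumed baseline loss: {self.baseline_loss:.3f}",
        ]
        if self.undefined:
            lines.append("  estimate: undefined (no scars or litters observed)")
        else:
            lines.append(
                f"  estimate: {self.estimate:.4f}   "
                f"{self.ci_level:.0%} bootstrap CI: "
                f"[{self.ci_lower:.4f}, {self.ci_upper:.4f}]"
            )
        return "\n".join(lines)


class NondisjunctionModel:
    """Method-of-moments estimator of the multivalent nondisjunction rate.

    Inverts ``E[scars − litter] / fertilised = rate/2 + (1−rate)·L`` for
    a known baseline post-implantation loss L, on breeding records from
    :func:`simulate_breeding` (or real data with the same columns).
    """

    def __init__(self, records: pd.DataFrame, baseline_loss: float = 0.0):
        required = {"female_id", "fertilized", "litter_size", "scars"}
        missing = required - set(records.columns)
        if missing:
            raise SegregationError(f"records missing columns: {sorted(missing)}")
        if not 0.0 <= baseline_loss < 0.5:
            raise SegregationError("baseline_loss must be in [0, 0.5)")
        self.records = records
        self.baseline_loss = baseline_loss

    @staticmethod
    def _rate_from_sums(excess: float, fertilized: float, L: float) -> float:
        if fertilized <= 0:
            return math.nan
        ratio = excess / fertilized
        rate = (ratio - L) / (0.5 - L)
        return min(max(rate, 0.0), 1.0)

    def fit(
        self, n_boot: int = 1000, ci_level: float = 0.99, seed: int = 0
    ) -> NondisjunctionResults:
        df = self.records
        per_female = df.groupby("female_id", sort=True).agg(
            excess=("scars", "sum"),
            litter=("litter_size", "sum"),
            fertilized=("fertilized", "sum"),
        )
        per_female["excess"] -= per_female["litter"]
        undefined = bool(
            (per_female["litter"].sum() == 0) and (df["scars"].sum() == 0)
        )
        L = self.baseline_loss
        est = self._rate_from_sums(
            per_female["excess"].sum(), per_female["fertilized"].sum(), L
        )
        if undefined:
            est = math.nan
        excess = per_female["excess"].to_numpy(float)
        fert = per_female["fertilized"].to_numpy(float)
        m = len(per_female)
        rng = np.random.default_rng(seed)
        boot = np.full(n_boot, math.nan)
        if not undefined and m > 0:
            idx = rng.integers(0, m, size=(n_boot, m))
            boot = np.array(
                [
                    self._rate_from_sums(excess[i].sum(), fert[i].sum(), L)
                    for i in idx
                ]
            )
        alpha = (1.0 - ci_level) / 2.0
        valid = boot[~np.isnan(boot)]
        if valid.size:
            ci = (
                float(np.quantile(valid, alpha)),
                float(np.quantile(valid, 1.0 - alpha)),
            )
        else:
            ci = (math.nan, math.nan)
        return NondisjunctionResults(
            estimate=est,
            ci=ci,
            boot=boot,
            n_females=m,
            ci_level=ci_level,
            undefined=undefined,
            baseline_loss=L,
        )


def f1_gamete_classes(
    mother: Karyotype, father: Karyotype, offspring_sex: str = "XX"
) -> list[GameteClass]:
    """Balanced gamete classes of the F1 hybrid of two races."""
    return enumerate_balanced_gametes(
        configurations_from_cross(mother, father, offspring_sex)
    )
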