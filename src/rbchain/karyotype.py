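"""Karyotype algebra for Robertsonian races of the western house mouse.

The ancestral karyotype of *Mus musculus domesticus* is 2n = 40, all
acrocentric: 19 autosome pairs plus a sex pair.  A Robertsonian (centric)
fusion joins two acrocentric autosomes at their centromeres into one
metacentric, written ``a.b`` with the smaller arm first (e.g. ``1.18``),
and each fusion pair reduces the diploid number by two.  A race karyotype
is therefore fully described by its set of fusions: a race with *k*
fusions has 2n = 40 − 2k, down to 2n = 22 for the most derived races.

Fusions are autosomal only; every autosomal arm 1–19 belongs to at most
one metacentric, and the arms not captured by any fusion remain as
acrocentric chromosomes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

N_AUTOSOMAL_ARMS = 19
ANCESTRAL_DIPLOID_NUMBER = 40
ALL_ARMS = frozenset(range(1, N_AUTOSOMAL_ARMS + 1))

_TOKEN_RE = re.compile(r"^([^.\s]+)\.([^.\s]+)$")
_SEX_LABELS = {"X", "Y", "x", "y"}


class KaryotypeError(ValueError):
    """Raised for an invalid karyotype definition (bad arm, reused arm, ...)."""


def _check_arm(arm: int) -> int:
    if isinstance(arm, bool) or not isinstance(arm, int):
        raise KaryotypeError(f"arm label must be an integer, got {arm!r}")
    if not 1 <= arm <= N_AUTOSOMAL_ARMS:
        raise KaryotypeError(
            f"arm {arm} outside the autosomal range 1-{N_AUTOSOMAL_ARMS}"
        )
    return arm


@dataclass(frozen=True, order=True)
class Metacentric:
    """A two-armed fusion chromosome, stored canonically with arm_a < arm_b."""

    arm_a: int
    arm_b: int

    def __post_init__(self) -> None:
        a, b = self.arm_a, self.arm_b
        _check_arm(a)
        _check_arm(b)
        if a == b:
            raise KaryotypeError(
                f"self-fusion {a}.{b}: a metacentric joins two distinct arms"
            )
        if a > b:  # accept either print order, canonicalise to (min, max)
            object.__setattr__(self, "arm_a", b)
            object.__setattr__(self, "arm_b", a)

    @property
    def arms(self) -> tuple[int, int]:
        return (self.arm_a, self.arm_b)

    def __str__(self) -> str:
        return f"{self.arm_a}.{self.arm_b}"


class Inventory(NamedTuple):
    """Per-haploid-set chromosome counts for one race."""

    metacentrics: int
    acrocentric_autosomes: int
    sex_chromosomes: int  # always 1 per haploid set


@dataclass(frozen=True)
class Karyotype:
    """A race karyotype: a named set of Robertsonian fusions plus a sex pair.

    Race definitions default to female (XX); individual animals carry an
    explicit ``sex_pair``.  Sex chromosomes never participate in fusions.
    """

    name: str = ""
    fusions: frozenset[Metacentric] = field(default_factory=frozenset)
    sex_pair: str = "XX"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fusions", frozenset(self.fusions))
        if self.sex_pair not in ("XX", "XY"):
            raise KaryotypeError(f"sex pair must be XX or XY, got {self.sex_pair!r}")
        seen: dict[int, Metacentric] = {}
        for met in sorted(self.fusions):
            for arm in met.arms:
                if arm in seen:
                    raise KaryotypeError(
                        f"arm {arm} used twice: in {seen[arm]} and {met}"
                    )
                seen[arm] = met

    # -- derived quantities -------------------------------------------------

    @property
    def diploid_number(self) -> int:
        """2n = 40 − 2 × (number of fusions)."""
        return ANCESTRAL_DIPLOID_NUMBER - 2 * len(self.fusions)

    @property
    def fused_arms(self) -> frozenset[int]:
        return frozenset(a for met in self.fusions for a in met.arms)

    @property
    def acrocentric_arms(self) -> tuple[int, ...]:
        """Autosomal arms that remain as acrocentric chromosomes, sorted."""
        return tuple(sorted(ALL_ARMS - self.fused_arms))

    def inventory(self) -> Inventory:
        """Haploid chromosome counts (double, plus the sex pair, for 2n)."""
        return Inventory(
            metacentrics=len(self.fusions),
            acrocentric_autosomes=len(self.acrocentric_arms),
            sex_chromosomes=1,
        )

    def haploid_autosome_count(self) -> int:
        return len(self.fusions) + len(self.acrocentric_arms)

    def haploid_count(self) -> int:
        """Chromosomes in one haploid set, sex chromosome included."""
        return self.haploid_autosome_count() + 1

    # -- formatting ---------------------------------------------------------

    def format(self) -> str:
        """Whitespace-separated fusion list, canonically ordered."""
        return " ".join(str(m) for m in sorted(self.fusions))

    def __str__(self) -> str:
        label = self.name or "karyotype"
        return f"{label} (2n={self.diploid_number}): {self.format() or '-'}"


def diploid_number(k: Karyotype) -> int:
    return k.diploid_number


def chromosome_inventory(k: Karyotype) -> Inventory:
    return k.inventory()


def _parse_token(token: str) -> Metacentric:
    m = _TOKEN_RE.match(token)
    if m is None:
        raise KaryotypeError(f"malformed fusion token {token!r} (expected 'a.b')")
    arms = []
    for part in m.groups():
        if part in _SEX_LABELS:
            raise KaryotypeError(
                f"sex chromosome {part!r} in fusion {token!r}: "
                "fusions are autosomal only"
            )
        try:
            arms.append(int(part))
        except ValueError:
            raise KaryotypeError(
                f"non-integer arm {part!r} in fusion token {token!r}"
            ) from None
    return Metacentric(*(_check_arm(a) for a in arms))


def parse_karyotype(text: str, name: str = "", sex_pair: str = "XX") -> Karyotype:
    """Parse a whitespace-separated fusion list such as ``"1.18 2.5 3.6"``.

    Token order is irrelevant and either arm order is accepted; the empty
    string yields the ancestral all-acrocentric karyotype (2n = 40).
    """
    fusions = [_parse_token(tok) for tok in text.split()]
    return Karyotype(name=name, fusions=frozenset(fusions), sex_pair=sex_pair)


def format_karyotype(k: Karyotype) -> str:
    return k.format()


def with_sex(k: Karyotype, sex_pair: str) -> Karyotype:
    """The same race karyotype carried by an individual of the given sex."""
    return Karyotype(name=k.name, fusions=k.fusions, sex_pair=sex_pair)
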