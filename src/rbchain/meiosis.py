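"""Meiosis-I pairing configurations of hybrids between Robertsonian races.

An F1 hybrid inherits one haploid set from each parental race.  At
meiosis I, chromosomes pair arm by arm: every autosomal arm is present on
exactly two chromosomes (one of each parental origin), so the pairing
structure is a graph with chromosomes as nodes and one edge per shared
arm.  Its connected components are the meiotic configurations:

* two chromosomes sharing all their arms form a **bivalent**;
* a path of three or more chromosomes — forced by monobrachial homology,
  where metacentrics of the two races share single arms — is a **chain**
  (an open multivalent ending in chromosomes with an unpaired arm);
* a closed cycle of metacentrics is a **ring**.

The sex pair is reported separately as the sex bivalent and excluded
from the autosomal graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import networkx as nx

from .karyotype import ALL_ARMS, Karyotype, Metacentric

Content = Union[Metacentric, int, str]  # metacentric, acrocentric arm, or sex label

MATERNAL = "maternal"
PATERNAL = "paternal"


class MeiosisError(ValueError):
    """Raised when a complement or pairing graph is internally inconsistent."""


@dataclass(frozen=True)
class ChromosomeCopy:
    """One chromosome of an F1 complement, tagged with its parental origin."""

    parent: str  # "maternal" or "paternal" (unique key within a complement)
    origin: str  # parental race label, for reporting
    content: Content = 0

    @property
    def arms(self) -> tuple[int, ...]:
        if isinstance(self.content, Metacentric):
            return self.content.arms
        if isinstance(self.content, int):
            return (self.content,)
        return ()  # sex chromosome

    @property
    def is_metacentric(self) -> bool:
        return isinstance(self.content, Metacentric)

    @property
    def is_sex(self) -> bool:
        return isinstance(self.content, str)

    def __str__(self) -> str:
        return f"{self.content}({self.origin})"

    def __lt__(self, other: "ChromosomeCopy") -> bool:  # deterministic ordering
        return self._key() < other._key()

    def _key(self):
        return (self.arms, self.parent, str(self.content))


def f1_complement(
    mother: Karyotype, father: Karyotype, offspring_sex: str = "XX"
) -> list[ChromosomeCopy]:
    """One haploid autosomal set per parent plus a sex pair.

    The maternal set contributes an X; the paternal set contributes the
    second letter of ``offspring_sex`` (X or Y).
    """
    if offspring_sex not in ("XX", "XY"):
        raise MeiosisError(f"offspring sex must be XX or XY, got {offspring_sex!r}")
    copies: list[ChromosomeCopy] = []
    for parent, race, sex_label in (
        (MATERNAL, mother, "X"),
        (PATERNAL, father, offspring_sex[1]),
    ):
        for met in sorted(race.fusions):
            copies.append(ChromosomeCopy(parent, race.name, met))
        for arm in race.acrocentric_arms:
            copies.append(ChromosomeCopy(parent, race.name, arm))
        copies.append(ChromosomeCopy(parent, race.name, sex_label))
    return copies


def complement_inventory(complement: Iterable[ChromosomeCopy]) -> tuple[int, int]:
    """(metacentrics, acrocentrics) in a complement.

    Sex chromosomes are counted among the acrocentrics, as in standard
    mouse metaphase counts (the X and Y are acrocentric/telocentric).
    """
    complement = list(complement)
    metas = sum(1 for c in complement if c.is_metacentric)
    return metas, len(complement) - metas


def pairing_graph(complement: Iterable[ChromosomeCopy]) -> nx.MultiGraph:
    """Arm-homology multigraph over the autosomal chromosomes.

    One edge per autosomal arm joins the two copies carrying that arm;
    a pair of identical metacentrics is joined by two parallel edges.
    """
    g: nx.MultiGraph = nx.MultiGraph()
    carriers: dict[int, list[ChromosomeCopy]] = {}
    for copy in complement:
        if copy.is_sex:
            continue
        g.add_node(copy)
        for arm in copy.arms:
            carriers.setdefault(arm, []).append(copy)
    for arm in sorted(carriers):
        nodes = carriers[arm]
        if len(nodes) != 2:
            raise MeiosisError(
                f"arm {arm} present {len(nodes)} times in complement (expected 2)"
            )
        g.add_edge(nodes[0], nodes[1], key=arm, arm=arm)
    missing = ALL_ARMS - set(carriers)
    if missing:
        raise MeiosisError(f"arms absent from complement: {sorted(missing)}")
    return g


BIVALENT = "bivalent"
CHAIN = "chain"
RING = "ring"


@dataclass(frozen=True)
class MeioticConfiguration:
    """One meiosis-I configuration: a bivalent, chain or ring of chromosomes."""

    kind: str
    members: tuple[ChromosomeCopy, ...]

    @property
    def length(self) -> int:
        return len(self.members)

    @property
    def is_multivalent(self) -> bool:
        return self.length > 2

    def __str__(self) -> str:
        if self.kind == BIVALENT:
            return f"bivalent({self.members[0].content})"
        return f"{self.kind}[{self.length}]: {chain_string(self)}"


@dataclass(frozen=True)
class MeioticConfigurationSet:
    """All meiosis-I configurations of one hybrid, sex bivalent separate."""

    configurations: tuple[MeioticConfiguration, ...]
    sex_pair: str
    f1_diploid_number: int
    sex_bivalent: bool = True

    def __post_init__(self) -> None:
        total = sum(c.length for c in self.configurations) + 2
        if total != self.f1_diploid_number:
            raise MeiosisError(
                f"configuration lengths sum to {total}, "
                f"but 2n = {self.f1_diploid_number}"
            )

    def bivalents(self) -> list[MeioticConfiguration]:
        return [c for c in self.configurations if c.kind == BIVALENT]

    def chains(self) -> list[MeioticConfiguration]:
        return [c for c in self.configurations if c.kind == CHAIN]

    def rings(self) -> list[MeioticConfiguration]:
        return [c for c in self.configurations if c.kind == RING]

    def multivalents(self) -> list[MeioticConfiguration]:
        return [c for c in self.configurations if c.is_multivalent]

    def longest_chain(self) -> int:
        chains = self.chains()
        return max((c.length for c in chains), default=0)


def _component_terminals(g: nx.MultiGraph, nodes: list[ChromosomeCopy]):
    return [n for n in nodes if g.degree(n) == 1]


def _walk(g: nx.MultiGraph, start: ChromosomeCopy, n: int) -> list[ChromosomeCopy]:
    order = [start]
    prev = None
    cur = start
    while len(order) < n:
        nxts = [nb for nb in g.neighbors(cur) if nb != prev]
        if prev is None and len(nxts) == 2:  # ring start: pick a direction
            nxts = [min(nxts)]
        if len(nxts) != 1:
            raise MeiosisError("component is neither a path nor a simple cycle")
        prev, cur = cur, nxts[0]
        order.append(cur)
    return order


def _classify_component(
    g: nx.MultiGraph, nodes: list[ChromosomeCopy]
) -> MeioticConfiguration:
    nodes = sorted(nodes)
    n = len(nodes)
    n_edges = g.subgraph(nodes).number_of_edges()
    if n == 2:
        # includes the double-edged homologous-metacentric pair: a bivalent,
        # not a "ring of two"
        return MeioticConfiguration(BIVALENT, tuple(nodes))
    terminals = _component_terminals(g, nodes)
    if len(terminals) == 2 and n_edges == n - 1:
        start = min(terminals)
        return MeioticConfiguration(CHAIN, tuple(_walk(g, start, n)))
    if not terminals and n_edges == n:
        if n % 2:
            raise MeiosisError(f"odd ring of {n} impossible with intact fusions")
        start = min(nodes, key=lambda c: (min(c.arms), c.parent))
        order = _walk(g, start, n)
        # ensure the walk closes
        if start not in g.neighbors(order[-1]):
            raise MeiosisError("component is neither a path nor a simple cycle")
        return MeioticConfiguration(RING, tuple(order))
    raise MeiosisError("component is neither a path nor a simple cycle")


def classify_configurations(
    graph: nx.MultiGraph,
    sex_pair: str = "XX",
    f1_diploid_number: int | None = None,
) -> MeioticConfigurationSet:
    """Label each connected component of the pairing graph."""
    configs = [
        _classify_component(graph, list(comp))
        for comp in nx.connected_components(graph)
    ]
    configs.sort(key=lambda c: (-c.length, c.members[0].arms))
    if f1_diploid_number is None:
        f1_diploid_number = graph.number_of_nodes() + 2
    return MeioticConfigurationSet(
        configurations=tuple(configs),
        sex_pair=sex_pair,
        f1_diploid_number=f1_diploid_number,
    )


def configurations_from_cross(
    mother: Karyotype, father: Karyotype, offspring_sex: str = "XX"
) -> MeioticConfigurationSet:
    """Meiotic configuration set of the hybrid of two race karyotypes."""
    complement = f1_complement(mother, father, offspring_sex)
    graph = pairing_graph(complement)
    return classify_configurations(
        graph, sex_pair=offspring_sex, f1_diploid_number=len(complement)
    )


# -- chain/ring string notation --------------------------------------------


def _shared_arm(a: ChromosomeCopy, b: ChromosomeCopy) -> int:
    shared = set(a.arms) & set(b.arms)
    if len(shared) != 1:
        raise MeiosisError(f"{a} and {b} share {len(shared)} arms, expected 1")
    return shared.pop()


def _direction_string(members: list[ChromosomeCopy], closed: bool, sep: str) -> str:
    parts: list[str] = []
    n = len(members)
    for i, m in enumerate(members):
        if not m.is_metacentric:
            parts.append(str(m.content))
            continue
        if i > 0:
            entering = _shared_arm(members[i - 1], m)
        elif closed:
            entering = _shared_arm(members[-1], m)
        else:
            # terminal metacentric: the free (unshared) arm is met first
            entering = next(a for a in m.arms if a != _shared_arm(m, members[1]))
        exiting = next(a for a in m.arms if a != entering)
        parts.append(f"{entering}.{exiting}")
    return sep.join(parts)


def chain_string(config: MeioticConfiguration, sep: str = "-") -> str:
    """Arm-ordered notation for a chain or ring, e.g. ``1-1.3-3``.

    Metacentrics are printed entering-arm first, following the traversal.
    The canonical orientation is the lexicographically smaller of the two
    traversal directions (and, for rings, of all rotations starting at
    the member carrying the smallest arm); use :func:`chain_strings_equal`
    for orientation-invariant comparison.
    """
    if config.kind == BIVALENT:
        raise MeiosisError("chain_string is defined for chains and rings only")
    members = list(config.members)
    closed = config.kind == RING
    forward = _direction_string(members, closed, sep)
    if closed:
        reverse_members = [members[0]] + list(reversed(members[1:]))
    else:
        reverse_members = list(reversed(members))
    backward = _direction_string(reverse_members, closed, sep)
    return min(forward, backward)


def _tokens(s: str, sep: str) -> list[str]:
    return s.split(sep)


def _flip(token: str) -> str:
    if "." in token:
        a, b = token.split(".")
        return f"{b}.{a}"
    return token


def chain_strings_equal(a: str, b: str, sep: str = "-") -> bool:
    """True if two chain strings denote the same configuration.

    Both traversal orientations of a chain compare equal; for rings all
    rotations in either direction compare equal.
    """
    ta, tb = _tokens(a, sep), _tokens(b, sep)
    if len(ta) != len(tb):
        return False
    reversed_b = [_flip(t) for t in reversed(tb)]
    if ta in (tb, reversed_b):
        return True
    # ring: allow rotations
    for variant in (tb, reversed_b):
        for k in range(len(variant)):
            if ta == variant[k:] + variant[:k]:
                return True
    return False
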