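"""Built-in reference karyotypes.

CHBU (Buchs) and CHHN (Hünikon) are two chromosomal races of the western
house mouse from north-eastern Switzerland with heavily fused karyotypes:
CHBU carries nine Robertsonian fusions (2n = 22), CHHN eight (2n = 24).
They share the metacentrics 4.12 and 9.14; their remaining fusions are
connected by monobrachial homology, which is what makes their F1 hybrids
form a single long meiotic chain.
"""

from .karyotype import Karyotype, parse_karyotype

CHBU_FUSION_LIST = "1.18 2.5 3.6 4.12 7.15 8.16 9.14 10.17 11.13"
CHHN_FUSION_LIST = "1.3 2.8 4.12 5.7 6.15 9.14 10.11 13.16"

CHBU: Karyotype = parse_karyotype(CHBU_FUSION_LIST, name="CHBU")
CHHN: Karyotype = parse_karyotype(CHHN_FUSION_LIST, name="CHHN")
ANCESTRAL: Karyotype = parse_karyotype("", name="ancestral")

BUILTIN: dict[str, Karyotype] = {
    "CHBU": CHBU,
    "CHHN": CHHN,
    "ancestral": ANCESTRAL,
}


def get_race(name: str) -> Karyotype:
    try:
        return BUILTIN[name]
    except KeyError:
        raise KeyError(
            f"unknown race {name!r}; built-in races: {sorted(BUILTIN)}"
        ) from None
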