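"""Small built-in example data.

A published rat intracerebral-hemorrhage study reported seven
ICH-responsive tsRNAs, two of whose synthetic mimic sequences are public,
plus a tsRNA–mRNA–pathway subnetwork around the GO term "embryonic
morphogenesis" and the KEGG "Endocytosis" pathway. These tiny sets are
bundled as worked-example inputs for the naming and network modules.
"""

from __future__ import annotations

import networkx as nx

from .enrich import build_network

#: mimic (synthetic oligo) sequences of two validated rat tsRNAs
MIMIC_SEQUENCES: dict[str, str] = {
    "rno-tRFi-Ser-25a": "AUGGACUGCUAAUCCAUUGUGCUCU",
    "rno-tRFi-Gln-16a": "UCUGGACUCUGAAUCC",
}

#: validated tsRNA → mRNA target pairs feeding the example subnetwork
EXAMPLE_TARGET_EDGES: dict[str, set[str]] = {
    "rno-tRFi-Cys-20a": {"Ret", "Hipk1"},
    "rno-tRFi-Ser-25a": {"Fzd1", "Il1rn", "Epn2"},
    "rno-tRFi-Gln-16a": {"Il1rn", "Epn2"},
    "rno-tRF5-Glu-29a": {"Aplnr"},
    "rno-tRF5-Ala-16a": {"Gbx2", "Tbx4"},
    "rno-tiR5-Lys-35b": {"Kdm6b"},
}

#: pathway memberships of the example mRNAs
EXAMPLE_TERM_MEMBERS: dict[str, set[str]] = {
    "GO:0048598": {"Ret", "Fzd1", "Il1rn", "Aplnr", "Gbx2", "Tbx4",
                   "Kdm6b", "Hipk1"},        # embryonic morphogenesis
    "rno04144": {"Ret", "Epn2"},             # endocytosis (example subset)
}

TERM_NAMES: dict[str, str] = {
    "GO:0048598": "embryonic morphogenesis",
    "rno04144": "Endocytosis",
}


def example_network() -> nx.DiGraph:
    """The bundled tsRNA–mRNA–pathway example as a directed graph."""
    return build_network(EXAMPLE_TARGET_EDGES, EXAMPLE_TERM_MEMBERS)
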