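"""Taspase cleavage-motif scanning.

Taspase cleaves after the aspartate of a Q-x-D|G tetrad, with the second
position drawn from {F, I, L, M} in the Drosophila consensus (human Taspase1
additionally tolerates V).  The scanner reports every occurrence in a
protein and censuses a proteome by proteins-with-at-least-one-site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

_AA = set("ACDEFGHIKLMNPQRSTVWYUOBZXJ")


@dataclass(frozen=True)
class MotifConfig:
    """Cleavage-motif definition: Q, one of ``position2_alphabet``, D, G."""

    position2_alphabet: frozenset[str] = field(
        default_factory=lambda: frozenset("FILM")
    )

    def __post_init__(self) -> None:
        alphabet = frozenset(a.upper() for a in self.position2_alphabet)
        object.__setattr__(self, "position2_alphabet", alphabet)
        if not alphabet:
            raise ValueError("position-2 alphabet must be non-empty")
        bad = alphabet - _AA
        if bad:
            raise ValueError(f"non-amino-acid letters in alphabet: {sorted(bad)}")

    @property
    def regex(self) -> re.Pattern[str]:
        inner = "".join(sorted(self.position2_alphabet))
        return re.compile(f"Q[{inner}]DG")


def find_cleavage_sites(protein: str, config: MotifConfig | None = None) -> list[int]:
    """1-based start positions of every (possibly overlapping) motif match.

    Matching is case-insensitive; a stop character '*' terminates the
    scanned region.  Non-amino-acid characters raise.
    """
    config = config or MotifConfig()
    seq = protein.upper()
    stop = seq.find("*")
    if stop != -1:
        seq = seq[:stop]
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"non-amino-acid characters in protein: {sorted(bad)}")
    pattern = config.regex
    sites: list[int] = []
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            break
        sites.append(m.start() + 1)
        pos = m.start() + 1  # allow overlaps
    return sites


def census(
    proteome: Mapping[str, str], config: MotifConfig | None = None
) -> tuple[int, pd.DataFrame]:
    """Count proteins with >= 1 cleavage site; detail table of all sites.

    Each protein contributes at most 1 to the count however many sites it
    carries.  Returns (count, DataFrame[protein, position, motif]).
    """
    config = config or MotifConfig()
    rows = []
    n_with_site = 0
    for name, seq in proteome.items():
        sites = find_cleavage_sites(seq, config)
        if sites:
            n_with_site += 1
        for s in sites:
            rows.append({"protein": name, "position": s, "motif": seq.upper()[s - 1 : s + 3]})
    detail = pd.DataFrame(rows, columns=["protein", "position", "motif"])
    return n_with_site, detail
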