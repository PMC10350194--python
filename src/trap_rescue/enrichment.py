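"""Gene-set overrepresentation against GMT collections.

A self-contained hypergeometric enrichment (upper tail, one-sided) with BH
correction across sets.  The universe should be the genes the differential
stage could actually test, not every annotated gene, to avoid detection-bias
inflation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from trap_rescue.diffexpr import bh_adjust
from trap_rescue.errors import DataError


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)


def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description,
    then members.  Lines with fewer than 3 fields are malformed."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"malformed GMT line {lineno}: fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise DataError(f"duplicate set name {name!r} at GMT line {lineno}")
            sets[name] = [m for m in fields[2:] if m]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def hypergeom_enrich(
    query: list[str], collection: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation per set, BH across sets.

    p = P(X >= overlap) drawing |query| genes from a universe of size N
    containing K set members.  Query genes outside the universe are dropped
    with a warning; set members are intersected with the universe.
    """
    uni = set(universe)
    if not uni:
        raise DataError("empty universe")
    q = set(query)
    outside = q - uni
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped", stacklevel=2
        )
        q &= uni
    n = len(q)
    rows = []
    for name, members in collection.sets.items():
        k_set = set(members) & uni
        overlap = sorted(q & k_set)
        x, big_k = len(overlap), len(k_set)
        p = float(stats.hypergeom.sf(x - 1, len(uni), big_k, n)) if x > 0 else 1.0
        rows.append((name, big_k, x, min(p, 1.0), ",".join(overlap)))
    table = pd.DataFrame(rows, columns=["set", "K", "overlap", "p", "overlap_genes"])
    table["q"] = bh_adjust(table["p"]).to_numpy()
    return table[["set", "K", "overlap", "p", "q", "overlap_genes"]]
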