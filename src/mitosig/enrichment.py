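"""Gene-set over-representation analysis (ORA) against GMT collections.

Aptamer-level calls are collapsed to genes before testing: the universe is
the set of unique gene symbols on the analyte panel (after any feature-space
restriction), and a gene is a hit when at least one of its analytes is
called upregulated.  Each gene set is tested with the one-sided
hypergeometric upper tail on the 2x2 overlap restricted to the universe,

    p = P(X >= k),  X ~ Hypergeom(N = |universe|, K = |set in universe|,
                                  n = |hits|),

followed by Benjamini-Hochberg adjustment across the tested sets.  Sets
whose intersection with the universe is below ``min_set_size`` (default 2)
are skipped and reported, since near-empty sets produce degenerate tails
that would otherwise dominate the BH correction.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "ora_test"]


@dataclasses.dataclass
class GeneSetCollection:
    """Named collection of gene sets; members deduplicated and uppercased."""

    name: str
    sets: dict  # set_id -> (description, tuple of member symbols)

    def __post_init__(self):
        clean = {}
        for set_id, (desc, members) in self.sets.items():
            norm = sorted({str(m).upper() for m in members if str(m).strip()})
            if not norm:
                raise ValueError(f"gene set {set_id!r} has no members")
            clean[set_id] = (desc, tuple(norm))
        self.sets = clean

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path, name=None) -> GeneSetCollection:
    """Read a standard GMT file (set_id, description, members; tab-delimited)."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}, line {lineno}: GMT lines need >= 3 tab-separated "
                    f"fields (set_id, description, members), found {len(fields)}")
            sets[fields[0]] = (fields[1], tuple(fields[2:]))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(name=name or str(path), sets=sets)


def write_gmt(collection: GeneSetCollection, path):
    with open(path, "w") as fh:
        for set_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def ora_test(hits: Iterable[str], universe: Iterable[str],
             collection: GeneSetCollection, min_set_size: int = 2):
    """Hypergeometric over-representation of ``hits`` within ``universe``.

    Returns ``(table, skipped)``: one row per tested set (sorted by q) and
    the ids of sets skipped for insufficient universe overlap.

    Raises
    ------
    ValueError
        If any hit is absent from the universe (offenders listed).
    """
    uni = {str(g).upper() for g in universe}
    hit = {str(g).upper() for g in hits}
    outside = sorted(hit - uni)
    if outside:
        raise ValueError(f"hits not contained in the universe: {outside}")
    N, n_hits = len(uni), len(hit)
    rows, skipped = [], []
    for set_id, (desc, members) in collection:
        in_uni = sorted(set(members) & uni)
        K = len(in_uni)
        if K < min_set_size:
            skipped.append(set_id)
            continue
        overlap = sorted(set(in_uni) & hit)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_hits))
        rows.append({
            "set_id": set_id,
            "name": desc,
            "overlap_count": k,
            "set_size_in_universe": K,
            "hit_count": n_hits,
            "universe_size": N,
            "p_hypergeom": min(p, 1.0),
            "overlap_symbols": ",".join(overlap),
        })
    if rows:
        table = pd.DataFrame(rows).set_index("set_id")
        table["q"] = bh_adjust(table["p_hypergeom"].to_numpy())
        table = table.sort_values(["q", "p_hypergeom"]).loc[
            :, ["name", "overlap_count", "set_size_in_universe", "hit_count",
                "universe_size", "p_hypergeom", "q", "overlap_symbols"]]
    else:
        table = pd.DataFrame(columns=[
            "name", "overlap_count", "set_size_in_universe", "hit_count",
            "universe_size", "p_hypergeom", "q", "overlap_symbols"])
    return table, skipped
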