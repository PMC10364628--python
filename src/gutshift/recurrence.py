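"""Metabolite recurrence ranking within pathway clusters.

For each cluster of significant pathways, every compound in the catalog is
counted by the number of member pathways whose compound set contains it;
compounds occurring more than once (n > 1) are the recurrent metabolites.
Recurrent compounds are intersected with a set of hormone-metabolism-related
compounds, and representative pathways of a cluster are those whose compound
sets intersect a focal compound family, ranked by intersection size then by
selection p-value.

Compound identity is exact string match on catalog ids; a packaged alias map
covers the butanoate- and mevalonate-related focal families.  A configurable
currency-compound blocklist (H2O/ATP-type ubiquitous metabolites) is
available and off by default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from scipy import stats

from .errors import ConsistencyError
from .io import PathwayDb

#: Focal compound families (butanoate- and mevalonate-related metabolites).
FOCAL_FAMILIES: Dict[str, Set[str]] = {
    "butanoate": {"butanoate", "butanoyl-CoA", "crotonyl-CoA", "acetoacetyl-CoA"},
    "mevalonate": {"(R)-mevalonate", "DMAPP", "IPP", "GPP", "GGPP", "MEP"},
}

#: Ubiquitous currency metabolites that can be excluded from recurrence counts.
CURRENCY_COMPOUNDS: Set[str] = {
    "WATER", "ATP", "ADP", "AMP", "NAD", "NADH", "NADP", "NADPH",
    "PROTON", "Pi", "PPI", "CO2", "CO-A",
}


@dataclass
class RecurrenceTable:
    """Per-cluster compound occurrence counts with recurrence/hormone flags."""

    counts: Dict[int, List[Tuple[str, int]]]  # cluster -> [(compound, count)] sorted
    cluster_sizes: Dict[int, int]
    recurrence_min: int = 2
    hormone_compounds: Set[str] = field(default_factory=set)

    def recurrent(self, cluster: int) -> List[str]:
        """Compounds in >= recurrence_min pathways of the cluster, ranked."""
        return [c for c, n in self.counts[cluster] if n >= self.recurrence_min]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cluster in sorted(self.counts):
            for compound, n in self.counts[cluster]:
                rows.append(
                    {
                        "cluster": cluster,
                        "compound": compound,
                        "count": n,
                        "recurrent": n >= self.recurrence_min,
                        "hormone_hit": compound in self.hormone_compounds,
                    }
                )
        return pd.DataFrame(rows, columns=["cluster", "compound", "count", "recurrent", "hormone_hit"])


def compound_recurrence(
    labels: Mapping[str, int],
    db: PathwayDb,
    recurrence_min: int = 2,
    exclude_currency: bool = False,
) -> RecurrenceTable:
    """Count compound occurrences per cluster of labeled pathways.

    ``labels`` maps pathway ids to cluster ids.  Counts are sorted by
    descending occurrence, ties broken lexicographically.
    """
    known = set(db.pathway_ids)
    missing = sorted(set(labels) - known)
    if missing:
        raise ConsistencyError(f"labeled pathways absent from DB: {', '.join(missing)}")
    blocked = CURRENCY_COMPOUNDS if exclude_currency else set()
    by_cluster: Dict[int, Counter] = {}
    sizes: Dict[int, int] = {}
    for pid, cluster in labels.items():
        cluster = int(cluster)
        sizes[cluster] = sizes.get(cluster, 0) + 1
        ctr = by_cluster.setdefault(cluster, Counter())
        ctr.update(set(db.compounds[pid]) - blocked)
    counts = {
        cluster: sorted(ctr.items(), key=lambda kv: (-kv[1], kv[0]))
        for cluster, ctr in by_cluster.items()
    }
    return RecurrenceTable(
        counts=counts,
        cluster_sizes=sizes,
        recurrence_min=recurrence_min,
        hormone_compounds=set(db.hormone_compounds),
    )


def hormone_overlap(rec: RecurrenceTable, db: PathwayDb) -> Dict[int, List[str]]:
    """Recurrent compounds per cluster that are hormone-metabolism-related.

    Preserves the recurrence ranking; an empty intersection is an empty list.
    """
    hormone = set(db.hormone_compounds)
    return {cluster: [c for c in rec.recurrent(cluster) if c in hormone] for cluster in rec.counts}


def representative_pathways(
    rec: RecurrenceTable,
    db: PathwayDb,
    focal_compounds: Set[str],
    labels: Mapping[str, int],
    p_values: Optional[Mapping[str, float]] = None,
    enrichment_p: bool = False,
) -> pd.DataFrame:
    """Pathways of each cluster whose compound sets hit the focal family.

    Rows are (cluster, pathway_id, p, n_matched, matched compounds), sorted
    by cluster, then descending intersection size, then p.  When
    ``enrichment_p`` is set, a hypergeometric enrichment p-value of the
    overlap against the catalog's compound universe is appended.
    """
    universe: Set[str] = set()
    for comp in db.compounds.values():
        universe |= comp
    p_values = p_values or {}
    rows = []
    for pid, cluster in labels.items():
        matched = sorted(db.compounds[pid] & focal_compounds)
        if not matched:
            continue
        row = {
            "cluster": int(cluster),
            "pathway_id": pid,
            "p_value": p_values.get(pid, float("nan")),
            "n_matched": len(matched),
            "matched_compounds": ",".join(matched),
        }
        if enrichment_p:
            M, n, N, k = len(universe), len(universe & focal_compounds), len(db.compounds[pid]), len(matched)
            row["enrichment_p"] = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append(row)
    cols = ["cluster", "pathway_id", "p_value", "n_matched", "matched_compounds"]
    if enrichment_p:
        cols.append("enrichment_p")
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df = df.sort_values(
            ["cluster", "n_matched", "p_value", "pathway_id"], ascending=[True, False, True, True]
        ).reset_index(drop=True)
    return df
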