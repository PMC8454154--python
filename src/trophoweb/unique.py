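"""Unique (soil-absent) microbial taxa and prevalence/abundance filters.

A taxon is *unique* to a faunal group when it is detected (>= 1 read,
post-rarefaction) in at least one sample of that group but in no soil
sample at any site.  Soil exclusion is absolute: a single soil read
disqualifies an OTU everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import OtuTable, SampleMetadata


@dataclass
class UniqueTaxaReport:
    by_group: dict[str, set[str]]
    per_sample_counts: pd.Series  # faunal sample -> number of unique OTUs present
    soil_detected: set[str]
    thresholds: dict = field(default_factory=dict)

    def all_unique(self) -> set[str]:
        out: set[str] = set()
        for s in self.by_group.values():
            out |= s
        return out


def unique_otus(table: OtuTable, metadata: SampleMetadata) -> UniqueTaxaReport:
    """Per-group sets of OTUs detected in the group but in no soil sample."""
    meta = metadata.aligned_to(table)
    soil_ids = [s for s in meta.soil_sample_ids() if s in table.sample_ids]
    if not soil_ids:
        raise ValueError("no soil samples present: cannot define uniqueness")
    pres = table.counts > 0
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    soil_mask = pres[[idx[s] for s in soil_ids]].any(axis=0)
    soil_detected = {o for o, m in zip(table.otu_ids, soil_mask) if m}

    by_group: dict[str, set[str]] = {}
    groups = meta.frame.loc[meta.faunal_sample_ids(), "sample_type"].unique()
    for g in groups:
        gids = [
            s
            for s in meta.frame.index[meta.frame["sample_type"] == g]
            if s in idx
        ]
        gmask = pres[[idx[s] for s in gids]].any(axis=0)
        by_group[str(g)] = {
            o for o, m, s in zip(table.otu_ids, gmask, soil_mask) if m and not s
        }

    unique_all = set().union(*by_group.values()) if by_group else set()
    ucols = np.array([o in unique_all for o in table.otu_ids])
    fauna_ids = [s for s in meta.faunal_sample_ids() if s in idx]
    per_sample = pd.Series(
        {s: int(pres[idx[s]][ucols].sum()) for s in fauna_ids}, name="unique_count"
    )
    return UniqueTaxaReport(
        by_group=by_group, per_sample_counts=per_sample, soil_detected=soil_detected
    )


def prevalence_abundance_filter(
    table: OtuTable,
    scope_samples: list[str] | None = None,
    min_max_rel_abund: float = 0.003,
    min_prevalence: float = 0.70,
) -> set[str]:
    """OTUs passing the joint dominance filter within a sample scope.

    Keeps OTUs whose *maximum* per-sample relative abundance exceeds
    ``min_max_rel_abund`` (strict >) AND whose detection prevalence across
    the scope exceeds ``min_prevalence`` (strict >).  The two conditions
    commute.  Default thresholds are 0.3% maximal abundance and 70%
    prevalence; other useful pairs are (5%, 0), (1%, 50%), (0.1%, 80%).
    """
    if not (0 <= min_max_rel_abund <= 1 and 0 <= min_prevalence <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    sub = table if scope_samples is None else table.select_samples(list(scope_samples))
    if sub.n_samples == 0:
        raise ValueError("empty sample scope")
    rel = sub.relative_abundance()
    max_rel = rel.max(axis=0)
    prevalence = (sub.counts > 0).mean(axis=0)
    keep = (max_rel > min_max_rel_abund) & (prevalence > min_prevalence)
    return {o for o, k in zip(sub.otu_ids, keep) if k}


def shared_otu_counts(
    table: OtuTable, metadata: SampleMetadata, group_field: str = "sample_type"
) -> dict:
    """Venn-region counts of detected-OTU sets across groups.

    Returns region counts keyed by frozenset of group names (the groups
    whose sets the region lies inside and no others) plus the fraction of
    all detected OTUs shared by every group.  Limited to six groups.
    """
    meta = metadata.aligned_to(table)
    groups = list(pd.unique(meta.frame[group_field].astype(str)))
    if not 2 <= len(groups) <= 6:
        raise ValueError("Venn partition supports 2-6 groups; use pairwise beyond")
    pres = table.counts > 0
    idx = {s: i for i, s in enumerate(table.sample_ids)}
    detected: dict[str, set[str]] = {}
    for g in groups:
        gids = [s for s in meta.frame.index[meta.frame[group_field].astype(str) == g]]
        mask = pres[[idx[s] for s in gids]].any(axis=0)
        detected[g] = {o for o, m in zip(table.otu_ids, mask) if m}
    universe = set().union(*detected.values())
    regions: dict[frozenset, int] = {}
    for r in range(1, len(groups) + 1):
        for inside in combinations(groups, r):
            inter = set.intersection(*(detected[g] for g in inside))
            outer = set().union(*(detected[g] for g in groups if g not in inside), set())
            regions[frozenset(inside)] = len(inter - outer)
    shared_all = set.intersection(*(detected[g] for g in groups))
    return {
        "regions": regions,
        "detected": detected,
        "fraction_shared_all": len(shared_all) / len(universe) if universe else 0.0,
    }


def unique_counts_by_level(
    report: UniqueTaxaReport,
    trophic: pd.DataFrame,
    metadata: SampleMetadata,
) -> tuple[pd.DataFrame, sps._stats_py.SignificanceResult]:
    """Unique-taxon counts per trophic level plus a monotone-trend test.

    ``trophic`` is the frame from :func:`trophoweb.trophic.assign_from_metadata`.
    The trend statistic is the Spearman rank correlation between each
    faunal sample's unique-OTU count and its trophic level.
    """
    meta = metadata.frame
    counts = report.per_sample_counts
    tl = trophic.loc[counts.index, "trophic_level"]
    per_level_sets: dict[int, set[str]] = {}
    for sid in counts.index:
        g = str(meta.loc[sid, "sample_type"])
        per_level_sets.setdefault(int(tl[sid]), set()).update(report.by_group.get(g, set()))
    rows = [
        {
            "trophic_level": level,
            "n_unique_otus": len(per_level_sets[level]),
            "mean_per_sample": float(counts[tl == level].mean()),
            "n_samples": int((tl == level).sum()),
        }
        for level in sorted(per_level_sets)
    ]
    trend = sps.spearmanr(tl.to_numpy(), counts.to_numpy())
    return pd.DataFrame(rows), trend
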