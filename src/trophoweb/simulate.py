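"""Synthetic soil food-web microbiome studies with planted ground truth.

The generator emulates a multi-site survey of soil-invertebrate microbiomes:
six faunal groups plus bulk soil, sampled at several sites under two land
uses.  Every structural feature that the downstream analyses are meant to
detect is planted explicitly, so each stage of the pipeline can be tested
against a known answer:

* a shared, lognormal soil source pool from which all communities draw;
* per-group neutral (Dirichlet–multinomial) assembly with a configurable
  migration parameter ``Nm`` — the exact distributional assumption under
  which the Sloan occurrence-frequency prediction holds;
* per-group *unique* OTUs that never receive a single read in any soil
  sample (a hard guarantee, not a probabilistic one), with counts that do
  not decrease with the group's trophic level;
* a delta-15N gradient: adjusted values centre on ``(TL - 1) * 3.4`` permil
  with Gaussian noise (default sd 0.8 permil — small relative to the 3.4
  permil bin so planted levels are recoverable, yet misassignment edge
  cases occur);
* planted enterotypes per group, realised as Dirichlet tilts toward a
  driver genus;
* a configurable fraction of OTUs whose class- and genus-rank labels are
  replaced by unknown markers (microbial dark matter).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .io import RANKS, OtuTable, SampleMetadata, TaxonomyTable
import pandas as pd

ENRICHMENT_PER_LEVEL = 3.4  # permil delta-15N per trophic transfer

#: Default per-group design: integer trophic level, planted-unique count,
#: neutral migration Nm, and number of planted enterotypes.  Unique counts
#: are lowest for soil/litter feeders and highest for predators; Nm defaults
#: follow the ordering collembolan > predatory mite > earthworm > oribatid
#: mite > potworm > nematode.
DEFAULT_GROUPS: dict[str, dict] = {
    "earthworm": dict(trophic_level=1, n_unique=15, Nm=1802.0, k_enterotypes=2),
    "collembolan": dict(trophic_level=2, n_unique=15, Nm=4026.0, k_enterotypes=2),
    "potworm": dict(trophic_level=2, n_unique=30, Nm=999.0, k_enterotypes=3),
    "nematode": dict(trophic_level=3, n_unique=40, Nm=667.0, k_enterotypes=2),
    "oribatid_mite": dict(trophic_level=4, n_unique=60, Nm=1369.0, k_enterotypes=3),
    "predatory_mite": dict(trophic_level=5, n_unique=80, Nm=2103.0, k_enterotypes=2),
}

UNKNOWN_RANK_MARKERS = ("unknown", "unassigned", "Ambiguous taxa", "uncultured", "uncultured bacterium", "NA")

PHYLA = (
    "Proteobacteria",
    "Actinobacteria",
    "Bacteroidetes",
    "Firmicutes",
    "Verrucomicrobia",
    "Acidobacteria",
    "Tenericutes",
    "Chloroflexi",
)


@dataclass
class SimConfig:
    """Configuration of one synthetic study."""

    n_sites: int = 6
    landuses: tuple[str, ...] = ("farmland", "forest")
    groups: dict[str, dict] = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_GROUPS.items()})
    n_individuals: int = 5  # faunal samples per group x site x landuse
    n_soil_per_site: int = 5  # soil samples per site x landuse
    n_otus_shared: int = 1000
    read_depth: int = 15000  # raw reads per sample, above the 13551 rarefaction depth
    soil_Nm: float = 3000.0
    delta15N_noise_sd: float = 0.8
    site_tilt_sd: float = 0.25
    group_tilt_sd: float = 0.3  # host-filter tilt sd for the top trophic level
    filter_sd_per_level: float = 0.3  # extra tilt sd per level below the top
    driver_mass_fraction: float = 0.3  # pool mass share of an enterotype's driver genus
    unique_mass_fraction: float = 0.08  # pool mass share of a group's planted
    # uniques; sized so each unique taxon stays observable (>=100 reads
    # study-wide) under the global min-count filter at realistic depths
    unknown_label_fraction: float = 0.3
    unique_min_reads: int = 120  # guaranteed study-wide total per planted unique
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.unknown_label_fraction <= 1.0:
            raise ValueError("unknown_label_fraction must be in [0, 1]")
        if self.n_sites < 1 or self.n_individuals < 0 or self.n_otus_shared < 2:
            raise ValueError("invalid study dimensions")
        for g, spec in self.groups.items():
            if spec.get("Nm", 1.0) <= 0:
                raise ValueError(f"Nm must be > 0 for group {g!r}")
            if spec.get("n_unique", 0) < 0:
                raise ValueError(f"n_unique must be >= 0 for group {g!r}")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for downstream recovery tests."""

    unique_otus: dict[str, set[str]]
    trophic_level: dict[str, int]  # per faunal sample
    nm: dict[str, float]
    enterotype: dict[str, str]  # per faunal sample
    unknown_otus: set[str]
    driver_genus: dict[str, str]  # enterotype label -> driver genus

    def to_json(self, path: str | Path) -> None:
        doc = {
            "unique_otus": {g: sorted(s) for g, s in self.unique_otus.items()},
            "trophic_level": self.trophic_level,
            "nm": self.nm,
            "enterotype": self.enterotype,
            "unknown_otus": sorted(self.unknown_otus),
            "driver_genus": self.driver_genus,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def simulate_source_pool(n_otus: int, seed: int | np.random.Generator = 0, sigma: float = 1.5) -> np.ndarray:
    """Lognormal rank-abundance source pool, strictly positive, summing to 1."""
    if n_otus < 2:
        raise ValueError("a source pool needs at least 2 OTUs")
    rng = np.random.default_rng(seed)
    abund = rng.lognormal(mean=0.0, sigma=sigma, size=n_otus)
    abund = np.maximum(abund, 1e-300)
    return abund / abund.sum()


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw tolerating structural zeros in the concentration."""
    g = np.zeros_like(alpha, dtype=float)
    pos = alpha > 0
    g[pos] = rng.gamma(alpha[pos])
    total = g.sum()
    if total <= 0:  # all tiny shapes underflowed; fall back to the mean
        g[pos] = alpha[pos]
        total = g.sum()
    return g / total


def simulate_neutral_community(
    pool: np.ndarray,
    N: int,
    m: float,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    sample_prefix: str = "s",
    otu_ids: list[str] | None = None,
) -> OtuTable:
    """Neutral Dirichlet–multinomial communities from a fixed source pool.

    Each sample's latent composition is Dirichlet(``N*m*pool``) and its reads
    a multinomial of size ``N`` — the generative counterpart of the Sloan
    occurrence-frequency model, under which the beta-CDF prediction used by
    the fitting routine is exact.
    """
    if not 0 < m <= 1:
        raise ValueError("migration probability m must be in (0, 1]")
    if N < 1:
        raise ValueError("community size N must be >= 1")
    pool = np.asarray(pool, dtype=float)
    rng = np.random.default_rng(seed)
    alpha = N * m * pool
    counts = np.zeros((n_samples, pool.size), dtype=np.int64)
    for i in range(n_samples):
        latent = _dirichlet(rng, alpha)
        counts[i] = rng.multinomial(N, latent)
    ids = [f"{sample_prefix}{i}" for i in range(n_samples)]
    if otu_ids is None:
        otu_ids = [f"otu{j}" for j in range(pool.size)]
    return OtuTable(counts, ids, otu_ids)


def _simulate_tree(otu_ids: list[str], rng: np.random.Generator) -> TreeNode:
    """Random binary tree over all OTUs by successive seeded pairing."""
    nodes = [f"{oid}:{rng.exponential(0.5):.6f}" for oid in otu_ids]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append(f"({a},{b}):{rng.exponential(0.5):.6f}")
    newick = f"({nodes[0]})root;" if len(otu_ids) == 1 else nodes[0].rsplit(":", 1)[0] + ";"
    import io as _io

    return TreeNode.read(_io.StringIO(newick))


def _simulate_taxonomy(
    otu_ids: list[str], rng: np.random.Generator, unknown_fraction: float
) -> tuple[TaxonomyTable, set[str], dict[str, list[str]]]:
    """Assign 7-rank lineages; a fraction get unknown class & genus labels.

    Returns the taxonomy, the set of unknown-flagged OTU ids, and a map
    genus -> member OTU ids (known genera only).
    """
    n = len(otu_ids)
    n_genera = max(2, n // 5)
    genus_names = [f"Genus{k:04d}" for k in range(n_genera)]
    genus_idx = rng.integers(n_genera, size=n)
    n_unknown = int(round(unknown_fraction * n))
    unknown_pick = rng.choice(n, size=n_unknown, replace=False) if n_unknown else np.array([], dtype=int)
    unknown_set = {otu_ids[i] for i in unknown_pick}
    lineages: dict[str, list[str]] = {}
    genus_members: dict[str, list[str]] = {}
    for i, oid in enumerate(otu_ids):
        phylum = PHYLA[int(genus_idx[i]) % len(PHYLA)]
        genus = genus_names[genus_idx[i]]
        lineage = [
            "Bacteria",
            phylum,
            f"{phylum}_class",
            f"{phylum}_order",
            f"Family{genus_idx[i] % 97:03d}",
            genus,
            f"{genus}_sp",
        ]
        if oid in unknown_set:
            lineage[2] = str(rng.choice(UNKNOWN_RANK_MARKERS))  # class
            lineage[5] = str(rng.choice(UNKNOWN_RANK_MARKERS))  # genus
            lineage[6] = "unknown"
        else:
            genus_members.setdefault(genus, []).append(oid)
        lineages[oid] = lineage
    return TaxonomyTable(lineages), unknown_set, genus_members


def simulate_foodweb_dataset(
    config: SimConfig,
) -> tuple[OtuTable, TaxonomyTable, SampleMetadata, TreeNode, GroundTruth]:
    """Generate one complete synthetic study.

    Soil samples are neutral draws from the shared source pool.  Faunal
    samples are neutral draws from a group-biased pool (lognormal Dirichlet
    tilt per group and mild site/landuse tilts) augmented with the group's
    planted unique OTUs, which carry zero concentration in every soil
    sample's pool and therefore can never appear in soil.
    """
    rng = np.random.default_rng(config.seed)
    groups = list(config.groups)
    tl_of = {g: int(config.groups[g]["trophic_level"]) for g in groups}
    # monotone design check: unique counts nondecreasing in trophic level
    order = sorted(groups, key=lambda g: tl_of[g])
    uniq_counts = [int(config.groups[g].get("n_unique", 0)) for g in order]
    if any(b < a for a, b in zip(uniq_counts, uniq_counts[1:])):
        raise ValueError("n_unique must be nondecreasing with trophic level")

    n_shared = config.n_otus_shared
    shared_ids = [f"otu{j:05d}" for j in range(n_shared)]
    unique_ids: dict[str, list[str]] = {}
    next_id = n_shared
    for g in groups:
        k = int(config.groups[g].get("n_unique", 0))
        unique_ids[g] = [f"otu{j:05d}" for j in range(next_id, next_id + k)]
        next_id += k
    all_ids = shared_ids + [o for g in groups for o in unique_ids[g]]
    n_total = len(all_ids)

    pool_shared = simulate_source_pool(n_shared, rng)
    soil_pool = np.zeros(n_total)
    soil_pool[:n_shared] = pool_shared  # uniques: structural zero in soil

    # Per-group biased pools.  Host filtering (the lognormal tilt) weakens
    # with trophic level: generalist predators integrate over many prey
    # microbiomes, so their effective pool is broader and more even — this
    # plants the positive diversity-vs-trophic-level gradient.
    tl_max = max(tl_of.values())
    group_pool: dict[str, np.ndarray] = {}
    for g in groups:
        tilt_sd = config.group_tilt_sd + config.filter_sd_per_level * (tl_max - tl_of[g])
        tilt = rng.lognormal(0.0, tilt_sd, size=n_shared)
        base = pool_shared * tilt
        base = base / base.sum() * (1.0 - (config.unique_mass_fraction if unique_ids[g] else 0.0))
        vec = np.zeros(n_total)
        vec[:n_shared] = base
        if unique_ids[g]:
            w = rng.lognormal(0.0, 0.3, size=len(unique_ids[g]))
            w = w / w.sum() * config.unique_mass_fraction
            for oid, wi in zip(unique_ids[g], w):
                vec[all_ids.index(oid)] = wi
        group_pool[g] = vec / vec.sum()

    site_tilts = {
        s: rng.lognormal(0.0, config.site_tilt_sd, size=n_total) for s in range(config.n_sites)
    }
    landuse_tilts = {
        lu: rng.lognormal(0.0, config.site_tilt_sd / 2, size=n_total) for lu in config.landuses
    }

    taxonomy, unknown_set, genus_members = _simulate_taxonomy(
        all_ids, rng, config.unknown_label_fraction
    )
    otu_pos = {o: j for j, o in enumerate(all_ids)}

    # planted enterotypes: per group, k driver genera (known-labelled, well
    # populated) whose member OTUs get an abundance boost
    big_genera = sorted(genus_members, key=lambda g: -len(genus_members[g]))
    driver_genus: dict[str, str] = {}
    group_et_labels: dict[str, list[str]] = {}
    gi = 0
    for g in groups:
        k = int(config.groups[g].get("k_enterotypes", 2))
        labels = []
        for c in range(k):
            genus = big_genera[gi % len(big_genera)]
            gi += 1
            label = f"{g[0].upper()}{c}_{genus}"
            driver_genus[label] = genus
            labels.append(label)
        group_et_labels[g] = labels

    litter = {s: float(rng.uniform(-2.0, 4.0)) for s in range(config.n_sites)}

    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    truth_tl: dict[str, int] = {}
    truth_et: dict[str, str] = {}
    N = config.read_depth

    def draw(pool_vec: np.ndarray, nm: float) -> np.ndarray:
        alpha = nm * pool_vec  # Nm * pool: Dirichlet concentration
        latent = _dirichlet(rng, alpha)
        return rng.multinomial(N, latent)

    for s in range(config.n_sites):
        site = f"site{s+1}"
        for lu in config.landuses:
            # soil
            for r in range(config.n_soil_per_site):
                sid = f"soil_{site}_{lu}_{r+1}"
                vec = soil_pool * site_tilts[s] * landuse_tilts[lu]
                vec = vec / vec.sum()
                vec[n_shared:] = 0.0  # re-assert the hard zero after tilting
                vec = vec / vec.sum()
                rows.append(draw(vec, config.soil_Nm))
                sample_ids.append(sid)
                meta_rows.append(
                    dict(
                        sample_id=sid,
                        sample_type="soil",
                        species="soil",
                        site=site,
                        landuse=lu,
                        delta15N_animal=np.nan,
                        delta15N_litter=litter[s],
                    )
                )
            # fauna
            for g in groups:
                nm = float(config.groups[g]["Nm"])
                ets = group_et_labels[g]
                for r in range(config.n_individuals):
                    sid = f"{g}_{site}_{lu}_{r+1}"
                    et = ets[int(rng.integers(len(ets)))]
                    vec = group_pool[g] * site_tilts[s] * landuse_tilts[lu]
                    vec = vec / vec.sum()
                    # the enterotype's driver genus takes a fixed dominant
                    # share of the pool (overrepresentation by construction)
                    members = np.array(
                        [otu_pos[oid] for oid in genus_members[driver_genus[et]]]
                    )
                    mass = vec[members].sum()
                    if mass > 0:
                        share = config.driver_mass_fraction
                        scale = np.full(n_total, (1.0 - share) / (1.0 - mass))
                        scale[members] = share / mass
                        vec = vec * scale
                        vec = vec / vec.sum()
                    rows.append(draw(vec, nm))
                    tl = tl_of[g]
                    adj = (tl - 1) * ENRICHMENT_PER_LEVEL + rng.normal(0.0, config.delta15N_noise_sd)
                    sample_ids.append(sid)
                    meta_rows.append(
                        dict(
                            sample_id=sid,
                            sample_type=g,
                            species=f"{g}_sp1",
                            site=site,
                            landuse=lu,
                            delta15N_animal=litter[s] + adj,
                            delta15N_litter=litter[s],
                        )
                    )
                    truth_tl[sid] = tl
                    truth_et[sid] = et

    counts = np.vstack(rows)
    # Detection floor: the soil survey represents the full source pool, and
    # every planted unique OTU is observed in its own group.  Rare taxa that
    # drew zero reads get one read moved from the dominant taxon of a seeded
    # sample of the right kind (row sums are preserved).  This makes the
    # planted unique sets *exactly* the operationally unique ones.
    soil_rows = [i for i, s in enumerate(sample_ids) if meta_rows[i]["sample_type"] == "soil"]
    group_rows = {
        g: [i for i, s in enumerate(sample_ids) if meta_rows[i]["sample_type"] == g]
        for g in groups
    }
    for j in range(n_shared):
        if counts[soil_rows, j].sum() == 0:
            i = soil_rows[int(rng.integers(len(soil_rows)))]
            counts[i, int(np.argmax(counts[i]))] -= 1
            counts[i, j] += 1
    for g in groups:
        rows_g = group_rows[g]
        if not rows_g or not unique_ids[g]:
            continue
        group_total = int(counts[rows_g].sum())
        # Planted uniques are guaranteed enough reads to survive the study's
        # global min-count filter.  The floor only clips the lower tail: it
        # never exceeds twice the natural expected per-unique total, so
        # shallow simulations are not distorted.
        expected = group_total * config.unique_mass_fraction / len(unique_ids[g])
        floor = min(config.unique_min_reads, int(2 * expected))
        for oid in unique_ids[g]:
            j = otu_pos[oid]
            deficit = floor - int(counts[rows_g, j].sum())
            for _ in range(max(deficit, 0)):
                i = rows_g[int(rng.integers(len(rows_g)))]
                donor = int(np.argmax(counts[i]))
                counts[i, donor] -= 1
                counts[i, j] += 1

    table = OtuTable(counts, sample_ids, all_ids)
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    tree = _simulate_tree(all_ids, rng)
    truth = GroundTruth(
        unique_otus={g: set(unique_ids[g]) for g in groups},
        trophic_level=truth_tl,
        nm={g: float(config.groups[g]["Nm"]) for g in groups},
        enterotype=truth_et,
        unknown_otus=unknown_set,
        driver_genus=driver_genus,
    )
    return table, taxonomy, meta, tree, truth
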