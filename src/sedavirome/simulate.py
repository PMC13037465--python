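"""Synthetic sediment-core generator with known ground truth.

Emits everything the pipeline consumes -- an NCBI-dump-like taxonomy, an
LCA-style assigned-count table over multi-site time series, sample
metadata, a curated virus-host pairing table, a VMR-style name table,
blank samples, and per-contig positional C-to-T damage counts -- from a
single seed, with the planted parameters recorded in a truth object so
every recovery property can be scored.

What is emulated
----------------
* environment-specific viral species pools (lake vs marine) with a planted
  shared fraction and one hyper-dominant taxon per environment;
* host-group trajectories as logistic-transformed Gaussian random walks
  with an epoch change-point in the drift, and virus groups coupled to
  them with a planted sign (+/-/0) and strength;
* an optionally planted "decoupled strain": one host strain following an
  independent pulse anchored at an event age, independent of the group's
  viruses;
* low-level blank contamination as Poisson carry-over from the pooled
  sample composition;
* binomially sampled positional C-to-T counts under the end-enriched
  decay model.

Observation noise enters only through multinomial read sampling; all
randomness flows from one seed through a fixed spawn order of
numpy SeedSequence streams (pools, one per site, blanks, damage).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .damage import ContigRecord, DamagePositionCounts
from .tables import CountMatrix, DEFAULT_EPOCH_BOUNDARY
from .taxonomy import TaxonomyTree

__all__ = [
    "SimulationError",
    "SiteConfig",
    "PoolConfig",
    "CouplingConfig",
    "DamageClassConfig",
    "DecoupledStrainConfig",
    "SimConfig",
    "SimResult",
    "simulate_core_set",
    "simulate_decoupled_strain",
    "simulate_damage_counts",
    "write_core_set",
]


class SimulationError(ValueError):
    """Invalid simulation configuration (message names the field)."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SiteConfig:
    name: str
    environment: str  # lake | marine
    age_min: float  # cal ka BP
    age_max: float
    n_samples: int = 30
    depth_log_mean: float = math.log(2e5)
    depth_log_sigma: float = 0.3


@dataclass(frozen=True)
class PoolConfig:
    """Per-environment viral species pool."""

    size: int = 120
    shared_fraction: float = 0.2  # target shared share of distinct species
    abundance_sigma: float = 1.0  # lognormal sigma of base species weights
    dominant_boost: float = 50.0  # x the largest independent weight

    @property
    def n_shared(self) -> int:
        f = self.shared_fraction
        return int(round(2 * self.size * f / (1 + f))) if f > 0 else 0


@dataclass(frozen=True)
class CouplingConfig:
    """One virus group coupled to a host group's trajectory."""

    name: str
    environment: str
    host_genus: str
    host_domain: str  # bacteria | eukaryota | archaea
    n_viruses: int = 6
    sign: int = 1  # +1 coupled, -1 antagonistic, 0 null
    strength: float = 0.9
    host_weight: float = 0.04  # base share of all mapped reads
    virus_weight: float = 0.12  # share of the viral block
    pleistocene_drift: float = 0.0  # latent drift per ka, age > boundary
    holocene_drift: float = 0.0
    phage_named: bool = True  # "<genus> phage simN" vs "<genus> virus simN"


@dataclass(frozen=True)
class DamageClassConfig:
    b: float = 0.01
    A: float = 0.15
    lam: float = 0.35
    n_contigs: int = 30
    n_per_position: int = 10_000
    positions: int = 25


@dataclass(frozen=True)
class DecoupledStrainConfig:
    """Pulse trajectory for one host strain, independent of the viruses."""

    site: str
    group: str  # coupling name
    amplitude: float = 6.0  # x the host group's base weight at pulse peak
    event_age: float = 12.4  # cal ka BP, pulse onset (old edge)
    end_age: float = 4.7  # pulse offset (young edge)
    rise: float = 0.6  # ka, onset smoothness
    decline: float = 0.8


def _default_sites() -> tuple[SiteConfig, ...]:
    return (
        SiteConfig("lake1", "lake", 0.2, 24.0),
        SiteConfig("lake2", "lake", 0.1, 30.0),
        SiteConfig("marine1", "marine", 0.5, 24.0),
        SiteConfig("marine2", "marine", 1.0, 20.0),
    )


def _default_couplings() -> tuple[CouplingConfig, ...]:
    return (
        CouplingConfig(
            "pelagiphage", "marine", "Pelagibacter", "bacteria",
            n_viruses=6, sign=1, strength=0.99,
            host_weight=0.05, virus_weight=0.25,
        ),
        CouplingConfig(
            "cyanophage", "marine", "Synechococcus", "bacteria",
            n_viruses=5, sign=-1, strength=0.9,
            host_weight=0.03, virus_weight=0.10,
            pleistocene_drift=-0.05, holocene_drift=0.20,
        ),
        CouplingConfig(
            "marine-null", "marine", "Colwellia", "bacteria",
            n_viruses=4, sign=0, strength=0.0,
            host_weight=0.02, virus_weight=0.08,
        ),
        CouplingConfig(
            "haptovirus", "lake", "Chrysochromulina", "eukaryota",
            n_viruses=6, sign=1, strength=0.9,
            host_weight=0.04, virus_weight=0.12,
            pleistocene_drift=-0.05, holocene_drift=0.20,
            phage_named=False,
        ),
        CouplingConfig(
            "flavophage", "lake", "Flavobacterium", "bacteria",
            n_viruses=5, sign=-1, strength=0.9,
            host_weight=0.03, virus_weight=0.10,
        ),
        CouplingConfig(
            "archaea-null", "lake", "Nitrosopumilus", "archaea",
            n_viruses=4, sign=0, strength=0.0,
            host_weight=0.02, virus_weight=0.08,
        ),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full study conditions for one synthetic core set."""

    seed: int = 0
    sites: tuple = field(default_factory=_default_sites)
    pool: PoolConfig = field(default_factory=PoolConfig)
    couplings: tuple = field(default_factory=_default_couplings)
    viral_share: float = 0.005  # viral share of mapped reads
    n_blanks: int = 12
    blank_read_mean: float = 150.0
    epoch_boundary: float = DEFAULT_EPOCH_BOUNDARY
    walk_sigma: float = 0.35  # latent step sd per sqrt(ka)
    damage: tuple = (
        ("virus", DamageClassConfig(b=0.01, A=0.15, lam=0.35)),
        ("bacteria", DamageClassConfig(b=0.012, A=0.14, lam=0.30)),
    )
    decoupled_strain: DecoupledStrainConfig | None = None

    def validate(self) -> None:
        if not 0 <= self.pool.shared_fraction <= 1:
            raise SimulationError("pool.shared_fraction must be in [0, 1]")
        if not 0 < self.viral_share < 1:
            raise SimulationError("viral_share must be in (0, 1)")
        if self.n_blanks < 0 or self.blank_read_mean < 0:
            raise SimulationError("blank settings must be non-negative")
        envs = {s.environment for s in self.sites}
        if not envs <= {"lake", "marine"}:
            raise SimulationError("sites.environment must be lake or marine")
        for s in self.sites:
            if s.age_max <= s.age_min:
                raise SimulationError(f"sites[{s.name}].age_max must exceed age_min")
            if s.n_samples < 2:
                raise SimulationError(f"sites[{s.name}].n_samples must be >= 2")
        for c in self.couplings:
            if not 0 <= c.strength <= 1:
                raise SimulationError(f"couplings[{c.name}].strength must be in [0, 1]")
            if c.sign not in (-1, 0, 1):
                raise SimulationError(f"couplings[{c.name}].sign must be -1, 0 or 1")
            if c.host_domain not in ("bacteria", "eukaryota", "archaea"):
                raise SimulationError(f"couplings[{c.name}].host_domain unknown")
        for label, d in self.damage:
            if not (0 <= d.b and 0 <= d.A and d.b + d.A <= 1 and 0 < d.lam <= 1):
                raise SimulationError(f"damage[{label}] parameters out of model bounds")
        env_vw = {"lake": 0.0, "marine": 0.0}
        for c in self.couplings:
            env_vw[c.environment] += c.virus_weight
        if max(env_vw.values()) >= 1:
            raise SimulationError("couplings.virus_weight must sum below 1 per environment")

    @classmethod
    def default(cls, seed: int = 0) -> "SimConfig":
        return cls(seed=seed)

    @classmethod
    def compact(
        cls, seed: int = 0, sites_per_env: int = 1, n_samples: int = 30,
        pool_size: int = 60,
    ) -> "SimConfig":
        """Smaller variant for replicated recovery loops."""
        base = _default_sites()
        sites = []
        for env in ("lake", "marine"):
            for s in [b for b in base if b.environment == env][:sites_per_env]:
                sites.append(replace(s, n_samples=n_samples))
        return cls(
            seed=seed,
            sites=tuple(sites),
            pool=PoolConfig(size=pool_size),
            n_blanks=4,
        )


def simulate_decoupled_strain(
    config: SimConfig, site: str, group: str, **kwargs
) -> SimConfig:
    """Plant an independently pulsed host strain into ``config``.

    The named coupling's host genus gains one strain whose abundance
    follows a rise/plateau/decline pulse anchored at the event age while
    the group's viruses stay coupled to the rest of the genus.
    """
    if group not in {c.name for c in config.couplings}:
        raise SimulationError(f"couplings[{group}] does not exist")
    if site not in {s.name for s in config.sites}:
        raise SimulationError(f"sites[{site}] does not exist")
    return replace(
        config,
        decoupled_strain=DecoupledStrainConfig(site=site, group=group, **kwargs),
    )


# ---------------------------------------------------------------------------
# world construction


class _TaxBuilder:
    def __init__(self) -> None:
        self.parents: dict[int, int] = {1: 1}
        self.ranks: dict[int, str] = {1: "no-rank"}
        self.names: dict[int, str] = {1: "root"}
        self._next = 2

    def add(self, name: str, parent: int, rank: str) -> int:
        t = self._next
        self._next += 1
        self.parents[t] = parent
        self.ranks[t] = rank
        self.names[t] = name
        return t

    def tree(self) -> TaxonomyTree:
        return TaxonomyTree(self.parents, self.ranks, self.names, root=1)


_HOST_LINEAGES = {
    "Pelagibacter": ("bacteria", ("Pseudomonadota", "Alphaproteobacteria", "Pelagibacterales", "Pelagibacteraceae")),
    "Synechococcus": ("bacteria", ("Cyanobacteriota", "Cyanophyceae", "Synechococcales", "Synechococcaceae")),
    "Colwellia": ("bacteria", ("Pseudomonadota", "Gammaproteobacteria", "Alteromonadales", "Colwelliaceae")),
    "Flavobacterium": ("bacteria", ("Bacteroidota", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae")),
    "Chrysochromulina": ("eukaryota", ("Haptophyta", "Prymnesiophyceae", "Prymnesiales", "Prymnesiaceae")),
    "Nitrosopumilus": ("archaea", ("Nitrososphaerota", "Nitrososphaeria", "Nitrosopumilales", "Nitrosopumilaceae")),
}

_LINEAGE_RANKS = ("phylum", "class", "order", "family")


@dataclass
class _World:
    """Static structure shared by all sites: taxa and base weights."""

    tree: TaxonomyTree
    viruses_root: int
    background: int
    # per environment
    env_species: dict  # env -> list of species taxids (full pool)
    shared_species: list
    dominant: dict  # env -> taxid
    indep_weight: dict  # env -> {taxid: base weight}
    strain_of: dict  # species taxid -> strain taxid (30% of species weight)
    virus_genus_members: dict  # genus taxid -> [species taxids]
    host_genus: dict  # genus name -> taxid
    host_species: dict  # genus name -> [species taxids]
    host_split: dict  # genus name -> np.ndarray proportions
    coupling_taxa: dict  # coupling name -> [virus species taxids]
    host_group_node: dict  # coupling name -> aggregation-rank taxid
    strain_taxid: int | None
    orphan_phage: dict  # env -> taxid (name-inference-only phage)


def _build_world(config: SimConfig, rng: np.random.Generator) -> _World:
    tb = _TaxBuilder()
    viruses = tb.add("Viruses", 1, "superkingdom")
    bacteria = tb.add("Bacteria", 1, "superkingdom")
    eukaryota = tb.add("Eukaryota", 1, "superkingdom")
    archaea = tb.add("Archaea", 1, "superkingdom")
    sk = {"bacteria": bacteria, "eukaryota": eukaryota, "archaea": archaea}

    caudo = tb.add("Caudoviricetes", viruses, "class")
    mega = tb.add("Megaviricetes", viruses, "class")
    caudo_fam = tb.add("Caudoviricetes incertae sedis", caudo, "family")
    mega_fam = tb.add("Megaviricetes incertae sedis", mega, "family")

    # hosts ----------------------------------------------------------------
    lineage_nodes: dict[tuple, int] = {}
    host_genus: dict[str, int] = {}
    host_species: dict[str, list[int]] = {}
    host_split: dict[str, np.ndarray] = {}
    for genus_name, (domain, lineage) in _HOST_LINEAGES.items():
        parent = sk[domain]
        for rank, name in zip(_LINEAGE_RANKS, lineage):
            key = (domain, name, rank)
            if key not in lineage_nodes:
                lineage_nodes[key] = tb.add(name, parent, rank)
            parent = lineage_nodes[key]
        g = tb.add(genus_name, parent, "genus")
        host_genus[genus_name] = g
        host_species[genus_name] = [
            tb.add(f"{genus_name} sp. sim-{i + 1}", g, "species") for i in range(3)
        ]
        host_split[genus_name] = rng.dirichlet(np.full(3, 4.0))
    background = tb.add("uncultured bacterium", bacteria, "species")

    # viral pools ----------------------------------------------------------
    n_shared = config.pool.n_shared
    shared_species: list[int] = []
    genus_members: dict[int, list[int]] = {}

    def add_species_block(prefix, count, parent_fam, genus_prefix, start=0):
        out = []
        genus = None
        for i in range(count):
            if i % 8 == 0:
                genus = tb.add(
                    f"{genus_prefix} genus sim{start + i // 8 + 1}",
                    parent_fam, "genus",
                )
                genus_members[genus] = []
            t = tb.add(f"{prefix} sim{start + i + 1}", genus, "species")
            genus_members[genus].append(t)
            out.append(t)
        return out

    shared_species = add_species_block(
        "shared aquatic virus", n_shared, caudo_fam, "shared virome"
    )

    env_species: dict[str, list[int]] = {}
    dominant: dict[str, int] = {}
    indep_weight: dict[str, dict[int, float]] = {}
    coupling_taxa: dict[str, list[int]] = {}
    host_group_node: dict[str, int] = {}
    orphan_phage: dict[str, int] = {}
    strain_of: dict[int, int] = {}

    for env in ("lake", "marine"):
        env_coups = [c for c in config.couplings if c.environment == env]
        n_coupled = sum(c.n_viruses for c in env_coups)
        n_indep = config.pool.size - n_shared - n_coupled
        if n_indep < 2:
            raise SimulationError("pool.size too small for the configured couplings")

        # coupled virus groups: one genus each
        for c in env_coups:
            fam = caudo_fam if c.host_domain != "eukaryota" else mega_fam
            g = tb.add(f"Sim{c.host_genus.lower()}virus", fam, "genus")
            genus_members[g] = []
            taxa = []
            kind = "phage" if c.phage_named else "virus"
            for j in range(c.n_viruses):
                t = tb.add(f"{c.host_genus} {kind} sim{j + 1}", g, "species")
                genus_members[g].append(t)
                taxa.append(t)
            coupling_taxa[c.name] = taxa
            rank = {"bacteria": "genus", "eukaryota": "phylum", "archaea": "superkingdom"}[c.host_domain]
            node = host_genus[c.host_genus]
            while tb.ranks[node] != rank:
                node = tb.parents[node]
            host_group_node[c.name] = node

        # independent environment-unique species
        prefix = (
            "uncultured freshwater virus" if env == "lake" else "uncultured marine virus"
        )
        indep = add_species_block(prefix, n_indep, caudo_fam, f"{env} virome")
        # dominant pseudo-taxon mirrors an environmental mega-group
        dom_name = (
            "uncultured Caudovirales phage" if env == "lake" else "uncultured marine virus MD-1"
        )
        tb.names[indep[0]] = dom_name
        dominant[env] = indep[0]
        # one phage resolvable only through its trivial name
        orphan = indep[1]
        orphan_genus = "Flavobacterium" if env == "lake" else "Synechococcus"
        tb.names[orphan] = f"{orphan_genus} phage orphan-sim-{env}"
        orphan_phage[env] = orphan

        # base weights: lognormal; dominant = boost x the largest other weight
        w = rng.lognormal(0.0, config.pool.abundance_sigma, size=n_indep + n_shared)
        weights = dict(zip(indep + shared_species, w))
        others_max = max(v for t, v in weights.items() if t != dominant[env])
        weights[dominant[env]] = config.pool.dominant_boost * others_max
        indep_weight[env] = weights

        env_species[env] = (
            indep + shared_species + [t for c in env_coups for t in coupling_taxa[c.name]]
        )

        # strains under a few species (30 % of the species weight)
        for t in indep[2:5]:
            strain_of[t] = tb.add(f"{tb.names[t]} strain s1", t, "strain")

    # planted decoupled strain, allocated last so its presence leaves every
    # other taxid unchanged relative to a strain-free run
    strain_taxid = None
    if config.decoupled_strain is not None:
        grp = config.decoupled_strain.group
        coup = next(c for c in config.couplings if c.name == grp)
        sp0 = host_species[coup.host_genus][0]
        strain_taxid = tb.add(
            f"{coup.host_genus} sp. sim-1 strain ARC-1", sp0, "strain"
        )

    return _World(
        tree=tb.tree(),
        viruses_root=viruses,
        background=background,
        env_species=env_species,
        shared_species=shared_species,
        dominant=dominant,
        indep_weight=indep_weight,
        strain_of=strain_of,
        virus_genus_members=genus_members,
        host_genus=host_genus,
        host_species=host_species,
        host_split=host_split,
        coupling_taxa=coupling_taxa,
        host_group_node=host_group_node,
        strain_taxid=strain_taxid,
        orphan_phage=orphan_phage,
    )


# ---------------------------------------------------------------------------
# trajectories


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


_REVERSION = 0.08  # per ka; keeps the latent state in the logistic's responsive range


def _latent_walk(ages_desc, drift_pleist, drift_holo, sigma, boundary, rng):
    """Gaussian random walk over ages (oldest first) with drift switching at
    the epoch boundary and mild mean reversion."""
    z = np.empty(len(ages_desc))
    z[0] = rng.normal(0.0, 0.7)
    for i in range(1, len(ages_desc)):
        dt = ages_desc[i - 1] - ages_desc[i]
        drift = drift_pleist if ages_desc[i] > boundary else drift_holo
        z[i] = (
            z[i - 1] * math.exp(-_REVERSION * dt)
            + drift * dt
            + sigma * math.sqrt(dt) * rng.normal()
        )
    return z


def _pulse(ages, cfg: DecoupledStrainConfig):
    a = np.asarray(ages, dtype=float)
    return _sigmoid((cfg.event_age - a) / cfg.rise) * _sigmoid(
        (a - cfg.end_age) / cfg.decline
    )


# ---------------------------------------------------------------------------
# main simulation


@dataclass
class SimResult:
    config: SimConfig
    tree: TaxonomyTree
    counts: CountMatrix  # assigned-only
    annotations: pd.DataFrame  # taxid -> name, rank
    meta: pd.DataFrame
    pairs: pd.DataFrame
    vmr: pd.DataFrame
    contigs: list
    truth: dict


def simulate_core_set(config: SimConfig) -> SimResult:
    """Draw one synthetic core set under ``config``.

    Per sample, reads are drawn multinomially at a lognormal depth from
    the site's true composition at the sample's age; identical configs
    (including the seed) reproduce identical outputs.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(3 + len(config.sites))
    rng_pool = np.random.default_rng(streams[0])
    world = _build_world(config, rng_pool)
    tree = world.tree

    # fixed category order: every taxid that can receive assigned reads
    categories: list[int] = [world.viruses_root, world.background]
    for env in ("lake", "marine"):
        for t in world.env_species[env]:
            if t not in categories:
                categories.append(t)
    for t in world.strain_of.values():
        categories.append(t)
    for g, members in world.virus_genus_members.items():
        categories.append(g)
    for gname, g in world.host_genus.items():
        categories.append(g)
        categories.extend(world.host_species[gname])
    if world.strain_taxid is not None:
        categories.append(world.strain_taxid)
    cat_pos = {t: i for i, t in enumerate(categories)}

    env_coups = {
        env: [c for c in config.couplings if c.environment == env]
        for env in ("lake", "marine")
    }

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    count_cols: list[np.ndarray] = []
    weight_cols: list[np.ndarray] = []  # composition, for blanks
    truth_couplings: dict[str, dict] = {
        c.name: {
            "sign": c.sign,
            "strength": c.strength,
            "environment": c.environment,
            "host_domain": c.host_domain,
            "host_group": world.host_group_node[c.name],
            "host_genus": world.host_genus[c.host_genus],
            "virus_taxa": world.coupling_taxa[c.name],
            "per_site": {},
        }
        for c in config.couplings
    }
    strain_truth = None

    for site_cfg, stream in zip(config.sites, streams[1 : 1 + len(config.sites)]):
        rng = np.random.default_rng(stream)
        ages = np.sort(
            np.round(
                rng.uniform(site_cfg.age_min, site_cfg.age_max, site_cfg.n_samples), 4
            )
        )
        for i in range(1, len(ages)):  # enforce strictly increasing
            if ages[i] <= ages[i - 1]:
                ages[i] = ages[i - 1] + 1e-4
        ages_desc = ages[::-1]  # oldest first for the walks

        env = site_cfg.environment
        n = site_cfg.n_samples
        W = np.zeros((len(categories), n))  # columns follow ages_desc

        # hosts + coupled viruses
        for c in env_coups[env]:
            z_h = _latent_walk(
                ages_desc, c.pleistocene_drift, c.holocene_drift,
                config.walk_sigma, config.epoch_boundary, rng,
            )
            z_i = _latent_walk(ages_desc, 0.0, 0.0, config.walk_sigma,
                               config.epoch_boundary, rng)
            m_h = _sigmoid(z_h)
            if c.sign == 0:
                z_v = z_i
            else:
                z_v = c.strength * c.sign * z_h + (1.0 - c.strength) * z_i
            m_v = _sigmoid(z_v)

            hw = c.host_weight * m_h
            split = world.host_split[c.host_genus]
            for frac, sp in zip(split, world.host_species[c.host_genus]):
                W[cat_pos[sp]] += frac * hw * 0.98
            W[cat_pos[world.host_genus[c.host_genus]]] += 0.02 * hw

            members = world.coupling_taxa[c.name]
            vw = config.viral_share * c.virus_weight * m_v
            for t in members:
                W[cat_pos[t]] += vw / len(members)

            truth_couplings[c.name]["per_site"][site_cfg.name] = {
                # aligned with ascending-age sample order
                "ages": ages.tolist(),
                "m_host": m_h[::-1].tolist(),
                "m_virus": m_v[::-1].tolist(),
            }

            ds = config.decoupled_strain
            if ds is not None and ds.group == c.name and ds.site == site_cfg.name:
                pulse = _pulse(ages_desc, ds)
                W[cat_pos[world.strain_taxid]] += ds.amplitude * c.host_weight * pulse
                strain_truth = {
                    "taxid": world.strain_taxid,
                    "site": ds.site,
                    "group": ds.group,
                    "amplitude": ds.amplitude,
                    "event_age": ds.event_age,
                    "end_age": ds.end_age,
                    "pulse": pulse[::-1].tolist(),
                }

        # independent viral species (incl. shared + dominant)
        indep = world.indep_weight[env]
        total_w = sum(indep.values())
        coup_share = sum(c.virus_weight for c in env_coups[env])
        indep_block = config.viral_share * (1.0 - coup_share)
        for t, w in indep.items():
            base = indep_block * w / total_w
            if t in world.strain_of:
                W[cat_pos[t]] += 0.7 * base
                W[cat_pos[world.strain_of[t]]] += 0.3 * base
            else:
                W[cat_pos[t]] += base

        # genus-level and realm-level stragglers (reads the classifier could
        # not place at species level)
        for g, members in world.virus_genus_members.items():
            gsum = sum(W[cat_pos[t]].sum() for t in members)
            if gsum > 0:
                W[cat_pos[g]] += 0.03 * sum(W[cat_pos[t]] for t in members)
        W[cat_pos[world.viruses_root]] += 0.04 * config.viral_share

        # background fills the remainder
        W[cat_pos[world.background]] = np.maximum(1.0 - W.sum(axis=0), 0.05)

        depths = np.maximum(
            np.round(
                rng.lognormal(site_cfg.depth_log_mean, site_cfg.depth_log_sigma, n)
            ).astype(np.int64),
            1000,
        )
        P = W / W.sum(axis=0, keepdims=True)
        counts_desc = np.column_stack(
            [rng.multinomial(depths[j], P[:, j]) for j in range(n)]
        )

        # register samples youngest-first
        order = np.arange(n)[::-1]  # map ascending-age position -> column
        for pos, j in enumerate(order):
            sid = f"{site_cfg.name}_s{pos + 1:02d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "site": site_cfg.name,
                    "environment": env,
                    "age_cal_ka_bp": float(ages[pos]),
                }
            )
            count_cols.append(counts_desc[:, j])
            weight_cols.append(P[:, j])

    # blanks: Poisson carry-over from the pooled sample composition
    rng_blank = np.random.default_rng(streams[1 + len(config.sites)])
    pooled = np.mean(np.column_stack(weight_cols), axis=1)
    pooled = pooled / pooled.sum()
    for i in range(config.n_blanks):
        sid = f"blank_{i + 1:02d}"
        nreads = int(rng_blank.poisson(config.blank_read_mean))
        col = (
            rng_blank.multinomial(nreads, pooled)
            if nreads > 0
            else np.zeros(len(categories), dtype=np.int64)
        )
        sample_ids.append(sid)
        meta_rows.append(
            {
                "sample_id": sid,
                "site": "blank",
                "environment": "blank",
                "age_cal_ka_bp": float("nan"),
            }
        )
        count_cols.append(col)

    data = pd.DataFrame(
        np.column_stack(count_cols),
        index=pd.Index(categories, name="taxid"),
        columns=sample_ids,
    ).sort_index()
    counts = CountMatrix(data.astype("int64"), "assigned")
    annotations = pd.DataFrame(
        {
            "name": [tree.name(t) for t in data.index],
            "rank": [tree.rank(t) for t in data.index],
        },
        index=data.index,
    )
    meta = pd.DataFrame(meta_rows)
    meta["epoch"] = [
        ("Holocene" if a <= config.epoch_boundary else "Pleistocene")
        if np.isfinite(a)
        else None
        for a in meta["age_cal_ka_bp"]
    ]

    pairs, vmr = _pairing_tables(config, world, tree)

    # damage counts
    rng_dam = np.random.default_rng(streams[2 + len(config.sites)])
    contigs: list[ContigRecord] = []
    for label, dcfg in config.damage:
        if label == "virus":
            taxa = world.env_species["lake"][:10] + world.env_species["marine"][:10]
        else:
            taxa = [s for sps in world.host_species.values() for s in sps]
        contigs.extend(
            simulate_damage_counts(
                dcfg.b, dcfg.A, dcfg.lam, dcfg.n_per_position, dcfg.positions,
                dcfg.n_contigs, rng=rng_dam, taxa=taxa, prefix=f"{label}_contig",
            )
        )

    truth = {
        "seed": config.seed,
        "viral_share": config.viral_share,
        "epoch_boundary": config.epoch_boundary,
        "viruses_root": world.viruses_root,
        "background": world.background,
        "pool": {
            "size": config.pool.size,
            "shared_fraction_target": config.pool.shared_fraction,
            "n_shared": len(world.shared_species),
            "n_distinct": 2 * config.pool.size - len(world.shared_species),
            "shared_species": world.shared_species,
            "dominant": {env: world.dominant[env] for env in world.dominant},
            "dominant_boost": config.pool.dominant_boost,
        },
        "couplings": truth_couplings,
        "decoupled_strain": strain_truth,
        "damage": {
            label: dataclasses.asdict(d) for label, d in config.damage
        },
    }
    return SimResult(
        config=config,
        tree=tree,
        counts=counts,
        annotations=annotations,
        meta=meta,
        pairs=pairs,
        vmr=vmr,
        contigs=contigs,
        truth=truth,
    )


def _pairing_tables(config, world, tree):
    """Curated pairs for every coupled virus; VMR rows for a subset plus one
    deliberate conflict (curated list must win)."""
    pair_rows = []
    vmr_rows = []
    for c in config.couplings:
        hosts = world.host_species[c.host_genus]
        for j, v in enumerate(world.coupling_taxa[c.name]):
            h = hosts[j % len(hosts)]
            evidence = "VMR" if (c.name == "cyanophage" and j < 2) else "literature"
            pair_rows.append(
                [v, tree.name(v), h, tree.name(h), c.host_domain, evidence]
            )
            if c.name == "cyanophage" and j < 2:
                vmr_rows.append([tree.name(v), c.host_genus])
    # conflicting VMR row: first pelagiphage listed under the wrong genus
    first_pelagi = world.coupling_taxa["pelagiphage"][0] if "pelagiphage" in world.coupling_taxa else None
    if first_pelagi is not None:
        vmr_rows.append([tree.name(first_pelagi), "Synechococcus"])
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "virus_taxid", "virus_name", "host_taxid", "host_name",
            "host_domain", "evidence",
        ],
    )
    vmr = pd.DataFrame(vmr_rows, columns=["virus_name", "host_genus"])
    return pairs, vmr


def simulate_damage_counts(
    b: float,
    A: float,
    lam: float,
    n_per_position: int,
    positions: int,
    n_contigs: int,
    seed=None,
    rng=None,
    taxa=(0,),
    prefix: str = "contig",
) -> list[ContigRecord]:
    """Binomially sampled positional C->T counts under the decay model.

    k_x ~ Binomial(n_x, b + A(1-lam)^x); accuracy uniform on [0, 1] so the
    retention filter is exercised; lengths uniform on 0.8-5 kb.
    """
    if not (0 <= b and 0 <= A and b + A <= 1 and 0 < lam <= 1):
        raise SimulationError("damage parameters out of model bounds")
    if n_per_position < 0:
        raise SimulationError("n_per_position must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = np.arange(positions)
    f = b + A * (1 - lam) ** x
    taxa = list(taxa)
    out = []
    for i in range(n_contigs):
        n = np.full(positions, int(n_per_position), dtype=np.int64)
        k = rng.binomial(n, f)
        out.append(
            ContigRecord(
                contig_id=f"{prefix}_{i + 1:04d}",
                taxon=int(taxa[i % len(taxa)]),
                length=int(rng.integers(800, 5001)),
                accuracy=float(rng.uniform(0.0, 1.0)),
                counts=DamagePositionCounts(k=k, n=n),
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers


def write_core_set(result: SimResult, outdir) -> dict[str, Path]:
    """Write the synthetic set in the exact dialects the parsers consume."""
    from .damage import write_damage_records
    from .tables import write_lca_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": outdir / "nodes.tsv",
        "names": outdir / "names.tsv",
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.csv",
        "pairs": outdir / "pairs.csv",
        "vmr": outdir / "vmr.csv",
        "damage": outdir / "damage.tsv",
        "truth": outdir / "truth.json",
    }
    tree = result.tree
    nodes = pd.DataFrame(
        [[t, tree.parent(t), tree.rank(t)] for t in sorted(tree)],
        columns=["taxid", "parent", "rank"],
    )
    nodes.to_csv(paths["nodes"], sep="\t", index=False, header=False)
    names = pd.DataFrame(
        [[t, tree.name(t)] for t in sorted(tree)], columns=["taxid", "name"]
    )
    names.to_csv(paths["names"], sep="\t", index=False, header=False)
    write_lca_counts(result.counts, result.annotations, paths["counts"])
    result.meta.drop(columns=["epoch"]).to_csv(paths["metadata"], index=False)
    result.pairs.to_csv(paths["pairs"], index=False)
    result.vmr.to_csv(paths["vmr"], index=False)
    write_damage_records(result.contigs, paths["damage"])
    with open(paths["truth"], "w") as fh:
        json.dump(result.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
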