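"""Synthetic incubation endpoints and communities with known ground truth.

The generator emulates a 120-day anaerobic bottle incubation of a
PCP-spiked flooded soil: 3 treatment groups (sterile abiotic, biotic,
biotic + molybdate) x 3 amendments (control, AQDS, biochar) x triplicate
bottles.  Electron allocations to the four reduction processes are drawn
per bottle around group-typical means, inverted through the bottle
stoichiometry into observable endpoint concentrations, and perturbed with
lognormal noise; the drawn (hidden) allocations are emitted alongside as a
ground-truth ledger so recovery can be scored without reverse-engineering
noise.

The default (:func:`paper_preset`) encodes the study conditions:

* sterile bottles show only sorption losses of PCP, background Fe(II)
  (4.4-6.8 mg/g), unchanged sulfate and zero methane;
* biotic bottles reduce Fe(III) strongly (AQDS strongest, via electron
  shuttling), reduce sulfate (biochar strongest, via sulfate-reducer
  growth) and methanogenise freely (~200 permil CH4);
* molybdate suppresses sulfate reduction and most methanogenesis and
  halves the total electron budget (biotic ~3570 vs molybdate ~1760 umol
  e- per bottle on average), while biochar partially rescues
  methanogenesis and dechlorination under molybdate.

Communities are Dirichlet-multinomial draws around a base composition with
treatment-specific fold-changes on designated taxa (e.g. SB-1 enriched by
biochar, Desulforudaceae by AQDS), paired with a random bifurcating tree
with exponential branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .budget import AMENDMENTS, GROUPS
from .community import OtuTable, RANKS
from .stoichiometry import (
    MOLAR_MASS,
    BottleGeometry,
    ChlorophenolSpecies,
    Unit,
    dechlorination_eeq,
    eeq_per_mol,
    micromoles_to_mass,
    micromoles_to_permil,
)

__all__ = [
    "ProcessAllocation",
    "SimulationConfig",
    "CommunityConfig",
    "paper_preset",
    "paper_community_preset",
    "simulate_incubation",
    "simulate_community",
    "ENDPOINT_COLUMNS",
    "TRUTH_COLUMNS",
]

ENDPOINT_COLUMNS = [
    "group", "amendment", "replicate",
    "fe2_mg_g", "sulfate_mg_g", "nitrate_mg_g", "ch4_permil", "co2_permil",
    "pcp_ug_g", "tecp_ug_g", "tcp_ug_g", "dcp_ug_g",
    "ph", "eh_mv", "doc_mg_kg", "don_mg_kg",
]

TRUTH_COLUMNS = [
    "group", "amendment", "replicate",
    "e_fe_umol", "e_so4_umol", "e_dechlor_umol", "e_ch4_umol", "e_total_umol",
]


@dataclass(frozen=True)
class ProcessAllocation:
    """Mean electron allocations (umol e-) and chlorophenol products (ug/g)
    for one (group, amendment) cell."""

    e_fe: float
    e_so4: float
    e_ch4: float
    tecp_ug_g: float = 0.0
    tcp_ug_g: float = 0.0
    dcp_ug_g: float = 0.0

    def total_electrons(self, geometry: BottleGeometry) -> float:
        e_d = 0.0
        for conc, sp in (
            (self.tecp_ug_g, ChlorophenolSpecies.TeCP_2345),
            (self.tcp_ug_g, ChlorophenolSpecies.TCP_345),
            (self.dcp_ug_g, ChlorophenolSpecies.DCP_35),
        ):
            e_d += (conc * geometry.soil_mass / sp.molar_mass) * dechlorination_eeq(
                ChlorophenolSpecies.PCP, sp
            )
        return self.e_fe + self.e_so4 + self.e_ch4 + e_d


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the endpoint simulator.

    ``allocations`` maps (group, amendment) of the two biotic groups to
    mean per-bottle electron allocations; sterile bottles are generated
    from the baseline dictionaries only.  ``noise_cv`` is the relative SD
    of the multiplicative lognormal noise on every concentration-like
    quantity (Eh and pH receive additive Gaussian noise scaled by
    ``noise_cv / 0.05``); ``noise_cv = 0`` yields deterministic output.
    ``electron_pool``, when set, bounds each cell's allocation total.
    """

    seed: int = 0
    n_replicates: int = 3
    noise_cv: float = 0.05
    geometry: BottleGeometry = field(default_factory=BottleGeometry)
    allocations: dict[tuple[str, str], ProcessAllocation] = field(default_factory=dict)
    fe2_baseline: dict[str, float] = field(default_factory=dict)  # mg/g
    sulfate_baseline: dict[str, float] = field(default_factory=dict)  # mg/g
    pcp_sterile: dict[str, float] = field(default_factory=dict)  # ug/g residual
    pcp_biotic: dict[tuple[str, str], float] = field(default_factory=dict)  # ug/g
    eh_mv: dict[str, float] = field(default_factory=dict)  # per group
    co2_permil: dict[str, float] = field(default_factory=dict)  # per group
    ph: float = 8.9
    doc_mg_kg: float = 150.0
    don_mg_kg: float = 15.0
    nitrate_mg_g: float = 0.05
    electron_pool: float | None = None

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for (grp, am), alloc in self.allocations.items():
            if grp not in GROUPS or am not in AMENDMENTS:
                raise ValueError(f"unknown treatment cell {(grp, am)}")
            if min(alloc.e_fe, alloc.e_so4, alloc.e_ch4,
                   alloc.tecp_ug_g, alloc.tcp_ug_g, alloc.dcp_ug_g) < 0:
                raise ValueError(f"negative allocation in cell {(grp, am)}")
            if (
                self.electron_pool is not None
                and alloc.total_electrons(self.geometry) > self.electron_pool
            ):
                raise ValueError(
                    f"allocations for {(grp, am)} exceed the electron pool"
                )


def paper_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """The calibrated study conditions (means chosen to match the reported
    endpoint contrasts and electron budgets; see the methods note)."""
    cfg = SimulationConfig(
        seed=seed,
        allocations={
            # biotic: free methanogenesis (~200 permil -> 1600 umol e-)
            ("biotic", "control"): ProcessAllocation(1217.0, 165.0, 1600.0, 10.0, 0.5),
            ("biotic", "AQDS"): ProcessAllocation(2096.0, 125.0, 1600.0, 4.5, 0.5),
            ("biotic", "biochar"): ProcessAllocation(1800.0, 501.0, 1600.0, 10.0, 0.5),
            # molybdate: sulfate reduction suppressed, CH4 mostly shut down
            ("biotic_molybdate", "control"):
                ProcessAllocation(1234.0, 62.5, 34.72, 5.0, 0.5),
            ("biotic_molybdate", "AQDS"):
                ProcessAllocation(1234.0, 62.5, 0.0, 1.2, 0.5),
            ("biotic_molybdate", "biochar"):
                ProcessAllocation(1234.0, 62.5, 1352.8, 5.0, 0.5),
        },
        fe2_baseline={"control": 4.4, "AQDS": 5.0, "biochar": 6.8},
        sulfate_baseline={"control": 0.74, "AQDS": 0.77, "biochar": 0.74},
        pcp_sterile={"control": 15.8, "AQDS": 14.7, "biochar": 13.9},
        pcp_biotic={
            ("biotic", "control"): 6.0,
            ("biotic", "AQDS"): 10.0,
            ("biotic", "biochar"): 8.0,
            ("biotic_molybdate", "control"): 11.6,
            ("biotic_molybdate", "AQDS"): 14.0,
            ("biotic_molybdate", "biochar"): 12.8,
        },
        eh_mv={"sterile_abiotic": 100.0, "biotic": -150.0,
               "biotic_molybdate": -130.0},
        co2_permil={"sterile_abiotic": 20.0, "biotic": 300.0,
                    "biotic_molybdate": 150.0},
    )
    return replace(cfg, **overrides) if overrides else cfg


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean 1 and relative SD ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


def simulate_incubation(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one experiment: (endpoints, hidden truth ledger) DataFrames.

    Endpoints carry the canonical CSV columns (:data:`ENDPOINT_COLUMNS`);
    the truth frame holds the per-bottle drawn electron allocations for
    the two biotic groups.
    """
    config = config or paper_preset()
    config.validate()
    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    cv = config.noise_cv
    env_scale = cv / 0.05 if cv > 0 else 0.0
    ch4_eeq = eeq_per_mol("methane_acetoclastic")

    endpoint_rows: list[dict] = []
    truth_rows: list[dict] = []
    for group in GROUPS:
        for amendment in AMENDMENTS:
            for rep in range(1, config.n_replicates + 1):
                row = {
                    "group": group, "amendment": amendment, "replicate": rep,
                    "nitrate_mg_g": config.nitrate_mg_g * _lognormal_factor(rng, cv),
                    "ph": config.ph + rng.normal(0, 0.1) * env_scale,
                    "eh_mv": config.eh_mv.get(group, 0.0)
                    + rng.normal(0, 10.0) * env_scale,
                    "co2_permil": config.co2_permil.get(group, 0.0)
                    * _lognormal_factor(rng, cv),
                    "doc_mg_kg": config.doc_mg_kg * _lognormal_factor(rng, cv),
                    "don_mg_kg": config.don_mg_kg * _lognormal_factor(rng, cv),
                }
                if group == "sterile_abiotic":
                    row.update(
                        fe2_mg_g=config.fe2_baseline[amendment]
                        * _lognormal_factor(rng, cv),
                        sulfate_mg_g=config.sulfate_baseline[amendment]
                        * _lognormal_factor(rng, cv),
                        ch4_permil=0.0,
                        pcp_ug_g=config.pcp_sterile[amendment]
                        * _lognormal_factor(rng, cv),
                        tecp_ug_g=0.0, tcp_ug_g=0.0, dcp_ug_g=0.0,
                    )
                    endpoint_rows.append(row)
                    continue

                alloc = config.allocations[(group, amendment)]
                e_fe = alloc.e_fe * _lognormal_factor(rng, cv)
                e_so4 = alloc.e_so4 * _lognormal_factor(rng, cv)
                e_ch4 = alloc.e_ch4 * _lognormal_factor(rng, cv)
                tecp = alloc.tecp_ug_g * _lognormal_factor(rng, cv)
                tcp = alloc.tcp_ug_g * _lognormal_factor(rng, cv)
                dcp = alloc.dcp_ug_g * _lognormal_factor(rng, cv)

                fe2 = config.fe2_baseline[amendment] + micromoles_to_mass(
                    e_fe / eeq_per_mol("ferrous_iron"), geom, MOLAR_MASS["Fe"]
                )
                so4_drop = micromoles_to_mass(
                    e_so4 / eeq_per_mol("sulfide"), geom, MOLAR_MASS["SO4"]
                )
                sulfate = config.sulfate_baseline[amendment] - so4_drop
                if sulfate < 0:
                    raise ValueError(
                        f"allocation draws sulfate below zero in {(group, amendment)}"
                    )
                ch4 = micromoles_to_permil(e_ch4 / ch4_eeq, geom)
                if ch4 > 1000:
                    raise ValueError("CH4 allocation exceeds the headspace basis")

                e_dechlor = 0.0
                for conc, sp in (
                    (tecp, ChlorophenolSpecies.TeCP_2345),
                    (tcp, ChlorophenolSpecies.TCP_345),
                    (dcp, ChlorophenolSpecies.DCP_35),
                ):
                    e_dechlor += (
                        conc * geom.soil_mass / sp.molar_mass
                    ) * dechlorination_eeq(ChlorophenolSpecies.PCP, sp)

                row.update(
                    fe2_mg_g=fe2,
                    sulfate_mg_g=sulfate,
                    ch4_permil=ch4,
                    pcp_ug_g=config.pcp_biotic[(group, amendment)]
                    * _lognormal_factor(rng, cv),
                    tecp_ug_g=tecp, tcp_ug_g=tcp, dcp_ug_g=dcp,
                )
                endpoint_rows.append(row)
                truth_rows.append(
                    {
                        "group": group, "amendment": amendment, "replicate": rep,
                        "e_fe_umol": e_fe, "e_so4_umol": e_so4,
                        "e_dechlor_umol": e_dechlor, "e_ch4_umol": e_ch4,
                        "e_total_umol": e_fe + e_so4 + e_dechlor + e_ch4,
                    }
                )
    endpoints = pd.DataFrame(endpoint_rows)[ENDPOINT_COLUMNS]
    truth = pd.DataFrame(truth_rows)[TRUTH_COLUMNS]
    return endpoints, truth


# ---------------------------------------------------------------------------
# community simulation
# ---------------------------------------------------------------------------

#: base composition of the biotic control community (taxon -> proportion,
#: lineage).  Named families cover the taxa that respond to the amendments;
#: the remaining mass is spread over filler OTUs.
_NAMED_TAXA: dict[str, tuple[float, str]] = {
    "Desulforudaceae": (0.293, "Bacteria;Firmicutes;Clostridia;Clostridiales;Desulforudaceae;Desulforudis"),
    "Clostridiaceae": (0.150, "Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae;Clostridium"),
    "Peptococcaceae": (0.060, "Bacteria;Firmicutes;Clostridia;Clostridiales;Peptococcaceae;Desulfosporosinus"),
    "SB-1": (0.045, "Bacteria;Bacteroidetes;SB-1_class;SB-1_order;SB-1;SB-1_genus"),
    "Spirochaetaceae": (0.035, "Bacteria;Spirochaetes;Spirochaetia;Spirochaetales;Spirochaetaceae;Spirochaeta"),
    "Desulfobulbaceae": (0.030, "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales;Desulfobulbaceae;Desulfobulbus"),
    "Desulfobacteraceae": (0.025, "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales;Desulfobacteraceae;Desulfobacter"),
    "Pelobacteraceae": (0.020, "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfuromonadales;Pelobacteraceae;Pelobacter"),
    "Dehalobacteriaceae": (0.015, "Bacteria;Firmicutes;Clostridia;Clostridiales;Dehalobacteriaceae;Dehalobacterium"),
    "Pseudomonadaceae": (0.020, "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas"),
    "Halomonadaceae": (0.010, "Bacteria;Proteobacteria;Gammaproteobacteria;Oceanospirillales;Halomonadaceae;Halomonas"),
}

_AQDS_EFFECT = {
    "Desulforudaceae": 2.2, "Pseudomonadaceae": 2.0, "Halomonadaceae": 2.0,
    "Pelobacteraceae": 2.0,
}
_BIOCHAR_EFFECT = {
    "SB-1": 5.9, "Dehalobacteriaceae": 2.5, "Pelobacteraceae": 2.5,
    "Desulfobulbaceae": 2.5, "Desulfobacteraceae": 2.5,
    "Clostridiaceae": 0.5, "Peptococcaceae": 0.5,
}
_MOLYBDATE_EFFECT = {
    "Desulforudaceae": 0.4, "Peptococcaceae": 0.4, "Spirochaetaceae": 0.4,
    "Desulfobulbaceae": 0.1, "Desulfobacteraceae": 0.1,
    "Clostridiaceae": 1.8, "Dehalobacteriaceae": 2.0,
    "Pseudomonadaceae": 2.0, "Halomonadaceae": 2.0,
}

BIOTIC_TREATMENTS = [
    (g, a) for g in ("biotic", "biotic_molybdate") for a in AMENDMENTS
]


@dataclass
class CommunityConfig:
    """Parameters of the Dirichlet-multinomial community simulator.

    ``effect_map`` gives per-treatment multiplicative fold-changes on named
    taxa (applied to base proportions before renormalisation);
    ``covariate_links`` optionally ties a taxon's abundance to a per-sample
    covariate (taxon -> (values aligned with samples, slope on the
    z-scored covariate)), which induces taxon-environment correlations for
    the association analysis.  ``theta`` is the Dirichlet precision: small
    values mean strong overdispersion between replicate bottles.
    """

    seed: int = 0
    n_otus: int = 120
    n_replicates: int = 3
    depth: int = 20000
    theta: float = 200.0
    treatments: list[tuple[str, str]] = field(
        default_factory=lambda: list(BIOTIC_TREATMENTS)
    )
    named_taxa: dict[str, tuple[float, str]] = field(
        default_factory=lambda: dict(_NAMED_TAXA)
    )
    effect_map: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    covariate_links: dict[str, tuple[list[float], float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.depth < 1000:
            raise ValueError("sequencing depth must be >= 1000")
        if self.n_otus < len(self.named_taxa) + 1:
            raise ValueError("n_otus must exceed the number of named taxa")
        known = set(self.named_taxa)
        for cell, effects in self.effect_map.items():
            for taxon, fold in effects.items():
                if taxon not in known:
                    raise ValueError(f"effect on unknown taxon {taxon!r} in {cell}")
                if fold <= 0:
                    raise ValueError(f"fold-change for {taxon!r} must be > 0")
        for taxon in self.covariate_links:
            if taxon not in known:
                raise ValueError(f"covariate link on unknown taxon {taxon!r}")


def paper_community_preset(seed: int = 0, **overrides) -> CommunityConfig:
    """Community conditions mirroring the reported family-level shifts."""
    effect_map: dict[tuple[str, str], dict[str, float]] = {}
    for group, amendment in BIOTIC_TREATMENTS:
        eff: dict[str, float] = {}
        if amendment == "AQDS":
            eff.update(_AQDS_EFFECT)
        elif amendment == "biochar":
            eff.update(_BIOCHAR_EFFECT)
        if group == "biotic_molybdate":
            for taxon, fold in _MOLYBDATE_EFFECT.items():
                eff[taxon] = eff.get(taxon, 1.0) * fold
        if eff:
            effect_map[(group, amendment)] = eff
    cfg = CommunityConfig(seed=seed, effect_map=effect_map)
    return replace(cfg, **overrides) if overrides else cfg


def _random_tree(otu_ids: list[str], rng: np.random.Generator,
                 mean_branch: float = 0.1) -> TreeNode:
    """Random bifurcating rooted tree over ``otu_ids`` with Exp branch lengths."""
    nodes = [TreeNode(name=o, length=float(rng.exponential(mean_branch)))
             for o in otu_ids]
    while len(nodes) > 2:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(length=float(rng.exponential(mean_branch)),
                          children=[a, b])
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    root = TreeNode(children=nodes)
    return root


def simulate_community(
    config: CommunityConfig | None = None,
) -> tuple[OtuTable, TreeNode, pd.DataFrame]:
    """Draw one sequencing experiment: (OTU table, rooted tree, metadata).

    One OTU per named taxon plus filler OTUs whose base proportions follow
    a lognormal species-abundance distribution over the remaining mass.
    Per sample, base proportions are multiplied by the treatment's
    fold-changes (and any covariate links), renormalised, and sampled as
    Dirichlet-multinomial counts.
    """
    config = config or paper_community_preset()
    config.validate()
    rng = np.random.default_rng(config.seed)

    named = list(config.named_taxa)
    named_props = np.array([config.named_taxa[t][0] for t in named])
    n_filler = config.n_otus - len(named)
    filler_raw = rng.lognormal(0.0, 1.0, n_filler)
    filler_props = filler_raw / filler_raw.sum() * max(1.0 - named_props.sum(), 0.0)
    base = np.concatenate([named_props, filler_props])

    filler_phyla = ["Firmicutes", "Proteobacteria", "Bacteroidetes", "Chloroflexi"]
    otu_ids, taxonomy = [], {}
    for i, t in enumerate(named):
        oid = f"OTU{i + 1:04d}"
        otu_ids.append(oid)
        taxonomy[oid] = config.named_taxa[t][1]
    for j in range(n_filler):
        oid = f"OTU{len(named) + j + 1:04d}"
        otu_ids.append(oid)
        ph = filler_phyla[j % len(filler_phyla)]
        taxonomy[oid] = (
            f"Bacteria;{ph};class_{j};order_{j};Family_{j};genus_{j}"
        )
    taxon_row = {t: i for i, t in enumerate(named)}

    samples, meta_rows = [], []
    counts = []
    sample_index = 0
    # pre-standardise covariates
    cov_z: dict[str, tuple[np.ndarray, float]] = {}
    n_samples = len(config.treatments) * config.n_replicates
    for taxon, (values, beta) in config.covariate_links.items():
        v = np.asarray(values, dtype=float)
        if v.size != n_samples:
            raise ValueError(
                f"covariate for {taxon!r} has length {v.size}, expected {n_samples}"
            )
        sd = v.std()
        cov_z[taxon] = ((v - v.mean()) / sd if sd > 0 else np.zeros_like(v), beta)

    for group, amendment in config.treatments:
        effects = config.effect_map.get((group, amendment), {})
        for rep in range(1, config.n_replicates + 1):
            p = base.copy()
            for taxon, fold in effects.items():
                p[taxon_row[taxon]] *= fold
            for taxon, (z, beta) in cov_z.items():
                p[taxon_row[taxon]] *= np.exp(beta * z[sample_index])
            p /= p.sum()
            dirichlet = rng.dirichlet(np.maximum(config.theta * p, 1e-8))
            counts.append(rng.multinomial(config.depth, dirichlet))
            sid = f"{group}.{amendment}.{rep}"
            samples.append(sid)
            meta_rows.append(
                {"sample_id": sid, "group": group, "amendment": amendment,
                 "replicate": rep}
            )
            sample_index += 1

    table = OtuTable(
        otu_ids=otu_ids,
        sample_ids=samples,
        counts=np.array(counts).T,
        taxonomy=taxonomy,
    )
    tree = _random_tree(otu_ids, rng)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return table, tree, metadata
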