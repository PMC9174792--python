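"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of a triplicate exometabolomics
screen: a pure-birth phylogeny of isolates; per-metabolite depletion
fractions that carry phylogenetic signal (a latent trait evolves by Brownian
motion along the tree, gets independent per-isolate jitter, and is mapped
through a logistic to (0, 1)); LC-MS-like peak tables with log-normal
multiplicative replicate noise, uninoculated-control replicates and
extraction-blank background; and logistic OD600 growth curves with an
explicit lag phase and additive Gaussian noise.

Default dimensions mirror a 30-isolate x 64-metabolite triplicate screen
with 18 control samples. Every routine takes an explicit seed and touches no
global random state, so identical configuration gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .exoprofile import ROLE_BLANK, ROLE_CONTROL, PeakTable
from .growth import WellTimeSeries


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for one synthetic screen.

    sigma_phylo is the Brownian rate (trait sd per unit branch length);
    sigma_noise is independent per-isolate jitter on the latent trait;
    abundance_cv is the log-normal coefficient of variation of replicate
    peak abundances; blank_fraction is the extraction-blank background as a
    fraction of the control signal.
    """

    seed: int
    n_isolates: int = 30
    n_metabolites: int = 64
    birth_rate: float = 1.0
    sigma_phylo: float = 1.5
    sigma_noise: float = 0.15
    n_replicates: int = 3
    n_controls: int = 18
    n_blanks: int = 3
    abundance_cv: float = 0.2
    blank_fraction: float = 0.05
    production_prob: float = 0.03

    def __post_init__(self):
        for name in ("birth_rate", "sigma_phylo", "sigma_noise", "abundance_cv",
                     "blank_fraction", "production_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """True generative state behind one synthetic screen.

    ``traits`` holds the latent Brownian leaf values (metabolite x isolate),
    ``depletion`` the logistic-mapped depletion fractions in [0, 1), and
    ``production`` multipliers (> 1) where a cell was flagged as produced
    instead - depletion and production are mutually exclusive per cell.
    """

    tree: dendropy.Tree
    traits: pd.DataFrame
    depletion: pd.DataFrame
    production: pd.DataFrame
    families: dict[str, str] = field(default_factory=dict)


def simulate_tree(n: int, birth_rate: float = 1.0, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with *n* leaves labeled iso_1..iso_n.

    Waiting times between splits are Exp(k x birth_rate) with k current
    lineages; after the n-th lineage appears the tips are extended by one
    more exponential waiting time so every pendant branch is positive.
    Deterministic given the seed.
    """
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if not birth_rate > 0:
        raise ValueError("birth rate must be > 0")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.birth_time = 0.0
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (len(active) * birth_rate))
        parent = active.pop(rng.integers(len(active)))
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            parent.add_child(child)
            active.append(child)
        parent.edge.length = t - parent.birth_time if parent is not root else None
    t += rng.exponential(1.0 / (n * birth_rate))
    for i, leaf in enumerate(active, start=1):
        leaf.edge.length = t - leaf.birth_time
        leaf.taxon = taxa.new_taxon(label=f"iso_{i}")
    return tree


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_profiles(
    tree: dendropy.Tree,
    sigma_phylo: float = 1.5,
    sigma_noise: float = 0.15,
    seed: int = 0,
    n_metabolites: int = 64,
    production_prob: float = 0.0,
    root_trait: float = 0.0,
) -> GroundTruth:
    """Phylogenetically structured depletion fractions with known truth.

    Each metabolite's latent trait evolves independently by Brownian motion
    along the tree (increment variance sigma_phylo^2 x branch length), so
    for leaves i, j at patristic distance d the expected squared trait
    difference is ``sigma_phylo^2 d + 2 sigma_noise^2`` after the
    independent Normal(0, sigma_noise^2) leaf jitter. Leaf traits map
    through a logistic to depletion fractions in (0, 1). With probability
    ``production_prob`` a cell is instead flagged as produced, with a
    multiplier drawn uniformly from (1.5, 4); such cells have depletion 0.
    """
    if sigma_phylo < 0 or sigma_noise < 0:
        raise ValueError("sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    metabolites = [f"met_{k + 1}" for k in range(n_metabolites)]
    node_traits: dict[int, np.ndarray] = {}
    leaf_labels: list[str] = []
    leaf_traits: list[np.ndarray] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            vals = np.full(n_metabolites, float(root_trait))
        else:
            length = node.edge.length or 0.0
            vals = node_traits[id(node.parent_node)] + rng.normal(
                0.0, sigma_phylo * np.sqrt(length), n_metabolites
            )
        node_traits[id(node)] = vals
        if node.is_leaf():
            leaf_labels.append(node.taxon.label)
            leaf_traits.append(vals + rng.normal(0.0, sigma_noise, n_metabolites))
    traits = pd.DataFrame(
        np.column_stack(leaf_traits), index=metabolites, columns=leaf_labels
    )
    depletion = pd.DataFrame(
        _logistic(traits.to_numpy()), index=metabolites, columns=leaf_labels
    )
    production = pd.DataFrame(np.nan, index=metabolites, columns=leaf_labels)
    if production_prob > 0:
        flag = rng.random(traits.shape) < production_prob
        mult = rng.uniform(1.5, 4.0, traits.shape)
        production = production.mask(flag, mult)
        depletion = depletion.mask(flag, 0.0)
    return GroundTruth(
        tree=tree, traits=traits, depletion=depletion, production=production
    )


def assign_families(tree: dendropy.Tree, depth_fraction: float = 0.25) -> dict[str, str]:
    """Group leaves into families by cutting the tree at a fixed depth.

    Every lineage crossing ``depth_fraction x max leaf depth`` founds a
    family; its descendant leaves share the label. Ground-truth-consistent
    by construction.
    """
    depths: dict[int, float] = {}
    max_depth = 0.0
    for node in tree.preorder_node_iter():
        d = 0.0 if node.parent_node is None else depths[id(node.parent_node)] + (node.edge.length or 0.0)
        depths[id(node)] = d
        if node.is_leaf():
            max_depth = max(max_depth, d)
    cutoff = depth_fraction * max_depth
    families: dict[str, str] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        d = depths[id(node)]
        parent_d = depths.get(id(node.parent_node)) if node.parent_node else None
        if d >= cutoff and (parent_d is None or parent_d < cutoff):
            counter += 1
            label = f"fam_{counter}"
            for leaf in node.leaf_iter():
                families[leaf.taxon.label] = label
    return families


def simulate_peak_table(truth: GroundTruth, config: SimulationConfig) -> PeakTable:
    """LC-MS-like peak table realizing a ground truth.

    Per metabolite the control abundance is drawn log-uniform over 1e4-1e7;
    isolate replicates are control x (1 - depletion) (or x production
    multiplier) under multiplicative log-normal noise with the configured
    CV; control replicates and extraction blanks (blank_fraction x control)
    are appended. All abundances are non-negative by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    metabolites = list(truth.depletion.index)
    isolates = list(truth.depletion.columns)
    n_met = len(metabolites)
    control = 10.0 ** rng.uniform(4.0, 7.0, n_met)
    cv = config.abundance_cv
    sigma = np.sqrt(np.log1p(cv**2))

    def noise(size) -> np.ndarray:
        if cv == 0:
            return np.ones(size)
        return rng.lognormal(-(sigma**2) / 2.0, sigma, size)

    columns: dict[str, np.ndarray] = {}
    ann_rows = []
    for iso in isolates:
        dep = truth.depletion[iso].to_numpy()
        prod = truth.production[iso].to_numpy()
        base = control * np.where(np.isnan(prod), 1.0 - dep, prod)
        for r in range(1, config.n_replicates + 1):
            sid = f"{iso}_r{r}"
            columns[sid] = base * noise(n_met)
            ann_rows.append({"sample_id": sid, "role": "culture", "isolate": iso, "replicate": r})
    for r in range(1, config.n_controls + 1):
        sid = f"ctrl_r{r}"
        columns[sid] = control * noise(n_met)
        ann_rows.append({"sample_id": sid, "role": ROLE_CONTROL, "isolate": "", "replicate": r})
    for r in range(1, config.n_blanks + 1):
        sid = f"blank_r{r}"
        columns[sid] = config.blank_fraction * control * noise(n_met)
        ann_rows.append({"sample_id": sid, "role": ROLE_BLANK, "isolate": "", "replicate": r})
    data = pd.DataFrame(columns, index=metabolites)
    samples = pd.DataFrame(ann_rows).set_index("sample_id")
    return PeakTable(data=data, samples=samples)


def simulate_growth(
    mu: float = 0.3,
    lag: float = 2.0,
    capacity: float = 0.6,
    noise_sd: float = 0.0,
    t_max: float = 48.0,
    dt: float = 0.25,
    od0: float = 0.02,
    seed: int = 0,
    well: str = "A1",
    medium: str = "NLDM",
    isolate: str = "iso_1",
) -> WellTimeSeries:
    """Three-phase logistic OD600 curve with explicit lag and Gaussian noise.

    OD stays at ``od0`` until ``lag`` hours, then follows the logistic
    ``K od0 / (od0 + (K - od0) exp(-mu (t - lag)))`` toward the carrying
    capacity K. Readings every ``dt`` hours (15 min default). Deterministic
    given the seed.
    """
    if not (mu > 0 and capacity > 0):
        raise ValueError("mu and capacity must be > 0")
    if od0 <= 0 or od0 >= capacity:
        raise ValueError("od0 must satisfy 0 < od0 < capacity")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max + dt / 2.0, dt)
    shifted = np.clip(t - lag, 0.0, None)
    od = capacity * od0 / (od0 + (capacity - od0) * np.exp(-mu * shifted))
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, od.shape)
    return WellTimeSeries(time=t, od=od, well=well, medium=medium, isolate=isolate)


def simulate_screen(config: SimulationConfig) -> tuple[GroundTruth, PeakTable]:
    """Tree + profiles + peak table for one configuration (one-stop shop)."""
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    tree = simulate_tree(config.n_isolates, config.birth_rate,
                         seed=seeds[0].generate_state(1)[0] % (2**31))
    truth = simulate_profiles(
        tree,
        sigma_phylo=config.sigma_phylo,
        sigma_noise=config.sigma_noise,
        seed=seeds[1].generate_state(1)[0] % (2**31),
        n_metabolites=config.n_metabolites,
        production_prob=config.production_prob,
    )
    truth.families = assign_families(tree)
    table = simulate_peak_table(truth, config)
    return truth, table


def write_simulation(outdir, config: SimulationConfig) -> dict[str, str]:
    """Write a full synthetic dataset in the formats the pipeline consumes.

    Emits tree.nwk, peaks.tsv, samples.tsv, truth.tsv, taxa.tsv plus a
    small plate of growth curves (growth.csv, map.tsv). Returns the mapping
    of artifact name to path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, table = simulate_screen(config)
    paths = {name: str(outdir / fname) for name, fname in [
        ("tree", "tree.nwk"), ("peaks", "peaks.tsv"), ("samples", "samples.tsv"),
        ("truth", "truth.tsv"), ("taxa", "taxa.tsv"),
        ("growth", "growth.csv"), ("map", "map.tsv"), ("config", "sim_config.json"),
    ]}
    truth.tree.write(path=paths["tree"], schema="newick", unquoted_underscores=True)
    table.data.rename_axis("metabolite").to_csv(paths["peaks"], sep="\t")
    table.samples.to_csv(paths["samples"], sep="\t")
    truth.depletion.rename_axis("metabolite").to_csv(paths["truth"], sep="\t")
    pd.DataFrame(
        {"isolate": list(truth.families), "family": list(truth.families.values())}
    ).to_csv(paths["taxa"], sep="\t", index=False)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    plate_rows, map_rows = [], []
    for i, iso in enumerate(list(truth.depletion.columns)[:8], start=1):
        well = f"A{i}"
        s = simulate_growth(
            mu=float(rng.uniform(0.1, 0.8)), lag=float(rng.uniform(0.5, 6.0)),
            capacity=float(rng.uniform(0.3, 0.9)), noise_sd=0.003, t_max=48.0,
            seed=int(rng.integers(2**31)), well=well, isolate=iso,
        )
        plate_rows.append(pd.DataFrame({"well": well, "time_h": s.time, "od600": s.od}))
        map_rows.append({"well": well, "isolate": iso, "medium": "NLDM", "role": "culture"})
    ctrl = simulate_growth(mu=0.3, lag=0.0, capacity=0.021, od0=0.02, noise_sd=0.003,
                           t_max=48.0, seed=int(rng.integers(2**31)), well="H12",
                           isolate="control")
    plate_rows.append(pd.DataFrame({"well": "H12", "time_h": ctrl.time, "od600": ctrl.od}))
    map_rows.append({"well": "H12", "isolate": "control", "medium": "NLDM", "role": "control"})
    pd.concat(plate_rows, ignore_index=True).to_csv(paths["growth"], index=False)
    pd.DataFrame(map_rows).to_csv(paths["map"], sep="\t", index=False)
    import json

    with open(paths["config"], "w", encoding="utf-8") as fh:
        json.dump(asdict(config), fh, indent=2)
        fh.write("\n")
    return paths
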