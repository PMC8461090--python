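"""Synthetic metacommunities with known assembly regimes.

Communities are multinomial read draws from per-sample taxon sampling
probabilities built from three ingredients:

* a regional species pool with log-normal rank abundances;
* a Gaussian fitness filter ``exp(−s·(trait − optimum)²)`` acting on
  Brownian-motion niche traits — this produces the selection regimes
  (homogeneous selection: one shared optimum anchored at the niche of a
  coherent guild clade; heterogeneous selection: divergent optima at ±2 SD
  of the trait distribution);
* Wright-Fisher drift of a finite local community seeded from the pool,
  with per-generation immigration ``m`` from the pool — this produces the
  dispersal/drift regimes (drift: moderate drift against immigration;
  dispersal limitation: isolated communities diverging with no
  immigration; homogenizing dispersal: a mass-effects landscape where a
  well-connected core of patches shares one realized community state while
  a minority of patches remain isolated).

Phylogenetic niche conservatism is the framework's core assumption, so the
trait fields used by the selection regimes are required to carry a minimum
realized phylogenetic signal (correlation between cophenetic distance and
squared trait difference); Brownian draws below the floor are redrawn.

``generate_study_like`` assembles a study with the design of a
membrane-bioreactor biofilm time series: 5 membrane types × flux/no-flux ×
days 1/10/20/30 plus MLSS (the suspended biomass, treated as the regional
pool), for DNA and cDNA datasets, with selection-dominated early biofilms
giving way to drift/dispersal-limitation late.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .community import CommunityTable, validate_metadata

SCENARIOS = ("HoS", "HeS", "HD", "DL", "DR")

#: Per-generation immigration rate used when ScenarioConfig leaves
#: migration_rate unset. DR drifts against substantial immigration (local
#: fluctuations around the pool); DL is fully cut off; the selection
#: scenarios and the HD core do not run drift chains.
DEFAULT_MIGRATION = {"HD": 0.0, "DR": 0.3, "DL": 0.0, "HoS": 0.0, "HeS": 0.0}

#: Default fitness-filter strength per selection scenario. Heterogeneous
#: selection uses a broader niche: very narrow filters concentrate each
#: community on a handful of taxa, which makes the taxa-shuffle null of
#: βNRI too noisy to resolve over-dispersion.
DEFAULT_SELECTION = {"HoS": 8.0, "HeS": 1.5}

#: Minimum realized phylogenetic signal (Pearson correlation between
#: cophenetic distance and squared trait difference) required of a trait
#: field before it is used for a selection regime.
MIN_TRAIT_SIGNAL = 0.2


@dataclass
class ScenarioConfig:
    """Parameters of one simulated assembly regime."""

    scenario: str
    n_taxa: int = 200
    n_samples: int = 10
    depth: int = 1000
    selection_strength: float | None = None  # inverse squared filter width
    migration_rate: float | None = None  # per-generation immigration from pool
    trait_sigma: float = 1.0  # Brownian-motion rate (tree height is 1)
    n_env: int = 2  # distinct environments (HeS only)
    pool_sigma: float = 0.3  # log-normal spread of pool abundances
    community_size: int | None = None  # local community J; default 10·depth
    n_generations: int = 50
    founder_size: int | None = None  # colonisation bottleneck (HD landscape)
    hd_isolated: int | None = None  # isolated patches in the HD landscape
    min_trait_signal: float = MIN_TRAIT_SIGNAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_taxa < 2 or self.n_samples < 2:
            raise ValueError("need n_taxa ≥ 2 and n_samples ≥ 2")
        if self.depth < 1:
            raise ValueError("depth must be ≥ 1")
        if self.selection_strength is None:
            self.selection_strength = DEFAULT_SELECTION.get(self.scenario, 5.0)
        if self.migration_rate is None:
            self.migration_rate = DEFAULT_MIGRATION[self.scenario]
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration_rate must be in [0, 1]")
        if self.scenario == "HeS" and self.n_env < 2:
            raise ValueError("HeS requires n_env ≥ 2")
        if self.community_size is None:
            self.community_size = 10 * self.depth
        if self.founder_size is None:
            # the HD landscape founds each patch from few colonists so the
            # realized metacommunity state is patchy; other regimes found
            # at full community size
            self.founder_size = (
                max(2 * self.depth // 5, 20) if self.scenario == "HD" else self.community_size
            )
        if self.hd_isolated is None:
            self.hd_isolated = max(self.n_samples // 5, 1)


@dataclass
class SyntheticStudy:
    """A simulated study: table, tree, metadata and ground truth."""

    table: CommunityTable
    tree: TreeNode
    metadata: pd.DataFrame
    truth: pd.DataFrame  # sample_id, truth (process label(s)), env
    traits: dict[str, float] = field(default_factory=dict, repr=False)


# -- tree and traits -------------------------------------------------------


def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Pure-birth (Yule) ultrametric tree with ``n_taxa`` tips, height 1.

    Lineages split at unit rate; tip branch lengths are extended to the
    present so root-to-tip distances are equal, then the whole tree is
    rescaled to height 1 so cophenetic distances share one scale across
    simulations.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None)
    # active lineages: (parent node, birth time)
    active: list[tuple[TreeNode, float]] = [(root, 0.0), (root, 0.0)]
    t = 0.0
    internal = []
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent, birth = active.pop(k)
        node = TreeNode(name=None, length=t - birth)
        parent.append(node)
        internal.append(node)
        active.append((node, t))
        active.append((node, t))
    t += rng.exponential(1.0 / len(active))
    height = t if t > 0 else 1.0
    for i, (parent, birth) in enumerate(active):
        tip = TreeNode(name=f"t{i + 1}", length=(t - birth) / height)
        parent.append(tip)
    for node in internal:
        node.length = node.length / height
    root.length = None
    return root


def simulate_traits(tree: TreeNode, trait_sigma: float, seed: int) -> dict[str, float]:
    """Brownian-motion niche optima along the tree (root value 0).

    Each branch adds N(0, σ²·branch_length); closely related tips therefore
    share most of their trait path and are correlated.
    """
    if trait_sigma <= 0:
        raise ValueError("trait_sigma must be > 0")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    traits: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, trait_sigma * np.sqrt(node.length or 0.0))
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            traits[node.name] = values[id(node)]
    return traits


def trait_signal(dmat: np.ndarray, traits: np.ndarray) -> float:
    """Phylogenetic signal of a trait field: Pearson correlation between
    cophenetic distance and squared trait difference over tip pairs."""
    iu = np.triu_indices(len(traits), k=1)
    diff2 = (traits[:, None] - traits[None, :])[iu] ** 2
    return float(np.corrcoef(dmat[iu], diff2)[0, 1])


def traits_with_signal(
    tree: TreeNode,
    dmat: np.ndarray,
    taxa: list[str],
    trait_sigma: float,
    seed: int,
    min_signal: float = MIN_TRAIT_SIGNAL,
    max_tries: int = 30,
) -> dict[str, float]:
    """Brownian trait field conditioned on a minimum phylogenetic signal.

    Brownian motion guarantees niche conservatism only in expectation; a
    single realization can leave the deep clades unseparated in trait
    space, which contradicts the conserved-niche assumption the binning
    framework rests on. Draws are repeated (new seeds derived from
    ``seed``) until the realized signal reaches ``min_signal``; the best
    draw is kept if none does.
    """
    best, best_r = None, -np.inf
    for i in range(max_tries):
        tm = simulate_traits(tree, trait_sigma, (seed + 104729 * i) % 2**31)
        tr = np.array([tm[t] for t in taxa])
        r = trait_signal(dmat, tr)
        if r > best_r:
            best, best_r = tm, r
        if r >= min_signal:
            return tm
    return best


# -- building blocks -------------------------------------------------------


def lognormal_pool(n_taxa: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Regional pool relative abundances with log-normal spread."""
    x = np.exp(rng.normal(0.0, sigma, size=n_taxa))
    return x / x.sum()


def gaussian_filter(traits: np.ndarray, optimum: float, strength: float) -> np.ndarray:
    """Fitness filter exp(−s·(trait − optimum)²)."""
    return np.exp(-strength * (traits - optimum) ** 2)


def guild_optimum(
    tree: TreeNode,
    taxa: list[str],
    traits: np.ndarray,
    size_min: int | None = None,
    size_max: int | None = None,
    edge: float = 1.0,
) -> float:
    """Environmental optimum anchored at the niche of a coherent guild.

    Scans mid-sized clades for the guild whose niche is most distinct
    (largest |clade mean − community mean| relative to its internal
    spread) and places the optimum ``edge`` guild-trait standard
    deviations outward of the guild mean (away from the community
    centroid). A stable environment generically resembles the niche of
    some phylogenetically coherent guild rather than the community-wide
    trait centroid; anchoring at the guild's outward flank keeps a fitness
    gradient across the guild's own clade instead of a flat filter top.
    """
    n = len(taxa)
    if size_min is None:  # guild spans roughly 10-30% of the taxon pool
        size_min = max(n // 10, 5)
    if size_max is None:
        size_max = max(n // 3, size_min + 5)
    idx = {t: i for i, t in enumerate(taxa)}
    center = traits.mean()
    best, best_sep = None, -np.inf
    for node in tree.non_tips(include_self=False):
        tips = [t.name for t in node.tips()]
        if size_min <= len(tips) <= size_max:
            tv = traits[[idx[t] for t in tips]]
            sep = abs(tv.mean() - center) / (tv.std() + 1e-9)
            if sep > best_sep:
                best_sep = sep
                best = (float(tv.mean()), float(tv.std()))
    if best is None:  # tree too small for the window: fall back to offset
        return float(center - 0.8 * traits.std())
    gmean, gsd = best
    direction = -1.0 if gmean < center else 1.0
    return float(gmean + edge * direction * gsd)


def drift_community(
    pool_p: np.ndarray,
    community_size: int,
    n_generations: int,
    migration_rate: float,
    rng: np.random.Generator,
    founder_size: int | None = None,
) -> np.ndarray:
    """Relative abundances after Wright-Fisher drift with immigration.

    A local community of ``community_size`` individuals is founded by a
    multinomial draw of ``founder_size`` colonists from the pool, then for
    each generation the sampling probabilities are
    (1−m)·local frequencies + m·pool and the community is resampled.
    """
    f0 = founder_size if founder_size is not None else community_size
    freq = rng.multinomial(f0, pool_p) / f0
    for _ in range(n_generations):
        p = (1.0 - migration_rate) * freq + migration_rate * pool_p
        freq = rng.multinomial(community_size, p) / community_size
    return freq


# -- scenarios -------------------------------------------------------------


def _scenario_metadata(sample_ids: list[str]) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "membrane_type": "COM",
            "surface_character": "n/a",
            "flux": "n/a",
            "day": 1,
            "compartment": "biofilm",
            "nucleic": "DNA",
        }
    )
    return validate_metadata(meta)


def simulate_scenario(config: ScenarioConfig) -> SyntheticStudy:
    """Simulate one community set under a single known assembly regime."""
    from .assembly import cophenetic_matrix  # local import, no cycle at module load

    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_taxa, int(rng.integers(2**31)))
    taxa = [t.name for t in tree.tips()]
    dmat = cophenetic_matrix(tree, taxa)
    traits_map = traits_with_signal(
        tree, dmat, taxa, config.trait_sigma, int(rng.integers(2**31)),
        min_signal=config.min_trait_signal,
    )
    traits = np.array([traits_map[t] for t in taxa])
    pool = lognormal_pool(config.n_taxa, config.pool_sigma, rng)

    truth_label = config.scenario
    env = np.zeros(config.n_samples, dtype=int)
    probs = np.empty((config.n_samples, config.n_taxa))

    if config.scenario in ("HoS", "HeS"):
        if config.selection_strength == 0:
            warnings.warn(
                "selection_strength = 0 degenerates to the neutral pool; "
                "ground truth relabelled DR",
                stacklevel=2,
            )
            truth_label = "DR"
            probs[:] = pool
        else:
            if config.scenario == "HoS":
                optima = np.array([guild_optimum(tree, taxa, traits)])
            else:
                # divergent optima spanning ±2·SD of the tip-trait distribution
                sd = traits.std()
                optima = traits.mean() + np.linspace(-2.0, 2.0, config.n_env) * sd
            env = np.arange(config.n_samples) % len(optima)
            for s in range(config.n_samples):
                w = pool * gaussian_filter(traits, optima[env[s]], config.selection_strength)
                probs[s] = w / w.sum()
    elif config.scenario == "HD":
        # mass-effects landscape: a connected core of patches shares one
        # realized (patchily founded) community state; a minority of
        # isolated patches diverge independently and supply the regional
        # heterogeneity against which the core's homogeneity is measurable
        n_iso = min(config.hd_isolated, config.n_samples - 2)
        core = drift_community(
            pool, config.community_size, config.n_generations, 0.0, rng,
            founder_size=config.founder_size,
        )
        for s in range(config.n_samples - n_iso):
            probs[s] = core
        for s in range(config.n_samples - n_iso, config.n_samples):
            probs[s] = drift_community(
                pool, config.community_size, config.n_generations, 0.0, rng,
                founder_size=config.founder_size,
            )
            env[s] = 1
    else:  # DR, DL
        for s in range(config.n_samples):
            probs[s] = drift_community(
                pool,
                config.community_size,
                config.n_generations,
                config.migration_rate,
                rng,
                founder_size=config.founder_size,
            )

    counts = np.vstack(
        [rng.multinomial(config.depth, np.maximum(p, 0) / p.sum()) for p in probs]
    )
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    table = CommunityTable(sample_ids, taxa, counts)
    truth = pd.DataFrame({"sample_id": sample_ids, "truth": truth_label, "env": env})
    return SyntheticStudy(
        table=table,
        tree=tree,
        metadata=_scenario_metadata(sample_ids),
        truth=truth,
        traits=traits_map,
    )


# -- study-shaped generator ------------------------------------------------

MEMBRANES = ("POX", "PTA", "SPTA", "SPSU", "COM")
SURFACE = {
    "POX": "hydrophobic",
    "PTA": "hydrophobic",
    "SPTA": "hydrophilic",
    "SPSU": "hydrophilic",
    "COM": "hydrophobic",
    "MLSS": "n/a",
}
DAYS = (1, 10, 20, 30)

#: Day-wise regime of the biofilm succession: early biofilms are under
#: strong homogeneous selection by the early-coloniser niche, selection
#: weakens at day 20 with drift appearing, and day-30 biofilms assemble by
#: drift plus colonisation-limited dispersal from a weakly filtered base.
STUDY_REGIMES = {
    1: {"truth": "HoS", "strength": 5.0, "drift": None},
    10: {"truth": "HoS", "strength": 5.0, "drift": None},
    20: {"truth": "HoS+DR", "strength": 2.0, "drift": "weak"},
    30: {"truth": "DR+DL", "strength": 0.0, "drift": "strong"},
}


def generate_study_like(
    seed: int,
    n_taxa: int = 480,
    depth_range: tuple[float, float] = (1392, 18070),
    mean_log_depth: float = float(np.log(8000.0)),
    sd_log_depth: float = 0.35,
) -> dict[str, SyntheticStudy]:
    """Generate the full study design for the DNA and cDNA datasets.

    Per nucleic type: 5 membranes × {flux, no-flux} × 4 days biofilm samples
    (40) plus one MLSS sample per day (4) — 44 samples. Membrane type and
    flux do not enter the sampling probabilities (the design's null
    factors); sampling day drives both the community optimum and the
    assembly regime. Per-sample read totals are log-normal within the
    bounds typical of a 454 amplicon run, so a few samples can fall below a
    4,386-read rarefaction depth. Returns ``{"DNA": study, "cDNA": study}``
    sharing one tree and pool.
    """
    from .assembly import cophenetic_matrix

    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_taxa, int(rng.integers(2**31)))
    taxa = [t.name for t in tree.tips()]
    dmat = cophenetic_matrix(tree, taxa)
    traits_map = traits_with_signal(tree, dmat, taxa, 1.0, int(rng.integers(2**31)))
    traits = np.array([traits_map[t] for t in taxa])
    sd = traits.std()
    pool = lognormal_pool(n_taxa, 0.3, rng)

    # succession along the niche axis: the early-coloniser guild optimum,
    # shifting toward the late-biofilm niche as redox zones develop
    early_opt = guild_optimum(tree, taxa, traits)
    direction = 1.0 if early_opt <= traits.mean() else -1.0
    day_optimum = {
        1: early_opt,
        10: early_opt + direction * 0.2 * sd,
        20: early_opt + direction * 1.0 * sd,
        30: early_opt + direction * 1.6 * sd,
    }

    studies: dict[str, SyntheticStudy] = {}
    for nucleic in ("DNA", "cDNA"):
        # cDNA (active fraction) sees a slightly displaced effective optimum
        nuc_shift = 0.0 if nucleic == "DNA" else 0.1 * sd
        rows, meta_rows, truth_rows = [], [], []
        for day in DAYS:
            regime = STUDY_REGIMES[day]
            base = pool * gaussian_filter(
                traits, day_optimum[day] + nuc_shift, regime["strength"]
            )
            base = base / base.sum()
            day_samples = [
                (f"{m}_{fx}_D{day}_{nucleic}", m, "flux" if fx == "F" else "no-flux")
                for m in MEMBRANES
                for fx in ("F", "NF")
            ]
            for sid, membrane, flux in day_samples:
                if regime["drift"] is None:
                    p = base
                elif regime["drift"] == "weak":
                    p = drift_community(base, 40000, 50, 0.3, rng)
                else:  # strong: isolated patches diverging by drift
                    p = drift_community(base, 40000, 50, 0.0, rng)
                n_reads = int(
                    np.clip(rng.lognormal(mean_log_depth, sd_log_depth), *depth_range)
                )
                rows.append(rng.multinomial(n_reads, p))
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "membrane_type": membrane,
                        "surface_character": SURFACE[membrane],
                        "flux": flux,
                        "day": day,
                        "compartment": "biofilm",
                        "nucleic": nucleic,
                    }
                )
                truth_rows.append(
                    {"sample_id": sid, "truth": regime["truth"], "env": day}
                )
            # MLSS: a draw from the unfiltered regional pool
            sid = f"MLSS_D{day}_{nucleic}"
            n_reads = int(
                np.clip(rng.lognormal(mean_log_depth, sd_log_depth), *depth_range)
            )
            rows.append(rng.multinomial(n_reads, pool))
            meta_rows.append(
                {
                    "sample_id": sid,
                    "membrane_type": "MLSS",
                    "surface_character": "n/a",
                    "flux": "n/a",
                    "day": day,
                    "compartment": "MLSS",
                    "nucleic": nucleic,
                }
            )
            truth_rows.append({"sample_id": sid, "truth": "pool", "env": day})
        table = CommunityTable(
            [r["sample_id"] for r in meta_rows], taxa, np.vstack(rows)
        )
        studies[nucleic] = SyntheticStudy(
            table=table,
            tree=tree,
            metadata=validate_metadata(pd.DataFrame(meta_rows)),
            truth=pd.DataFrame(truth_rows),
            traits=traits_map,
        )
    return studies


def scenario_with_defaults(scenario: str, seed: int, **overrides) -> ScenarioConfig:
    """Convenience constructor used by the CLI and analysis drivers."""
    return replace(ScenarioConfig(scenario=scenario, seed=seed), **overrides)
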