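"""Synthetic host pools with the structure the analyses assume.

The generator emulates a compiled flea-host database at desk scale: a
pure-birth host phylogeny, phylogenetically autocorrelated continuous
traits (Brownian motion along the tree), threshold-on-liability binary
habitat flags, a softmax-of-liabilities 10-category diet composition, an
IUCN-style threat class, and infestation outcomes drawn from exactly the
hierarchical logistic model the regression stage fits. A truth file records
every generative parameter so recovery can be checked end to end.

Defaults stand in for the real pool at 300 species, with an anthropogenic
habitat-use effect of 1.5 on the log-odds scale and unit phylogenetic
variance; the remaining coefficients default to zero apart from a negative
body-mass effect.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .io import AssociationTable, HostTree, TraitTable, ValidationError
from .regression import RegressionSpec, phylo_correlation
from .traits import prepare_traits

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_bm_trait",
    "simulate_binary_habitat",
    "simulate_diet",
    "simulate_threat_status",
    "simulate_infestation",
    "SimulatedDataset",
    "simulate_dataset",
]

#: Raw IUCN-style habitat flags carried by the synthetic trait table; the
#: first seven feed the composite indicators, all nine feed the habitat
#: niche matrix.
HABITAT_FLAGS = (
    "artificial_terrestrial",
    "introduced_vegetation",
    "forest",
    "shrubland",
    "desert",
    "savanna",
    "grassland",
    "wetland",
    "rocky_areas",
)

THREAT_CLASSES = ("LC", "NT", "VU", "EN")

DIET_CATEGORIES = tuple(f"diet_{c}" for c in (
    "invertebrates", "vertebrates", "carrion", "fish", "fruit",
    "nectar", "seeds", "plants", "fungus", "other",
))


def _default_betas() -> dict:
    return {
        "intercept": -1.5,
        "body_mass_kg_s": -0.5,
        "diet_diversity_s": 0.0,
        "cohabitation_diversity_s": 0.0,
        "anthropogenic_use": 1.5,
        "forest_use": 0.0,
        "dry_bush_use": 0.0,
        "citations_parasite_s": 0.0,
        "citations_ectoparasite_s": 0.0,
        "cohabitation_diversity_s:anthropogenic_use": 0.0,
    }


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic host pool."""

    n_species: int = 300
    birth_rate: float = 1.0
    trait_sigma2: float = 1.0          # Brownian rate for continuous liabilities
    habitat_sigma2: float = 1.0
    habitat_threshold: float = 0.5     # liability cut for each binary flag
    diet_sigma2: float = 1.0
    diet_concentration: tuple = tuple(1.0 for _ in range(10))
    betas: dict = field(default_factory=_default_betas)
    sigma2_phylo: float = 1.0
    sigma2_threat: float = 0.5
    n_parasites: int = 2
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise ValidationError("n_species must be >= 4")
        if self.birth_rate <= 0:
            raise ValidationError("birth_rate must be > 0")
        for name in ("trait_sigma2", "habitat_sigma2", "diet_sigma2",
                     "sigma2_phylo", "sigma2_threat"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if any(c <= 0 for c in self.diet_concentration):
            raise ValidationError("diet_concentration entries must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# Tree and trait processes
# ---------------------------------------------------------------------------


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int = 0) -> HostTree:
    """Pure-birth (Yule) ultrametric tree with ``n_species`` tips.

    Waiting times are exponential at rate ``birth_rate x lineage count``; a
    final exponential hold time is appended to every tip so the youngest
    cherry has positive branch lengths. Tips are relabelled S0001... in
    birth order. Deterministic given ``seed``.
    """
    if n_species < 2:
        raise ValidationError("need at least 2 species")
    rnd = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rnd,
    )
    hold = rnd.expovariate(birth_rate * n_species)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + hold
    width = max(4, len(str(n_species)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"S{i:0{width}d}"
    return HostTree(tree)


def _bm_tip_values(tree: HostTree, sigma2: float, rng: np.random.Generator) -> pd.Series:
    """Brownian trait: root 0, Gaussian increments with variance
    sigma2 x branch length; returns tip values keyed by label."""
    t = tree.dendropy_tree
    value = {}
    out = {}
    for node in t.preorder_node_iter():
        parent = node.parent_node
        start = value[id(parent)] if parent is not None else 0.0
        edge = node.edge.length or 0.0
        v = start + (rng.standard_normal() * np.sqrt(sigma2 * edge) if sigma2 > 0 and edge > 0 else 0.0)
        value[id(node)] = v
        if node.is_leaf():
            out[node.taxon.label] = v
    return pd.Series(out).loc[tree.tips]


def simulate_bm_trait(tree: HostTree, sigma2: float, seed: int = 0) -> pd.Series:
    """Continuous Brownian-motion trait over the tips (root value 0)."""
    if sigma2 < 0:
        raise ValidationError("sigma2 must be >= 0")
    return _bm_tip_values(tree, sigma2, np.random.default_rng(seed))


def simulate_binary_habitat(
    tree: HostTree, sigma2: float, threshold: float, seed: int = 0
) -> pd.Series:
    """Binary habitat-use flag: 1 where a Brownian liability exceeds
    ``threshold``; the threshold controls prevalence."""
    liab = simulate_bm_trait(tree, sigma2, seed)
    return (liab > threshold).astype(int)


def simulate_diet(
    tree: HostTree,
    concentration=None,
    sigma2: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """10-category diet composition per species: softmax of independent
    Brownian liabilities offset by log-concentration, so rows sum to 1 and
    phylogenetic signal carries over from the liabilities."""
    conc = np.asarray(
        concentration if concentration is not None else np.ones(10), dtype=float
    )
    if conc.size != len(DIET_CATEGORIES):
        raise ValidationError(f"need {len(DIET_CATEGORIES)} concentration values")
    if (conc <= 0).any():
        raise ValidationError("concentration values must be > 0")
    rng = np.random.default_rng(seed)
    liab = np.column_stack(
        [_bm_tip_values(tree, sigma2, rng).to_numpy() for _ in DIET_CATEGORIES]
    )
    logits = np.log(conc)[None, :] + liab
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return pd.DataFrame(p, index=tree.tips, columns=DIET_CATEGORIES)


def simulate_threat_status(n: int, seed: int = 0) -> np.ndarray:
    """Threat classes assigned uniformly at random among four labels."""
    rng = np.random.default_rng(seed)
    return rng.choice(THREAT_CLASSES, size=n)


# ---------------------------------------------------------------------------
# Infestation outcomes
# ---------------------------------------------------------------------------


def simulate_infestation(
    tree: HostTree,
    X: pd.DataFrame,
    threat: np.ndarray,
    betas: dict,
    sigma2_phylo: float,
    sigma2_threat: float,
    seed: int = 0,
    parasite: str = "parasite_1",
) -> tuple[pd.Series, dict]:
    """Draw one parasite's presence/absence from the hierarchical logistic
    model (the generative twin of the fitted regression).

    Returns the 0/1 outcome per species plus the realised random effects.
    """
    rng = np.random.default_rng(seed)
    species = list(X.index)
    unknown = set(betas) - set(X.columns)
    if unknown:
        raise ValidationError(f"betas name unknown design columns: {sorted(unknown)}")
    beta = np.array([betas.get(c, 0.0) for c in X.columns])
    eta = X.to_numpy() @ beta

    labels, K = phylo_correlation(tree)
    order = [labels.index(s) for s in species]
    K = K[np.ix_(order, order)]
    lam, Q = np.linalg.eigh(K)
    lam = np.maximum(lam, 0.0)
    u_phylo = np.sqrt(sigma2_phylo) * (Q @ (np.sqrt(lam) * rng.standard_normal(len(species))))

    classes = sorted(set(threat))
    w = np.sqrt(sigma2_threat) * rng.standard_normal(len(classes))
    u_threat = np.array([w[classes.index(t)] for t in threat])

    e = rng.standard_normal(len(species))
    eta = eta + u_phylo + u_threat + e
    y = (rng.uniform(size=len(species)) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    truth = {
        "u_phylo": dict(zip(species, u_phylo.tolist())),
        "u_threat": dict(zip(classes, w.tolist())),
    }
    return pd.Series(y, index=species, name=parasite), truth


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    tree: HostTree
    traits: TraitTable
    associations: AssociationTable
    truth: dict

    def write(self, outdir) -> dict:
        """Write tree/traits/associations/truth in the package's own text
        dialects; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": outdir / "host_tree.nwk",
            "traits": outdir / "host_traits.csv",
            "associations": outdir / "associations.csv",
            "truth": outdir / "truth.json",
            "schema": outdir / "trait_schema.json",
        }
        self.tree.write(paths["tree"])
        self.traits.data.to_csv(paths["traits"], na_rep="")
        self.associations.records.to_csv(paths["associations"], index=False, na_rep="")
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        schema = {
            col: (f"fuzzy:diet" if typ == "fuzzy" else typ)
            for col, typ in self.traits.types.items()
        }
        paths["schema"].write_text(json.dumps(schema, indent=2, sort_keys=True))
        return {k: str(v) for k, v in paths.items()}


def trait_schema() -> dict:
    """Column-type schema of the synthetic trait table."""
    schema = {
        "body_mass_kg": "continuous",
        "cohabitation_diversity": "continuous",
        "citations_parasite": "continuous",
        "citations_ectoparasite": "continuous",
        "midrange_latitude": "continuous",
        "midrange_longitude": "continuous",
        "threat_status": "categorical",
    }
    schema.update({flag: "binary" for flag in HABITAT_FLAGS})
    schema.update({c: "fuzzy:diet" for c in DIET_CATEGORIES})
    return schema


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a complete synthetic input set (tree, traits, associations)
    plus the ground-truth parameter record."""
    config = config or SimulationConfig()
    seed = config.seed
    tree = simulate_tree(config.n_species, config.birth_rate, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    sp = tree.tips
    data = pd.DataFrame(index=pd.Index(sp, name="species"))
    # log-Brownian body mass in kilograms
    data["body_mass_kg"] = np.exp(_bm_tip_values(tree, config.trait_sigma2, rng))
    data["cohabitation_diversity"] = _bm_tip_values(tree, config.trait_sigma2, rng)
    # citation counts: skewed, weak phylogenetic signal plus sampling noise
    for col in ("citations_parasite", "citations_ectoparasite"):
        data[col] = np.exp(
            _bm_tip_values(tree, config.trait_sigma2 / 2, rng)
            + 0.5 * rng.standard_normal(len(sp))
        )
    data["midrange_latitude"] = np.clip(
        30.0 * _bm_tip_values(tree, config.trait_sigma2, rng), -90, 90
    )
    data["midrange_longitude"] = np.clip(
        60.0 * _bm_tip_values(tree, config.trait_sigma2, rng), -180, 180
    )
    for flag in HABITAT_FLAGS:
        # liabilities are standardised across the pool before thresholding so
        # each flag's prevalence is stable across tree realisations (deep
        # shared branches otherwise let whole pools drift past the cut)
        liab = _bm_tip_values(tree, config.habitat_sigma2, rng)
        sd = liab.std(ddof=0)
        if sd > 0:
            liab = (liab - liab.mean()) / sd
        data[flag] = (liab > config.habitat_threshold).astype(int)
    diet = simulate_diet(
        tree,
        config.diet_concentration,
        config.diet_sigma2,
        seed=int(rng.integers(2**31)),
    )
    for c in DIET_CATEGORIES:
        data[c] = diet[c]
    threat = simulate_threat_status(len(sp), seed=int(rng.integers(2**31)))
    data["threat_status"] = threat

    schema = trait_schema()
    types = {c: ("fuzzy" if t.startswith("fuzzy") else t) for c, t in schema.items()}
    table = TraitTable(data, types, {"diet": list(DIET_CATEGORIES)})

    prepared = prepare_traits(table)
    spec = RegressionSpec()
    X = spec.build_design(prepared)

    records = []
    effects = {}
    for k in range(config.n_parasites):
        name = f"parasite_{k + 1}"
        y, eff = simulate_infestation(
            tree, X, threat, config.betas, config.sigma2_phylo,
            config.sigma2_threat, seed=int(rng.integers(2**31)), parasite=name,
        )
        effects[name] = eff
        for s in sp:
            records.append({"host": s, "parasite": name, "present": int(y[s])})
    associations = AssociationTable(pd.DataFrame(records))

    if config.missing_rate > 0:
        blank = table.data.copy()
        maskable = [
            c for c, t in types.items() if t in ("continuous", "fuzzy")
        ]
        mask = rng.uniform(size=(len(sp), len(maskable))) < config.missing_rate
        for j, c in enumerate(maskable):
            blank.loc[mask[:, j], c] = np.nan
        table = TraitTable(blank, types, {"diet": list(DIET_CATEGORIES)})

    truth = {
        "config": {
            **asdict(config),
            "diet_concentration": list(config.diet_concentration),
        },
        "random_effects": effects,
    }
    return SimulatedDataset(tree, table, associations, truth)
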