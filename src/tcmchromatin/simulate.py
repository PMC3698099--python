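"""Seeded synthetic bundles emulating the study's input data.

One bundle = a phylogeny of medicinals with cold-hot/flavor annotations
carrying tunable phylogenetic signal, constituent chemicals, an interaction
table with optional planted score-potency associations, and formulas with
tunable chromatin-class homophily.  Everything is reproducible from the
config seed and round-trips through the catalog readers.

The trait model is Brownian motion on a pure-birth (Yule) tree plus iid
noise, discretized into the seven nature tokens by equal-frequency bins;
with the Brownian rate at zero and no noise every leaf stays at the root
value and gets the same token.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .catalog import (
    FormulaRecord,
    InteractionRecord,
    MedicinalCatalog,
    MedicinalRecord,
    ModificationCatalog,
    load_default_modification_catalog,
    write_formulas,
    write_interaction_table,
    write_medicinal_catalog,
)
from .constants import ATTRIBUTE_ORDER, NATURE_SCORES

_NATURE_TOKENS = list(NATURE_SCORES)  # cold .. hot
_YANG_FLAVORS = ("sweet", "mild sweet", "pungent", "mild pungent", "plain")
_YIN_FLAVORS = ("sour", "mild sour", "bitter", "mild bitter", "salty",
                "mild salty")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic bundle.

    Defaults plant all three signals the analysis is designed to detect:
    phylogenetic autocorrelation of the nature trait, a cold-enriched H3K9
    association, and chromatin-class homophily in formula composition.
    ``null_config`` switches all of them off.
    """

    seed: int
    n_medicinals: int = 200
    n_chemicals_per_medicinal: tuple[int, int] = (2, 5)
    n_enzymes_per_attribute: tuple[int, int] = (2, 10)
    sigma_bm: float = 1.0            # Brownian rate of the latent nature trait
    trait_noise_sd: float = 0.25     # iid noise on leaf traits
    na_fraction: float = 0.1         # leaves without a nature annotation
    flavor_nature_coupling: float = 1.0
    n_flavors: tuple[int, int] = (1, 3)
    base_interaction_rate: float = 0.001
    action_mix: tuple[float, float, float] = (0.2, 0.5, 0.3)
    # (attribute, side of the cold-hot scale, extra pair rate per candidate
    # pair at full grade)
    planted_associations: tuple[tuple[str, str, float], ...] = (
        ("H3K9", "cold", 0.02),)
    formula_count: int = 50
    formula_size_range: tuple[int, int] = (4, 10)
    homophily_strength: float = 0.9

    def validate(self) -> None:
        if self.n_medicinals < 4:
            raise ValueError("n_medicinals must be >= 4")
        if not 0 <= self.na_fraction < 1:
            raise ValueError("na_fraction must be in [0, 1)")
        if not 0 <= self.homophily_strength <= 1:
            raise ValueError("homophily_strength must be in [0, 1]")
        if abs(sum(self.action_mix) - 1.0) > 1e-9:
            raise ValueError("action_mix must sum to 1")
        if self.base_interaction_rate < 0 or self.base_interaction_rate > 1:
            raise ValueError("base_interaction_rate must be in [0, 1]")
        for attr, side, eff in self.planted_associations:
            if attr not in ATTRIBUTE_ORDER:
                raise ValueError(f"planted association on unknown attribute "
                                 f"{attr!r}")
            if side not in ("cold", "hot"):
                raise ValueError(f"planted association side must be cold/hot, "
                                 f"got {side!r}")
            if eff < 0:
                raise ValueError("effect size must be >= 0")


def null_config(seed: int, **overrides) -> GeneratorConfig:
    """Zero-signal variant: iid traits, no planted effects, no homophily."""
    base = dict(seed=seed, sigma_bm=0.0, trait_noise_sd=1.0,
                planted_associations=(), homophily_strength=0.0)
    base.update(overrides)
    return GeneratorConfig(**base)


@dataclass
class SyntheticBundle:
    config: GeneratorConfig
    tree: dendropy.Tree
    catalog: MedicinalCatalog
    traits: dict[str, float]          # latent continuous trait per medicinal
    interactions: list[InteractionRecord]
    modcat: ModificationCatalog
    formulas: list[FormulaRecord] = field(default_factory=list)


def _yule_tree(n: int, rng: random.Random) -> dendropy.Tree:
    """Pure-birth tree: split a uniformly chosen leaf at exponential times."""
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    leaves = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        leaves.append(child)
    t = 0.0
    while True:
        k = len(leaves)
        dt = rng.expovariate(k)  # birth rate 1 per lineage
        t += dt
        for leaf in leaves:
            leaf.edge.length += dt
        if k == n:
            break
        parent = leaves.pop(rng.randrange(k))
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            leaves.append(child)
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.new_taxon(f"M{i:04d}")
    return tree


def _bin_natures(values: np.ndarray) -> list[str]:
    """Equal-frequency seven-bin discretization of the latent trait."""
    if np.ptp(values) == 0:
        return ["neutral"] * len(values)
    edges = np.quantile(values, np.linspace(0, 1, 8)[1:-1])
    bins = np.searchsorted(edges, values, side="left")
    return [_NATURE_TOKENS[b] for b in bins]


def simulate_tree_and_traits(config: GeneratorConfig
                             ) -> tuple[dendropy.Tree, MedicinalCatalog,
                                        dict[str, float]]:
    """Yule tree, Brownian nature trait, flavors coupled to the trait.

    Returns the tree, a catalog (chemicals included) and the latent
    continuous trait per medicinal.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_trait, s_annot = [int(s.generate_state(1)[0] % (2 ** 31))
                                for s in ss.spawn(3)]
    tree = _yule_tree(config.n_medicinals, random.Random(s_tree))
    rng = np.random.default_rng(s_trait)
    node_value: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_value[id(node)] = 0.0
            continue
        elen = node.edge.length or 0.0
        node_value[id(node)] = (node_value[id(node.parent_node)]
                                + config.sigma_bm * np.sqrt(elen)
                                * rng.standard_normal())
    leaves = list(tree.leaf_node_iter())
    traits = {}
    for leaf in leaves:
        traits[leaf.taxon.label] = (node_value[id(leaf)]
                                    + config.trait_noise_sd
                                    * rng.standard_normal())
    labels = [leaf.taxon.label for leaf in leaves]
    values = np.array([traits[lab] for lab in labels])
    natures = _bin_natures(values)

    arng = np.random.default_rng(s_annot)
    na_mask = arng.random(len(labels)) < config.na_fraction
    z = values if np.ptp(values) == 0 else (values - values.mean()) / values.std()
    catalog = MedicinalCatalog()
    lo_c, hi_c = config.n_chemicals_per_medicinal
    lo_f, hi_f = config.n_flavors
    for i, lab in enumerate(labels):
        p_yang = 1.0 / (1.0 + np.exp(-config.flavor_nature_coupling * z[i]))
        k = int(arng.integers(lo_f, hi_f + 1))
        flavors: set[str] = set()
        for _ in range(k):
            pool = _YANG_FLAVORS if arng.random() < p_yang else _YIN_FLAVORS
            flavors.add(pool[int(arng.integers(len(pool)))])
        n_chem = int(arng.integers(lo_c, hi_c + 1))
        catalog.records[lab] = MedicinalRecord(
            medicinal_id=lab,
            scientific_name=f"Synthetica {lab.lower()}",
            nature_token=None if na_mask[i] else natures[i],
            flavor_tokens=frozenset(flavors),
            chemical_ids=frozenset(f"C{lab}_{j:02d}" for j in range(n_chem)),
        )
    return tree, catalog, traits


def simulate_modification_catalog(config: GeneratorConfig,
                                  seed: int) -> ModificationCatalog:
    """Synthetic enzyme families (2-10 members) for the 18 attributes."""
    rng = np.random.default_rng(seed)
    lo, hi = config.n_enzymes_per_attribute
    base = load_default_modification_catalog()
    proteins = {}
    for code in ATTRIBUTE_ORDER:
        k = int(rng.integers(lo, hi + 1))
        proteins[code] = frozenset(f"ENZ_{code}_{j:02d}" for j in range(k))
    return ModificationCatalog(conformation=dict(base.conformation),
                               proteins=proteins)


def simulate_interactions(catalog: MedicinalCatalog,
                          modcat: ModificationCatalog,
                          config: GeneratorConfig,
                          seed: int) -> list[InteractionRecord]:
    """Bernoulli chemical-enzyme pairs plus planted nature-linked effects.

    Every chemical x enzyme pair enters at the base rate; a planted
    association (attribute, side, effect) adds pairs for that attribute's
    enzymes at rate effect * |score|/3 for medicinals on that side of the
    cold-hot scale.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    enzymes = [(p, code) for code in ATTRIBUTE_ORDER
               for p in sorted(modcat.proteins_for(code))]
    enz_ids = np.array([p for p, _ in enzymes])
    enz_attr = np.array([code for _, code in enzymes])
    records: list[InteractionRecord] = []
    p_act, p_inh, p_unspec = config.action_mix
    for rec in catalog:
        score = NATURE_SCORES.get(rec.nature_token)  # None when NA
        extra = np.zeros(len(enzymes))
        for attr, side, eff in config.planted_associations:
            if score is None:
                continue
            grade = max(0.0, -score if side == "cold" else score) / 3.0
            extra[enz_attr == attr] += eff * grade
        p_pair = np.clip(config.base_interaction_rate + extra, 0.0, 1.0)
        for chem in sorted(rec.chemical_ids):
            hits = np.nonzero(rng.random(len(enzymes)) < p_pair)[0]
            for h in hits:
                u = rng.random()
                action = ("activation" if u < p_act
                          else "inhibition" if u < p_act + p_inh
                          else "unspecified")
                records.append(InteractionRecord(chem, str(enz_ids[h]), action))
    return records


def simulate_formulas(catalog: MedicinalCatalog, calls: dict[str, str],
                      config: GeneratorConfig, seed: int) -> list[FormulaRecord]:
    """Formulas with chromatin-class homophily.

    ``calls`` maps medicinal_id -> chromatin label.  The first member is
    uniform; each later member comes from the first member's class with
    probability ``homophily_strength``, else uniformly from the rest.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    ids = catalog.ids()
    by_class: dict[str, list[str]] = {}
    for mid in ids:
        by_class.setdefault(calls[mid], []).append(mid)
    lo, hi = config.formula_size_range
    out = []
    for k in range(config.formula_count):
        size = int(rng.integers(lo, hi + 1))
        if size > len(ids):
            raise ValueError(f"formula size {size} exceeds catalog size")
        first = ids[int(rng.integers(len(ids)))]
        members = [first]
        cls_pool = by_class[calls[first]]
        while len(members) < size:
            if rng.random() < config.homophily_strength:
                candidates = [m for m in cls_pool if m not in members]
                if not candidates:
                    if config.homophily_strength >= 1.0:
                        raise ValueError(
                            f"class {calls[first]!r} pool too small for "
                            f"formula size {size}")
                    candidates = [m for m in ids if m not in members]
            else:
                candidates = [m for m in ids if m not in members]
            members.append(candidates[int(rng.integers(len(candidates)))])
        out.append(FormulaRecord(f"F{k:03d}", tuple(members)))
    return out


def generate_bundle(config: GeneratorConfig,
                    out_dir: str | Path | None = None) -> SyntheticBundle:
    """Full bundle: tree, catalog, chemistry, interactions, formulas.

    With ``out_dir`` the catalog-readable files plus a JSON manifest are
    written; identical config and seed give byte-identical files.
    """
    from .profiling import build_potency_profiles, chromatin_call

    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5)]
    tree, catalog, traits = simulate_tree_and_traits(config)
    modcat = simulate_modification_catalog(config, seeds[3])
    interactions = simulate_interactions(catalog, modcat, config, seeds[1])
    profiles = build_potency_profiles(catalog, interactions, modcat)
    calls = {p.entity_id: chromatin_call(p, modcat).label for p in profiles}
    formulas = simulate_formulas(catalog, calls, config, seeds[2])
    bundle = SyntheticBundle(config=config, tree=tree, catalog=catalog,
                             traits=traits, interactions=interactions,
                             modcat=modcat, formulas=formulas)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "medicinals": out / "medicinals.tsv",
        "interactions": out / "interactions.tsv",
        "modifications": out / "modification_catalog.tsv",
        "formulas": out / "formulas.tsv",
        "tree": out / "tree.nwk",
        "manifest": out / "manifest.json",
    }
    write_medicinal_catalog(bundle.catalog, paths["medicinals"])
    write_interaction_table(bundle.interactions, paths["interactions"])
    rows = ["attribute_code\tconformation\tprotein_id"]
    for code in ATTRIBUTE_ORDER:
        for p in sorted(bundle.modcat.proteins_for(code)):
            rows.append(f"{code}\t{bundle.modcat.conformation[code]}\t{p}")
    paths["modifications"].write_text("\n".join(rows) + "\n")
    write_formulas(bundle.formulas, paths["formulas"])
    newick = bundle.tree.as_string(schema="newick", suppress_rooting=True)
    paths["tree"].write_text(newick)
    manifest = {"config": dataclasses.asdict(bundle.config),
                "seed": bundle.config.seed,
                "n_medicinals": len(bundle.catalog),
                "n_interactions": len(bundle.interactions),
                "n_formulas": len(bundle.formulas)}
    paths["manifest"].write_text(json.dumps(manifest, indent=2,
                                            default=list) + "\n")
    return {k: str(v) for k, v in paths.items()}
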