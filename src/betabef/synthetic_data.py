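"""Synthetic multi-cruise survey generator with known ground truth.

Emulates a repeated transect survey: ``n_cruises`` visits to ``n_sites``
stations, each yielding a sequencing-depth-standardized taxon count vector,
an environmental profile along an inshore-offshore gradient, and a bacterial
biomass measurement. Every stochastic ingredient is controlled:

* the phylogeny is a pure-birth (Yule) tree;
* community assembly follows one of three regimes — ``neutral`` (taxon
  sampling weights independent of phylogeny), ``homogenizing`` (all sites
  favor taxa whose Brownian-motion trait sits near one shared optimum,
  producing phylogenetically clustered communities), or ``diversifying``
  (sites receive maximally spread optima, producing phylogenetic
  overdispersion between sites);
* biomass carries a planted per-cruise beta-diversity effect ``slope_c``,
  either through a site-level mechanism or as an exact pair-level linear
  model for isolating the regression stages.

All draws descend from one integer seed through per-cruise substreams, so
runs are bit-reproducible and individual cruises can be regenerated alone.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .diversity import bray_curtis, build_pair_table
from .errors import ValidationError
from .io import ENV_COLUMNS, METADATA_COLUMNS, CommunityTable, validate_phylogeny

REGIMES = ("neutral", "homogenizing", "diversifying")

#: Inshore->offshore gradients: (inshore value, per-site step or decay).
#: Temperature/salinity/PAR rise linearly offshore; riverine nutrients and
#: chlorophyll a decay exponentially. Units: degC, PSU, uM, uM,
#: umol photons m-2 s-1, ug/L.
_ENV_GRADIENTS = {
    "temperature": ("linear", 20.0, 1.4, 3.0, 0.3),
    "salinity": ("linear", 29.5, 0.9, 0.4, 0.15),
    "nitrogen": ("decay", 18.0, 0.7, 0.3, 0.05),
    "phosphate": ("decay", 1.1, 0.6, 0.3, 0.01),
    "par": ("linear", 350.0, 30.0, 60.0, 20.0),
    "chla": ("decay", 2.6, 0.55, 0.4, 0.02),
}


@dataclass
class SyntheticConfig:
    """Study design and generative parameters for one synthetic survey."""

    n_cruises: int = 14
    n_sites: int = 6
    n_taxa: int = 150
    depth: int = 13129
    regime: str = "neutral"
    selection_strength: float = 5.0
    trait_sigma: float = 1.0
    #: per-cruise intercepts/slopes of the planted biomass model (natural
    #: log scale); scalars broadcast to all cruises.
    biomass_intercept_per_cruise: list[float] | float = 3.7
    biomass_slope_per_cruise: list[float] | float = 0.17
    noise_sd: float = 0.1
    #: lognormal sigma of per-site baseline relative abundances.
    abundance_sigma: float = 1.5
    seed: int = 0

    intercepts: np.ndarray = field(init=False, repr=False)
    slopes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if min(self.n_cruises, self.n_sites, self.n_taxa, self.depth) <= 0:
            raise ValidationError("all design counts must be positive")
        if self.depth < 1000:
            raise ValidationError("depth must be at least 1000 reads")
        if self.regime not in REGIMES:
            raise ValidationError(f"regime must be one of {REGIMES}")
        if self.selection_strength < 0 or self.noise_sd < 0:
            raise ValidationError("selection_strength and noise_sd must be >= 0")
        self.intercepts = self._broadcast(self.biomass_intercept_per_cruise)
        self.slopes = self._broadcast(self.biomass_slope_per_cruise)

    def _broadcast(self, v) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if arr.size == 1:
            arr = np.repeat(arr, self.n_cruises)
        if arr.size != self.n_cruises:
            raise ValidationError(
                f"per-cruise vector has length {arr.size}, expected {self.n_cruises}"
            )
        return arr

    def cruise_ids(self) -> list[str]:
        return [f"c{k + 1:02d}" for k in range(self.n_cruises)]

    def site_ids(self) -> list[str]:
        return [f"s{j + 1}" for j in range(self.n_sites)]

    def to_dict(self) -> dict:
        return {
            "n_cruises": self.n_cruises,
            "n_sites": self.n_sites,
            "n_taxa": self.n_taxa,
            "depth": self.depth,
            "regime": self.regime,
            "selection_strength": self.selection_strength,
            "trait_sigma": self.trait_sigma,
            "biomass_intercept_per_cruise": self.intercepts.tolist(),
            "biomass_slope_per_cruise": self.slopes.tolist(),
            "noise_sd": self.noise_sd,
            "abundance_sigma": self.abundance_sigma,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValidationError(f"unknown synthetic config keys: {sorted(unknown)}")
        return cls(**known)


def _cruise_rng(cfg: SyntheticConfig, stream: int, cruise: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream, cruise]))


def simulate_phylogeny(n_taxa: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule, birth rate 1) tree with ``n_taxa`` labeled tips.

    The birth-death simulator stops at the instant the last speciation
    creates the n-th lineage, which leaves that sibling pair with
    zero-length terminal edges; every tip edge is therefore extended by one
    further exponential waiting time (the time to the next, uncounted,
    event), keeping all branch lengths strictly positive without leaving
    the Yule model.
    """
    if n_taxa < 3:
        raise ValidationError("need at least 3 taxa for a usable phylogeny")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa, rng=rng
    )
    dt = rng.expovariate(n_taxa * 1.0)
    width = len(str(n_taxa))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.edge.length = (leaf.edge.length or 0.0) + dt
        leaf.taxon.label = f"t{i + 1:0{width}d}"
    tree.seed_node.edge.length = None
    return validate_phylogeny(tree)


def brownian_trait(
    tree: dendropy.Tree, sigma: float, seed: int | np.random.Generator
) -> pd.Series:
    """Evolve one continuous trait along the tree by Brownian motion.

    Root value 0; each edge adds a Normal(0, sigma^2 * length) increment.
    Returns tip values indexed by tip label.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    values: dict[int, float] = {}
    out = {}
    for node in tree.preorder_node_iter():
        parent = values.get(id(node.parent_node), 0.0)
        length = node.edge.length or 0.0
        values[id(node)] = parent + rng.normal(0.0, sigma * np.sqrt(length))
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out).sort_index()


def _site_optima(
    cfg: SyntheticConfig, trait: np.ndarray, rng: np.random.Generator
) -> np.ndarray | None:
    """Per-site trait optima for the selection regimes (None under neutral)."""
    if cfg.regime == "neutral":
        return None
    if cfg.regime == "homogenizing":
        # one shared optimum at a randomly chosen taxon's trait value, so
        # every site concentrates on the same neighborhood of the tree
        opt = float(trait[rng.integers(len(trait))])
        return np.repeat(opt, cfg.n_sites)
    # diversifying: optima maximally spread across the observed trait range
    return np.linspace(trait.min(), trait.max(), cfg.n_sites)


def simulate_communities(
    phylo: dendropy.Tree, cfg: SyntheticConfig
) -> list[CommunityTable]:
    """Draw per-cruise site x taxon read counts under the chosen regime.

    Per site, sampling weights are a lognormal baseline (independent across
    sites, emulating stochastic local dynamics) multiplied — under the
    selection regimes — by a Gaussian kernel of the distance between each
    taxon's trait and the site's optimum. The selected trait is redrawn for
    every cruise (each cruise selects on its own environmental axis) and
    z-standardized before the kernel is applied, so ``selection_strength``
    is in units of inverse squared trait standard deviations and its effect
    does not depend on the depth of any particular tree. Reads are a single
    multinomial draw of ``cfg.depth`` per site.
    """
    labels = sorted(leaf.taxon.label for leaf in phylo.leaf_node_iter())
    if len(labels) < cfg.n_taxa:
        raise ValidationError(
            f"tree has {len(labels)} tips < n_taxa={cfg.n_taxa}"
        )
    labels = labels[: cfg.n_taxa]

    tables = []
    for k, cruise in enumerate(cfg.cruise_ids()):
        rng = _cruise_rng(cfg, 1, k)
        trait = brownian_trait(phylo, cfg.trait_sigma, rng).loc[labels].to_numpy()
        sd = trait.std()
        if sd > 0:
            trait = (trait - trait.mean()) / sd
        optima = _site_optima(cfg, trait, rng)
        counts = np.empty((cfg.n_sites, cfg.n_taxa), dtype=np.int64)
        for j in range(cfg.n_sites):
            base = rng.lognormal(0.0, cfg.abundance_sigma, size=cfg.n_taxa)
            if optima is None:
                w = base
            else:
                kernel = np.exp(
                    -cfg.selection_strength * (trait - optima[j]) ** 2
                )
                w = base * kernel
            counts[j] = rng.multinomial(cfg.depth, w / w.sum())
        df = pd.DataFrame(counts, index=cfg.site_ids(), columns=labels)
        tables.append(CommunityTable(cruise_id=cruise, counts=df).validate())
    return tables


def simulate_environment(cfg: SyntheticConfig) -> pd.DataFrame:
    """Environmental covariates along the inshore-offshore gradient."""
    rows = []
    for k, cruise in enumerate(cfg.cruise_ids()):
        rng = _cruise_rng(cfg, 2, k)
        for j, site in enumerate(cfg.site_ids()):
            row = {"cruise": cruise, "site": site}
            for col, (kind, a, b, cr_sd, site_term) in _ENV_GRADIENTS.items():
                if kind == "linear":
                    cruise_off = rng.normal(0.0, cr_sd)
                    row[col] = a + b * j + cruise_off + rng.normal(0.0, site_term)
                else:  # exponential decay with multiplicative noise
                    row[col] = max(
                        site_term, a * np.exp(-b * j) * rng.lognormal(0.0, cr_sd)
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_site_biomass(
    tables: list[CommunityTable], cfg: SyntheticConfig, mode: str = "site"
) -> pd.DataFrame:
    """Attach biomass (and environment) to the simulated communities.

    mode="site" returns a metadata table (one row per cruise-site). Site
    biomass is ``exp(intercept_c / 2) * mbar^slope_c`` times lognormal
    noise, where ``mbar`` is the site's mean Bray-Curtis dissimilarity to
    the cruise's other sites — pairs of dissimilar sites then sum to higher
    biomass when ``slope_c > 0``.

    mode="pair-exact" returns a pair-observation table in which
    ``log(summed_biomass) = intercept_c + slope_c * log(BC) +
    Normal(0, noise_sd)`` holds exactly at the pair level, for isolating
    the regression stages.
    """
    if mode not in ("site", "pair-exact"):
        raise ValidationError(f"unknown biomass mode {mode!r}")
    if len(tables) != cfg.n_cruises:
        raise ValidationError(
            f"{len(tables)} community tables but n_cruises={cfg.n_cruises}"
        )
    env = simulate_environment(cfg)

    if mode == "site":
        rows = []
        for k, t in enumerate(tables):
            rng = _cruise_rng(cfg, 4, k)
            counts = t.counts.to_numpy()
            n = counts.shape[0]
            bc = np.zeros((n, n))
            for i, j in combinations(range(n), 2):
                bc[i, j] = bc[j, i] = bray_curtis(counts[i], counts[j])
            mbar = bc.sum(axis=1) / (n - 1)
            biomass = (
                np.exp(cfg.intercepts[k] / 2.0)
                * mbar ** cfg.slopes[k]
                * rng.lognormal(0.0, cfg.noise_sd, size=n)
            )
            hnf = rng.lognormal(np.log(2.0), 0.5, size=n)
            for j, site in enumerate(t.site_ids):
                rows.append(
                    {
                        "cruise": t.cruise_id,
                        "site": site,
                        "bacterial_biomass": biomass[j],
                        "hnf_biomass": hnf[j],
                    }
                )
        meta = pd.DataFrame(rows).merge(env, on=["cruise", "site"])
        return meta[METADATA_COLUMNS]

    # pair-exact: start from a placeholder metadata table, then overwrite
    # summed biomass with the exact pair-level linear model
    meta = env.copy()
    meta["bacterial_biomass"] = 1.0
    meta["hnf_biomass"] = 1.0
    meta = meta[METADATA_COLUMNS]
    pairs = build_pair_table(tables, meta)
    cruise_index = {c: k for k, c in enumerate(cfg.cruise_ids())}
    log_bc = np.log(pairs["bray_curtis"].to_numpy())
    summed = np.empty(len(pairs))
    for cruise, sub in pairs.groupby("cruise", sort=False):
        k = cruise_index[cruise]
        rng = _cruise_rng(cfg, 4, k)
        noise = rng.normal(0.0, cfg.noise_sd, size=len(sub))
        idx = sub.index.to_numpy()
        summed[idx] = np.exp(
            cfg.intercepts[k] + cfg.slopes[k] * log_bc[idx] + noise
        )
    pairs["summed_biomass"] = summed
    return pairs


def truth_table(cfg: SyntheticConfig) -> pd.DataFrame:
    """Ground-truth record of the planted generative parameters."""
    return pd.DataFrame(
        {
            "cruise": cfg.cruise_ids(),
            "regime": cfg.regime,
            "intercept": cfg.intercepts,
            "slope": cfg.slopes,
        }
    )
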