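"""Phylogenetic Mantel correlogram of taxon habitat preferences.

The use of phylogenetic turnover to infer assembly processes presupposes
that ecological similarity tracks phylogenetic relatedness. This module
tests that premise: each taxon gets a niche value per environmental
variable (abundance-weighted mean of the environment where it occurs), and
a Mantel correlogram relates between-taxon niche distances to between-taxon
phylogenetic distances, class by class, with permutation tests and a Holm
correction across distance classes. Significant negative correlations at
short phylogenetic distances indicate phylogenetic signal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .assembly import PhyloDistances
from .errors import ValidationError
from .io import ENV_COLUMNS, CommunityTable

logger = logging.getLogger(__name__)


def niche_values(
    tables: list[CommunityTable],
    metadata: pd.DataFrame,
    variable: str,
) -> pd.Series:
    """Abundance-weighted mean environment per taxon.

    niche(t) = sum_sites(relative abundance of t x env) /
               sum_sites(relative abundance of t), pooled over every
    cruise-site with a non-missing value of ``variable``. Taxa never
    observed are excluded with a warning.
    """
    if variable not in metadata.columns:
        raise ValidationError(f"variable {variable!r} not in metadata")
    meta = metadata.set_index(["cruise", "site"])[variable]
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for t in tables:
        counts = t.counts.to_numpy(dtype=float)
        rel = counts / counts.sum(axis=1, keepdims=True)
        for i, site in enumerate(t.site_ids):
            env = meta.get((t.cruise_id, site), np.nan)
            if pd.isna(env):
                continue
            for j, taxon in enumerate(t.taxon_ids):
                if rel[i, j] > 0:
                    num[taxon] = num.get(taxon, 0.0) + rel[i, j] * env
                    den[taxon] = den.get(taxon, 0.0) + rel[i, j]
    all_taxa = {tax for t in tables for tax in t.taxon_ids}
    unobserved = all_taxa - set(den)
    if unobserved:
        logger.warning("%d never-observed taxa excluded from niche values",
                       len(unobserved))
    return pd.Series({k: num[k] / den[k] for k in sorted(den)})


def niche_distance_matrix(
    tables: list[CommunityTable],
    metadata: pd.DataFrame,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Euclidean between-taxon distances over standardized niche values.

    Niche values for each variable are z-standardized before computing
    distances so no single covariate's units dominate.
    """
    variables = list(variables) if variables is not None else list(ENV_COLUMNS)
    cols = {}
    for v in variables:
        nv = niche_values(tables, metadata, v)
        sd = nv.std(ddof=0)
        cols[v] = (nv - nv.mean()) / sd if sd > 0 else nv * 0.0
    niche = pd.DataFrame(cols).dropna()
    d = squareform(pdist(niche.to_numpy()))
    return pd.DataFrame(d, index=niche.index, columns=niche.index)


def _condensed(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_correlogram(
    niche_dist: pd.DataFrame,
    phylo_dist: PhyloDistances | pd.DataFrame,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mantel correlogram of niche distance against phylogenetic distance.

    Phylogenetic distances are cut into equal-width classes (Sturges' rule
    by default). For each class, the Mantel statistic is the Pearson
    correlation between the condensed niche-distance vector and the class
    membership indicator; p-values come from ``n_perm`` taxon-label
    permutations (two-sided) and are Holm-corrected across classes.
    Classes with fewer than 3 pairs are reported with missing statistics.
    """
    if isinstance(phylo_dist, PhyloDistances):
        phylo_dist = pd.DataFrame(
            phylo_dist.matrix, index=phylo_dist.labels, columns=phylo_dist.labels
        )
    taxa = sorted(set(niche_dist.index) & set(phylo_dist.index))
    if len(taxa) < 4:
        raise ValidationError("need at least 4 shared taxa for a correlogram")
    nd = niche_dist.loc[taxa, taxa].to_numpy(dtype=float)
    pdm = phylo_dist.loc[taxa, taxa].to_numpy(dtype=float)
    t = len(taxa)
    x = _condensed(nd)
    g = _condensed(pdm)
    n_pairs = len(g)
    if n_classes is None:
        n_classes = int(np.ceil(np.log2(n_pairs))) + 1  # Sturges
    edges = np.linspace(g.min(), g.max(), n_classes + 1)
    which = np.clip(np.digitize(g, edges[1:-1], right=False), 0, n_classes - 1)

    # centered indicator matrix, one row per class
    indicators = np.zeros((n_classes, n_pairs))
    class_n = np.zeros(n_classes, dtype=int)
    for k in range(n_classes):
        mask = which == k
        class_n[k] = int(mask.sum())
        indicators[k] = mask.astype(float)
    ind_c = indicators - indicators.mean(axis=1, keepdims=True)
    ind_norm = np.linalg.norm(ind_c, axis=1)

    def class_r(vec: np.ndarray) -> np.ndarray:
        vc = vec - vec.mean()
        nv = np.linalg.norm(vc)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                (ind_norm > 0) & (nv > 0), (ind_c @ vc) / (ind_norm * nv), np.nan
            )

    r_obs = class_r(x)

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(t, k=1)
    exceed = np.zeros(n_classes)
    for _ in range(n_perm):
        p = rng.permutation(t)
        r_perm = class_r(nd[np.ix_(p, p)][iu])
        exceed += np.abs(r_perm) >= np.abs(r_obs) - 1e-12
    pvals = (exceed + 1.0) / (n_perm + 1.0)

    usable = (class_n >= 3) & np.isfinite(r_obs)
    pvals = np.where(usable, pvals, np.nan)
    r_obs = np.where(usable, r_obs, np.nan)
    p_holm = np.full(n_classes, np.nan)
    if usable.any():
        p_holm[usable] = multipletests(pvals[usable], method="holm")[1]

    return pd.DataFrame(
        {
            "lower": edges[:-1],
            "upper": edges[1:],
            "n_pairs": class_n,
            "mantel_r": r_obs,
            "p_value": pvals,
            "p_holm": p_holm,
            "significant": np.where(usable, p_holm < alpha, False).astype(bool),
        }
    )
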