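"""Between-community phylogenetic turnover against a tip-shuffle null.

For each pair of communities we compute the observed mean pairwise
phylogenetic distance (MPD_obs) between their taxa and compare it with a
null distribution obtained by shuffling tip labels of the phylogeny. The
z-score

    beta_mpti = (MPD_obs - mean(MPD_null)) / sd(MPD_null)

is negative when the two communities hold taxa more closely related than a
random draw from the taxon pool (homogenizing selection) and positive when
they hold more distantly related taxa than random (diversifying selection).
Values near zero are consistent with stochastic assembly.

The null pool — the set of tips whose labels are permuted — is configurable:
``all`` (every tip of the tree, the convention of regional-pool null models
and the default), ``cruise`` (taxa observed anywhere in the same cruise), or
``pair`` (only the union of the two communities' taxa).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from itertools import permutations

import dendropy
import numpy as np
import pandas as pd

from .errors import DegenerateNullError, ValidationError
from .io import CommunityTable

logger = logging.getLogger(__name__)

DEFAULT_N_RAND = 999
POOLS = ("pair", "cruise", "all")
PAIR_SETS = ("between", "union")


@dataclass
class PhyloDistances:
    """Cophenetic (patristic) distance matrix with a stable label order."""

    labels: list[str]
    matrix: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {lab: i for i, lab in enumerate(self.labels)}

    def positions(self, taxa) -> np.ndarray:
        try:
            return np.fromiter(
                (self.index[t] for t in taxa), dtype=np.intp, count=len(taxa)
            )
        except KeyError as exc:
            raise ValidationError(f"taxon {exc.args[0]!r} not in tree") from exc


@dataclass
class NullDistribution:
    mpd_values: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.mpd_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.mpd_values, ddof=0))


@dataclass
class BetaMPTIResult:
    mpd_obs: float
    null: NullDistribution
    beta_mpti: float


def cophenetic_distances(tree: dendropy.Tree) -> PhyloDistances:
    """Tip-to-tip path-length (patristic) distances, sorted tip order."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return PhyloDistances(labels=labels, matrix=mat)


def _mean_pair_distance(
    mat: np.ndarray, ia: np.ndarray, ib: np.ndarray, pair_set: str
) -> float:
    if pair_set == "between":
        # all cross pairs; shared taxa contribute zero-distance self pairs
        return float(mat[np.ix_(ia, ib)].mean())
    if pair_set == "union":
        iu = np.unique(np.concatenate([ia, ib]))
        k = len(iu)
        if k < 2:
            return 0.0
        sub = mat[np.ix_(iu, iu)]
        return float(sub.sum() / (k * (k - 1)))
    raise ValidationError(f"pair_set must be one of {PAIR_SETS}, got {pair_set!r}")


def mpd_between(dist: PhyloDistances, taxa_a, taxa_b, pair_set: str = "between") -> float:
    """Mean pairwise phylogenetic distance for one community pair.

    ``between`` (default) averages over all cross-community pairs, shared
    taxa entering as zero-distance pairs; ``union`` averages over all
    unordered pairs of distinct taxa in the union of both communities.
    """
    if not len(taxa_a) or not len(taxa_b):
        raise ValidationError("both taxon sets must be non-empty")
    ia = dist.positions(sorted(taxa_a))
    ib = dist.positions(sorted(taxa_b))
    return _mean_pair_distance(dist.matrix, ia, ib, pair_set)


def _pair_seed(seed: int, taxa_a, taxa_b) -> np.random.SeedSequence:
    """Content-addressed per-pair RNG stream.

    Keyed on the unordered pair of taxon sets, so any execution order (or
    parallel schedule) reproduces the same nulls, and pairs with identical
    composition receive identical z-scores.
    """
    ka = zlib.crc32(",".join(sorted(taxa_a)).encode())
    kb = zlib.crc32(",".join(sorted(taxa_b)).encode())
    lo, hi = sorted((ka, kb))
    return np.random.SeedSequence([seed, lo, hi])


def beta_mpti(
    dist: PhyloDistances,
    taxa_a,
    taxa_b,
    n_rand: int = DEFAULT_N_RAND,
    pool: str = "all",
    pair_set: str = "between",
    seed: int = 0,
    pool_taxa=None,
) -> BetaMPTIResult:
    """z-score of MPD_obs against ``n_rand`` tip-label shuffles.

    ``pool`` selects which tips are shuffled: the whole tree (``all``), an
    explicit regional set (``cruise``, supplied via ``pool_taxa``), or the
    union of the two communities (``pair``). Raises
    :class:`DegenerateNullError` when the null has zero spread (e.g. both
    communities contain every pooled taxon, so shuffling cannot change MPD).
    """
    if pool not in POOLS:
        raise ValidationError(f"pool must be one of {POOLS}, got {pool!r}")
    taxa_a = sorted(taxa_a)
    taxa_b = sorted(taxa_b)
    if not taxa_a or not taxa_b:
        raise ValidationError("both taxon sets must be non-empty")
    if len(set(taxa_a) | set(taxa_b)) < 2:
        raise DegenerateNullError("pair union has fewer than 2 taxa")

    if pool == "all":
        pool_labels = dist.labels
    elif pool == "cruise":
        if pool_taxa is None:
            raise ValidationError("pool='cruise' requires pool_taxa")
        pool_labels = sorted(set(pool_taxa) | set(taxa_a) | set(taxa_b))
    else:  # pair
        pool_labels = sorted(set(taxa_a) | set(taxa_b))

    pool_idx = dist.positions(pool_labels)
    sub = dist.matrix[np.ix_(pool_idx, pool_idx)]
    pos_in_pool = {lab: i for i, lab in enumerate(pool_labels)}
    ia = np.fromiter((pos_in_pool[t] for t in taxa_a), dtype=np.intp)
    ib = np.fromiter((pos_in_pool[t] for t in taxa_b), dtype=np.intp)

    mpd_obs = _mean_pair_distance(sub, ia, ib, pair_set)

    rng = np.random.default_rng(_pair_seed(seed, taxa_a, taxa_b))
    m = len(pool_labels)
    nulls = np.empty(n_rand)
    for k in range(n_rand):
        perm = rng.permutation(m)
        nulls[k] = _mean_pair_distance(sub, perm[ia], perm[ib], pair_set)

    null = NullDistribution(mpd_values=nulls)
    # summation order across permutations leaves O(eps) jitter even when the
    # null is exactly degenerate, so test spread relative to the mean
    if null.sd <= 1e-12 * max(1.0, abs(null.mean)):
        raise DegenerateNullError(
            "null MPD distribution has zero spread; beta_mpti undefined"
        )
    return BetaMPTIResult(
        mpd_obs=mpd_obs, null=null, beta_mpti=(mpd_obs - null.mean) / null.sd
    )


def exhaustive_null(
    dist: PhyloDistances, taxa_a, taxa_b, pool_labels, pair_set: str = "between"
) -> np.ndarray:
    """MPD under every tip-label permutation of a (small) pool.

    Brute-force counterpart of the sampled null, for pools small enough to
    enumerate (factorial growth: practical up to ~8 tips).
    """
    pool_labels = sorted(pool_labels)
    pool_idx = dist.positions(pool_labels)
    sub = dist.matrix[np.ix_(pool_idx, pool_idx)]
    pos = {lab: i for i, lab in enumerate(pool_labels)}
    ia = np.fromiter((pos[t] for t in sorted(taxa_a)), dtype=np.intp)
    ib = np.fromiter((pos[t] for t in sorted(taxa_b)), dtype=np.intp)
    vals = [
        _mean_pair_distance(sub, np.asarray(p)[ia], np.asarray(p)[ib], pair_set)
        for p in permutations(range(len(pool_labels)))
    ]
    return np.asarray(vals)


def pairwise_assembly(
    pairs: pd.DataFrame,
    tables: list[CommunityTable],
    dist: PhyloDistances,
    n_rand: int = DEFAULT_N_RAND,
    pool: str = "all",
    pair_set: str = "between",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill ``beta_mpti`` for every pair row and summarize per cruise.

    Taxon sets are presence/absence reductions of the (rarefied) counts, so
    scaling all counts changes nothing. Degenerate nulls are recorded as
    missing with a warning. Returns the completed pair table and a cruise
    summary (``mean_beta_mpti`` over that cruise's pairs, pair/missing
    counts).
    """
    presence_by_cruise = {t.cruise_id: t.presence() for t in tables}
    pairs = pairs.copy()
    values = np.full(len(pairs), np.nan)
    for i, row in enumerate(pairs.itertuples(index=False)):
        presence = presence_by_cruise[row.cruise]
        taxa_a = presence[row.site_a]
        taxa_b = presence[row.site_b]
        pool_taxa = None
        if pool == "cruise":
            pool_taxa = set().union(*presence.values())
        try:
            res = beta_mpti(
                dist, taxa_a, taxa_b, n_rand=n_rand, pool=pool,
                pair_set=pair_set, seed=seed, pool_taxa=pool_taxa,
            )
            values[i] = res.beta_mpti
        except DegenerateNullError:
            logger.warning(
                "degenerate null for cruise %s pair (%s, %s); beta_mpti missing",
                row.cruise, row.site_a, row.site_b,
            )
    pairs["beta_mpti"] = values

    summary = (
        pairs.groupby("cruise", sort=True)["beta_mpti"]
        .agg(
            mean_beta_mpti="mean",
            n_pairs="size",
            n_missing=lambda s: int(s.isna().sum()),
        )
        .reset_index()
    )
    return pairs, summary
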