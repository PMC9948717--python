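"""Depth standardization, alpha/beta diversity and biomass conversion.

The unit of downstream analysis is the unordered site pair within a cruise:
for every pair we record Bray-Curtis dissimilarity (the beta-diversity
measure), the summed bacterial biomass of the two sites (the functioning
proxy), pooled alpha diversity of the combined composition, and the
arithmetic mean of the two sites' environmental covariates.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import distance as ssd
from scipy.stats import entropy

from .errors import ValidationError
from .io import ENV_COLUMNS, CommunityTable

#: Carbon content per cell, in grams of carbon. Bacterial cells are assigned
#: 2e-14 g C/cell and heterotrophic nanoflagellates 4.7e-12 g C/cell.
CARBON_PER_CELL_G = {"bacteria": 2e-14, "hnf": 4.7e-12}

#: Columns of the pair-observation table, in canonical order.
PAIR_COLUMNS = (
    ["cruise", "site_a", "site_b", "bray_curtis", "summed_biomass",
     "pooled_richness", "pooled_shannon", "beta_mpti"] + ENV_COLUMNS
)


def cells_to_biomass(density: float, organism: str) -> float:
    """Convert a cell density (cells/L) to biomass in ug C/L."""
    if organism not in CARBON_PER_CELL_G:
        raise ValidationError(f"unknown organism {organism!r}")
    if density < 0:
        raise ValidationError("cell density must be non-negative")
    return density * CARBON_PER_CELL_G[organism] * 1e6  # g -> ug


def subsample_counts(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Rarefy every site once, without replacement, to a common depth.

    Each row is redrawn as a multivariate hypergeometric sample of exactly
    ``depth`` reads, so output counts never exceed input counts. Rows whose
    total already equals ``depth`` pass through unchanged.
    """
    counts = table.counts.to_numpy()
    totals = counts.sum(axis=1)
    short = totals < depth
    if short.any():
        site = table.site_ids[int(np.argmax(short))]
        raise ValidationError(
            f"cruise {table.cruise_id}: site {site!r} has "
            f"{int(totals[short][0])} reads < requested depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        if totals[i] == depth:
            out[i] = counts[i]
        else:
            out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    df = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return CommunityTable(cruise_id=table.cruise_id, counts=df).validate()


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("count vectors must be 1-D and of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("negative abundances")
    if x.sum() == 0 and y.sum() == 0:
        raise ValidationError("both communities empty: dissimilarity undefined")
    return x, y


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(x,y)) / (sum x + sum y)."""
    x, y = _check_pair(x, y)
    return float(ssd.braycurtis(x, y))


def pooled_alpha(x, y) -> tuple[int, float]:
    """Richness and Shannon entropy (nats) of the combined composition."""
    x, y = _check_pair(x, y)
    combined = x + y
    richness = int(np.count_nonzero(combined))
    shannon = float(entropy(combined[combined > 0]))
    return richness, shannon


def build_pair_table(
    tables: list[CommunityTable], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Assemble one row per unordered within-cruise site pair.

    ``beta_mpti`` is left as NaN; the assembly stage fills it. Environmental
    covariates are the mean of the two sites, ignoring missing values
    pairwise (mean of the available site if one is missing, NaN if both are).
    """
    meta = metadata.set_index(["cruise", "site"])
    rows = []
    for t in tables:
        counts = t.counts
        for site_a, site_b in combinations(t.site_ids, 2):
            x = counts.loc[site_a].to_numpy()
            y = counts.loc[site_b].to_numpy()
            bc = bray_curtis(x, y)
            rich, shan = pooled_alpha(x, y)
            ma = meta.loc[(t.cruise_id, site_a)]
            mb = meta.loc[(t.cruise_id, site_b)]
            row = {
                "cruise": t.cruise_id,
                "site_a": site_a,
                "site_b": site_b,
                "bray_curtis": bc,
                "summed_biomass": float(
                    ma["bacterial_biomass"] + mb["bacterial_biomass"]
                ),
                "pooled_richness": rich,
                "pooled_shannon": shan,
                "beta_mpti": np.nan,
            }
            for col in ENV_COLUMNS:
                avail = [v for v in (ma[col], mb[col]) if pd.notna(v)]
                row[col] = float(np.mean(avail)) if avail else np.nan
            rows.append(row)
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)
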