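"""Readers/writers and the validated on-disk data model.

Three artifact kinds flow through the pipeline:

* a rooted phylogeny with branch lengths (newick),
* per-cruise site x taxon count tables (TSV, integer cells),
* per-site metadata (TSV) with biomass and environmental covariates.

All tables are tab-separated UTF-8 with a header row; missing values are
encoded as the literal string ``NA``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import CrossReferenceError, ValidationError

#: Environmental covariates carried through pair averaging and regressions.
ENV_COLUMNS = ["temperature", "salinity", "nitrogen", "phosphate", "par", "chla"]

#: Full metadata schema, in canonical column order.
METADATA_COLUMNS = ["cruise", "site", "bacterial_biomass", "hnf_biomass"] + ENV_COLUMNS

NA_REP = "NA"


@dataclass
class CommunityTable:
    """One cruise's site x taxon count matrix (rarefied or raw).

    ``counts`` is a site-indexed DataFrame with taxon columns and
    non-negative integer cells.
    """

    cruise_id: str
    counts: pd.DataFrame

    @property
    def site_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def validate(self) -> "CommunityTable":
        c = self.counts
        c.index.name = "site"
        c.columns.name = None
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValidationError(
                f"cruise {self.cruise_id}: duplicate site or taxon identifiers"
            )
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.round(vals)):
                raise ValidationError(
                    f"cruise {self.cruise_id}: counts must be finite integers"
                )
            self.counts = c.astype(np.int64)
            vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValidationError(f"cruise {self.cruise_id}: negative counts")
        if np.any(vals.sum(axis=1) == 0):
            empty = [s for s, t in zip(c.index, vals.sum(axis=1)) if t == 0]
            raise ValidationError(
                f"cruise {self.cruise_id}: all-zero site rows {empty}"
            )
        return self

    def presence(self) -> dict[str, frozenset[str]]:
        """Per-site sets of observed taxa (presence/absence view)."""
        out = {}
        arr = self.counts.to_numpy()
        taxa = np.asarray(self.counts.columns)
        for i, site in enumerate(self.counts.index):
            out[site] = frozenset(taxa[arr[i] > 0])
        return out


# ---------------------------------------------------------------------------
# phylogeny


def validate_phylogeny(tree: dendropy.Tree) -> dendropy.Tree:
    """Check tip-label uniqueness and non-negative branch lengths."""
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate tip labels: {dupes}")
    if any(l is None or l == "" for l in labels):
        raise ValidationError("unlabeled tip in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError(f"negative branch length {edge.length}")
    return tree


def read_phylogeny(path: str | Path) -> dendropy.Tree:
    """Parse a rooted newick tree and validate it.

    Zero-length branches are permitted (maximum-likelihood trees commonly
    clamp negative estimates to zero); negative lengths are not.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ValidationError(f"malformed newick in {path}: {exc}") from exc
    return validate_phylogeny(tree)


def write_phylogeny(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# count tables


_CRUISE_FROM_NAME = re.compile(r"counts_(?P<cruise>[^./]+)\.tsv$")


def read_counts(path: str | Path, cruise_id: str | None = None) -> CommunityTable:
    """Read one cruise's site x taxon TSV (first column = site id)."""
    path = Path(path)
    if cruise_id is None:
        m = _CRUISE_FROM_NAME.search(path.name)
        cruise_id = m.group("cruise") if m else path.stem
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing values in count table")
    vals = df.to_numpy()
    if np.any(vals != np.floor(vals)):
        bad = df.columns[(vals != np.floor(vals)).any(axis=0)][0]
        raise ValidationError(f"{path}: non-integer count in column {bad!r}")
    return CommunityTable(cruise_id=cruise_id, counts=df.astype(np.int64)).validate()


def write_counts(table: CommunityTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = "site"
    out.to_csv(path, sep="\t", na_rep=NA_REP)


# ---------------------------------------------------------------------------
# site metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-site metadata table and validate its schema."""
    df = pd.read_csv(
        path, sep="\t", na_values=[NA_REP], dtype={"cruise": str, "site": str}
    )
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    if df.duplicated(["cruise", "site"]).any():
        raise ValidationError("duplicate (cruise, site) rows in metadata")
    bb = df["bacterial_biomass"]
    if bb.isna().any() or (bb <= 0).any():
        raise ValidationError("bacterial_biomass must be present and > 0")
    for col in ENV_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        if np.any(np.isinf(vals)):
            raise ValidationError(f"non-finite value in metadata column {col!r}")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def cross_check(
    tables: list[CommunityTable], metadata: pd.DataFrame, tree: dendropy.Tree | None = None
) -> None:
    """Verify that counts, metadata and (optionally) the tree agree.

    Every (cruise, site) in any count table must have a metadata row, and
    every taxon column must resolve to a tree tip when a tree is supplied.
    """
    meta_keys = set(zip(metadata["cruise"], metadata["site"]))
    for t in tables:
        for site in t.site_ids:
            if (t.cruise_id, site) not in meta_keys:
                raise CrossReferenceError(
                    f"site ({t.cruise_id!r}, {site!r}) present in counts but "
                    "absent from metadata"
                )
    if tree is not None:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        for t in tables:
            unknown = set(t.taxon_ids) - tips
            if unknown:
                raise CrossReferenceError(
                    f"cruise {t.cruise_id}: taxa not in tree: "
                    f"{sorted(unknown)[:5]}..."
                )
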