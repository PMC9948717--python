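"""End-to-end orchestration: simulate/load -> rarefy -> beta diversity ->
assembly null models -> hypothesis tests -> phylogenetic signal.

A run is described by a :class:`RunConfig` (usually parsed from YAML) and
produces a directory of TSV tables plus a JSON manifest with the config
echo, seed, package versions, input checksums and all warnings raised
during the run. Identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import cophenetic_distances, pairwise_assembly
from .bef_regression import (
    RegressionResult,
    beta_vs_assembly,
    cross_cruise_regression,
    cruise_covariates,
    fit_cruise_slopes,
    fit_hypothesis1,
)
from .diversity import build_pair_table, subsample_counts
from .errors import BetaBefError, ConfigError
from .io import (
    CommunityTable,
    cross_check,
    read_counts,
    read_metadata,
    read_phylogeny,
    write_counts,
    write_metadata,
    write_phylogeny,
)
from .phylosignal import mantel_correlogram, niche_distance_matrix
from .synthetic_data import (
    SyntheticConfig,
    simulate_communities,
    simulate_phylogeny,
    simulate_site_biomass,
    truth_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    synthetic: SyntheticConfig | None = None
    tree_path: str | None = None
    counts_paths: list[str] = field(default_factory=list)
    metadata_path: str | None = None
    depth: int | str = "min"  # "min" = global minimum row sum
    n_rand: int = 999
    pool: str = "all"
    pair_set: str = "between"
    alpha: float = 0.05
    protect: tuple[str, ...] = ("log_bray_curtis",)
    n_perm: int = 999
    n_classes: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        has_real = bool(self.tree_path or self.counts_paths or self.metadata_path)
        if self.synthetic is not None and has_real:
            raise ConfigError(
                "config must supply either synthetic parameters or real-data "
                "paths, not both"
            )
        if self.synthetic is None:
            if not (self.tree_path and self.counts_paths and self.metadata_path):
                raise ConfigError(
                    "real-data runs need tree, counts and metadata paths"
                )
        if isinstance(self.depth, str) and self.depth != "min":
            raise ConfigError("depth must be an integer or 'min'")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        synthetic = None
        if "synthetic" in raw:
            synthetic = SyntheticConfig.from_dict(raw["synthetic"] or {})
        data = raw.get("data", {}) or {}
        params = raw.get("params", {}) or {}
        cfg = cls(
            synthetic=synthetic,
            tree_path=data.get("tree"),
            counts_paths=list(data.get("counts", [])),
            metadata_path=data.get("metadata"),
            seed=raw.get("seed", 0),
            **params,
        )
        if seed is not None:
            cfg.seed = seed
            if cfg.synthetic is not None:
                cfg.synthetic.seed = seed
        return cfg

    def echo(self) -> dict:
        d = {
            "depth": self.depth,
            "n_rand": self.n_rand,
            "pool": self.pool,
            "pair_set": self.pair_set,
            "alpha": self.alpha,
            "protect": list(self.protect),
            "n_perm": self.n_perm,
            "n_classes": self.n_classes,
            "seed": self.seed,
        }
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        else:
            d["data"] = {
                "tree": self.tree_path,
                "counts": list(self.counts_paths),
                "metadata": self.metadata_path,
            }
        return d


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(self.format(record))


@contextmanager
def _stage(name: str):
    try:
        yield
    except BetaBefError as exc:
        raise BetaBefError(f"pipeline stage {name!r} failed: {exc}") from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _regression_record(res: RegressionResult) -> dict:
    return {
        "model_type": res.model_type,
        "nobs": res.nobs,
        "marginal_r2": res.marginal_r2,
        "random_effect_var": res.random_effect_var,
        "resid_var": res.resid_var,
        "selection_trace": res.selection_trace,
        "notes": res.notes,
    }


def _write_model(res: RegressionResult, path: Path) -> None:
    out = res.terms.copy()
    out.index.name = "term"
    out.to_csv(path, sep="\t", na_rep="NA")


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full analysis and write all artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("betabef").addHandler(collector)
    manifest: dict = {
        "package": {"name": "betabef", "version": __version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": config.echo(),
        "input_checksums": {},
        "models": {},
    }
    try:
        # --- inputs -------------------------------------------------------
        if config.synthetic is not None:
            with _stage("simulate"):
                cfg = config.synthetic
                tree = simulate_phylogeny(cfg.n_taxa, cfg.seed)
                tables = simulate_communities(tree, cfg)
                metadata = simulate_site_biomass(tables, cfg, mode="site")
                write_phylogeny(tree, outdir / "tree.nwk")
                for t in tables:
                    write_counts(t, outdir / f"counts_{t.cruise_id}.tsv")
                write_metadata(metadata, outdir / "metadata.tsv")
                truth_table(cfg).to_csv(
                    outdir / "truth.tsv", sep="\t", index=False
                )
        else:
            with _stage("load"):
                tree = read_phylogeny(config.tree_path)
                tables = [read_counts(p) for p in config.counts_paths]
                metadata = read_metadata(config.metadata_path)
                cross_check(tables, metadata, tree)
                for p in [config.tree_path, *config.counts_paths,
                          config.metadata_path]:
                    manifest["input_checksums"][str(p)] = _sha256(Path(p))

        # --- rarefaction --------------------------------------------------
        with _stage("rarefy"):
            if config.depth == "min":
                depth = min(
                    int(t.counts.sum(axis=1).min()) for t in tables
                )
            else:
                depth = int(config.depth)
            manifest["depth_used"] = depth
            rarefied = []
            for k, t in enumerate(tables):
                sub_seed = int(
                    np.random.SeedSequence([config.seed, 5, k]).generate_state(1)[0]
                    % (2**31)
                )
                rarefied.append(subsample_counts(t, depth, sub_seed))
            tables = rarefied

        # --- beta diversity ----------------------------------------------
        with _stage("betadiv"):
            pairs = build_pair_table(tables, metadata)

        # --- assembly null models ----------------------------------------
        with _stage("assembly"):
            dist = cophenetic_distances(tree)
            pairs, cruise_assembly = pairwise_assembly(
                pairs, tables, dist, n_rand=config.n_rand, pool=config.pool,
                pair_set=config.pair_set, seed=config.seed,
            )
            pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False, na_rep="NA")
            cruise_assembly.to_csv(
                outdir / "cruise_assembly.tsv", sep="\t", index=False, na_rep="NA"
            )

        # --- hypothesis tests --------------------------------------------
        with _stage("bef"):
            effects = fit_cruise_slopes(pairs, alpha=config.alpha)
            effects = effects.merge(
                cruise_assembly[["cruise", "mean_beta_mpti"]], on="cruise"
            )
            effects.to_csv(
                outdir / "cruise_effects.tsv", sep="\t", index=False, na_rep="NA"
            )
            h1 = fit_hypothesis1(pairs, alpha=config.alpha, protect=config.protect)
            _write_model(h1, outdir / "h1_model.tsv")
            manifest["models"]["h1"] = _regression_record(h1)
            bva = beta_vs_assembly(pairs)
            _write_model(bva, outdir / "beta_vs_assembly.tsv")
            manifest["models"]["beta_vs_assembly"] = _regression_record(bva)
            h2 = cross_cruise_regression(
                effects, cruise_covariates(pairs), alpha=config.alpha
            )
            _write_model(h2, outdir / "h2_model.tsv")
            manifest["models"]["h2"] = _regression_record(h2)
            trace_lines = [
                f"h1: {' -> '.join(h1.selection_trace) or '(no removals)'}",
                f"h2: {' -> '.join(h2.selection_trace) or '(no removals)'}",
            ]
            (outdir / "selection_trace.txt").write_text(
                "\n".join(trace_lines) + "\n", encoding="utf-8"
            )

        # --- phylogenetic signal -----------------------------------------
        with _stage("signal"):
            niche = niche_distance_matrix(tables, metadata)
            correlogram = mantel_correlogram(
                niche, dist, n_classes=config.n_classes,
                n_perm=config.n_perm, seed=config.seed,
            )
            correlogram.to_csv(
                outdir / "correlogram.tsv", sep="\t", index=False, na_rep="NA"
            )

        manifest["warnings"] = collector.messages
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    finally:
        logging.getLogger("betabef").removeHandler(collector)
    return outdir
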