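"""End-to-end orchestration: ingest -> features -> diversity -> comparison.

A run is a pure function of (inputs, config, seed): the same config produces
byte-identical TSV outputs.  Every table carries a header comment with the
tool version, the config hash and the seed so results are traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composition import DEFAULT_N_WINDOWS, gc_content, gcsi, genome_size
from .codon_selection import s_value_for_record
from .diversity16s import genus_diversity_table, read_alignment
from .genome_io import (
    COMMON_BE,
    DEFAULT_THRESHOLD,
    ChromosomeRecord,
    assign_groups,
    parse_env_flags,
    read_genbank,
    read_grouping_table,
    select_largest_replicon,
)
from .group_stats import bh_fdr, cliffs_delta, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

DEFAULT_FEATURES = ["size_bp", "gc_percent", "gcsi", "s_value"]


@dataclass
class RunConfig:
    genbank_dir: str
    grouping: str
    out_dir: str
    alignment: str | None = None
    tree: str | None = None
    threshold: int = DEFAULT_THRESHOLD
    n_windows: int = DEFAULT_N_WINDOWS
    env_categories: list[str] = field(default_factory=list)
    features: list[str] = field(default_factory=lambda: list(DEFAULT_FEATURES))
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("genbank_dir", "grouping", "alignment", "tree"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config path {name}={path} does not exist")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant config (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("out_dir", "log_level")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def load_records(genbank_dir) -> list[ChromosomeRecord]:
    """Read all GenBank files in a directory, one representative per organism."""
    per_organism: dict[str, list[ChromosomeRecord]] = {}
    paths = sorted(Path(genbank_dir).glob("*.gb")) + sorted(Path(genbank_dir).glob("*.gbk"))
    if not paths:
        raise FileNotFoundError(f"no .gb/.gbk files under {genbank_dir}")
    for path in paths:
        for rec in read_genbank(path):
            per_organism.setdefault(rec.organism, []).append(rec)
    return [select_largest_replicon(recs) for _, recs in sorted(per_organism.items())]


def feature_table(
    records: list[ChromosomeRecord],
    grouping: pd.DataFrame,
    threshold: int = DEFAULT_THRESHOLD,
    n_windows: int = DEFAULT_N_WINDOWS,
) -> pd.DataFrame:
    """Per-genome table of the four genomic features (Table S8 shape)."""
    table = assign_groups(records, grouping, threshold=threshold)
    rows = []
    for rec in records:
        g = gcsi(rec, n_windows=n_windows)
        sres = s_value_for_record(rec)
        rows.append(
            {
                "accession": rec.accession,
                "size_bp": genome_size(rec),
                "gc_percent": gc_content(rec),
                "gcsi": g.gcsi,
                "sr": g.sr,
                "dist": g.dist,
                "s_value": sres.s if sres is not None else float("nan"),
                "heg_gene_count": sres.heg_gene_count if sres is not None else 0,
            }
        )
    feats = pd.DataFrame(rows)
    return table.drop(columns=["size_bp"]).merge(feats, on="accession")


def environment_battery(
    features: pd.DataFrame,
    categories: list[str] | None = None,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Within-"Common BE" comparisons split by environment-category flags.

    For each category, genomes flagged with it are compared against the
    remaining Common BE genomes on every feature; BH adjustment is applied
    jointly across the whole battery.  Splits with fewer than 2 genomes on
    either side are skipped with a notice.
    """
    feature_names = feature_names or [f for f in DEFAULT_FEATURES if f in features.columns]
    be = features[features["group"] == COMMON_BE].copy()
    flag_sets = be["env_flags"].map(parse_env_flags)
    if categories is None:
        categories = sorted(set().union(*flag_sets) if len(flag_sets) else set())
    rows = []
    for cat in categories:
        mask = flag_sets.map(lambda s: cat in s)
        for feat in feature_names:
            sub = be[[feat]].assign(flagged=mask).dropna()
            x = sub.loc[sub["flagged"], feat].to_numpy(dtype=float)
            y = sub.loc[~sub["flagged"], feat].to_numpy(dtype=float)
            if x.size < 2 or y.size < 2:
                logger.info("category %r / %s skipped: %d vs %d genomes",
                            cat, feat, x.size, y.size)
                continue
            u, p = wilcoxon_rank_sum(x, y)
            delta, mag = cliffs_delta(x, y)
            rows.append(
                {"category": cat, "feature": feat, "n1": x.size, "n2": y.size,
                 "median1": float(np.median(x)), "median2": float(np.median(y)),
                 "U": u, "p": p, "delta": delta, "magnitude": mag}
            )
    out = pd.DataFrame(
        rows, columns=["category", "feature", "n1", "n2", "median1", "median2",
                       "U", "p", "delta", "magnitude"]
    )
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out[["category", "feature", "n1", "n2", "median1", "median2",
                   "U", "p", "q", "delta", "magnitude"]]
    return out


def genus_summary(features: pd.DataFrame, feature_names: list[str] | None = None) -> pd.DataFrame:
    """Five-number summary plus 1.5*IQR outlier count per genus and feature."""
    feature_names = feature_names or [f for f in DEFAULT_FEATURES if f in features.columns]
    rows = []
    for genus, sub in features.groupby("genus"):
        for feat in feature_names:
            v = sub[feat].dropna().to_numpy(dtype=float)
            if v.size == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            outliers = v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)]
            rows.append(
                {"genus": genus, "feature": feat, "n": v.size,
                 "min": float(v.min()), "q25": float(q1), "median": float(med),
                 "q75": float(q3), "max": float(v.max()),
                 "n_outliers": int(outliers.size),
                 "outliers": ";".join(f"{o:.6g}" for o in sorted(outliers))}
            )
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = (
        f"# begenomics {__version__} | config {config.config_hash()} | "
        f"seed {config.seed} | coordinates 1-based inclusive\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and write the report bundle.

    Outputs: features.tsv, comparison.tsv, genus_summary.tsv, optionally
    diversity.tsv and env_battery.tsv, plus manifest.json.  A stage failure
    aborts with the stage name; partial outputs are retained.
    """
    from .group_stats import compare_groups

    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "ingest"
    try:
        records = load_records(config.genbank_dir)
        grouping = read_grouping_table(config.grouping)

        stage = "features"
        feats = feature_table(records, grouping, threshold=config.threshold,
                              n_windows=config.n_windows)
        if (feats["group"] == COMMON_BE).sum() == 0:
            raise ValueError(
                "assign_groups produced an empty 'Common BE' group "
                f"(threshold {config.threshold})"
            )
        outputs["features"] = out_dir / "features.tsv"
        _write_tsv(feats, outputs["features"], config)

        if config.alignment:
            stage = "diversity"
            alignment = read_alignment(config.alignment)
            tree = None
            if config.tree:
                import dendropy

                tree = dendropy.Tree.get(path=str(config.tree), schema="newick")
            div = genus_diversity_table(alignment, tree=tree)
            outputs["diversity"] = out_dir / "diversity.tsv"
            _write_tsv(div, outputs["diversity"], config)

        stage = "comparison"
        usable = [f for f in config.features if feats[f].notna().sum() >= 4]
        comparison = compare_groups(feats, usable)
        outputs["comparison"] = out_dir / "comparison.tsv"
        _write_tsv(comparison, outputs["comparison"], config)

        stage = "genus_summary"
        outputs["genus_summary"] = out_dir / "genus_summary.tsv"
        _write_tsv(genus_summary(feats), outputs["genus_summary"], config)

        if config.env_categories:
            stage = "environment_battery"
            env = environment_battery(feats, categories=config.env_categories)
            outputs["env_battery"] = out_dir / "env_battery.tsv"
            _write_tsv(env, outputs["env_battery"], config)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": asdict(config),
            "outputs": {k: str(v) for k, v in outputs.items()},
            "n_records": len(records),
        }
        outputs["manifest"] = out_dir / "manifest.json"
        outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outputs
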