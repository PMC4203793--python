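"""End-to-end pipeline: QC -> table -> tests -> views -> ordination -> RF.

The pipeline is a pure function of (inputs, config, seed): every
statistical output is a tab-separated table written under the output
directory and listed, with input hashes, in a JSON manifest.  Floats are
written at 6 significant digits so runs diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import forest, ordination, qc, tables, twopart, views

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: either ``fastq_dir`` (per-sample FASTQ named
    ``<sample>.fastq``) plus ``taxonomy_tsv``, or a pre-built
    ``count_tsv``.  ``metadata_tsv`` is always required.
    """

    out_dir: str
    metadata_tsv: str
    fastq_dir: str | None = None
    taxonomy_tsv: str | None = None
    count_tsv: str | None = None
    comparisons: Sequence[tuple[str, str]] = ()
    qc_params: qc.QCParams = field(default_factory=qc.QCParams)
    min_prop: float = 0.5
    pca_k: int = 3
    rf_trees: int = 10000
    rf_groups: Sequence[str] | None = None
    seed: int = 0
    make_figures: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        fastq_mode = self.fastq_dir is not None
        table_mode = self.count_tsv is not None
        if fastq_mode == table_mode:
            raise ValueError(
                "set exactly one input mode: fastq_dir+taxonomy_tsv or count_tsv"
            )
        if fastq_mode and self.taxonomy_tsv is None:
            raise ValueError("fastq_dir input requires taxonomy_tsv")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a YAML config file; keyword arguments override file values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    qc_raw = raw.pop("qc_params", None)
    if qc_raw is not None:
        raw["qc_params"] = qc.QCParams(**qc_raw)
    comps = raw.get("comparisons")
    if comps:
        raw["comparisons"] = [tuple(c) for c in comps]
    return PipelineConfig(**raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> Path:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the artifact manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
        "stages_completed": [],
    }

    # --- validation before any compute
    groups = tables.read_metadata(config.metadata_tsv)
    manifest["inputs"]["metadata_tsv"] = _sha256(config.metadata_tsv)
    known = set(groups)
    for a, b in config.comparisons:
        for g in (a, b):
            if g not in known:
                raise ValueError(f"comparison group {g!r} not in metadata")
    if config.rf_groups:
        for g in config.rf_groups:
            if g not in known:
                raise ValueError(f"rf group {g!r} not in metadata")

    # --- stage: qc / table
    if config.count_tsv is not None:
        table = tables.read_count_table(config.count_tsv, config.metadata_tsv)
        manifest["inputs"]["count_tsv"] = _sha256(config.count_tsv)
        logger.info("loaded count table: %d samples x %d taxa",
                    len(table.samples), len(table.taxa))
    else:
        fastq_dir = Path(config.fastq_dir)
        fastq_by_sample = {
            p.stem: p for p in sorted(fastq_dir.glob("*.fastq"))
        }
        if not fastq_by_sample:
            raise ValueError(f"no .fastq files under {fastq_dir}")
        taxonomy = qc.read_taxonomy_tsv(config.taxonomy_tsv)
        manifest["inputs"]["taxonomy_tsv"] = _sha256(config.taxonomy_tsv)
        table, report = qc.run_qc(
            fastq_by_sample, taxonomy, groups, config.qc_params
        )
        manifest["outputs"]["qc_report"] = str(
            _write_tsv(report.reset_index(), out / "qc_report.tsv")
        )
    table.to_tsv(out / "count_table.tsv")
    manifest["outputs"]["count_table"] = str(out / "count_table.tsv")
    manifest["stages_completed"].append("table")

    # --- stage: group summaries
    summary = tables.group_summary(table)
    manifest["outputs"]["group_summary"] = str(
        _write_tsv(summary, out / "group_summary.tsv")
    )
    manifest["stages_completed"].append("summaries")

    # --- stage: per-pair two-part comparisons + effect views
    for a, b in config.comparisons:
        tag = f"{a}_vs_{b}".replace("/", "-")
        results = twopart.run_comparison(table, a, b, min_prop=config.min_prop)
        frame = twopart.results_to_frame(results)
        manifest["outputs"][f"twopart_{tag}"] = str(
            _write_tsv(frame, out / f"twopart_{tag}.tsv")
        )
        if results:
            manhattan = views.manhattan_points(results)
            effects = views.delta_effects(table, a, b, results)
            manifest["outputs"][f"manhattan_{tag}"] = str(
                _write_tsv(manhattan, out / f"manhattan_{tag}.tsv")
            )
            manifest["outputs"][f"effects_{tag}"] = str(
                _write_tsv(effects, out / f"effects_{tag}.tsv")
            )
            if config.make_figures:
                views.plot_manhattan(
                    manhattan, out / f"manhattan_{tag}.svg", title=f"{a} vs {b}"
                )
                views.plot_delta_effects(effects, out / f"effects_{tag}.svg", a, b)
                manifest["outputs"][f"manhattan_{tag}_fig"] = str(
                    out / f"manhattan_{tag}.svg"
                )
                manifest["outputs"][f"effects_{tag}_fig"] = str(
                    out / f"effects_{tag}.svg"
                )
    manifest["stages_completed"].append("twopart")

    # --- stage: Kruskal-Wallis screen across all groups
    if len(table.group_names) >= 2:
        kw = twopart.kruskal_wallis_screen(table)
        kw_frame = pd.DataFrame(
            [
                {"taxon": r.taxon, "H": r.h, "df": r.df,
                 "p_raw": r.p_raw, "p_adj": r.p_adj}
                for r in kw
            ]
        )
        manifest["outputs"]["kruskal_wallis"] = str(
            _write_tsv(kw_frame, out / "kruskal_wallis.tsv")
        )
        manifest["stages_completed"].append("kruskal_wallis")

    # --- stage: CLR-PCA ordination
    clr = ordination.clr_transform(table)
    k = min(config.pca_k, len(table.samples) - 1, len(table.taxa))
    pca = ordination.pca_fit(clr, k)
    manifest["outputs"]["clr"] = str(
        _write_tsv(clr.values, out / "clr.tsv", index=True)
    )
    manifest["outputs"]["pca_scores"] = str(
        _write_tsv(pca.scores, out / "pca_scores.tsv", index=True)
    )
    manifest["outputs"]["pca_loadings"] = str(
        _write_tsv(pca.loadings, out / "pca_loadings.tsv", index=True)
    )
    ratio = pd.DataFrame(
        {
            "component": [f"PC{j + 1}" for j in range(k)],
            "explained_variance_ratio": pca.explained_variance_ratio,
        }
    )
    manifest["outputs"]["pca_variance"] = str(
        _write_tsv(ratio, out / "pca_variance.tsv")
    )
    if config.make_figures and k >= 2:
        _plot_biplot(table, pca, out / "pca_biplot_12.svg", 0, 1)
        manifest["outputs"]["pca_biplot_12"] = str(out / "pca_biplot_12.svg")
        if k >= 3:
            _plot_biplot(table, pca, out / "pca_biplot_23.svg", 1, 2)
            manifest["outputs"]["pca_biplot_23"] = str(out / "pca_biplot_23.svg")
    manifest["stages_completed"].append("ordination")

    # --- stage: random forest
    rf = forest.rf_importance(
        table,
        groups=config.rf_groups,
        n_trees=config.rf_trees,
        seed=config.seed,
    )
    manifest["outputs"]["rf_ranking"] = str(
        _write_tsv(rf.ranking, out / "rf_ranking.tsv")
    )
    manifest["rf_oob_error"] = rf.oob_error
    if config.make_figures:
        _plot_importance(rf, out / "rf_importance.svg")
        manifest["outputs"]["rf_importance_fig"] = str(out / "rf_importance.svg")
    manifest["stages_completed"].append("random_forest")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def _plot_biplot(table, pca, path, i: int, j: int) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5))
    ratio = pca.explained_variance_ratio
    cols = pca.scores.columns
    for group in table.group_names:
        rows = table.group_samples(group)
        ax.scatter(
            pca.scores.loc[rows, cols[i]],
            pca.scores.loc[rows, cols[j]],
            label=group,
            s=22,
        )
    # arrows for the most influential taxa, scaled for biplot parity
    influence = (pca.loadings[[cols[i], cols[j]]] ** 2).sum(axis=1)
    scale = pca.scores[[cols[i], cols[j]]].abs().to_numpy().max()
    for taxon in influence.nlargest(5).index:
        lx, ly = pca.loadings.loc[taxon, [cols[i], cols[j]]]
        ax.annotate(
            taxon.split("/")[-1],
            (lx * scale, ly * scale),
            fontsize=7,
            color="dimgrey",
        )
        ax.arrow(0, 0, lx * scale * 0.9, ly * scale * 0.9,
                 color="dimgrey", lw=0.6, head_width=0.0)
    ax.set_xlabel(f"{cols[i]} ({100 * ratio[i]:.1f}%)")
    ax.set_ylabel(f"{cols[j]} ({100 * ratio[j]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_importance(rf, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = rf.ranking.head(15)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.barh(
        [t.split("/")[-1] for t in top["taxon"]][::-1],
        top["importance"][::-1],
        color="steelblue",
    )
    ax.set_xlabel("mean decrease in impurity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
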