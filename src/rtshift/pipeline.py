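"""End-to-end orchestration: inputs -> preprocess -> profiles -> GC -> stats.

``run_pipeline`` binds the stages in the fixed order (rarefy, outlier
scoring, replicate equalization, class aggregation, per-condition profiles,
weighted class GC, pairwise enrichment, per-pair GC regressions) and writes
every product as schema-versioned TSV plus a JSON manifest carrying inputs,
parameters, seeds and output checksums, so a run is reproducible from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .class_profiles import (
    aggregate_to_class,
    collapse_low_abundance,
    condition_profiles,
    diversity_indices,
    diversity_kruskal,
    profiles_frame,
)
from .enrichment import (
    enrichment_frame,
    fit_all_regressions,
    pairwise_enrichment,
    regressions_frame,
)
from .gc_content import class_gc_frame, class_weighted_gc, otu_weights
from .io_formats import (
    SCHEMA_COMMENT,
    check_join_closure,
    read_fasta,
    read_metadata,
    read_otu_table,
    read_taxonomy,
)
from .preprocess import RarefactionSpec, drop_samples, equalize_replicates, flag_outliers, rarefy

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    otu_table: Path
    taxonomy: Path
    metadata: Path
    sequences: Path | None = None  # GC analyses skipped if absent
    out_dir: Path = Path("rtshift_out")
    table_format: str = "tsv"
    orientation: str = "samples"
    depth: int = 9000
    seed_rarefy: int = 0
    outlier_k: float = 3.0
    drop_outliers: bool = False  # flag-based removal; default report-only
    drop_samples: list[str] = field(default_factory=list)
    replicates: int | str = "auto"
    seed_equalize: int = 0
    top_fraction: float = 0.15
    holm: bool = False
    allow_single: bool = False

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("otu_table", "taxonomy", "metadata", "sequences", "out_dir"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=index)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for p in (cfg.otu_table, cfg.taxonomy, cfg.metadata):
        if not Path(p).exists():
            raise FileNotFoundError(f"required input missing: {p}")
    if cfg.sequences is not None and not Path(cfg.sequences).exists():
        raise FileNotFoundError(f"FASTA input missing: {cfg.sequences}")

    table = read_otu_table(cfg.otu_table, format=cfg.table_format, orientation=cfg.orientation)
    tax = read_taxonomy(cfg.taxonomy)
    meta = read_metadata(cfg.metadata)
    seqs = read_fasta(cfg.sequences) if cfg.sequences is not None else None
    check_join_closure(table, tax, meta=meta, seqs=seqs)
    if seqs is None:
        log.warning("no FASTA supplied: GC-dependent analyses are skipped")

    # preprocess: rarefy -> outliers -> equalize (fixed order)
    rarefied, report = rarefy(table, RarefactionSpec(cfg.depth, cfg.seed_rarefy))
    if cfg.drop_samples:
        rarefied = drop_samples(rarefied, cfg.drop_samples)
    scores = flag_outliers(rarefied, meta, k=cfg.outlier_k)
    report.flagged_outliers = scores
    if cfg.drop_outliers:
        flagged = [s.sample_id for s in scores if s.flagged]
        if flagged:
            rarefied = drop_samples(rarefied, flagged)
    rarefied, removed = equalize_replicates(rarefied, meta, n=cfg.replicates, seed=cfg.seed_equalize)
    report.removed_for_balance = removed
    report.final_replicates_per_condition = {
        c: len(m) for c, m in meta.conditions(rarefied.sample_ids).items()
    }
    report.validate_disjoint()

    ct = aggregate_to_class(rarefied, tax)
    profiles = condition_profiles(ct, meta, allow_single=cfg.allow_single)
    diversity = diversity_indices(rarefied)

    outputs: dict[str, Path] = {}
    _write_tsv(ct.to_frame(), out / "class_table.tsv", index=True)
    outputs["class_table"] = out / "class_table.tsv"
    _write_tsv(profiles_frame(profiles), out / "condition_profiles.tsv")
    outputs["condition_profiles"] = out / "condition_profiles.tsv"
    _write_tsv(diversity.reset_index(), out / "diversity.tsv")
    outputs["diversity"] = out / "diversity.tsv"

    report_rows = (
        [{"sample_id": s, "rule": "shallow", "score": ""} for s in report.dropped_shallow]
        + [
            {"sample_id": o.sample_id, "rule": "outlier" if o.flagged else "outlier_score",
             "score": f"{o.score:.6f}"}
            for o in report.flagged_outliers
        ]
        + [{"sample_id": s, "rule": "balance", "score": ""} for s in report.removed_for_balance]
    )
    _write_tsv(pd.DataFrame(report_rows, columns=["sample_id", "rule", "score"]),
               out / "preprocess_report.tsv")
    outputs["preprocess_report"] = out / "preprocess_report.tsv"

    gc = None
    records = pairwise_enrichment(profiles)
    if seqs is not None:
        gc = class_weighted_gc(tax, seqs, otu_weights(rarefied))
        _write_tsv(class_gc_frame(gc), out / "class_gc.tsv")
        outputs["class_gc"] = out / "class_gc.tsv"
        reports = fit_all_regressions(records, gc, holm=cfg.holm)
        _write_tsv(regressions_frame(reports), out / "regressions.tsv")
        outputs["regressions"] = out / "regressions.tsv"
    _write_tsv(enrichment_frame(records, gc), out / "enrichment.tsv")
    outputs["enrichment"] = out / "enrichment.tsv"

    fig_outputs = export_figure_tables(profiles, records, gc, diversity, out,
                                       top_fraction=cfg.top_fraction)
    outputs.update(fig_outputs)

    cfg_dict = {
        k: (str(v) if isinstance(v, Path) else v)
        for k, v in dataclasses.asdict(cfg).items()
    }
    manifest = {
        "tool": "rtshift",
        "version": __version__,
        "config": cfg_dict,
        "seeds": {"rarefy": cfg.seed_rarefy, "equalize": cfg.seed_equalize},
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in {
                "otu_table": cfg.otu_table,
                "taxonomy": cfg.taxonomy,
                "metadata": cfg.metadata,
                **({"sequences": cfg.sequences} if cfg.sequences else {}),
            }.items()
        },
        "preprocess": {
            "dropped_shallow": report.dropped_shallow,
            "flagged_outliers": [
                {"sample_id": o.sample_id, "score": o.score, "flagged": o.flagged}
                for o in report.flagged_outliers
            ],
            "removed_for_balance": report.removed_for_balance,
            "final_replicates_per_condition": {
                f"{c[0]} {c[1]:g}C": n
                for c, n in report.final_replicates_per_condition.items()
            },
        },
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def export_figure_tables(profiles, records, gc, diversity: pd.DataFrame, out: Path,
                         top_fraction: float = 0.15) -> dict[str, Path]:
    """Emit plot-ready long-format tables (stacked bars, enrichment-vs-GC,
    per-sample diversity)."""
    out = Path(out)
    outputs: dict[str, Path] = {}

    collapsed = collapse_low_abundance(profiles, top_fraction=top_fraction)
    _write_tsv(profiles_frame(collapsed), out / "fig_stacked_bar.tsv")
    outputs["fig_stacked_bar"] = out / "fig_stacked_bar.tsv"

    enr = enrichment_frame(records, gc)
    enr = enr[["class", "condition_a", "condition_b", "enrichment", "enrichment_sd",
               "weighted_gc"]]
    _write_tsv(enr, out / "fig_enrichment.tsv")
    outputs["fig_enrichment"] = out / "fig_enrichment.tsv"

    _write_tsv(diversity.reset_index(), out / "fig_diversity.tsv")
    outputs["fig_diversity"] = out / "fig_diversity.tsv"
    return outputs
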