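"""Sampling-effort and replicate-structure normalization.

The pipeline order is fixed: rarefy to an even depth (dropping samples
shallower than the target), score within-condition outliers, then remove
random samples so every condition keeps the same number of replicates.
Each step is a pure function of its inputs and named seed.

Outlier scoring is report-only: the score is each sample's mean Bray-Curtis
dissimilarity (on relative abundances) to its same-condition replicates, and
a sample is flagged when its score exceeds the within-condition median by
more than ``k`` median absolute deviations. Actual removal requires an
explicit sample list, preserving an audit trail for manual curation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import braycurtis

from .io_formats import OtuTable, SampleMetadata

log = logging.getLogger(__name__)


@dataclass
class RarefactionSpec:
    depth: int = 9000
    seed: int = 0
    drop_below: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("rarefaction depth must be >= 1")


@dataclass
class OutlierScore:
    sample_id: str
    condition: tuple[str, float]
    score: float
    flagged: bool


@dataclass
class PreprocessReport:
    dropped_shallow: list[str] = field(default_factory=list)
    flagged_outliers: list[OutlierScore] = field(default_factory=list)
    removed_for_balance: list[str] = field(default_factory=list)
    final_replicates_per_condition: dict[tuple[str, float], int] = field(default_factory=dict)

    def validate_disjoint(self) -> None:
        a = set(self.dropped_shallow)
        b = {o.sample_id for o in self.flagged_outliers if o.flagged}
        c = set(self.removed_for_balance)
        if a & b or a & c or b & c:
            raise ValueError("preprocess removal lists overlap")


def rarefy(table: OtuTable, spec: RarefactionSpec) -> tuple[OtuTable, PreprocessReport]:
    """Subsample each sample without replacement to exactly ``spec.depth`` reads.

    Each retained sample's counts are a single multivariate-hypergeometric
    draw of ``depth`` reads from that sample's reads; samples with fewer
    total reads than ``depth`` are dropped (when ``drop_below``) and listed
    in the report. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    totals = table.sample_totals()
    report = PreprocessReport()
    keep_rows: list[int] = []
    for i, (sid, tot) in enumerate(zip(table.sample_ids, totals)):
        if tot < spec.depth:
            if not spec.drop_below:
                raise ValueError(
                    f"sample {sid!r} has {tot} < depth {spec.depth} and drop_below is off"
                )
            report.dropped_shallow.append(sid)
            log.info("rarefy: dropped %s (%d reads < depth %d)", sid, tot, spec.depth)
        else:
            keep_rows.append(i)
    if not keep_rows:
        raise ValueError("no samples survive rarefaction")
    new_counts = np.empty((len(keep_rows), table.n_otus), dtype=np.int64)
    for j, i in enumerate(keep_rows):
        new_counts[j] = rng.multivariate_hypergeometric(table.counts[i], spec.depth)
    rarefied = OtuTable([table.sample_ids[i] for i in keep_rows], list(table.otu_ids), new_counts)
    return rarefied, report


def flag_outliers(table: OtuTable, meta: SampleMetadata, k: float = 3.0) -> list[OutlierScore]:
    """Score within-condition dissimilarity and flag outlying replicates.

    Returns one record per sample in conditions with >= 2 replicates;
    conditions with fewer are skipped with a warning. Flagging is advisory:
    callers remove samples explicitly.
    """
    scores: list[OutlierScore] = []
    rel = table.counts / table.sample_totals()[:, None]
    row = {s: i for i, s in enumerate(table.sample_ids)}
    for cond, members in meta.conditions(table.sample_ids).items():
        if len(members) < 2:
            warnings.warn(
                f"condition {cond} has {len(members)} sample(s); outlier scoring skipped",
                stacklevel=2,
            )
            continue
        if len(members) < 3:
            log.info("flag_outliers: condition %s has only 2 replicates; scores reported "
                     "but MAD threshold is weak", cond)
        cond_scores = []
        for s in members:
            others = [braycurtis(rel[row[s]], rel[row[t]]) for t in members if t != s]
            cond_scores.append(float(np.mean(others)))
        med = float(np.median(cond_scores))
        mad = float(np.median(np.abs(np.asarray(cond_scores) - med)))
        cutoff = med + k * mad
        for s, sc in zip(members, cond_scores):
            flagged = bool(np.isfinite(cutoff) and sc > cutoff)
            scores.append(OutlierScore(s, cond, sc, flagged))
            if flagged:
                log.info("flag_outliers: %s flagged in %s (score %.4f > %.4f)", s, cond, sc, cutoff)
    return scores


def equalize_replicates(table: OtuTable, meta: SampleMetadata,
                        n: int | str = "auto", seed: int = 0) -> tuple[OtuTable, list[str]]:
    """Remove random samples so every condition retains exactly ``n`` replicates.

    ``n="auto"`` targets the current minimum replicate count. Removals are
    uniform at random within each over-represented condition and
    deterministic given ``seed``.
    """
    groups = meta.conditions(table.sample_ids)
    counts = {c: len(ms) for c, ms in groups.items()}
    target = min(counts.values()) if n == "auto" else int(n)
    too_small = [c for c, m in counts.items() if m < target]
    if too_small:
        raise ValueError(
            f"condition(s) {too_small} have fewer than {target} replicates"
        )
    rng = np.random.default_rng(seed)
    removed: list[str] = []
    for cond in groups:  # iteration order fixed by conditions() sort
        members = groups[cond]
        excess = len(members) - target
        if excess > 0:
            drop = rng.choice(len(members), size=excess, replace=False)
            for i in sorted(drop):
                removed.append(members[i])
                log.info("equalize_replicates: removed %s from %s", members[i], cond)
    keep = [s for s in table.sample_ids if s not in set(removed)]
    return table.select_samples(keep), removed


def drop_samples(table: OtuTable, samples: list[str]) -> OtuTable:
    """Remove an explicit sample list (manual outlier curation)."""
    missing = [s for s in samples if s not in table.sample_ids]
    if missing:
        raise ValueError(f"cannot drop unknown sample(s) {missing}")
    keep = [s for s in table.sample_ids if s not in set(samples)]
    return table.select_samples(keep)
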