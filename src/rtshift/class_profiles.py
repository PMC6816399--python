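"""Class-level aggregation, per-condition abundance profiles, alpha diversity.

OTU counts are summed to taxonomic class (OTUs without a class rank pool
into "Unclassified"), converted to within-sample relative abundances, then
averaged across the replicates of each condition. The per-condition mean and
replicate standard deviation of each class are the A/B and dA/dB that feed
the enrichment statistic downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import UNCLASSIFIED, OtuTable, SampleMetadata, TaxonomyMap

LOW_ABUNDANCE_LABEL = "Low abundance groups"


@dataclass
class ClassTable:
    """Counts summed to taxonomic class; same samples as the source table."""

    sample_ids: list[str]
    class_labels: list[str]
    counts: np.ndarray  # samples x classes, int64

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.class_labels)


@dataclass
class ConditionProfile:
    """Mean and replicate SD of one class's relative abundance in one condition."""

    condition: tuple[str, float]
    class_label: str
    mean_rel_abund: float
    sd_rel_abund: float
    n_replicates: int


def aggregate_to_class(table: OtuTable, tax: TaxonomyMap) -> ClassTable:
    """Sum OTU counts to class per sample; reads are conserved exactly."""
    missing = [o for o in table.otu_ids if o not in tax]
    if missing:
        raise ValueError(f"OTUs without taxonomy entry: {missing}")
    labels = [tax.class_of(o) for o in table.otu_ids]
    df = table.to_frame().T.groupby(pd.Index(labels, name="class")).sum().T
    # drop phantom all-zero classes, keep deterministic (sorted) class order
    df = df.loc[:, df.sum(axis=0) > 0]
    df = df[sorted(df.columns)]
    return ClassTable(list(df.index), list(df.columns), df.to_numpy(dtype=np.int64))


def condition_profiles(ct: ClassTable, meta: SampleMetadata,
                       allow_single: bool = False) -> list[ConditionProfile]:
    """Average within-sample relative abundances over each condition's replicates.

    The mean is the A (or B) of the enrichment statistic and the sample
    standard deviation (n-1 denominator) is dA (or dB). Classes absent from
    a condition get mean 0, sd 0.
    """
    totals = ct.counts.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(ct.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero-total sample(s): {bad}")
    rel = ct.counts / totals[:, None]
    row = {s: i for i, s in enumerate(ct.sample_ids)}
    profiles: list[ConditionProfile] = []
    for cond, members in meta.conditions(ct.sample_ids).items():
        if len(members) < 2 and not allow_single:
            raise ValueError(
                f"condition {cond} has a single replicate; sd undefined "
                "(pass allow_single=True to accept)"
            )
        sub = rel[[row[s] for s in members], :]
        means = sub.mean(axis=0)
        sds = sub.std(axis=0, ddof=1) if len(members) > 1 else np.zeros(sub.shape[1])
        for j, cls in enumerate(ct.class_labels):
            profiles.append(ConditionProfile(cond, cls, float(means[j]), float(sds[j]), len(members)))
    return profiles


def profiles_frame(profiles: list[ConditionProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "enzyme": [p.condition[0] for p in profiles],
            "temperature_c": [p.condition[1] for p in profiles],
            "class": [p.class_label for p in profiles],
            "mean_rel_abund": [p.mean_rel_abund for p in profiles],
            "sd_rel_abund": [p.sd_rel_abund for p in profiles],
            "n_replicates": [p.n_replicates for p in profiles],
        }
    )


def collapse_low_abundance(profiles: list[ConditionProfile], top_fraction: float = 0.15,
                           label: str = LOW_ABUNDANCE_LABEL) -> list[ConditionProfile]:
    """Keep the top fraction of classes by grand-mean abundance; pool the rest.

    Classes are ranked by their mean relative abundance averaged over all
    conditions; the top ``ceil(top_fraction * K)`` of the K non-Unclassified
    classes are kept, the remainder is merged into ``label`` (mean = sum of
    member means, sd = root-sum-square of member sds). "Unclassified" is
    never pooled. Ties at the cutoff break lexicographically by class label.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    ranked_classes = sorted({p.class_label for p in profiles if p.class_label != UNCLASSIFIED})
    grand = {
        c: float(np.mean([p.mean_rel_abund for p in profiles if p.class_label == c]))
        for c in ranked_classes
    }
    k_keep = math.ceil(top_fraction * len(ranked_classes))
    order = sorted(ranked_classes, key=lambda c: (-grand[c], c))
    keep = set(order[:k_keep])
    out: list[ConditionProfile] = []
    pooled: dict[tuple[str, float], list[ConditionProfile]] = {}
    for p in profiles:
        if p.class_label == UNCLASSIFIED or p.class_label in keep:
            out.append(p)
        else:
            pooled.setdefault(p.condition, []).append(p)
    for cond, members in pooled.items():
        out.append(
            ConditionProfile(
                cond,
                label,
                sum(m.mean_rel_abund for m in members),
                math.sqrt(sum(m.sd_rel_abund**2 for m in members)),
                members[0].n_replicates,
            )
        )
    return out


def diversity_indices(table: OtuTable) -> pd.DataFrame:
    """Per-sample richness, Shannon diversity (nats) and Pielou evenness.

    Richness counts OTUs with nonzero reads; H = -sum p_i ln p_i over
    nonzero proportions; J = H / ln(richness) is reported as missing when
    richness is 1. Warns when sample totals are unequal (compare rarefied
    tables only).
    """
    totals = table.sample_totals()
    if (totals <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero-total sample(s): {bad}")
    if len(set(totals.tolist())) > 1:
        warnings.warn("sample totals are unequal; rarefy before comparing diversity",
                      stacklevel=2)
    rows = []
    for i, sid in enumerate(table.sample_ids):
        counts = table.counts[i]
        nz = counts[counts > 0]
        p = nz / nz.sum()
        richness = int(nz.size)
        shannon = float(-(p * np.log(p)).sum())
        pielou = shannon / math.log(richness) if richness > 1 else np.nan
        rows.append({"sample_id": sid, "richness": richness,
                     "shannon": shannon, "pielou": pielou})
    return pd.DataFrame(rows).set_index("sample_id")


def diversity_kruskal(diversity: pd.DataFrame, meta: SampleMetadata) -> dict[str, float]:
    """Kruskal-Wallis p-value per diversity index across conditions (convenience)."""
    groups = meta.conditions(list(diversity.index))
    out = {}
    for index in ("richness", "shannon", "pielou"):
        samples = [diversity.loc[m, index].dropna().to_numpy() for m in groups.values()]
        samples = [s for s in samples if s.size > 0]
        if len(samples) < 2:
            out[index] = float("nan")
            continue
        out[index] = float(stats.kruskal(*samples).pvalue)
    return out
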