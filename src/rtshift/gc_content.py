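"""GC content of representative amplicon sequences, aggregated to class.

Per-class GC is the abundance-weighted mean over member OTUs and serves as
the explanatory variable of the enrichment-vs-GC regressions. GC here is
computed from the amplicon representative sequences (V3-V4), not whole
genomes — a proxy, since amplicons are the only sequence the pipeline sees.
Ambiguity codes contribute their expected GC share (e.g. N counts 0.5,
S counts 1), avoiding the length bias of simply excluding ambiguous
positions in short amplicons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import IUPAC_EXPANSION, UNCLASSIFIED, OtuTable, RepSeqSet, TaxonomyMap

log = logging.getLogger(__name__)

#: Expected GC contribution of each IUPAC code: |{G,C} in expansion| / |expansion|.
GC_SHARE: Mapping[str, float] = {
    code: sum(b in "GC" for b in exp) / len(exp) for code, exp in IUPAC_EXPANSION.items()
}


@dataclass
class ClassGc:
    class_label: str
    weighted_gc: float
    n_otus: int
    weight_basis: str


def gc_fraction(seq: str) -> float:
    """Expected GC fraction of a nucleotide sequence under IUPAC ambiguity."""
    if not seq:
        raise ValueError("empty sequence")
    try:
        return sum(GC_SHARE[c] for c in seq.upper()) / len(seq)
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in sequence") from exc


def otu_weights(table: OtuTable) -> dict[str, float]:
    """Grand-mean relative abundance of each OTU over all samples (global basis)."""
    rel = table.counts / table.sample_totals()[:, None]
    means = rel.mean(axis=0)
    return dict(zip(table.otu_ids, means.astype(float)))


def class_weighted_gc(tax: TaxonomyMap, seqs: RepSeqSet,
                      weights: Mapping[str, float],
                      weight_basis: str = "global-mean") -> list[ClassGc]:
    """Abundance-weighted mean GC per class over member OTUs.

    A class whose member weights are all zero falls back to the unweighted
    mean with a warning; classes with no sequenced members are excluded and
    logged.
    """
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be non-negative")
    members: dict[str, list[tuple[float, float]]] = {}
    skipped: dict[str, int] = {}
    for otu, w in weights.items():
        cls = tax.class_of(otu) if otu in tax else UNCLASSIFIED
        if otu not in seqs:
            skipped[cls] = skipped.get(cls, 0) + 1
            continue
        members.setdefault(cls, []).append((float(w), gc_fraction(seqs[otu])))
    for cls, n in skipped.items():
        if cls not in members:
            log.warning("class %s has no sequenced members (%d OTUs skipped); excluded", cls, n)
    out: list[ClassGc] = []
    for cls in sorted(members):
        ws = np.array([m[0] for m in members[cls]])
        gcs = np.array([m[1] for m in members[cls]])
        if ws.sum() == 0:
            log.warning("class %s has all-zero weights; using unweighted mean GC", cls)
            wgc = float(gcs.mean())
        else:
            wgc = float((ws * gcs).sum() / ws.sum())
        out.append(ClassGc(cls, wgc, len(members[cls]), weight_basis))
    return out


def class_gc_frame(gcs: list[ClassGc]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": [g.class_label for g in gcs],
            "weighted_gc": [g.weighted_gc for g in gcs],
            "n_otus": [g.n_otus for g in gcs],
            "weight_basis": [g.weight_basis for g in gcs],
        }
    )
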