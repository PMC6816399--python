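"""Synthetic RT-bias experiments with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
single underlying soil community is read through several reverse-
transcription conditions whose capture efficiency depends on template GC
content. Efficiency follows the monotone family

    eff(gc) = e0 * exp(-lambda * gc),

so a condition with larger lambda depletes high-GC classes more strongly
(the mechanism proposed for low-temperature RT). The effective class
profile of a condition re-weights the base community by efficiency and
renormalizes; replicate-level proportions are Dirichlet-distributed around
it (concentration theta controls between-replicate overdispersion) and read
counts are multinomial at fixed sequencing depth. Optional per-condition,
per-class log-normal "enzyme effects" add GC-independent bias of the kind
attributed to enzyme processivity, so conditions can differ in ways GC
cannot explain.

Representative sequences are composition-exact shuffles: each OTU gets a
sequence whose GC count matches its assigned GC fraction to the nearest
base. GC is the only sequence property the pipeline consumes, so no
phylogenetic realism is attempted (and none is claimed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .class_profiles import aggregate_to_class, condition_profiles
from .enrichment import fit_gc_regression, pairwise_enrichment
from .gc_content import class_weighted_gc, otu_weights
from .io_formats import (
    OtuTable,
    RepSeqSet,
    SampleMetadata,
    TaxonomyMap,
    write_fasta,
    write_metadata,
    write_otu_table,
    write_taxonomy,
)
from .preprocess import RarefactionSpec, rarefy


@dataclass
class ConditionSpec:
    """One RT condition: enzyme label, reaction temperature and bias parameters."""

    enzyme: str
    temperature: float
    lam: float  # GC-bias strength, >= 0
    e0: float = 1.0  # baseline efficiency in (0, 1]

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0 < self.e0 <= 1:
            raise ValueError("e0 must be in (0, 1]")


def default_conditions() -> list[ConditionSpec]:
    """The four-condition experimental design the generator emulates.

    The 42 C reaction carries the strongest GC penalty; the three
    high-temperature conditions are mildly and similarly biased.
    """
    return [
        ConditionSpec("ImProm-II", 42, lam=3.0),
        ConditionSpec("ImProm-II", 55, lam=0.8),
        ConditionSpec("SuperScript IV", 55, lam=0.4),
        ConditionSpec("TGIRT", 57, lam=0.4),
    ]


@dataclass
class SimScenario:
    """Full parameterization of a synthetic experiment."""

    n_classes: int = 40
    otus_per_class: int = 3
    gc_range: tuple[float, float] = (0.35, 0.75)
    conditions: list[ConditionSpec] = field(default_factory=default_conditions)
    replicates: int = 4
    depth: int = 9000
    theta: float = 200.0  # Dirichlet concentration (replicate overdispersion)
    base_sigma: float = 1.0  # log-normal spread of true class abundances
    enzyme_effect_sigma: float = 0.0  # GC-independent per-(condition, class) bias
    unclassified_fraction: float = 0.02
    gc_jitter: float = 0.02  # SD of per-OTU GC around its class GC
    seq_length: int = 450  # V3-V4 amplicon scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates for replicate dispersion")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        lo, hi = self.gc_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("gc_range must be within [0, 1]")
        if self.seq_length < 1:
            raise ValueError("sequence length must be >= 1 (infeasible GC/length)")
        if not 0 <= self.unclassified_fraction < 1:
            raise ValueError("unclassified_fraction must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment, for parameter recovery."""

    class_labels: list[str]
    class_gc: dict[str, float]
    base_abundance: dict[str, float]
    lambdas: dict[tuple[str, float], float]
    effective_profiles: dict[tuple[str, float], dict[str, float]]


@dataclass
class SimResult:
    table: OtuTable
    taxonomy: TaxonomyMap
    sequences: RepSeqSet
    metadata: SampleMetadata
    truth: SimTruth


def rt_efficiency(gc: float, lam: float, e0: float = 1.0) -> float:
    """GC-dependent capture efficiency e0 * exp(-lam * gc)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0 < e0 <= 1:
        raise ValueError("e0 must be in (0, 1]")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be a fraction in [0, 1]")
    return e0 * float(np.exp(-lam * gc))


def _make_sequence(rng: np.random.Generator, gc: float, length: int) -> str:
    n_gc = int(round(gc * length))
    n_g = n_gc // 2
    n_a = (length - n_gc) // 2
    letters = np.array(
        ["G"] * n_g + ["C"] * (n_gc - n_g) + ["A"] * n_a + ["T"] * (length - n_gc - n_a)
    )
    return "".join(rng.permutation(letters))


def _sample_id(cond: ConditionSpec, rep: int) -> str:
    enz = "".join(ch for ch in cond.enzyme if ch.isalnum())
    return f"{enz}{cond.temperature:g}_r{rep}"


def simulate_experiment(sc: SimScenario) -> SimResult:
    """Generate one complete synthetic dataset, deterministic given the seed."""
    rng = np.random.default_rng(sc.seed)

    classes = [f"Class{k + 1:02d}" for k in range(sc.n_classes)]
    lo, hi = sc.gc_range
    class_gc = (
        np.linspace(lo, hi, sc.n_classes) if sc.n_classes > 1 else np.array([(lo + hi) / 2])
    )
    base = rng.lognormal(mean=0.0, sigma=sc.base_sigma, size=sc.n_classes)
    base = base / base.sum()

    if sc.unclassified_fraction > 0:
        classes = classes + ["__unassigned__"]
        class_gc = np.append(class_gc, (lo + hi) / 2)
        base = np.append(base * (1 - sc.unclassified_fraction), sc.unclassified_fraction)

    # split each class over its member OTUs, jitter OTU GC around class GC
    otu_ids: list[str] = []
    otu_class_idx: list[int] = []
    otu_base: list[float] = []
    otu_gc: list[float] = []
    for k, cls in enumerate(classes):
        split = rng.dirichlet(np.ones(sc.otus_per_class))
        for m in range(sc.otus_per_class):
            otu_ids.append(f"OTU{len(otu_ids) + 1:04d}")
            otu_class_idx.append(k)
            otu_base.append(float(base[k] * split[m]))
            otu_gc.append(float(np.clip(class_gc[k] + rng.normal(0, sc.gc_jitter), 0.02, 0.98)))
    otu_base_arr = np.array(otu_base)
    otu_gc_arr = np.array(otu_gc)
    otu_class_arr = np.array(otu_class_idx)

    # per-condition effective weights and replicate counts
    sample_ids: list[str] = []
    counts_rows: list[np.ndarray] = []
    enzyme_map: dict[str, str] = {}
    temp_map: dict[str, float] = {}
    repl_map: dict[str, str] = {}
    effective_profiles: dict[tuple[str, float], dict[str, float]] = {}
    lambdas: dict[tuple[str, float], float] = {}
    for cond in sc.conditions:
        eff = cond.e0 * np.exp(-cond.lam * otu_gc_arr)
        w = otu_base_arr * eff
        if sc.enzyme_effect_sigma > 0:
            class_effect = rng.lognormal(0.0, sc.enzyme_effect_sigma, size=len(classes))
            w = w * class_effect[otu_class_arr]
        w = w / w.sum()
        key = (cond.enzyme, cond.temperature)
        lambdas[key] = cond.lam
        class_w = np.bincount(otu_class_arr, weights=w, minlength=len(classes))
        effective_profiles[key] = {c: float(class_w[k]) for k, c in enumerate(classes)}
        for rep in range(1, sc.replicates + 1):
            p = rng.dirichlet(sc.theta * w)
            counts_rows.append(rng.multinomial(sc.depth, p))
            sid = _sample_id(cond, rep)
            sample_ids.append(sid)
            enzyme_map[sid] = cond.enzyme
            temp_map[sid] = float(cond.temperature)
            repl_map[sid] = f"R{rep}"

    table = OtuTable(sample_ids, otu_ids, np.vstack(counts_rows))
    metadata = SampleMetadata(enzyme_map, temp_map, repl_map)

    lineages: dict[str, tuple[str, ...]] = {}
    for otu, k in zip(otu_ids, otu_class_arr):
        cls = classes[k]
        if cls == "__unassigned__":
            lineages[otu] = ("Bacteria", "PhylumU")  # no class rank -> Unclassified
        else:
            lineages[otu] = ("Bacteria", f"Phylum{k % 8 + 1:02d}", cls)
    taxonomy = TaxonomyMap(lineages)

    sequences = RepSeqSet(
        {otu: _make_sequence(rng, gc, sc.seq_length) for otu, gc in zip(otu_ids, otu_gc_arr)}
    )

    visible = [c for c in classes if c != "__unassigned__"]
    truth = SimTruth(
        class_labels=visible,
        class_gc={c: float(class_gc[k]) for k, c in enumerate(classes) if c in visible},
        base_abundance={c: float(base[k]) for k, c in enumerate(classes) if c in visible},
        lambdas=lambdas,
        effective_profiles={
            cond: {c: v for c, v in prof.items() if c in visible}
            for cond, prof in effective_profiles.items()
        },
    )
    return SimResult(table, taxonomy, sequences, metadata, truth)


def write_simulation(sim: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write the four pipeline inputs plus the ground truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": outdir / "otu_table.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "sequences": outdir / "rep_seqs.fasta",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_otu_table(sim.table, paths["otu_table"])
    write_taxonomy(sim.taxonomy, paths["taxonomy"])
    write_fasta(sim.sequences, paths["sequences"])
    write_metadata(sim.metadata, paths["metadata"])
    rows = []
    for cls in sim.truth.class_labels:
        row = {
            "class": cls,
            "gc": sim.truth.class_gc[cls],
            "base_abundance": sim.truth.base_abundance[cls],
        }
        for cond, prof in sim.truth.effective_profiles.items():
            row[f"effective_{cond[0]}_{cond[1]:g}"] = prof[cls]
        rows.append(row)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("#rtshift:1\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Parameter recovery


@dataclass
class RecoveryResult:
    rejection_rate: float
    negative_slope_rate: float
    p_values: np.ndarray
    slopes: np.ndarray


def _analyze_pair(sim: SimResult, depth: int, seed: int):
    """Condensed pipeline for a two-condition simulation: preprocess ->
    profiles -> GC -> enrichment -> regression."""
    rarefied, _ = rarefy(sim.table, RarefactionSpec(depth=depth, seed=seed))
    ct = aggregate_to_class(rarefied, sim.taxonomy)
    profiles = condition_profiles(ct, sim.metadata)
    gc = class_weighted_gc(sim.taxonomy, sim.sequences, otu_weights(rarefied))
    records = pairwise_enrichment(profiles)
    return fit_gc_regression(records, gc)


def recovery_experiment(sc: SimScenario, reps: int, alpha: float = 0.05,
                        seed: int = 0) -> RecoveryResult:
    """Run the full pipeline on ``reps`` simulated two-condition datasets.

    Reports the fraction of replicate datasets whose GC regression rejects
    at ``alpha`` and the fraction with a negative fitted slope (high-GC
    classes depleted under the larger lambda).
    """
    if len(sc.conditions) != 2:
        raise ValueError("recovery_experiment expects a two-condition scenario")
    rep_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=reps)
    ps = np.empty(reps)
    slopes = np.empty(reps)
    for i, s in enumerate(rep_seeds):
        sim = simulate_experiment(replace(sc, seed=int(s)))
        report = _analyze_pair(sim, sc.depth, int(s))
        ps[i] = report.p_value
        slopes[i] = report.slope
    return RecoveryResult(
        rejection_rate=float((ps < alpha).mean()),
        negative_slope_rate=float((slopes < 0).mean()),
        p_values=ps,
        slopes=slopes,
    )


def power_curve(sc: SimScenario, delta_lams: list[float], reps: int,
                alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Power along a grid of lambda differences, under common random numbers.

    The second condition keeps its lambda; the first (the "low-temperature"
    arm, which is condition A under the pair orientation) is set to
    lam + dlam, so high-GC classes are depleted in A and the expected
    regression slope is negative. The same per-replicate seeds are reused at
    every grid point so the power estimates share their randomness.
    """
    if len(sc.conditions) != 2:
        raise ValueError("power_curve expects a two-condition scenario")
    rows = []
    for dlam in delta_lams:
        cond1 = sc.conditions[1]
        cond0 = replace(sc.conditions[0], lam=cond1.lam + dlam)
        sc_d = replace(sc, conditions=[cond0, cond1])
        res = recovery_experiment(sc_d, reps, alpha=alpha, seed=seed)
        rows.append(
            {
                "delta_lambda": dlam,
                "power": res.rejection_rate,
                "negative_slope_rate": res.negative_slope_rate,
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)
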