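"""Enrichment between condition pairs and its regression on class GC.

For each of the six unordered condition pairs, computes the normalized
enrichment (A - B)/(A + B) per class with delta-method SD, the abundance-
weighted class GC content, and the OLS regression of enrichment on GC with
adjusted R^2, slope t and p, significance stars and assumption diagnostics.
"""

from pathlib import Path

from rtshift.class_profiles import aggregate_to_class, condition_profiles
from rtshift.enrichment import (
    enrichment_frame,
    fit_all_regressions,
    pairwise_enrichment,
    regressions_frame,
)
from rtshift.gc_content import class_gc_frame, class_weighted_gc, otu_weights
from rtshift.io_formats import read_fasta, read_metadata, read_otu_table, read_taxonomy

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "scratch" / "analysis" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    table = read_otu_table(ROOT / "scratch" / "analysis" / "otu_table_preprocessed.tsv")
    tax = read_taxonomy(SIM_DIR / "taxonomy.tsv")
    meta = read_metadata(SIM_DIR / "metadata.tsv")
    seqs = read_fasta(SIM_DIR / "rep_seqs.fasta")

    profiles = condition_profiles(aggregate_to_class(table, tax), meta)
    gc = class_weighted_gc(tax, seqs, otu_weights(table))
    records = pairwise_enrichment(profiles)
    reports = fit_all_regressions(records, gc)

    class_gc_frame(gc).to_csv(RESULTS / "class_gc.tsv", sep="\t", index=False)
    enrichment_frame(records, gc).to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    reg = regressions_frame(reports)
    reg.to_csv(RESULTS / "regressions.tsv", sep="\t", index=False)

    cols = ["condition_a", "condition_b", "adjusted_r2", "t_value", "p_value",
            "significance", "caveat"]
    print(reg[cols].to_string(index=False,
                              float_format=lambda v: f"{v:.4g}"))
    print(f"tables -> {RESULTS}/class_gc.tsv, enrichment.tsv, regressions.tsv")


if __name__ == "__main__":
    main()
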