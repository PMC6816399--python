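"""Readers, writers and validated containers for the pipeline's external formats.

The pipeline consumes four inputs produced upstream (read merging, OTU
clustering and taxonomy assignment are out of scope here):

* an OTU count table (samples x OTUs, non-negative integers), TSV or a
  minimal dense BIOM-JSON;
* a taxonomy table mapping each OTU to a semicolon-delimited SILVA-style
  lineage (rank prefixes such as ``c__`` are tolerated and stripped);
* representative sequences per OTU as FASTA (optional; only needed for
  GC-content analyses);
* sample metadata mapping each sample to an experimental condition
  (RT enzyme, reaction temperature) and a replicate block.

All tabular outputs carry a schema-version comment line ``#rtshift:1``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SCHEMA_COMMENT = "#rtshift:1"
UNCLASSIFIED = "Unclassified"

#: IUPAC nucleotide codes and their unambiguous expansions (U treated as T).
IUPAC_EXPANSION: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


class FormatError(ValueError):
    """A file does not conform to the expected external format."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


def _check_unique(labels: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    dups = [x for x in labels if x in seen or seen.add(x)]
    if dups:
        raise ValidationError(f"duplicate {kind} ids: {sorted(set(dups))}")


@dataclass
class OtuTable:
    """Integer read-count matrix, samples in rows, OTUs in columns."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_ids),
            len(self.otu_ids),
        ):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(self.sample_ids) < 1 or len(self.otu_ids) < 1:
            raise ValidationError("need at least one sample and one OTU")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        if not np.issubdtype(self.counts.dtype, np.integer):
            flo = np.asarray(self.counts, dtype=float)
            if np.isnan(flo).any() or (flo % 1 != 0).any():
                raise ValidationError("counts must be integers (no NaN/fractional cells)")
            self.counts = flo.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            s, o = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[s]!r}, OTU {self.otu_ids[o]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, keep: Iterable[str]) -> "OtuTable":
        keep = list(keep)
        idx = [self.sample_ids.index(s) for s in keep]
        return OtuTable(keep, list(self.otu_ids), self.counts[idx, :])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class TaxonomyMap:
    """OTU -> ranked lineage; the class rank (position 3) drives aggregation."""

    lineages: dict[str, tuple[str, ...]]
    class_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_labels:
            self.class_labels = {
                otu: _class_from_lineage(lin) for otu, lin in self.lineages.items()
            }

    def class_of(self, otu_id: str) -> str:
        return self.class_labels[otu_id]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.class_labels


def _class_from_lineage(lineage: tuple[str, ...]) -> str:
    # domain;phylum;class;... -> class is the third rank (1-based position 3)
    if len(lineage) >= 3 and lineage[2]:
        return lineage[2]
    return UNCLASSIFIED


@dataclass
class SampleMetadata:
    """Per-sample experimental annotation; condition := (enzyme, temperature)."""

    enzyme: dict[str, str]
    temperature: dict[str, float]
    replicate: dict[str, str]

    def condition(self, sample_id: str) -> tuple[str, float]:
        return (self.enzyme[sample_id], self.temperature[sample_id])

    def conditions(self, sample_ids: Iterable[str] | None = None) -> dict[tuple[str, float], list[str]]:
        """Map condition -> member samples, in (enzyme, temperature) order."""
        ids = list(sample_ids) if sample_ids is not None else list(self.enzyme)
        groups: dict[tuple[str, float], list[str]] = {}
        for s in ids:
            if s not in self.enzyme:
                raise ValidationError(f"sample {s!r} missing from metadata")
            groups.setdefault(self.condition(s), []).append(s)
        return dict(sorted(groups.items()))

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.enzyme


@dataclass
class RepSeqSet:
    """Representative nucleotide sequence per OTU (uppercase IUPAC)."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for otu, seq in self.sequences.items():
            seq = seq.upper()
            if not seq:
                raise ValidationError(f"empty sequence for OTU {otu!r}")
            bad = set(seq) - set(IUPAC_EXPANSION)
            if bad:
                raise ValidationError(
                    f"non-IUPAC character(s) {sorted(bad)} in sequence for OTU {otu!r}"
                )
            self.sequences[otu] = seq

    def __getitem__(self, otu_id: str) -> str:
        return self.sequences[otu_id]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)


# ---------------------------------------------------------------------------
# OTU table I/O


def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap any parser failure
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc
    if df.columns.size == 0:
        raise FormatError(f"{path}: no data columns found (malformed header?)")
    return df


def read_otu_table(path: str | Path, format: str = "tsv", orientation: str = "samples") -> OtuTable:
    """Read an OTU count table.

    Parameters
    ----------
    format:
        ``"tsv"`` (first column = row ids, header = column ids) or
        ``"biom-json"`` (minimal dense BIOM subset; rows are OTUs there
        by BIOM convention, so ``orientation`` is ignored).
    orientation:
        ``"samples"`` if TSV rows are samples (default), ``"otus"`` if rows
        are OTUs (the table is transposed on read).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "biom-json":
        return _read_biom_json(path)
    if format != "tsv":
        raise FormatError(f"unknown OTU-table format {format!r}")
    df = _read_tsv_matrix(path)
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        r, c = next(zip(*np.where(vals.isna().to_numpy())))
        raise ValidationError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    arr = vals.to_numpy(dtype=float)
    if orientation == "otus":
        return OtuTable(list(df.columns), list(df.index), arr.T)
    if orientation != "samples":
        raise FormatError(f"unknown orientation {orientation!r}")
    return OtuTable(list(df.index), list(df.columns), arr)


def write_otu_table(table: OtuTable, path: str | Path, format: str = "tsv",
                    orientation: str = "samples") -> None:
    path = Path(path)
    if format == "biom-json":
        _write_biom_json(table, path)
        return
    if format != "tsv":
        raise FormatError(f"unknown OTU-table format {format!r}")
    df = table.to_frame()
    if orientation == "otus":
        df = df.T
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index_label="id")


def _read_biom_json(path: Path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        if doc.get("matrix_type") != "dense":
            raise FormatError(f"{path}: only dense BIOM-JSON matrices are supported")
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        data = np.asarray(doc["data"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed BIOM-JSON: {exc}") from exc
    # BIOM rows are observations (OTUs); our container is samples x OTUs.
    return OtuTable(sample_ids, otu_ids, data.T)


def _write_biom_json(table: OtuTable, path: Path) -> None:
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "rtshift:1",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [table.n_otus, table.n_samples],
        "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": table.counts.T.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Taxonomy, FASTA, metadata


def parse_lineage(text: str) -> tuple[str, ...]:
    """Split a semicolon-delimited lineage, stripping QIIME-style rank prefixes."""
    fields = [_RANK_PREFIX.sub("", f.strip()) for f in text.split(";")]
    while fields and fields[-1] == "":
        fields.pop()
    return tuple(fields)


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV of (otu_id, semicolon-delimited lineage)."""
    path = Path(path)
    lineages: dict[str, tuple[str, ...]] = {}
    first_row = True
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{i}: expected otu_id<TAB>lineage")
            otu_id, lineage_text = parts[0], parts[1]
            if first_row:
                first_row = False
                if otu_id.lower() in {"otu_id", "otu", "id", "feature id"}:
                    continue  # tolerated header row
            if otu_id in lineages:
                raise ValidationError(f"{path}: duplicate taxonomy entry for {otu_id!r}")
            lineage = parse_lineage(lineage_text)
            if len(lineage) < 1:
                raise FormatError(f"{path}:{i}: empty lineage for {otu_id!r}")
            lineages[otu_id] = lineage
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        fh.write("otu_id\tlineage\n")
        for otu, lineage in tax.lineages.items():
            fh.write(f"{otu}\t{';'.join(lineage)}\n")


def read_fasta(path: str | Path) -> RepSeqSet:
    """Read representative sequences; record id = token before first whitespace."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValidationError(f"{path}: duplicate FASTA record {rec.id!r}")
        sequences[rec.id] = str(rec.seq)
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return RepSeqSet(sequences)


def write_fasta(seqs: RepSeqSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=otu, description="") for otu, seq in seqs.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata TSV: sample_id, enzyme, temperature_c, replicate."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "enzyme", "temperature_c", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample rows {dups}")
    if df[list(required)].isna().any().any():
        bad = df.loc[df[list(required)].isna().any(axis=1), "sample_id"].tolist()
        raise ValidationError(f"{path}: missing metadata cell(s) for sample(s) {bad}")
    temps = pd.to_numeric(df["temperature_c"], errors="coerce")
    if temps.isna().any():
        bad = df.loc[temps.isna(), "sample_id"].tolist()
        raise ValidationError(f"{path}: non-numeric temperature for sample(s) {bad}")
    return SampleMetadata(
        enzyme=dict(zip(df["sample_id"], df["enzyme"])),
        temperature=dict(zip(df["sample_id"], temps.astype(float))),
        replicate=dict(zip(df["sample_id"], df["replicate"])),
    )


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SCHEMA_COMMENT + "\n")
        fh.write("sample_id\tenzyme\ttemperature_c\treplicate\n")
        for s in meta.enzyme:
            temp = meta.temperature[s]
            temp_txt = f"{temp:g}"
            fh.write(f"{s}\t{meta.enzyme[s]}\t{temp_txt}\t{meta.replicate[s]}\n")


# ---------------------------------------------------------------------------
# Join closure


def check_join_closure(table: OtuTable, tax: TaxonomyMap,
                       meta: SampleMetadata | None = None,
                       seqs: RepSeqSet | None = None) -> None:
    """Verify cross-references between loaded inputs, reporting ALL violations.

    Every OTU in the table must have a taxonomy entry; if sequences are
    supplied, every OTU must also have one; if metadata is supplied, every
    sample must be annotated.
    """
    problems: list[str] = []
    no_tax = [o for o in table.otu_ids if o not in tax]
    if no_tax:
        problems.append(f"OTUs without taxonomy: {no_tax}")
    if seqs is not None:
        no_seq = [o for o in table.otu_ids if o not in seqs]
        if no_seq:
            problems.append(f"OTUs without representative sequence: {no_seq}")
    if meta is not None:
        no_meta = [s for s in table.sample_ids if s not in meta]
        if no_meta:
            problems.append(f"samples without metadata: {no_meta}")
    if problems:
        raise ValidationError("join closure violated: " + "; ".join(problems))
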