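"""Domain types and file formats.

The pipeline exchanges plain tab-delimited UTF-8 text: an expression matrix
(probes x samples), a two-column sample->group table, a BED-style probe
annotation, GMT gene-set collections, and SIF edge lists for network tools.
All genomic coordinates follow the BED convention: 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .errors import CoordinateError, FormatError, ValidationError

BIOTYPES = ("mRNA", "lncRNA")
_BIOTYPE_ALIASES = {"mrna": "mRNA", "lncrna": "lncRNA"}
STRANDS = ("+", "-", ".")

ANNOTATION_COLUMNS = ("gene_symbol", "biotype", "chrom", "start", "end", "strand")


@dataclass(frozen=True)
class GeneLocus:
    """A genomic interval, 0-based half-open, with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity grid with a two-group sample design.

    ``data`` is a DataFrame indexed by probe ID with one column per sample.
    ``scale`` is ``"raw"`` (non-negative intensities) or ``"log2"``.
    """

    data: pd.DataFrame
    groups: dict[str, str]
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        idx = self.data.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe IDs: {dups[:5]}")
        cols = self.data.columns
        if cols.has_duplicates:
            raise FormatError("duplicate sample IDs in expression matrix")
        for col in self.data.columns:
            if not pd.api.types.is_numeric_dtype(self.data[col]):
                bad = self.data[col][pd.to_numeric(self.data[col], errors="coerce").isna()]
                raise FormatError(
                    f"non-numeric value in sample {col!r}"
                    + (f" at probe {bad.index[0]!r}: {bad.iloc[0]!r}" if len(bad) else "")
                )
        missing = [s for s in cols if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without group assignment: {missing}")
        labels = {self.groups[s] for s in cols}
        if len(labels) > 2:
            raise ValidationError(f"more than two group labels: {sorted(labels)}")
        if self.scale == "raw" and (self.data.to_numpy() < 0).any():
            raise ValidationError("raw-scale matrix contains negative values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == label]

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.data.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(data, dict(self.groups), scale or self.scale)


@dataclass
class ProbeAnnotation:
    """Probe -> (gene symbol, biotype, optional genomic locus).

    ``table`` is indexed by probe ID with columns ``gene_symbol``,
    ``biotype``, ``chrom``, ``start``, ``end``, ``strand``; locus columns are
    NA when the probe has no mapped locus.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe IDs in annotation: {dups[:5]}")
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing_cols:
            raise FormatError(f"annotation missing columns: {missing_cols}")
        bad = set(self.table["biotype"]) - set(BIOTYPES)
        if bad:
            raise FormatError(f"unknown biotype values: {sorted(bad)}")

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def symbol(self, probe_id: str) -> str:
        return self.table.at[probe_id, "gene_symbol"]

    def biotype(self, probe_id: str) -> str:
        return self.table.at[probe_id, "biotype"]

    def locus(self, probe_id: str) -> GeneLocus | None:
        row = self.table.loc[probe_id]
        if pd.isna(row["chrom"]) or pd.isna(row["start"]) or pd.isna(row["end"]):
            return None
        strand = row["strand"]
        return GeneLocus(
            str(row["chrom"]),
            int(row["start"]),
            int(row["end"]),
            "." if pd.isna(strand) else str(strand),
        )

    def probes_of_biotype(self, biotype: str) -> list[str]:
        if biotype not in BIOTYPES:
            raise ValidationError(f"unknown biotype {biotype!r}")
        mask = self.table["biotype"] == biotype
        return list(self.table.index[mask])

    def symbols_of_biotype(self, biotype: str) -> list[str]:
        """Unique gene symbols of one biotype, in annotation order."""
        probes = self.probes_of_biotype(biotype)
        seen: dict[str, None] = {}
        for p in probes:
            seen.setdefault(self.table.at[p, "gene_symbol"], None)
        return list(seen)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets (the local stand-in for GO/KEGG category tables)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if not gs.members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) tab-delimited table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"], dtype=str)
    if len(df) and tuple(df.iloc[0]) == ("sample_id", "group"):
        df = df.iloc[1:]
    if df.isna().any().any():
        raise FormatError(f"groups file {path} has missing fields")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"sample {dup!r} assigned twice in groups file")
    labels = sorted(df["group"].unique())
    if len(labels) > 2:
        raise ValidationError(f"groups file lists more than two labels: {labels}")
    return dict(zip(df["sample_id"], df["group"]))


def read_expression(
    matrix_path: str | Path, groups_path: str | Path, scale: str = "raw"
) -> ExpressionMatrix:
    """Read a probes x samples TSV (first column probe IDs, header sample IDs)
    together with its sample->group table."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    groups = read_groups(groups_path)
    missing = [s for s in df.columns if s not in groups]
    if missing:
        raise ValidationError(
            f"samples in matrix but absent from groups file: {missing}"
        )
    return ExpressionMatrix(df, {s: groups[s] for s in df.columns}, scale)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="probe_id")


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample, label in groups.items():
            fh.write(f"{sample}\t{label}\n")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a probe annotation TSV with columns probe_id, gene_symbol,
    biotype, chrom, start, end, strand. Locus columns may be empty."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ("probe_id",) + ANNOTATION_COLUMNS
    if tuple(df.columns) != expected:
        raise FormatError(
            f"annotation columns must be {list(expected)}, got {list(df.columns)}"
        )
    records: dict[str, list] = {c: [] for c in ANNOTATION_COLUMNS}
    index: list[str] = []
    for _, row in df.iterrows():
        index.append(row["probe_id"])
        bt = _BIOTYPE_ALIASES.get(row["biotype"].strip().lower())
        if bt is None:
            raise FormatError(
                f"unknown biotype {row['biotype']!r} for probe {row['probe_id']!r}; "
                f"allowed: {list(BIOTYPES)}"
            )
        records["gene_symbol"].append(row["gene_symbol"])
        records["biotype"].append(bt)
        locus_fields = (row["chrom"], row["start"], row["end"])
        if all(f == "" for f in locus_fields):
            records["chrom"].append(pd.NA)
            records["start"].append(pd.NA)
            records["end"].append(pd.NA)
            records["strand"].append(pd.NA)
        elif any(f == "" for f in locus_fields):
            raise FormatError(
                f"probe {row['probe_id']!r} has a partially specified locus"
            )
        else:
            try:
                start, end = int(row["start"]), int(row["end"])
            except ValueError as exc:
                raise FormatError(
                    f"non-integer coordinate for probe {row['probe_id']!r}"
                ) from exc
            strand = row["strand"] or "."
            # constructing validates 0 <= start < end and the strand symbol
            GeneLocus(row["chrom"], start, end, strand)
            records["chrom"].append(row["chrom"])
            records["start"].append(start)
            records["end"].append(end)
            records["strand"].append(strand)
    table = pd.DataFrame(records, index=pd.Index(index, name="probe_id"))
    table["start"] = table["start"].astype("Int64")
    table["end"] = table["end"].astype("Int64")
    return ProbeAnnotation(table)


def write_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    out = ann.table.copy()
    out.to_csv(path, sep="\t", index_label="probe_id", na_rep="")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member..."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, description, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = tuple(dict.fromkeys(m for m in members if m))
            if not deduped:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = GeneSet(name, description, deduped)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join((gs.name, gs.description) + gs.members) + "\n")


def write_pairs_sif(pairs: Sequence, path: str | Path) -> None:
    """Write regulatory pairs as SIF lines ``lnc <tab> cis|trans <tab> mRNA``,
    in input order."""
    with open(path, "w", encoding="utf-8") as fh:
        for rp in pairs:
            fh.write(
                f"{rp.pair.lnc_symbol}\t{rp.regulation}\t{rp.pair.mrna_symbol}\n"
            )
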