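import numpy as np
import pandas as pd
import pytest

from coexnet.io_formats import ExpressionMatrix, ProbeAnnotation


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        [[8.0, 6.0, 2.0, 1.0], [4.0, 5.0, 9.0, 7.0], [1.0, 2.0, 3.0, 4.0]],
        index=pd.Index(["P1", "P2", "P3"], name="probe_id"),
        columns=["S1", "S2", "S3", "S4"],
    )
    groups = {"S1": "tibetan", "S2": "tibetan", "S3": "han", "S4": "han"}
    return ExpressionMatrix(data, groups, "raw")


def make_annotation(rows: dict) -> ProbeAnnotation:
    """rows: probe_id -> (symbol, biotype, chrom, start, end, strand); locus
    fields may be None."""
    records = {c: [] for c in ("gene_symbol", "biotype", "chrom", "start", "end", "strand")}
    for symbol, biotype, chrom, start, end, strand in rows.values():
        records["gene_symbol"].append(symbol)
        records["biotype"].append(biotype)
        records["chrom"].append(chrom if chrom is not None else pd.NA)
        records["start"].append(start if start is not None else pd.NA)
        records["end"].append(end if end is not None else pd.NA)
        records["strand"].append(strand if strand is not None else pd.NA)
    table = pd.DataFrame(records, index=pd.Index(list(rows), name="probe_id"))
    table["start"] = table["start"].astype("Int64")
    table["end"] = table["end"].astype("Int64")
    return ProbeAnnotation(table)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
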