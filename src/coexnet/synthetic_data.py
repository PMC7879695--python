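"""Seeded synthetic datasets with known ground truth.

The generator emulates the statistical structure of a two-group cartilage
microarray study: five case samples versus three controls, mRNA and lncRNA
probes with uniform log2 baselines, a planted group-mean shift on a known
probe subset, planted lncRNA-mRNA correlations via a shared latent factor,
deterministic locus geometry for cis/trans classification, and a gene-set
collection with one set enriched in the planted DE mRNAs.

Signal model for probe i, sample s (log2 scale):

    x_is = baseline_i + effect_i * 1[s in case] + noise_is

where ``effect_i`` is +/- ``effect_log2fc`` on planted probes and 0
elsewhere, and ``noise_is`` is N(0, noise_sd^2). For a planted correlated
pair the two noise rows share a latent factor:

    noise = noise_sd * (sqrt(|rho|) * sign * f + sqrt(1 - |rho|) * e)

with f and e independent standard normal, which gives the pair an expected
within-group Pearson correlation of rho while keeping the marginal variance
at noise_sd^2. Across both groups the observed correlation of two planted
DE probes is larger, because the shared group shift adds covariance — the
same phenomenon real two-group designs show.

The matrix is exported on the raw scale (2**x), so the pipeline's
normalize-then-log2 path is exercised on its true input regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ProbeAnnotation,
    write_annotation,
    write_expression,
    write_gmt,
    write_groups,
)

GEOMETRIES = ("cis_near", "cis_boundary", "trans_far", "trans_diffchrom")

# same-chromosome gap planted per geometry class; the boundary class sits
# exactly on the 300 kb cis/trans decision point
GEOMETRY_GAPS = {"cis_near": 100_000, "cis_boundary": 300_000, "trans_far": 500_000}

_PROBE_LENGTH = 10_000
_PAIR_REGION_SPACING = 10_000_000
_BACKGROUND_SPACING = 1_000_000
_BACKGROUND_CHROMS = [f"chr{c}" for c in range(3, 23)]

ENRICHED_SET_NAME = "PLANTED_DE_SET"

REPLICA_SEED = 20210


@dataclass(frozen=True)
class CorrPairSpec:
    """One planted lncRNA-mRNA correlation with its locus geometry."""

    lnc_index: int
    mrna_index: int
    rho: float
    geometry: str
    lnc_symbol: str | None = None
    mrna_symbol: str | None = None


@dataclass
class SimConfig:
    """Synthetic study design; defaults mirror the emulated experiment
    (5 case vs 3 control samples, log2FC 3 effects, noise SD 0.5)."""

    n_case: int = 5
    n_control: int = 3
    n_mrna: int = 2_000
    n_lnc: int = 1_000
    n_up_lnc: int = 10
    n_down_lnc: int = 10
    n_up_mrna: int = 20
    n_down_mrna: int = 20
    effect_log2fc: float = 3.0
    noise_sd: float = 0.5
    baseline_log2_range: tuple[float, float] = (4.0, 12.0)
    corr_pairs: list[CorrPairSpec] = field(default_factory=list)
    n_random_sets: int = 10
    set_size: int = 30
    enriched_frac: float = 0.8
    case_label: str = "tibetan"
    control_label: str = "han"
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigError("each group needs at least 2 samples")
        if self.n_up_lnc + self.n_down_lnc > self.n_lnc:
            raise ConfigError("planted lncRNA DE counts exceed n_lnc")
        if self.n_up_mrna + self.n_down_mrna > self.n_mrna:
            raise ConfigError("planted mRNA DE counts exceed n_mrna")
        lo, hi = self.baseline_log2_range
        if not lo < hi:
            raise ConfigError("baseline_log2_range must be increasing")
        has_de = self.n_up_lnc + self.n_down_lnc + self.n_up_mrna + self.n_down_mrna
        if has_de and not (hi - abs(self.effect_log2fc) > lo):
            raise ConfigError(
                "effect_log2fc must be smaller than the baseline range width "
                "so that shifted probes stay inside the dynamic range"
            )
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        used_lnc: set[int] = set()
        used_mrna: set[int] = set()
        for spec in self.corr_pairs:
            if not -1.0 < spec.rho < 1.0:
                raise ConfigError(f"rho must lie in (-1, 1), got {spec.rho}")
            if spec.geometry not in GEOMETRIES:
                raise ConfigError(f"unknown geometry {spec.geometry!r}")
            if not 0 <= spec.lnc_index < self.n_lnc:
                raise ConfigError(f"lnc_index {spec.lnc_index} out of range")
            if not 0 <= spec.mrna_index < self.n_mrna:
                raise ConfigError(f"mrna_index {spec.mrna_index} out of range")
            if spec.lnc_index in used_lnc or spec.mrna_index in used_mrna:
                raise ConfigError("each probe may appear in at most one planted pair")
            used_lnc.add(spec.lnc_index)
            used_mrna.add(spec.mrna_index)


@dataclass(frozen=True)
class PlantedPair:
    lnc_probe: str
    mrna_probe: str
    lnc_symbol: str
    mrna_symbol: str
    rho: float
    geometry: str


@dataclass
class SyntheticTruth:
    """Ground truth carried by a generated dataset."""

    de_status: pd.Series  # probe_id -> up | down | null
    pairs: list[PlantedPair]
    enriched_set_names: list[str]

    def de_counts(self) -> dict[str, int]:
        return self.de_status.value_counts().to_dict()


def simulate_correlated_pair(
    rho: float, n: int, rng: np.random.Generator, sd: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two length-n vectors with expected Pearson correlation rho and
    marginal SD ``sd`` via a shared latent factor."""
    if not -1.0 < rho < 1.0:
        raise ConfigError("rho must lie in (-1, 1)")
    f = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    a = np.sqrt(abs(rho))
    b = np.sqrt(1.0 - abs(rho))
    x = sd * (a * f + b * e1)
    y = sd * (np.sign(rho) * a * f + b * e2)
    return x, y


def _mrna_probe(i: int) -> str:
    return f"MR{i:05d}"


def _lnc_probe(j: int) -> str:
    return f"LN{j:05d}"


def generate_dataset(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, ProbeAnnotation, GeneSetCollection, SyntheticTruth]:
    """Generate one seeded dataset plus its ground truth.

    The same config and seed reproduce the dataset bit for bit; changing
    only the seed changes values but neither dimensions, truth structure
    nor annotation geometry.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    mrna_probes = [_mrna_probe(i) for i in range(cfg.n_mrna)]
    lnc_probes = [_lnc_probe(j) for j in range(cfg.n_lnc)]
    probes = mrna_probes + lnc_probes
    n_probes = len(probes)

    mrna_symbols = [f"G{i:05d}" for i in range(cfg.n_mrna)]
    lnc_symbols = [f"LNC{j:05d}" for j in range(cfg.n_lnc)]
    for spec in cfg.corr_pairs:
        if spec.mrna_symbol is not None:
            mrna_symbols[spec.mrna_index] = spec.mrna_symbol
        if spec.lnc_symbol is not None:
            lnc_symbols[spec.lnc_index] = spec.lnc_symbol

    # planted DE status: leading probes up, the next block down (structure
    # is positional, so it is invariant to the seed)
    effect = np.zeros(n_probes)
    status = np.full(n_probes, "null", dtype=object)
    effect[: cfg.n_up_mrna] = cfg.effect_log2fc
    status[: cfg.n_up_mrna] = "up"
    effect[cfg.n_up_mrna : cfg.n_up_mrna + cfg.n_down_mrna] = -cfg.effect_log2fc
    status[cfg.n_up_mrna : cfg.n_up_mrna + cfg.n_down_mrna] = "down"
    effect[cfg.n_mrna : cfg.n_mrna + cfg.n_up_lnc] = cfg.effect_log2fc
    status[cfg.n_mrna : cfg.n_mrna + cfg.n_up_lnc] = "up"
    lo = cfg.n_mrna + cfg.n_up_lnc
    effect[lo : lo + cfg.n_down_lnc] = -cfg.effect_log2fc
    status[lo : lo + cfg.n_down_lnc] = "down"

    n_samples = cfg.n_case + cfg.n_control
    sample_ids = [f"T{i + 1}" for i in range(cfg.n_case)] + [
        f"H{i + 1}" for i in range(cfg.n_control)
    ]
    groups = {
        s: (cfg.case_label if i < cfg.n_case else cfg.control_label)
        for i, s in enumerate(sample_ids)
    }
    in_case = np.array([1.0] * cfg.n_case + [0.0] * cfg.n_control)

    # Baselines are uniform over the dynamic range, but planted probes draw
    # from the sub-range that keeps their shifted (case) state inside the
    # same range: up-probes from [lo, hi - effect], down-probes from
    # [lo + effect, hi]. Real arrays behave this way (a transcript cannot be
    # induced beyond the scanner's dynamic range), and it keeps the two
    # groups' intensity distributions exchangeable — the regime in which
    # quantile normalization is unbiased.
    lo_b, hi_b = cfg.baseline_log2_range
    eff = abs(cfg.effect_log2fc)
    baseline = rng.uniform(lo_b, hi_b, size=n_probes)
    up_mask = status == "up"
    down_mask = status == "down"
    baseline[up_mask] = rng.uniform(lo_b, hi_b - eff, size=int(up_mask.sum()))
    baseline[down_mask] = rng.uniform(lo_b + eff, hi_b, size=int(down_mask.sum()))
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_probes, n_samples))
    for spec in sorted(cfg.corr_pairs, key=lambda s: (s.lnc_index, s.mrna_index)):
        x, y = simulate_correlated_pair(spec.rho, n_samples, rng, sd=cfg.noise_sd)
        noise[cfg.n_mrna + spec.lnc_index] = x
        noise[spec.mrna_index] = y

    log2_signal = baseline[:, None] + effect[:, None] * in_case[None, :] + noise
    raw = np.exp2(log2_signal)
    data = pd.DataFrame(raw, index=pd.Index(probes, name="probe_id"), columns=sample_ids)
    matrix = ExpressionMatrix(data, groups, scale="raw")

    annotation = _build_annotation(cfg, mrna_probes, lnc_probes, mrna_symbols, lnc_symbols)
    truth_pairs = [
        PlantedPair(
            lnc_probe=_lnc_probe(spec.lnc_index),
            mrna_probe=_mrna_probe(spec.mrna_index),
            lnc_symbol=lnc_symbols[spec.lnc_index],
            mrna_symbol=mrna_symbols[spec.mrna_index],
            rho=spec.rho,
            geometry=spec.geometry,
        )
        for spec in cfg.corr_pairs
    ]
    gene_sets, enriched_names = _build_gene_sets(cfg, mrna_symbols, status, rng)
    truth = SyntheticTruth(
        de_status=pd.Series(status, index=probes, name="de_status"),
        pairs=truth_pairs,
        enriched_set_names=enriched_names,
    )
    return matrix, annotation, gene_sets, truth


def _build_annotation(
    cfg: SimConfig,
    mrna_probes: list[str],
    lnc_probes: list[str],
    mrna_symbols: list[str],
    lnc_symbols: list[str],
) -> ProbeAnnotation:
    """Deterministic loci: planted pairs sit in reserved regions of chr1
    (and chr2 for cross-chromosome pairs) at their class-defining gap;
    every other probe is tiled over chr3..chr22 with ~1 Mb spacing, far
    beyond the 300 kb window from any neighbor."""
    n_probes = len(mrna_probes) + len(lnc_probes)
    chrom = [""] * n_probes
    start = [0] * n_probes
    paired = set()
    for rank, spec in enumerate(sorted(cfg.corr_pairs, key=lambda s: (s.lnc_index, s.mrna_index))):
        base = (rank + 1) * _PAIR_REGION_SPACING
        lnc_row = len(mrna_probes) + spec.lnc_index
        mrna_row = spec.mrna_index
        chrom[lnc_row] = "chr1"
        start[lnc_row] = base
        if spec.geometry == "trans_diffchrom":
            chrom[mrna_row] = "chr2"
            start[mrna_row] = base
        else:
            chrom[mrna_row] = "chr1"
            start[mrna_row] = base + _PROBE_LENGTH + GEOMETRY_GAPS[spec.geometry]
        paired.update((lnc_row, mrna_row))
    slot = 0
    for row in range(n_probes):
        if row in paired:
            continue
        chrom[row] = _BACKGROUND_CHROMS[slot % len(_BACKGROUND_CHROMS)]
        start[row] = 10_000 + (slot // len(_BACKGROUND_CHROMS)) * _BACKGROUND_SPACING
        slot += 1
    table = pd.DataFrame(
        {
            "gene_symbol": mrna_symbols + lnc_symbols,
            "biotype": ["mRNA"] * len(mrna_probes) + ["lncRNA"] * len(lnc_probes),
            "chrom": chrom,
            "start": pd.array(start, dtype="Int64"),
            "end": pd.array([s + _PROBE_LENGTH for s in start], dtype="Int64"),
            "strand": ["+"] * n_probes,
        },
        index=pd.Index(mrna_probes + lnc_probes, name="probe_id"),
    )
    return ProbeAnnotation(table)


def _build_gene_sets(
    cfg: SimConfig,
    mrna_symbols: list[str],
    status: np.ndarray,
    rng: np.random.Generator,
) -> tuple[GeneSetCollection, list[str]]:
    de_mrna = [s for s, st in zip(mrna_symbols, status[: cfg.n_mrna]) if st != "null"]
    null_mrna = [s for s, st in zip(mrna_symbols, status[: cfg.n_mrna]) if st == "null"]
    sets: dict[str, GeneSet] = {}
    enriched_names: list[str] = []
    if de_mrna and cfg.set_size > 0:
        n_de_members = min(round(cfg.enriched_frac * cfg.set_size), len(de_mrna))
        n_null_members = min(cfg.set_size - n_de_members, len(null_mrna))
        members = list(rng.choice(de_mrna, size=n_de_members, replace=False))
        members += list(rng.choice(null_mrna, size=n_null_members, replace=False))
        sets[ENRICHED_SET_NAME] = GeneSet(
            ENRICHED_SET_NAME,
            "synthetic set drawn mostly from planted DE mRNAs",
            tuple(members),
        )
        enriched_names.append(ENRICHED_SET_NAME)
    for i in range(cfg.n_random_sets):
        name = f"RANDOM_SET_{i + 1:02d}"
        size = min(cfg.set_size, len(mrna_symbols))
        members = tuple(rng.choice(mrna_symbols, size=size, replace=False))
        sets[name] = GeneSet(name, "uniform-random synthetic set", members)
    return GeneSetCollection(sets), enriched_names


# ---------------------------------------------------------------------------
# replica fixture
# ---------------------------------------------------------------------------


def replica_config(seed: int = REPLICA_SEED) -> SimConfig:
    """The packaged recovery fixture: 49/68 up/down lncRNAs and 158/139
    up/down mRNAs planted with effect 3.0 and noise 0.5 on a 5-vs-3 design,
    four cis pairs (one pinned exactly on the 300 kb boundary) and six
    trans pairs.

    Probe totals (500 mRNA, 200 lncRNA) are sized so that the expected
    number of chance volcano calls among the null probes is well under one
    per class, letting recovery of the planted counts be asserted tightly.
    """
    cis = [
        CorrPairSpec(0, 0, 0.805, "cis_near", "lnc-SDIM1", "SDIM1"),
        CorrPairSpec(1, 1, 0.833, "cis_near", "lnc-CYB5R2", "CYB5R2"),
        CorrPairSpec(2, 2, 0.833, "cis_boundary", "lnc-CCDC67", "CCDC67"),
        CorrPairSpec(3, 3, 0.857, "cis_near", "lnc-OTOA", "OTOA"),
    ]
    trans = [
        CorrPairSpec(4, 4, 0.90, "trans_far"),
        CorrPairSpec(5, 5, 0.85, "trans_far"),
        CorrPairSpec(6, 6, 0.88, "trans_diffchrom"),
        CorrPairSpec(7, 7, 0.92, "trans_diffchrom"),
        CorrPairSpec(8, 160, -0.85, "trans_far"),
        CorrPairSpec(60, 200, 0.80, "trans_diffchrom"),
    ]
    return SimConfig(
        n_case=5,
        n_control=3,
        n_mrna=500,
        n_lnc=200,
        n_up_lnc=49,
        n_down_lnc=68,
        n_up_mrna=158,
        n_down_mrna=139,
        effect_log2fc=3.0,
        noise_sd=0.5,
        corr_pairs=cis + trans,
        n_random_sets=15,
        set_size=40,
        seed=seed,
    )


def write_truth(truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    paths = {
        "truth": out_dir / "truth.tsv",
        "truth_pairs": out_dir / "truth_pairs.tsv",
        "truth_sets": out_dir / "truth_sets.tsv",
    }
    truth.de_status.to_csv(paths["truth"], sep="\t", index_label="probe_id")
    pd.DataFrame([asdict(p) for p in truth.pairs]).to_csv(
        paths["truth_pairs"], sep="\t", index=False
    )
    pd.Series(truth.enriched_set_names, name="enriched_set").to_csv(
        paths["truth_sets"], sep="\t", index=False
    )
    return paths


def write_dataset(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    gene_sets: GeneSetCollection,
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the four dataset artifacts plus the truth tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "raw_matrix.tsv",
        "groups": out_dir / "groups.tsv",
        "annotation": out_dir / "annotation.tsv",
        "gmt": out_dir / "gene_sets.gmt",
    }
    write_expression(matrix, paths["matrix"])
    write_groups(matrix.groups, paths["groups"])
    write_annotation(annotation, paths["annotation"])
    write_gmt(gene_sets, paths["gmt"])
    paths.update(write_truth(truth, out_dir))
    return paths


def replica_fixture(
    out_dir: str | Path, seed: int = REPLICA_SEED
) -> tuple[dict[str, Path], SyntheticTruth]:
    """Generate and write the replica fixture; returns the file paths and
    the ground truth."""
    matrix, annotation, gene_sets, truth = generate_dataset(replica_config(seed))
    return write_dataset(matrix, annotation, gene_sets, truth, out_dir), truth
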