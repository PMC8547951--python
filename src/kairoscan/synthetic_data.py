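"""Seeded generators for every input the pipeline consumes.

The generator emulates the statistical structure of the real inputs —
non-overlapping gene models on a small genome, binned per-mark signal
tracks with a right-skewed (lognormal) baseline, a pathway/domain
annotation, and qPCR / metabolite tables — with *planted* ground truth:

* per-pathway, per-mark signal multipliers (multiplicative enrichment),
* a bivalent gene subset whose windows are co-elevated for a mark pair,
* known expression fold-change schedules, ChIP abundance ratios,
  sequential-ChIP recovery fractions and metabolite accumulation factors.

Every planted effect is recorded in a :class:`TruthTable` so recovery
tests never peek at the generator's internals.  Generation is fully
deterministic given (config, seed): the same config writes a byte-identical
file set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    ConcentrationTable,
    CqTable,
    GeneModel,
    GenomeAnnotation,
    MetabolicAnnotation,
    SignalTrack,
    write_bedgraph,
    write_conc_csv,
    write_cq_csv,
    write_gff3,
    write_pathway_table,
    _tool_comment,
)
from .errors import ConfigError
from .signal_density import build_windows

CAMALEXIN_GENES = ("CYP79B2", "CYP71A13", "PAD3")
DEFAULT_TIMES = (5, 30, 60, 180, 360)  # 5 min .. 6 hr, in minutes


@dataclass
class MarkSpec:
    """Baseline signal model for one epigenetic mark: lognormal(mu, sigma)."""

    name: str
    mu: float = 0.0
    sigma: float = 0.75


@dataclass
class PathwaySpec:
    """A planted pathway: member count plus per-mark signal multipliers."""

    pathway_id: str
    domain_id: str
    n_genes: int
    multipliers: dict[str, float] = field(default_factory=dict)


@dataclass
class BivalentSpec:
    """A planted co-marked gene subset, emitted as its own pathway."""

    size: int = 20
    marks: tuple[str, str] = ("H3K27me3", "H3K18ac")
    multiplier: float = 4.0
    pathway_id: str = "PWY-BIVALENT"
    domain_id: str = "specialized"


def _default_marks() -> list[MarkSpec]:
    return [MarkSpec("H3K27me3"), MarkSpec("H3K18ac")]


def _default_pathways() -> list[PathwaySpec]:
    out = [
        PathwaySpec(
            "PWY-CAMALEXIN", "specialized", 20,
            {"H3K27me3": 3.0, "H3K18ac": 3.0},
        ),
        PathwaySpec(
            "PWY-GLUCOSINOLATE", "specialized", 20,
            {"H3K27me3": 2.5, "H3K18ac": 2.5},
        ),
    ]
    out += [PathwaySpec(f"PWY-SPEC-{i:02d}", "specialized", 20) for i in range(1, 9)]
    return out


def _default_expression_fc() -> dict[tuple[str, str, int], float]:
    # Induction schedules per genotype class: wild type inducts from 30-60
    # min, repressive-mark mutants (clf28, pkl-1) precociously from 5 min
    # with a stronger late response, activating-mark mutants (idm1, idm2)
    # with a 1-3 hr delay.
    profiles = {
        "Col-0": {
            "CYP71A13": (1, 4, 6, 10, 16),
            "PAD3": (1, 4, 6, 10, 16),
            "CYP79B2": (1, 1, 4, 8, 12),
        },
        "clf28": {g: (4, 8, 12, 16, 32) for g in CAMALEXIN_GENES},
        "pkl-1": {g: (4, 8, 12, 16, 32) for g in CAMALEXIN_GENES},
        "idm1": {
            "CYP71A13": (1, 1, 4, 8, 12),
            "PAD3": (1, 1, 4, 8, 12),
            "CYP79B2": (1, 1, 1, 4, 8),
        },
        "idm2": {
            "CYP71A13": (1, 1, 4, 8, 12),
            "PAD3": (1, 1, 4, 8, 12),
            "CYP79B2": (1, 1, 1, 4, 8),
        },
    }
    sched = {}
    for genotype, targets in profiles.items():
        for target, fcs in targets.items():
            for time, fc in zip(DEFAULT_TIMES, fcs):
                sched[(target, genotype, time)] = float(fc)
    return sched


def _default_chip_effects() -> dict[tuple[str, str], float]:
    effects = {}
    for region in CAMALEXIN_GENES:
        effects[(region, "H3K18ac")] = 1.8
        effects[(region, "H3K27me3")] = 0.55
    return effects


def _default_seqchip_recovery() -> dict[tuple[str, str, str], float]:
    rec = {}
    for region in CAMALEXIN_GENES:
        rec[(region, "H3K27me3", "H3K18ac")] = 0.25
        rec[(region, "H3K18ac", "H3K27me3")] = 0.25
        rec[(region, "H3K27me3", "NoAb")] = 0.01
        rec[(region, "H3K18ac", "NoAb")] = 0.01
    return rec


def _default_conc_fc() -> dict[tuple[str, int], float]:
    profiles = {
        "Col-0": (1, 1, 1, 3, 6),
        "clf28": (1, 1, 2, 4, 8),
        "pkl-1": (1, 1, 2, 4, 8),
        "idm1": (1, 1, 1, 1, 3),
        "idm2": (1, 1, 1, 1, 3),
    }
    return {
        (genotype, time): float(fc)
        for genotype, fcs in profiles.items()
        for time, fc in zip(DEFAULT_TIMES, fcs)
    }


@dataclass
class SimConfig:
    """Full description of one synthetic dataset.

    Genome/track parameters control the epigenomic half of the pipeline;
    the qPCR and metabolite schedules control the validation half.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 2_500_000
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (1000, 3000)
    bin_size_bp: int = 200
    upstream_bp: int = 1000
    downstream_bp: int = 500
    marks: list[MarkSpec] = field(default_factory=_default_marks)
    pathways: list[PathwaySpec] = field(default_factory=_default_pathways)
    bivalent_set: BivalentSpec | None = field(default_factory=BivalentSpec)
    background_pathway_id: str = "PWY-BACKGROUND"
    background_domain_id: str = "general"
    n_multi_pathway_genes: int = 0
    times: tuple[int, ...] = DEFAULT_TIMES
    replicates: int = 6
    cq_noise_sd: float = 0.2
    conc_noise_sd: float = 0.15
    cq_base: float = 24.0
    cq_ref: float = 18.0
    cq_input: float = 20.0
    input_fraction: float = 0.01
    chip_baseline_percent: float = 1.0
    chip_time: int = 30
    reference_gene: str = "ACT2"
    expression_fc: dict[tuple[str, str, int], float] = field(
        default_factory=_default_expression_fc
    )
    chip_effects: dict[tuple[str, str], float] = field(
        default_factory=_default_chip_effects
    )
    seqchip_recovery: dict[tuple[str, str, str], float] = field(
        default_factory=_default_seqchip_recovery
    )
    conc_base_nM: float = 50.0
    conc_fc: dict[tuple[str, int], float] = field(default_factory=_default_conc_fc)

    def validate(self) -> None:
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ConfigError(f"invalid gene_length_range {self.gene_length_range}")
        if self.bin_size_bp <= 0:
            raise ConfigError("bin_size_bp must be positive")
        if self.n_chroms <= 0 or self.n_genes <= 0:
            raise ConfigError("n_chroms and n_genes must be positive")
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        if self.cq_noise_sd < 0 or self.conc_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        mark_names = [m.name for m in self.marks]
        if len(set(mark_names)) != len(mark_names):
            raise ConfigError("duplicate mark names")
        demand = sum(p.n_genes for p in self.pathways)
        if self.bivalent_set is not None:
            demand += self.bivalent_set.size
            if self.bivalent_set.multiplier < 0:
                raise ConfigError("bivalent multiplier must be >= 0")
            for m in self.bivalent_set.marks:
                if m not in mark_names:
                    raise ConfigError(f"bivalent mark {m!r} not among track marks")
        if demand > self.n_genes:
            raise ConfigError(
                f"pathway gene demand {demand} exceeds n_genes {self.n_genes}"
            )
        for p in self.pathways:
            for mark, m in p.multipliers.items():
                if m < 0:
                    raise ConfigError(f"{p.pathway_id}: multiplier for {mark} < 0")
                if mark not in mark_names:
                    raise ConfigError(
                        f"{p.pathway_id}: multiplier for unknown mark {mark!r}"
                    )
        for fc in self.expression_fc.values():
            if fc <= 0:
                raise ConfigError("expression fold changes must be > 0")
        for fc in self.conc_fc.values():
            if fc <= 0:
                raise ConfigError("concentration fold changes must be > 0")
        if not (0 < self.input_fraction <= 1):
            raise ConfigError("input_fraction must be in (0, 1]")


@dataclass
class TruthTable:
    """Planted ground truth written alongside every generated dataset."""

    set_multipliers: pd.DataFrame  # set_id, mark, multiplier
    co_marked: pd.DataFrame  # gene_id, co_marked (0/1)
    expression_fc: pd.DataFrame  # target, genotype, time, fold_change

    def co_marked_genes(self) -> frozenset[str]:
        sub = self.co_marked[self.co_marked["co_marked"] == 1]
        return frozenset(sub["gene_id"])

    def multiplier(self, set_id: str, mark: str) -> float:
        sub = self.set_multipliers[
            (self.set_multipliers["set_id"] == set_id)
            & (self.set_multipliers["mark"] == mark)
        ]
        return float(sub["multiplier"].iloc[0]) if len(sub) else 1.0

    def planted_fc(self, target: str, genotype: str, time: int) -> float:
        sub = self.expression_fc[
            (self.expression_fc["target"] == target)
            & (self.expression_fc["genotype"] == genotype)
            & (self.expression_fc["time"] == time)
        ]
        return float(sub["fold_change"].iloc[0])


@dataclass
class SimulatedDataset:
    config: SimConfig
    annotation: GenomeAnnotation
    metabolic: MetabolicAnnotation
    pathway_genes: dict[str, list[str]]
    bivalent_genes: list[str]
    tracks: list[SignalTrack]
    cq: CqTable
    concentrations: ConcentrationTable
    truth: TruthTable


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> GenomeAnnotation:
    """Place non-overlapping genes so every analysis window fits in bounds.

    Genes are spread across chromosomes as evenly as possible; the free
    space left after drawing gene lengths is distributed between genes by
    a multinomial draw, which keeps placement deterministic and O(n).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    margin = max(config.upstream_bp, config.downstream_bp)
    lo, hi = config.gene_length_range
    genes: list[GeneModel] = []
    chrom_sizes: dict[str, int] = {}
    counts = [
        config.n_genes // config.n_chroms + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    gene_no = 0
    for ci in range(config.n_chroms):
        chrom = f"Chr{ci + 1}"
        length = config.chrom_length_bp
        chrom_sizes[chrom] = length
        n = counts[ci]
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        span = length - 2 * margin
        free = span - int(lengths.sum())
        if free < 0:
            raise ConfigError(
                f"{chrom}: cannot place {n} genes of total length "
                f"{int(lengths.sum())} in {span} bp of usable sequence"
            )
        gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
        strands = rng.integers(0, 2, size=n)
        pos = margin
        for i in range(n):
            pos += int(gaps[i])
            start = pos
            end = start + int(lengths[i])
            pos = end
            gene_no += 1
            genes.append(
                GeneModel(
                    gene_id=f"AT{ci + 1}G{gene_no:05d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if strands[i] == 0 else "-",
                )
            )
    return GenomeAnnotation(genes=genes, chrom_sizes=chrom_sizes)


# ---------------------------------------------------------------------------
# gene-set assignment
# ---------------------------------------------------------------------------


def assign_gene_sets(
    config: SimConfig,
    annotation: GenomeAnnotation,
    rng: np.random.Generator | None = None,
) -> tuple[MetabolicAnnotation, dict[str, list[str]], list[str]]:
    """Randomly partition genes into the configured pathways.

    Returns (metabolic annotation, set_id -> member gene ids, bivalent
    gene ids).  Leftover genes go to the background pathway so that every
    gene maps to at least one pathway.  With ``n_multi_pathway_genes`` > 0
    that many background genes get a second membership in an extra
    specialized pathway, making their domain ambiguous — these exercise
    the unique-domain filter.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    ids = list(annotation.gene_ids)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    pathway_genes: dict[str, list[str]] = {}
    rows: list[tuple[str, str, str]] = []
    cursor = 0
    for p in config.pathways:
        members = shuffled[cursor : cursor + p.n_genes]
        cursor += p.n_genes
        pathway_genes[p.pathway_id] = members
        rows += [(g, p.pathway_id, p.domain_id) for g in members]
    bivalent_genes: list[str] = []
    if config.bivalent_set is not None:
        bv = config.bivalent_set
        bivalent_genes = shuffled[cursor : cursor + bv.size]
        cursor += bv.size
        pathway_genes[bv.pathway_id] = bivalent_genes
        rows += [(g, bv.pathway_id, bv.domain_id) for g in bivalent_genes]
    background = shuffled[cursor:]
    if background:
        pathway_genes[config.background_pathway_id] = background
        rows += [
            (g, config.background_pathway_id, config.background_domain_id)
            for g in background
        ]
    if config.n_multi_pathway_genes > 0:
        if config.n_multi_pathway_genes > len(background):
            raise ConfigError("not enough background genes for multi-pathway flags")
        multi = background[: config.n_multi_pathway_genes]
        rows += [(g, "PWY-MULTI", "specialized") for g in multi]
        pathway_genes["PWY-MULTI"] = list(multi)
    return MetabolicAnnotation.from_records(rows), pathway_genes, bivalent_genes


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def simulate_tracks(
    config: SimConfig,
    annotation: GenomeAnnotation,
    pathway_genes: Mapping[str, Sequence[str]] | None = None,
    bivalent_genes: Sequence[str] | None = None,
    rngs: Sequence[np.random.Generator] | None = None,
) -> list[SignalTrack]:
    """Per-mark binned tracks with multiplicative planted enrichment.

    Every bin draws a lognormal baseline; bins overlapping the analysis
    window of a gene in a multiplied pathway are scaled by that pathway's
    per-mark multiplier, and bins of bivalent genes by the bivalent
    multiplier on both paired marks.
    """
    config.validate()
    if pathway_genes is None or bivalent_genes is None:
        metabolic, pathway_genes, bivalent_genes = assign_gene_sets(config, annotation)
    if rngs is None:
        children = np.random.SeedSequence(config.seed).spawn(3 + len(config.marks))
        rngs = [np.random.default_rng(s) for s in children[2 : 2 + len(config.marks)]]
    windows = {
        w.gene_id: w
        for w in build_windows(annotation, config.upstream_bp, config.downstream_bp)
    }
    bin_size = config.bin_size_bp
    chroms = sorted(annotation.chrom_sizes)

    def window_mask(chrom: str, n_bins: int, genes: Sequence[str]) -> np.ndarray:
        mask = np.zeros(n_bins, dtype=bool)
        for gid in genes:
            w = windows[gid]
            if w.chrom != chrom:
                continue
            i0 = w.win_start // bin_size
            i1 = min(-(-w.win_end // bin_size), n_bins)
            mask[i0:i1] = True
        return mask

    tracks = []
    for spec, rng in zip(config.marks, rngs):
        data = {}
        for chrom in chroms:
            length = annotation.chrom_sizes[chrom]
            n_bins = -(-length // bin_size)
            starts = np.arange(n_bins, dtype=np.int64) * bin_size
            ends = np.minimum(starts + bin_size, length)
            values = rng.lognormal(spec.mu, spec.sigma, size=n_bins)
            for p in config.pathways:
                m = p.multipliers.get(spec.name)
                if m is None or m == 1.0:
                    continue
                mask = window_mask(chrom, n_bins, pathway_genes[p.pathway_id])
                values[mask] *= m
            bv = config.bivalent_set
            if bv is not None and spec.name in bv.marks and bv.multiplier != 1.0:
                mask = window_mask(chrom, n_bins, bivalent_genes)
                values[mask] *= bv.multiplier
            data[chrom] = (starts, ends, values)
        tracks.append(SignalTrack(spec.name, data, resolution=bin_size))
    return tracks


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------


def simulate_cq(config: SimConfig, rng: np.random.Generator | None = None) -> CqTable:
    """Cq records for expression kinetics, ChIP-qPCR and sequential ChIP.

    Expression: cq_target = cq_base - log2(planted FC) + N(0, sd) under
    treatment, cq_base + noise under mock; the reference gene sits at a
    constant cq_ref + noise.  ChIP: the planted treated/mock abundance
    ratio is encoded through percent-input arithmetic.  SeqChIP: the
    planted recovery fraction f of the first pull-down gives
    cq_2nd = cq_1st_nominal - log2(f) + noise.
    """
    config.validate()
    if rng is None:
        children = np.random.SeedSequence(config.seed).spawn(3 + len(config.marks))
        rng = np.random.default_rng(children[2 + len(config.marks)])
    sd = config.cq_noise_sd
    records: list[dict] = []

    def noise() -> float:
        return float(rng.normal(0.0, sd)) if sd > 0 else 0.0

    # expression records
    contexts = sorted({(g, t) for (_, g, t) in config.expression_fc})
    for (target, genotype, time), fc in sorted(config.expression_fc.items()):
        for treatment in ("treated", "mock"):
            shift = math.log2(fc) if treatment == "treated" else 0.0
            for rep in range(1, config.replicates + 1):
                records.append(
                    {
                        "target_gene": target,
                        "sample": f"{genotype}_t{time}_{treatment}",
                        "genotype": genotype,
                        "treatment": treatment,
                        "time": time,
                        "replicate": rep,
                        "assay": "expression",
                        "antibody": "",
                        "cq": config.cq_base - shift + noise(),
                    }
                )
    for genotype, time in contexts:
        for treatment in ("treated", "mock"):
            for rep in range(1, config.replicates + 1):
                records.append(
                    {
                        "target_gene": config.reference_gene,
                        "sample": f"{genotype}_t{time}_{treatment}",
                        "genotype": genotype,
                        "treatment": treatment,
                        "time": time,
                        "replicate": rep,
                        "assay": "expression",
                        "antibody": "",
                        "cq": config.cq_ref + noise(),
                    }
                )

    # ChIP-qPCR records: planted treated/mock abundance ratio
    adjusted = config.cq_input - math.log2(1.0 / config.input_fraction)
    for (region, antibody), ratio in sorted(config.chip_effects.items()):
        if ratio <= 0:
            raise ConfigError(f"chip ratio for ({region}, {antibody}) must be > 0")
        for treatment in ("treated", "mock"):
            percent = config.chip_baseline_percent * (ratio if treatment == "treated" else 1.0)
            for rep in range(1, config.replicates + 1):
                sample = f"chip_{region}_{antibody}_{treatment}"
                records.append(
                    {
                        "target_gene": region,
                        "sample": sample,
                        "genotype": "Col-0",
                        "treatment": treatment,
                        "time": config.chip_time,
                        "replicate": rep,
                        "assay": "chip_input",
                        "antibody": antibody,
                        "cq": config.cq_input + noise(),
                    }
                )
                records.append(
                    {
                        "target_gene": region,
                        "sample": sample,
                        "genotype": "Col-0",
                        "treatment": treatment,
                        "time": config.chip_time,
                        "replicate": rep,
                        "assay": "chip_ip",
                        "antibody": antibody,
                        "cq": adjusted - math.log2(percent / 100.0) + noise(),
                    }
                )

    # sequential ChIP: recovery fraction of the first pull-down
    cq_first_nominal = config.cq_base
    for (region, ab1, ab2), frac in sorted(config.seqchip_recovery.items()):
        if not (0 < frac <= 1):
            raise ConfigError(
                f"seqchip recovery for ({region}, {ab1}>{ab2}) must be in (0, 1]"
            )
        sample = f"seqchip_{region}_{ab1}-{ab2}"
        for rep in range(1, config.replicates + 1):
            records.append(
                {
                    "target_gene": region,
                    "sample": sample,
                    "genotype": "Col-0",
                    "treatment": "mock",
                    "time": 0,
                    "replicate": rep,
                    "assay": "seqchip_1st",
                    "antibody": ab1,
                    "cq": cq_first_nominal + noise(),
                }
            )
            records.append(
                {
                    "target_gene": region,
                    "sample": sample,
                    "genotype": "Col-0",
                    "treatment": "mock",
                    "time": 0,
                    "replicate": rep,
                    "assay": "seqchip_2nd",
                    "antibody": ab2,
                    "cq": cq_first_nominal - math.log2(frac) + noise(),
                }
            )
    return CqTable.from_records(records)


def simulate_concentrations(
    config: SimConfig, rng: np.random.Generator | None = None
) -> ConcentrationTable:
    """Metabolite titers (nM) with multiplicative lognormal noise."""
    config.validate()
    if rng is None:
        children = np.random.SeedSequence(config.seed).spawn(4 + len(config.marks))
        rng = np.random.default_rng(children[3 + len(config.marks)])
    rows = []
    for (genotype, time), fc in sorted(config.conc_fc.items()):
        for treatment in ("treated", "mock"):
            level = config.conc_base_nM * (fc if treatment == "treated" else 1.0)
            for rep in range(1, config.replicates + 1):
                eps = (
                    float(rng.normal(0.0, config.conc_noise_sd))
                    if config.conc_noise_sd > 0
                    else 0.0
                )
                rows.append(
                    {
                        "genotype": genotype,
                        "treatment": treatment,
                        "time": time,
                        "replicate": rep,
                        "concentration": level * math.exp(eps),
                    }
                )
    return ConcentrationTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# truth + orchestration
# ---------------------------------------------------------------------------


def build_truth(
    config: SimConfig,
    annotation: GenomeAnnotation,
    bivalent_genes: Sequence[str],
) -> TruthTable:
    mark_names = [m.name for m in config.marks]
    set_rows = []
    for p in config.pathways:
        for mark in mark_names:
            set_rows.append(
                {
                    "set_id": p.pathway_id,
                    "mark": mark,
                    "multiplier": float(p.multipliers.get(mark, 1.0)),
                }
            )
    if config.bivalent_set is not None:
        bv = config.bivalent_set
        for mark in mark_names:
            set_rows.append(
                {
                    "set_id": bv.pathway_id,
                    "mark": mark,
                    "multiplier": float(bv.multiplier) if mark in bv.marks else 1.0,
                }
            )
    co = set(bivalent_genes)
    gene_rows = [
        {"gene_id": g, "co_marked": int(g in co)} for g in annotation.gene_ids
    ]
    fc_rows = [
        {"target": t, "genotype": g, "time": time, "fold_change": fc}
        for (t, g, time), fc in sorted(config.expression_fc.items())
    ]
    return TruthTable(
        set_multipliers=pd.DataFrame(set_rows),
        co_marked=pd.DataFrame(gene_rows),
        expression_fc=pd.DataFrame(fc_rows),
    )


def simulate_all(config: SimConfig) -> SimulatedDataset:
    """Generate the complete dataset for one config, deterministically."""
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(4 + len(config.marks))
    rng_genome = np.random.default_rng(children[0])
    rng_assign = np.random.default_rng(children[1])
    rngs_tracks = [np.random.default_rng(s) for s in children[2 : 2 + len(config.marks)]]
    rng_cq = np.random.default_rng(children[2 + len(config.marks)])
    rng_conc = np.random.default_rng(children[3 + len(config.marks)])

    annotation = simulate_genome(config, rng=rng_genome)
    metabolic, pathway_genes, bivalent_genes = assign_gene_sets(
        config, annotation, rng=rng_assign
    )
    tracks = simulate_tracks(
        config, annotation, pathway_genes, bivalent_genes, rngs=rngs_tracks
    )
    cq = simulate_cq(config, rng=rng_cq)
    conc = simulate_concentrations(config, rng=rng_conc)
    truth = build_truth(config, annotation, bivalent_genes)
    return SimulatedDataset(
        config=config,
        annotation=annotation,
        metabolic=metabolic,
        pathway_genes={k: list(v) for k, v in pathway_genes.items()},
        bivalent_genes=list(bivalent_genes),
        tracks=tracks,
        cq=cq,
        concentrations=conc,
        truth=truth,
    )


def write_truth(truth: TruthTable, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_tool_comment() + "\n")
        fh.write("kind\tk1\tk2\tk3\tvalue\n")
        for r in truth.set_multipliers.itertuples(index=False):
            fh.write(f"set_multiplier\t{r.set_id}\t{r.mark}\t\t{r.multiplier!r}\n")
        for r in truth.co_marked.itertuples(index=False):
            fh.write(f"co_marked\t{r.gene_id}\t\t\t{r.co_marked}\n")
        for r in truth.expression_fc.itertuples(index=False):
            fh.write(
                f"expression_fc\t{r.target}\t{r.genotype}\t{r.time}\t{r.fold_change!r}\n"
            )


def read_truth(path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    sm = df[df["kind"] == "set_multiplier"]
    cm = df[df["kind"] == "co_marked"]
    fc = df[df["kind"] == "expression_fc"]
    return TruthTable(
        set_multipliers=pd.DataFrame(
            {
                "set_id": sm["k1"].to_list(),
                "mark": sm["k2"].to_list(),
                "multiplier": sm["value"].astype(float).to_list(),
            }
        ),
        co_marked=pd.DataFrame(
            {
                "gene_id": cm["k1"].to_list(),
                "co_marked": cm["value"].astype(int).to_list(),
            }
        ),
        expression_fc=pd.DataFrame(
            {
                "target": fc["k1"].to_list(),
                "genotype": fc["k2"].to_list(),
                "time": fc["k3"].astype(int).to_list(),
                "fold_change": fc["value"].astype(float).to_list(),
            }
        ),
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write the full file set; returns a name -> path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.gff3"
    write_gff3(dataset.annotation, paths["genome"])
    for track in dataset.tracks:
        p = outdir / f"{track.mark_name}.bedgraph"
        write_bedgraph(track, p)
        paths[f"track:{track.mark_name}"] = p
    paths["pathways"] = outdir / "pathways.tsv"
    write_pathway_table(dataset.metabolic, paths["pathways"])
    expr = CqTable(dataset.cq.select(assay="expression"))
    chip_df = dataset.cq.df[dataset.cq.df["assay"] != "expression"]
    paths["cq_expression"] = outdir / "cq_expression.csv"
    write_cq_csv(expr, paths["cq_expression"])
    paths["cq_chip"] = outdir / "cq_chip.csv"
    write_cq_csv(CqTable(chip_df), paths["cq_chip"])
    paths["camalexin"] = outdir / "camalexin.csv"
    write_conc_csv(dataset.concentrations, paths["camalexin"])
    paths["truth"] = outdir / "truth.tsv"
    write_truth(dataset.truth, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# YAML config round trip
# ---------------------------------------------------------------------------


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["gene_length_range"] = list(config.gene_length_range)
    d["times"] = list(config.times)
    d["marks"] = [asdict(m) for m in config.marks]
    d["pathways"] = [asdict(p) for p in config.pathways]
    if config.bivalent_set is not None:
        bv = asdict(config.bivalent_set)
        bv["marks"] = list(config.bivalent_set.marks)
        d["bivalent_set"] = bv
    d["expression_fc"] = [
        {"target": t, "genotype": g, "time": time, "fold_change": fc}
        for (t, g, time), fc in sorted(config.expression_fc.items())
    ]
    d["chip_effects"] = [
        {"region": r, "antibody": ab, "ratio": v}
        for (r, ab), v in sorted(config.chip_effects.items())
    ]
    d["seqchip_recovery"] = [
        {"region": r, "first": a1, "second": a2, "fraction": f}
        for (r, a1, a2), f in sorted(config.seqchip_recovery.items())
    ]
    d["conc_fc"] = [
        {"genotype": g, "time": time, "fold_change": fc}
        for (g, time), fc in sorted(config.conc_fc.items())
    ]
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    kwargs = {}
    simple = {
        f: d[f]
        for f in (
            "seed",
            "n_chroms",
            "chrom_length_bp",
            "n_genes",
            "bin_size_bp",
            "upstream_bp",
            "downstream_bp",
            "background_pathway_id",
            "background_domain_id",
            "n_multi_pathway_genes",
            "replicates",
            "cq_noise_sd",
            "conc_noise_sd",
            "cq_base",
            "cq_ref",
            "cq_input",
            "input_fraction",
            "chip_baseline_percent",
            "chip_time",
            "reference_gene",
            "conc_base_nM",
        )
        if f in d
    }
    kwargs.update(simple)
    if "gene_length_range" in d:
        kwargs["gene_length_range"] = tuple(d["gene_length_range"])
    if "times" in d:
        kwargs["times"] = tuple(d["times"])
    if "marks" in d:
        kwargs["marks"] = [MarkSpec(**m) for m in d["marks"]]
    if "pathways" in d:
        kwargs["pathways"] = [PathwaySpec(**p) for p in d["pathways"]]
    if "bivalent_set" in d:
        bv = d["bivalent_set"]
        if bv is None:
            kwargs["bivalent_set"] = None
        else:
            bv = dict(bv)
            bv["marks"] = tuple(bv["marks"])
            kwargs["bivalent_set"] = BivalentSpec(**bv)
    if "expression_fc" in d:
        kwargs["expression_fc"] = {
            (r["target"], r["genotype"], int(r["time"])): float(r["fold_change"])
            for r in d["expression_fc"]
        }
    if "chip_effects" in d:
        kwargs["chip_effects"] = {
            (r["region"], r["antibody"]): float(r["ratio"]) for r in d["chip_effects"]
        }
    if "seqchip_recovery" in d:
        kwargs["seqchip_recovery"] = {
            (r["region"], r["first"], r["second"]): float(r["fraction"])
            for r in d["seqchip_recovery"]
        }
    if "conc_fc" in d:
        kwargs["conc_fc"] = {
            (r["genotype"], int(r["time"])): float(r["fold_change"])
            for r in d["conc_fc"]
        }
    config = SimConfig(**kwargs)
    config.validate()
    return config


def load_config_yaml(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return config_from_dict(data)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config_yaml(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
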