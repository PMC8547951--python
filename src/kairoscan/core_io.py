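"""Data model and readers/writers for all external formats.

Single home for coordinate conventions: internally every interval is 0-based,
half-open.  GFF3 (1-based, closed) is converted at the boundary on read and
write; bedGraph is native half-open and passes through unchanged.

Formats handled here:

* GFF3 gene models (``gene`` features only; other feature types are ignored)
* 4-column bedGraph signal tracks, one file per epigenetic mark
* gene -> pathway -> domain membership tables (TSV, PlantCyc/PMN-style export)
* long-format qPCR quantification-cycle (Cq) tables (CSV)
* metabolite concentration tables (CSV)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from ._version import __version__
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

VALID_STRANDS = frozenset({"+", "-"})
VALID_TREATMENTS = frozenset({"treated", "mock"})
VALID_ASSAYS = frozenset(
    {"expression", "chip_input", "chip_ip", "seqchip_1st", "seqchip_2nd"}
)

CQ_COLUMNS = [
    "target_gene",
    "sample",
    "genotype",
    "treatment",
    "time",
    "replicate",
    "assay",
    "antibody",
    "cq",
]
CQ_KEY = CQ_COLUMNS[:-1]
CONC_COLUMNS = ["genotype", "treatment", "time", "replicate", "concentration"]


def _tool_comment() -> str:
    return f"# kairoscan {__version__}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic interval; the unit onto which signal is aggregated."""

    gene_id: str
    chrom: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Ordered gene models plus chromosome sizes; lookup by gene_id is total."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    _by_id: dict[str, GeneModel] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self._by_id = {}
        for gene in self.genes:
            if gene.gene_id in self._by_id:
                raise ValidationError(f"duplicate gene_id {gene.gene_id!r}")
            self._by_id[gene.gene_id] = gene
            size = self.chrom_sizes.get(gene.chrom)
            if size is None:
                raise ValidationError(
                    f"gene {gene.gene_id!r}: unknown chromosome {gene.chrom!r}"
                )
            if gene.end > size:
                raise ValidationError(
                    f"gene {gene.gene_id!r} extends past {gene.chrom} length {size}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene_id {gene_id!r} not in annotation") from None

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


class SignalTrack:
    """Binned genome-wide signal for one epigenetic mark.

    Bins are stored per chromosome as parallel numpy arrays (starts, ends,
    values), sorted and non-overlapping.  ``rank_normalized`` records whether
    values are genome-wide fractional ranks (see
    :func:`kairoscan.signal_density.rank_normalize`).
    """

    def __init__(
        self,
        mark_name: str,
        data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        resolution: int = 0,
        rank_normalized: bool = False,
    ) -> None:
        self.mark_name = mark_name
        self.data = {c: tuple(np.asarray(a) for a in arrs) for c, arrs in data.items()}
        self.resolution = resolution
        self.rank_normalized = rank_normalized
        self._validate()

    def _validate(self) -> None:
        for chrom, (starts, ends, values) in self.data.items():
            if not (len(starts) == len(ends) == len(values)):
                raise ValidationError(f"{chrom}: ragged bin arrays")
            if len(starts) == 0:
                continue
            if np.any(ends <= starts):
                raise ValidationError(f"{chrom}: bin with end <= start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(
                    f"track {self.mark_name!r}, {chrom}: overlapping or unsorted bins"
                )
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise ValidationError(
                    f"track {self.mark_name!r}, {chrom}: values must be finite and >= 0"
                )

    @classmethod
    def from_bins(
        cls,
        mark_name: str,
        bins: Iterable[tuple[str, int, int, float]],
        resolution: int = 0,
        rank_normalized: bool = False,
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in bins:
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        data = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            data[chrom] = (starts, ends, values)
        return cls(mark_name, data, resolution=resolution, rank_normalized=rank_normalized)

    @property
    def n_bins(self) -> int:
        return sum(len(starts) for starts, _, _ in self.data.values())

    def iter_bins(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in sorted(self.data):
            starts, ends, values = self.data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.iter_bins()), columns=["chrom", "start", "end", "value"]
        )


@dataclass
class MetabolicAnnotation:
    """gene -> pathway(s) -> domain(s) hierarchy with set-membership queries.

    A pathway's domain assignment is transferred to every gene annotated to
    that pathway.  ``unique_domain(gene)`` is defined only when all of a
    gene's pathways map to exactly one common domain; domain-level analyses
    use only such genes.
    """

    gene_to_pathways: dict[str, frozenset[str]]
    pathway_to_domains: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for pid, domains in self.pathway_to_domains.items():
            if not domains:
                raise ValidationError(f"pathway {pid!r} has no domain")
        for gid, pids in self.gene_to_pathways.items():
            if not pids:
                raise ValidationError(f"gene {gid!r} maps to no pathway")
            for pid in pids:
                if pid not in self.pathway_to_domains:
                    raise ValidationError(
                        f"gene {gid!r} references unknown pathway {pid!r}"
                    )
        self._pathway_genes: dict[str, frozenset[str]] = {}
        inv: dict[str, set[str]] = {p: set() for p in self.pathway_to_domains}
        for gid, pids in self.gene_to_pathways.items():
            for pid in pids:
                inv[pid].add(gid)
        self._pathway_genes = {p: frozenset(g) for p, g in inv.items()}

    @classmethod
    def from_records(
        cls, rows: Iterable[tuple[str, str, str]]
    ) -> "MetabolicAnnotation":
        g2p: dict[str, set[str]] = {}
        p2d: dict[str, set[str]] = {}
        for gene_id, pathway_id, domain_id in rows:
            g2p.setdefault(gene_id, set()).add(pathway_id)
            p2d.setdefault(pathway_id, set()).add(domain_id)
        return cls(
            {g: frozenset(p) for g, p in g2p.items()},
            {p: frozenset(d) for p, d in p2d.items()},
        )

    @property
    def domains(self) -> list[str]:
        return sorted({d for ds in self.pathway_to_domains.values() for d in ds})

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.pathway_to_domains)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.gene_to_pathways)

    def genes_in_pathway(self, pathway_id: str) -> frozenset[str]:
        try:
            return self._pathway_genes[pathway_id]
        except KeyError:
            raise KeyError(f"unknown pathway {pathway_id!r}") from None

    def gene_domains(self, gene_id: str) -> frozenset[str]:
        pids = self.gene_to_pathways[gene_id]
        return frozenset(d for p in pids for d in self.pathway_to_domains[p])

    def unique_domain(self, gene_id: str) -> str | None:
        """The gene's single domain, or None when ambiguous.

        Defined iff every pathway of the gene maps to exactly one common
        domain; multi-domain genes return None and are excluded from
        domain-level analyses.
        """
        domains = self.gene_domains(gene_id)
        if len(domains) == 1:
            return next(iter(domains))
        return None

    def genes_in_domain(self, domain_id: str, unique_only: bool = True) -> frozenset[str]:
        if domain_id not in self.domains:
            raise KeyError(f"unknown domain {domain_id!r}")
        if unique_only:
            return frozenset(
                g for g in self.gene_to_pathways if self.unique_domain(g) == domain_id
            )
        return frozenset(
            g for g in self.gene_to_pathways if domain_id in self.gene_domains(g)
        )

    def to_records(self) -> list[tuple[str, str, str]]:
        rows = []
        for gid in sorted(self.gene_to_pathways):
            for pid in sorted(self.gene_to_pathways[gid]):
                for did in sorted(self.pathway_to_domains[pid]):
                    rows.append((gid, pid, did))
        return rows


class CqTable:
    """Long-format qPCR quantification-cycle records.

    One row per (target, sample, genotype, treatment, time, replicate,
    assay, antibody); the key is unique and ``cq`` is finite.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in CQ_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"Cq table missing columns: {missing}")
        df = df[CQ_COLUMNS].copy()
        df["time"] = df["time"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        df["cq"] = df["cq"].astype(float)
        df["antibody"] = df["antibody"].fillna("").astype(str)
        bad_treat = set(df["treatment"]) - VALID_TREATMENTS
        if bad_treat:
            raise ValidationError(f"unknown treatment values: {sorted(bad_treat)}")
        bad_assay = set(df["assay"]) - VALID_ASSAYS
        if bad_assay:
            raise ValidationError(f"unknown assay values: {sorted(bad_assay)}")
        if not np.all(np.isfinite(df["cq"].to_numpy())):
            raise ValidationError("non-finite cq value")
        if df.duplicated(subset=CQ_KEY).any():
            dup = df[df.duplicated(subset=CQ_KEY, keep=False)].iloc[0]
            raise ValidationError(
                f"duplicate Cq record key: {tuple(dup[k] for k in CQ_KEY)}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def select(self, **filters) -> pd.DataFrame:
        """Rows matching all equality ``filters`` (column=value)."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in filters.items():
            if col not in self.df.columns:
                raise KeyError(f"no Cq column {col!r}")
            mask &= self.df[col] == val
        return self.df[mask]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "CqTable":
        return cls(pd.DataFrame(list(records)))


class ConcentrationTable:
    """Metabolite titer records (nM), one row per replicate measurement."""

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in CONC_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"concentration table missing columns: {missing}")
        df = df[CONC_COLUMNS].copy()
        df["time"] = df["time"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        df["concentration"] = df["concentration"].astype(float)
        if (df["concentration"] < 0).any():
            raise ValidationError("negative concentration")
        bad_treat = set(df["treatment"]) - VALID_TREATMENTS
        if bad_treat:
            raise ValidationError(f"unknown treatment values: {sorted(bad_treat)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _prescan_gff3(path: Path) -> None:
    # gffutils gives no line numbers, so the spec'd line-level diagnostics
    # (missing ID, end < start on gene features) come from a cheap pre-scan.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            if fields[2] != "gene":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if end < start:
                raise ParseError(f"{path}:{lineno}: end < start")
            if "ID=" not in fields[8]:
                raise ParseError(f"{path}:{lineno}: gene feature lacks an ID attribute")


def read_gff3(path) -> GenomeAnnotation:
    """Read gene features from a GFF3 file.

    GFF3 1-based closed coordinates become 0-based half-open.  Chromosome
    sizes are taken from ``##sequence-region`` pragmas when present, else
    from the maximum gene end per chromosome.  Feature types other than
    ``gene`` are ignored.
    """
    path = Path(path)
    _prescan_gff3(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", keep_order=True, merge_strategy="error"
        )
    except Exception as exc:  # sqlite/gffutils errors surface as InputError
        raise ParseError(f"{path}: {exc}") from exc
    chrom_sizes: dict[str, int] = {}
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            if len(parts) >= 4:
                chrom_sizes[parts[1]] = int(parts[3])
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        strand = feat.strand if feat.strand in VALID_STRANDS else None
        if strand is None:
            raise ParseError(
                f"{path}: gene {feat.id!r} has strand {feat.strand!r} (need + or -)"
            )
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,  # 1-based closed -> 0-based half-open
                end=feat.end,
                strand=strand,
            )
        )
    if not chrom_sizes:
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
    return GenomeAnnotation(genes=genes, chrom_sizes=chrom_sizes)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"#{_tool_comment()[1:]}\n")
        for chrom in sorted(annotation.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}\n")
        for g in annotation.genes:
            fh.write(
                f"{g.chrom}\tkairoscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(path, mark_name: str) -> SignalTrack:
    """Read a 4-column bedGraph (0-based half-open) into a SignalTrack.

    Overlapping bins and negative values are errors — no silent merging.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from None
            if value < 0 or not np.isfinite(value):
                raise ValidationError(
                    f"{path}:{lineno}: value must be finite and >= 0, got {value}"
                )
            rows.append((chrom, start, end, value))
    if not rows:
        raise ValidationError(f"{path}: empty bedGraph")
    return SignalTrack.from_bins(mark_name, rows)


def write_bedgraph(track: SignalTrack, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_tool_comment() + "\n")
        for chrom, start, end, value in track.iter_bins():
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


# ---------------------------------------------------------------------------
# pathway membership TSV
# ---------------------------------------------------------------------------


def read_pathway_table(path) -> MetabolicAnnotation:
    """Read a gene_id / pathway_id / domain_id membership TSV.

    The domain(s) assigned to a pathway are transferred to every gene
    annotated to that pathway.  Duplicated identical rows are deduplicated
    with a logged warning; an empty table is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["gene_id", "pathway_id", "domain_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValidationError(f"{path}: empty pathway table")
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        logger.warning(
            "%s: deduplicated %d identical membership rows", path, n_before - len(df)
        )
    return MetabolicAnnotation.from_records(
        df[required].itertuples(index=False, name=None)
    )


def write_pathway_table(annotation: MetabolicAnnotation, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_tool_comment() + "\n")
        fh.write("gene_id\tpathway_id\tdomain_id\n")
        for gid, pid, did in annotation.to_records():
            fh.write(f"{gid}\t{pid}\t{did}\n")


# ---------------------------------------------------------------------------
# Cq and concentration CSVs
# ---------------------------------------------------------------------------


def read_cq_csv(path) -> CqTable:
    """Read a headered Cq CSV; times are minutes (e.g. 1 hr is encoded 60)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    cq = pd.to_numeric(df["cq"], errors="coerce")
    bad = cq.isna() | ~np.isfinite(cq.fillna(np.nan))
    if bad.any():
        # +2: one for the header, one for 1-based line numbering
        lineno = int(bad.idxmax()) + 2
        raise ParseError(f"{path}:{lineno}: non-numeric cq value {df['cq'][bad.idxmax()]!r}")
    df["cq"] = cq
    for col in ("time", "replicate"):
        try:
            df[col] = pd.to_numeric(df[col]).astype(int)
        except (ValueError, TypeError):
            raise ParseError(f"{path}: non-integer values in column {col!r}") from None
    return CqTable(df)


def write_cq_csv(table: CqTable, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_tool_comment() + "\n")
        table.df.to_csv(fh, index=False)


def read_conc_csv(path) -> ConcentrationTable:
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in CONC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    conc = pd.to_numeric(df["concentration"], errors="coerce")
    if conc.isna().any():
        lineno = int(conc.isna().idxmax()) + 2
        raise ParseError(f"{path}:{lineno}: non-numeric concentration")
    df["concentration"] = conc
    for col in ("time", "replicate"):
        df[col] = pd.to_numeric(df[col]).astype(int)
    return ConcentrationTable(df)


def write_conc_csv(table: ConcentrationTable, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_tool_comment() + "\n")
        table.df.to_csv(fh, index=False)
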