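"""Readers and writers for every external format the pipeline touches.

BED3/BED6 for intervals and peaks, GTF or a 6+-column TSV for genes, a
normalized RepeatMasker-like TSV for repeat instances, TSV count tables, and
a per-family metadata table. All readers validate records against the type
invariants in :mod:`corepeat.genome`, log accepted/rejected counts, and are
inverse to the corresponding writers on valid files.

Coordinates are 0-based half-open internally (BED native); GTF 1-based
inclusive coordinates are converted on read. Fixed-width RepeatMasker .out
parsing is intentionally not implemented: repeats are exchanged through the
tab-separated dialect documented in :func:`read_repeats`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .genome import (
    Gene,
    GenomicInterval,
    IntervalError,
    Peak,
    RepeatInstance,
)

log = logging.getLogger(__name__)

REPEAT_COLUMNS = ["chrom", "start", "end", "strand", "family", "repclass", "divergence"]
GENE_COLUMNS = [
    "id",
    "symbol",
    "chrom",
    "start",
    "end",
    "strand",
    "biotype",
    "conservation",
    "lca_clade",
]
FAMILY_COLUMNS = ["family", "repclass", "age_myr", "active", "consensus_length"]


@dataclass(frozen=True)
class RepeatFamilyInfo:
    """Per-family metadata: class, mean age (Myr), activity, consensus length."""

    family: str
    repclass: str
    age_myr: Optional[float] = None
    active: bool = False
    consensus_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.age_myr is not None and self.age_myr < 0:
            raise ValueError(f"{self.family}: age_myr must be >= 0")
        if self.consensus_length is not None and self.consensus_length <= 0:
            raise ValueError(f"{self.family}: consensus_length must be > 0")


@dataclass
class AnnotationBundle:
    """Everything the interval statistics need: genes, repeats, family metadata, chrom sizes."""

    genes: List[Gene]
    repeats: List[RepeatInstance]
    family_info: Dict[str, RepeatFamilyInfo] = field(default_factory=dict)
    chrom_sizes: Dict[str, int] = field(default_factory=dict)

    def validate(self) -> List[str]:
        """Return a list of problems (unknown families, out-of-bounds intervals)."""
        problems = []
        for r in self.repeats:
            if r.family not in self.family_info:
                problems.append(f"repeat family {r.family!r} missing from family_info")
        seen = set(p.split(" ", 1)[0] for p in problems)
        problems = [p for i, p in enumerate(problems) if p not in problems[:i]]
        if self.chrom_sizes:
            for obj, span in [(g.id, g.span) for g in self.genes] + [
                (r.family, r.span) for r in self.repeats
            ]:
                size = self.chrom_sizes.get(span.chrom)
                if size is None or span.end > size:
                    problems.append(f"{obj}: interval {span} outside chrom_sizes")
        return problems


def _header_comment(seed: Optional[int]) -> str:
    tail = f" seed={seed}" if seed is not None else ""
    return f"# corepeat v{__version__}{tail}\n"


def read_bed(path, as_peaks: bool = False, sample: str = ""):
    """Read BED3/BED6 into intervals (or :class:`Peak` objects with ``as_peaks``).

    Malformed lines raise with their line number; zero-length features are
    rejected. Missing strand/score columns default to "." / ``None``.
    """
    records = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                iv = GenomicInterval(
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[5] if len(fields) >= 6 else ".",
                )
            except (IntervalError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if as_peaks:
                score = None
                if len(fields) >= 5 and fields[4] not in (".", ""):
                    score = float(fields[4])
                records.append(Peak(span=iv, sample=sample, score=score))
            else:
                records.append(iv)
    log.info("read_bed(%s): %d records, %d rejected", path, len(records), n_bad)
    return records


def write_bed(path, items, seed: Optional[int] = None) -> None:
    """Write intervals or peaks as BED6 with a version/seed header comment."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        for item in items:
            iv = item.span if isinstance(item, Peak) else item
            name = item.sample if isinstance(item, Peak) else "."
            score = (
                item.score
                if isinstance(item, Peak) and item.score is not None
                else "."
            )
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name or '.'}\t{score}\t{iv.strand}\n"
            )


def _opt_float(v):
    return None if pd.isna(v) else float(v)


def read_gene_table(path, dialect: str = "tsv") -> List[Gene]:
    """Read genes from a TSV (native dialect) or a GTF file.

    TSV columns: id, symbol, chrom, start, end, strand, biotype and optional
    conservation (fraction in [0,1]) and lca_clade; coordinates 0-based
    half-open. GTF coordinates (1-based inclusive) are converted, the span is
    the union of each gene_id's lines, and the gene must lie on one chromosome
    and strand (duplicate ids across chromosomes are a hard error). Records
    with unknown strand are rejected with a warning.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        missing = [c for c in GENE_COLUMNS[:7] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing gene columns {missing}")
    elif dialect == "gtf":
        import pyranges

        gr = pyranges.read_gtf(path).df
        gr = gr[gr["Feature"].isin(["gene", "transcript", "exon"])]
        rows = []
        for gid, grp in gr.groupby("gene_id"):
            if grp["Chromosome"].nunique() > 1:
                raise ValueError(f"{path}: gene id {gid!r} on multiple chromosomes")
            symbol = (
                grp["gene_name"].iloc[0]
                if "gene_name" in grp and pd.notna(grp["gene_name"].iloc[0])
                else gid
            )
            biotype = (
                grp["gene_biotype"].iloc[0]
                if "gene_biotype" in grp and pd.notna(grp["gene_biotype"].iloc[0])
                else "other"
            )
            rows.append(
                {
                    "id": gid,
                    "symbol": symbol,
                    # pyranges keeps GTF starts 0-based after read_gtf
                    "chrom": grp["Chromosome"].iloc[0],
                    "start": int(grp["Start"].min()),
                    "end": int(grp["End"].max()),
                    "strand": grp["Strand"].iloc[0],
                    "biotype": biotype,
                }
            )
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown gene dialect {dialect!r}")

    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups[:5]}")

    genes, n_bad = [], 0
    for _, row in df.iterrows():
        if row["strand"] not in ("+", "-"):
            warnings.warn(f"gene {row['id']}: unknown strand, record skipped")
            n_bad += 1
            continue
        try:
            genes.append(
                Gene(
                    id=str(row["id"]),
                    symbol=str(row["symbol"]),
                    span=GenomicInterval(
                        str(row["chrom"]), int(row["start"]), int(row["end"]), row["strand"]
                    ),
                    biotype=str(row.get("biotype", "other")),
                    conservation=_opt_float(row.get("conservation")),
                    lca_clade=(
                        None
                        if "lca_clade" not in row or pd.isna(row.get("lca_clade"))
                        else str(row["lca_clade"])
                    ),
                )
            )
        except (IntervalError, ValueError) as exc:
            warnings.warn(f"gene {row['id']} rejected: {exc}")
            n_bad += 1
    log.info("read_gene_table(%s): %d accepted, %d rejected", path, len(genes), n_bad)
    return genes


def write_gene_table(path, genes: List[Gene], seed: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for g in genes:
            cons = "" if g.conservation is None else repr(g.conservation)
            lca = "" if g.lca_clade is None else g.lca_clade
            fh.write(
                f"{g.id}\t{g.symbol}\t{g.span.chrom}\t{g.span.start}\t{g.span.end}"
                f"\t{g.span.strand}\t{g.biotype}\t{cons}\t{lca}\n"
            )


def read_repeats(path) -> List[RepeatInstance]:
    """Read repeat instances from the normalized RepeatMasker-like TSV.

    Columns: chrom, start, end, strand, family, repclass, divergence
    (percent, may be empty). Records violating the type invariants
    (divergence outside [0,100], bad class, zero length) are rejected with a
    warning; accepted/rejected counts are logged.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in REPEAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing repeat columns {missing}")
    repeats, n_bad = [], 0
    for i, row in df.iterrows():
        try:
            repeats.append(
                RepeatInstance(
                    span=GenomicInterval(
                        str(row["chrom"]), int(row["start"]), int(row["end"]), row["strand"]
                    ),
                    family=str(row["family"]),
                    repclass=str(row["repclass"]),
                    divergence=_opt_float(row.get("divergence")),
                )
            )
        except (IntervalError, ValueError) as exc:
            warnings.warn(f"{path} row {i}: repeat rejected: {exc}")
            n_bad += 1
    log.info("read_repeats(%s): %d accepted, %d rejected", path, len(repeats), n_bad)
    return repeats


def write_repeats(path, repeats: List[RepeatInstance], seed: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        fh.write("\t".join(REPEAT_COLUMNS) + "\n")
        for r in repeats:
            div = "" if r.divergence is None else repr(r.divergence)
            fh.write(
                f"{r.span.chrom}\t{r.span.start}\t{r.span.end}\t{r.span.strand}"
                f"\t{r.family}\t{r.repclass}\t{div}\n"
            )


def read_counts(path) -> pd.DataFrame:
    """Read a features x samples TSV count table (feature-id first column).

    An optional ``length`` column (feature length in bp, for RPKM) is kept
    and exposed as ``df.attrs['length']``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    length = None
    if "length" in df.columns:
        length = df.pop("length")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    df = df.astype(int)
    if length is not None:
        df.attrs["length"] = length.astype(int)
    return df


def write_counts(path, counts: pd.DataFrame, seed: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        out = counts.copy()
        if "length" in counts.attrs:
            out.insert(0, "length", counts.attrs["length"])
        out.to_csv(fh, sep="\t", index_label="feature")


def read_family_info(path) -> Dict[str, RepeatFamilyInfo]:
    """Read the per-family metadata table (family, repclass, age_myr, active, consensus_length)."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in FAMILY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing family columns {missing}")
    info = {}
    for _, row in df.iterrows():
        fam = str(row["family"])
        info[fam] = RepeatFamilyInfo(
            family=fam,
            repclass=str(row["repclass"]),
            age_myr=_opt_float(row.get("age_myr")),
            active=bool(row["active"]),
            consensus_length=(
                None if pd.isna(row.get("consensus_length")) else int(row["consensus_length"])
            ),
        )
    return info


def write_family_info(path, info: Dict[str, RepeatFamilyInfo], seed: Optional[int] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        fh.write("\t".join(FAMILY_COLUMNS) + "\n")
        for fam in sorted(info):
            fi = info[fam]
            age = "" if fi.age_myr is None else repr(fi.age_myr)
            cl = "" if fi.consensus_length is None else str(fi.consensus_length)
            fh.write(f"{fi.family}\t{fi.repclass}\t{age}\t{fi.active}\t{cl}\n")


def write_chrom_sizes(path, sizes: Dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes
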