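"""Gene models, mutation records and the text formats that carry them.

Coordinates are 0-based half-open everywhere in memory and 1-based on text
I/O (except BED, which is 0-based by definition). Splice-site offsets follow
the donor/acceptor convention used throughout splicing genetics: positions
are numbered in transcript orientation away from the exon/intron boundary,
negative on one side and positive on the other, with no position zero. The
canonical windows are

* 5' splice site (donor):  -3 (exonic) .. +6 (intronic)
* 3' splice site (acceptor): -20 (intronic) .. +3 (exonic)

A disease variant is an SSM when it lies inside one of these windows *and*
the catalog labels it as a splicing mutation; both conditions are required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger("ssmprone")

DONOR_WINDOW = (-3, 6)      # exonic -3..-1, intronic +1..+6
ACCEPTOR_WINDOW = (-20, 3)  # intronic -20..-1, exonic +1..+3

REGION_EXONIC = "exonic"
REGION_5SS = "ss5_window"
REGION_3SS = "ss3_window"
REGION_DEEP_INTRONIC = "deep_intronic"

DM_CLASSES = ("missense", "nonsense", "splicing", "other")


@dataclass(frozen=True)
class GeneModel:
    """One canonical transcript: exon intervals plus derived splice sites.

    ``exons`` are genomic-order, 0-based half-open, non-overlapping
    intervals. ``cds_length`` defaults to the summed exon length when a
    distinct coding span is not annotated.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if len(self.exons) == 0:
            raise ValueError(f"{self.gene_id}: zero-exon gene model rejected")
        exons = tuple(tuple(e) for e in self.exons)
        prev_end = None
        for start, end in exons:
            if end <= start:
                raise ValueError(f"{self.gene_id}: empty/inverted exon ({start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
        object.__setattr__(self, "exons", exons)
        if self.cds_length == 0:
            object.__setattr__(self, "cds_length", sum(e - s for s, e in exons))
        if self.cds_length <= 0:
            raise ValueError(f"{self.gene_id}: cds_length must be > 0")

    # -- derived structure -------------------------------------------------
    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def n_splice_sites(self) -> int:
        """Two splice sites flank every intron."""
        return 2 * self.n_introns

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def gene_length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def tx_exons(self) -> tuple[tuple[int, int], ...]:
        """Exons in transcript (5'->3') order; reversed for the - strand."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def splice_sites(self) -> list[tuple[str, int]]:
        """All splice sites as (kind, transcript intron index).

        Intron ``i`` (transcript order) lies between transcript exon ``i``
        and exon ``i+1``; it carries one donor ('5ss') and one acceptor
        ('3ss').
        """
        return [(kind, i) for i in range(self.n_introns) for kind in ("5ss", "3ss")]

    def site_position(self, kind: str, intron_index: int, offset: int) -> int:
        """Genomic position of a splice-site offset (transcript orientation).

        Donor offsets: -3..-1 exonic (last bases of the upstream exon),
        +1..+6 intronic (first bases of the intron). Acceptor offsets:
        -20..-1 intronic (last bases of the intron), +1..+3 exonic (first
        bases of the downstream exon). Offset 0 does not exist.
        """
        if offset == 0:
            raise ValueError("splice-site offsets have no position 0")
        if not (0 <= intron_index < self.n_introns):
            raise IndexError(f"{self.gene_id}: intron index {intron_index} out of range")
        tx = self.tx_exons
        if kind == "5ss":
            up = tx[intron_index]  # exon upstream of the intron
            if self.strand == "+":
                boundary = up[1]  # first intronic base
                return boundary + offset - 1 if offset > 0 else boundary + offset
            boundary = up[0] - 1  # first intronic base going left
            return boundary - offset + 1 if offset > 0 else boundary - offset
        if kind == "3ss":
            down = tx[intron_index + 1]  # exon downstream of the intron
            if self.strand == "+":
                start = down[0]  # first exonic base
                return start + offset - 1 if offset > 0 else start + offset
            last = down[1] - 1  # first exonic base in transcript orientation
            return last - offset + 1 if offset > 0 else last - offset
        raise ValueError(f"unknown splice-site kind {kind!r}")

    def site_offset(self, kind: str, intron_index: int, position: int) -> int:
        """Inverse of :meth:`site_position` (any integer offset, never 0)."""
        p1 = self.site_position(kind, intron_index, 1)
        step = 1 if self.site_position(kind, intron_index, 2) > p1 else -1
        d = (position - p1) * step
        return d + 1 if d >= 0 else d


@dataclass(frozen=True)
class MutationRecord:
    """A single-nucleotide disease mutation from a catalog."""

    gene_id: str
    chrom: str
    position: int  # 0-based
    ref: str
    alt: str
    dm_class: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.gene_id}@{self.position}: ref == alt")
        if self.dm_class not in DM_CLASSES:
            raise ValueError(f"unknown dm_class {self.dm_class!r}")


@lru_cache(maxsize=None)
def _window_index(gene: GeneModel) -> dict[int, str]:
    """Map every genomic position in a canonical window to its tag.

    A position inside both windows (micro-exon or micro-intron shorter than
    the windows) takes the nearer boundary; a distance tie goes to the 5'
    window.
    """
    best: dict[int, tuple[int, int, str]] = {}  # pos -> (distance, kind priority, tag)
    for i in range(gene.n_introns):
        for kind, (lo, hi), prio, tag in (
            ("5ss", DONOR_WINDOW, 0, REGION_5SS),
            ("3ss", ACCEPTOR_WINDOW, 1, REGION_3SS),
        ):
            for off in range(lo, hi + 1):
                if off == 0:
                    continue
                pos = gene.site_position(kind, i, off)
                cand = (abs(off), prio, tag)
                if pos not in best or cand < best[pos]:
                    best[pos] = cand
    return {pos: tag for pos, (_d, _p, tag) in best.items()}


def classify_region(position: int, gene: GeneModel) -> str:
    """Region tag of a genomic position relative to one gene model.

    Returns one of ``exonic``, ``ss5_window``, ``ss3_window`` or
    ``deep_intronic``. Exonic positions falling inside a canonical window
    take the window tag.
    """
    lo, hi = gene.span
    if not (lo <= position < hi):
        raise ValueError(f"position {position} outside gene {gene.gene_id} span [{lo},{hi})")
    tag = _window_index(gene).get(position)
    if tag is not None:
        return tag
    for start, end in gene.exons:
        if start <= position < end:
            return REGION_EXONIC
    return REGION_DEEP_INTRONIC


def is_ssm(record: MutationRecord, gene: GeneModel) -> bool:
    """SSM = inside a canonical splice-site window AND splicing-labelled."""
    if record.dm_class != "splicing":
        return False
    return classify_region(record.position, gene) in (REGION_5SS, REGION_3SS)


# ---------------------------------------------------------------------------
# Gene model readers / writers
# ---------------------------------------------------------------------------

def load_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models from BED12 (.bed) or GFF3 (.gff/.gff3).

    Returns a mapping gene_id -> GeneModel. Malformed lines raise a parse
    error naming the line number; zero-exon records are rejected.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return _load_bed12(path)
    if suffix in (".gff", ".gff3"):
        return _load_gff3(path)
    raise ValueError(f"unsupported gene-model format: {path.name}")


def _load_bed12(path: Path) -> dict[str, GeneModel]:
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path.name}:{lineno}: BED12 needs 12 fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
                starts = [int(x) for x in fields[11].rstrip(",").split(",") if x]
            except ValueError as e:
                raise ValueError(f"{path.name}:{lineno}: malformed BED12 line ({e})") from None
            if n_blocks == 0 or len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path.name}:{lineno}: block count mismatch")
            exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
            cds = sum(max(0, min(e, thick_end) - max(s, thick_start)) for s, e in exons)
            models[name] = GeneModel(
                gene_id=name, chrom=chrom, strand=strand, exons=exons,
                cds_length=cds if cds > 0 else 0,
            )
    return models


def _load_gff3(path: Path) -> dict[str, GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, int] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path.name}:{lineno}: GFF3 needs 9 fields, got {len(fields)}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype not in ("exon", "CDS"):
                continue
            try:
                s, e = int(start) - 1, int(end)  # GFF3 is 1-based inclusive
            except ValueError:
                raise ValueError(f"{path.name}:{lineno}: non-integer coordinates") from None
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gid = attr.get("gene_id") or attr.get("Parent") or attr.get("ID")
            if gid is None:
                raise ValueError(f"{path.name}:{lineno}: no gene_id/Parent attribute")
            meta[gid] = (chrom, strand)
            if ftype == "exon":
                exons.setdefault(gid, []).append((s, e))
            else:
                cds[gid] = cds.get(gid, 0) + (e - s)
    models = {}
    for gid, ex in exons.items():
        chrom, strand = meta[gid]
        models[gid] = GeneModel(
            gene_id=gid, chrom=chrom, strand=strand,
            exons=tuple(sorted(ex)), cds_length=cds.get(gid, 0),
        )
    return models


def write_gene_models_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in models:
            start, end = g.span
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - start) for s, e in g.exons)
            fh.write("\t".join(map(str, [
                g.chrom, start, end, g.gene_id, 0, g.strand,
                start, end, "0,0,0", g.n_exons, sizes, starts,
            ])) + "\n")


# ---------------------------------------------------------------------------
# Mutation catalogs and variant tables
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = ["gene_id", "chrom", "pos_1based", "ref", "alt", "dm_class"]


def read_mutation_catalog(path: str | Path) -> list[MutationRecord]:
    """Read a tab-delimited mutation catalog (1-based positions on disk)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    return [
        MutationRecord(
            gene_id=row.gene_id, chrom=row.chrom,
            position=int(row.pos_1based) - 1,
            ref=row.ref, alt=row.alt, dm_class=row.dm_class,
        )
        for row in df.itertuples(index=False)
    ]


def write_mutation_catalog(records: Sequence[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.chrom, r.position + 1, r.ref, r.alt, r.dm_class) for r in records],
        columns=CATALOG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_population_variants(path: str | Path, maf_key: str = "AF") -> pd.DataFrame:
    """Read MAF-annotated population variants from a TSV or plain-text VCF.

    The TSV dialect needs columns ``gene_id, chrom, pos_1based, ref, alt,
    maf`` (and optionally ``delta``). VCF input takes MAF from the INFO key
    ``maf_key`` and the gene id from an INFO ``GENE`` key when present.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        import pysam

        rows = []
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                maf = rec.info.get(maf_key)
                if isinstance(maf, tuple):
                    maf = maf[0]
                rows.append({
                    "gene_id": rec.info.get("GENE", ""),
                    "chrom": rec.chrom, "pos_1based": rec.pos,
                    "ref": rec.ref, "alt": rec.alts[0] if rec.alts else "",
                    "maf": float(maf) if maf is not None else float("nan"),
                })
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "pos_1based", "ref", "alt", "maf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    df["position"] = df["pos_1based"].astype(int) - 1
    return df


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
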