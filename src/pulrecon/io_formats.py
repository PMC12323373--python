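"""Readers and writers for the external formats the pipeline consumes.

Everything downstream works on the domain types defined here: ordered
:class:`GeneFeature` tables, :class:`DomainHit` records from the various
search tools, and :class:`GenomeSequence` nucleotide records.

Coordinate conventions: gene coordinates are 1-based inclusive (the GFF3
convention); gene ranks are 0-based and assigned per replicon by sorting on
``(start, end, gene_id)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "GeneFeature",
    "DomainHit",
    "GenomeSequence",
    "ParseError",
    "read_gene_table",
    "write_gene_table",
    "read_hits",
    "write_hits",
    "read_fasta",
    "write_fasta",
    "read_leaf_map",
    "VALID_TOOLS",
]

#: tools accepted per hit database
VALID_TOOLS = {
    "CAZy": {"HMMER", "DIAMOND", "eCAMI"},
    "Pfam": {"HMMER", "BLASTP"},
    "TIGRFAM": {"HMMER", "BLASTP"},
    "MEROPS": {"BLASTP"},
    "SulfAtlas": {"BLASTP"},
}

_CANONICAL_TOOLS = {t.lower(): t for db in VALID_TOOLS.values() for t in db}

_IUPAC = set("ACGTURYSWKMBDHVN")


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True, order=True)
class GeneFeature:
    """One protein-coding gene in its genomic context."""

    replicon_id: str
    rank: int
    start: int
    end: int
    strand: str
    gene_id: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParseError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ParseError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class DomainHit:
    """One tool's assignment of a family/accession to a gene."""

    gene_id: str
    accession: str
    tool: str
    evalue: float
    source_db: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ParseError(f"hit for {self.gene_id}: empty accession")
        if self.evalue < 0:
            raise ParseError(f"hit for {self.gene_id}: negative e-value")


@dataclass
class GenomeSequence:
    replicon_id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"{self.replicon_id}: empty sequence")
        bad = set(self.sequence) - _IUPAC
        if bad:
            raise ParseError(
                f"{self.replicon_id}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _assign_ranks(
    rows: list[tuple[str, int, int, str, str, str]]
) -> list[GeneFeature]:
    """Sort raw rows by (replicon, start, end, gene_id) and assign per-replicon ranks."""
    seen: set[str] = set()
    for rep, start, end, strand, gid, prod in rows:
        if gid in seen:
            raise ParseError(f"duplicate gene_id {gid!r}")
        seen.add(gid)
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[4]))
    out: list[GeneFeature] = []
    rank = 0
    prev_rep: str | None = None
    for rep, start, end, strand, gid, prod in rows:
        if rep != prev_rep:
            rank = 0
            prev_rep = rep
        out.append(GeneFeature(rep, rank, start, end, strand, gid, prod))
        rank += 1
    return out


_GFF_ATTR_RE = re.compile(r"([^=;]+)=([^;]*)")


def _parse_gff3(path: Path) -> list[GeneFeature]:
    rows: list[tuple[str, int, int, str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise ParseError(f"{path}:{lineno}: end {end} < start {start}")
            attr = dict(_GFF_ATTR_RE.findall(attrs))
            gid = attr.get("ID") or attr.get("locus_tag")
            if not gid:
                raise ParseError(f"{path}:{lineno}: CDS without ID/locus_tag")
            rows.append((seqid, start, end, strand, gid, attr.get("product", "")))
    return rows and _assign_ranks(rows) or []


def _parse_genbank(path: Path) -> list[GeneFeature]:
    rows: list[tuple[str, int, int, str, str, str]] = []
    for record in SeqIO.parse(str(path), "genbank"):
        for feat in record.features:
            if feat.type != "CDS":
                continue
            tags = feat.qualifiers.get("locus_tag")
            if not tags:
                continue  # CDS without locus_tag carries no stable id
            product = feat.qualifiers.get("product", [""])[0]
            strand = "-" if feat.location.strand == -1 else "+"
            rows.append(
                (
                    record.id,
                    int(feat.location.start) + 1,
                    int(feat.location.end),
                    strand,
                    tags[0],
                    product,
                )
            )
    return _assign_ranks(rows)


def _parse_gene_tsv(path: Path) -> list[GeneFeature]:
    rows: list[tuple[str, int, int, str, str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = {"gene_id", "replicon_id", "start", "end", "strand"}
        if not required <= set(idx):
            raise ParseError(f"{path}: missing columns {sorted(required - set(idx))}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                start = int(parts[idx["start"]])
                end = int(parts[idx["end"]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end < start:
                raise ParseError(f"{path}:{lineno}: end < start")
            prod = parts[idx["product"]] if "product" in idx and len(parts) > idx["product"] else ""
            rows.append(
                (
                    parts[idx["replicon_id"]],
                    start,
                    end,
                    parts[idx["strand"]],
                    parts[idx["gene_id"]],
                    prod,
                )
            )
    return _assign_ranks(rows)


def read_gene_table(path: str | Path, format: str = "gff3") -> list[GeneFeature]:
    """Read a per-genome gene table.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``gff3`` (CDS features only), ``genbank_ft`` (CDS features with a
        locus_tag), or ``tsv`` (columns gene_id, replicon_id, start, end,
        strand[, product]).

    Returns
    -------
    list of :class:`GeneFeature` sorted by (replicon_id, start) with
    per-replicon 0-based ranks.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gff3":
        return _parse_gff3(path)
    if format == "genbank_ft":
        return _parse_genbank(path)
    if format == "tsv":
        return _parse_gene_tsv(path)
    raise ValueError(f"unknown gene-table format {format!r}")


def write_gene_table(genes: Sequence[GeneFeature], path: str | Path) -> None:
    """Write genes as a TSV readable by ``read_gene_table(format='tsv')``."""
    with open(path, "w") as fh:
        fh.write("gene_id\treplicon_id\tstart\tend\tstrand\tproduct\n")
        for g in sorted(genes, key=lambda g: (g.replicon_id, g.rank)):
            fh.write(
                f"{g.gene_id}\t{g.replicon_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.product}\n"
            )


def write_gff3(genes: Sequence[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.replicon_id, g.rank)):
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.replicon_id}\tpulrecon\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


def read_hits(path: str | Path, source_db: str) -> list[DomainHit]:
    """Read a TSV hit table (columns gene_id, accession, tool, evalue).

    Tool names are normalised case-insensitively; tools outside the allowed
    set for ``source_db`` are rejected.
    """
    if source_db not in VALID_TOOLS:
        raise ValueError(f"unknown source_db {source_db!r}")
    allowed = VALID_TOOLS[source_db]
    hits: list[DomainHit] = []
    with open(path) as fh:
        first = fh.readline()
        lines = []
        if first and not first.lower().startswith("gene_id"):
            lines.append((1, first))
        lines.extend((i, l) for i, l in enumerate(fh.readlines(), 2))
        for lineno, line in lines:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            gid, acc, tool_raw, ev_s = parts[:4]
            tool = _CANONICAL_TOOLS.get(tool_raw.lower())
            if tool is None or tool not in allowed:
                raise ParseError(
                    f"{path}:{lineno}: tool {tool_raw!r} not allowed for {source_db}"
                )
            try:
                evalue = float(ev_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric e-value {ev_s!r}") from exc
            hits.append(DomainHit(gid, acc, tool, evalue, source_db))
    return hits


def write_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\taccession\ttool\tevalue\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.accession}\t{h.tool}\t{h.evalue:g}\n")


def read_fasta(path: str | Path, topology: str = "linear") -> list[GenomeSequence]:
    """Read FASTA; sequences are uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty or not FASTA")
    return [
        GenomeSequence(rec.id, str(rec.seq).upper(), topology) for rec in records
    ]


def write_fasta(seqs: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.replicon_id}\n")
            for i in range(0, len(s.sequence), width):
                fh.write(s.sequence[i : i + width] + "\n")


def read_leaf_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping gene-tree leaf -> species-tree leaf."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if parts[0] == "leaf" and parts[1] == "species" and lineno == 1:
                continue
            if parts[0] in mapping:
                raise ParseError(f"{path}:{lineno}: duplicate leaf {parts[0]!r}")
            mapping[parts[0]] = parts[1]
    return mapping


def write_leaf_map(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("leaf\tspecies\n")
        for leaf in sorted(mapping):
            fh.write(f"{leaf}\t{mapping[leaf]}\n")
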