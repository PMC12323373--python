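"""Genome-level descriptive and comparative statistics.

Covers G+C content, total length, per-Mb role densities and the
peptidase/CAZyme (P/C) ratio, fragment-based reciprocal-best-hit average
nucleotide identity (ANI), and global-alignment 16S identity.

The ANI fragment aligner is pluggable: the default backend shells out to
``blastn`` (fast enough for real chromosomes); a pure-library backend based
on Bio.Align is provided so the module works with no external binaries on
small inputs.  All rounding happens at the reporting layer only.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

from Bio import Align

from .annotation import GeneRoleTable
from .io_formats import GenomeSequence

__all__ = [
    "GenomeStats",
    "AniConfig",
    "gc_content",
    "genome_length",
    "densities",
    "orthoani",
    "pairwise_identity_16S",
    "BlastnFragmentAligner",
    "LocalFragmentAligner",
]


@dataclass
class GenomeStats:
    genome_id: str
    length_bp: int = 0
    gc_percent: float = 0.0
    cazyme_count: int = 0
    peptidase_count: int = 0
    sulfatase_count: int = 0
    cazyme_per_mb: float = 0.0
    peptidase_per_mb: float = 0.0
    sulfatase_per_mb: float = 0.0
    pc_ratio: float | None = None  # None reported as NA
    cazyme_by_class: dict[str, int] | None = None


@dataclass(frozen=True)
class AniConfig:
    fragment_length: int = 1020
    reciprocal: bool = True
    min_coverage: float = 0.35  # fraction of fragment that must align
    backend: str = "auto"  # auto | blastn | local

    def __post_init__(self) -> None:
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be > 0")


def gc_content(seqs: Sequence[GenomeSequence] | GenomeSequence) -> float:
    """Percent G+C over unambiguous bases only (full precision; round on report)."""
    if isinstance(seqs, GenomeSequence):
        seqs = [seqs]
    gc = at = 0
    for s in seqs:
        seq = s.sequence
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases; cannot compute G+C content")
    return 100.0 * gc / (gc + at)


def genome_length(seqs: Sequence[GenomeSequence] | GenomeSequence) -> int:
    """Total bp including ambiguous bases."""
    if isinstance(seqs, GenomeSequence):
        seqs = [seqs]
    return sum(len(s) for s in seqs)


def densities(roles: GeneRoleTable, length_bp: int, genome_id: str = "") -> GenomeStats:
    """Role counts, per-Mb densities, P/C ratio and per-class CAZyme counts."""
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    caz = sum(1 for r in roles.values() if r.cazyme_families)
    pep = sum(1 for r in roles.values() if r.is_peptidase)
    sul = sum(1 for r in roles.values() if r.is_sulfatase)
    by_class = {c: 0 for c in ("GH", "GT", "PL", "CE", "CBM", "AA")}
    for r in roles.values():
        for fam in r.cazyme_families:
            for cls in ("CBM", "GH", "GT", "PL", "CE", "AA"):  # CBM before CE prefix-wise safe
                if fam.startswith(cls):
                    by_class[cls] += 1
                    break
    mb = length_bp / 1e6
    return GenomeStats(
        genome_id=genome_id,
        length_bp=length_bp,
        cazyme_count=caz,
        peptidase_count=pep,
        sulfatase_count=sul,
        cazyme_per_mb=caz / mb,
        peptidase_per_mb=pep / mb,
        sulfatase_per_mb=sul / mb,
        pc_ratio=(pep / caz) if caz else None,
        cazyme_by_class=by_class,
    )


# ---------------------------------------------------------------------------
# fragment-based reciprocal-best-hit ANI
# ---------------------------------------------------------------------------

class FragmentAligner(Protocol):
    """Best local-alignment hit of every query fragment against subject fragments.

    Returns {query_index: (subject_index, identity_percent, aligned_length)}
    for queries with a reportable hit.
    """

    def best_hits(self, queries: list[str], subjects: list[str]) -> dict[int, tuple[int, float, int]]:
        ...


class BlastnFragmentAligner:
    """blastn-backed fragment search (requires the blastn/makeblastdb binaries)."""

    def __init__(self, evalue: float = 1e-15, threads: int = 1) -> None:
        self.evalue = evalue
        self.threads = threads
        if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
            raise RuntimeError("blastn/makeblastdb not found on PATH")

    def best_hits(self, queries: list[str], subjects: list[str]) -> dict[int, tuple[int, float, int]]:
        with tempfile.TemporaryDirectory(prefix="pulrecon_ani_") as tmp:
            qpath = Path(tmp) / "q.fa"
            spath = Path(tmp) / "s.fa"
            for path, seqs in ((qpath, queries), (spath, subjects)):
                with open(path, "w") as fh:
                    for i, seq in enumerate(seqs):
                        fh.write(f">f{i}\n{seq}\n")
            subprocess.run(
                ["makeblastdb", "-in", str(spath), "-dbtype", "nucl"],
                check=True, capture_output=True,
            )
            proc = subprocess.run(
                [
                    "blastn", "-query", str(qpath), "-db", str(spath),
                    "-task", "blastn", "-evalue", str(self.evalue),
                    "-num_threads", str(self.threads),
                    "-max_target_seqs", "5",
                    "-outfmt", "6 qseqid sseqid pident length bitscore",
                ],
                check=True, capture_output=True, text=True,
            )
        best: dict[int, tuple[float, float, int, int]] = {}
        for line in proc.stdout.splitlines():
            q, s, pident, length, bits = line.split("\t")
            qi, si = int(q[1:]), int(s[1:])
            key = (float(bits), float(pident), -si)
            cur = best.get(qi)
            if cur is None or key > (cur[0], cur[1], -cur[3]):
                best[qi] = (float(bits), float(pident), int(length), si)
        return {qi: (si, pident, length) for qi, (_b, pident, length, si) in best.items()}


class LocalFragmentAligner:
    """All-vs-all local alignment via Bio.Align; only for small fragment sets."""

    def __init__(self) -> None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
        self._aligner = aligner

    def _identity(self, aln) -> tuple[float, int]:
        a, b = aln[0], aln[1]
        matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
        cols = len(a)
        return (100.0 * matches / cols if cols else 0.0), cols

    def best_hits(self, queries: list[str], subjects: list[str]) -> dict[int, tuple[int, float, int]]:
        out: dict[int, tuple[int, float, int]] = {}
        for qi, q in enumerate(queries):
            best_key = None
            best_val = None
            for si, s in enumerate(subjects):
                score = self._aligner.score(q, s)
                if score <= 0:
                    continue
                aln = next(iter(self._aligner.align(q, s)))
                ident, cols = self._identity(aln)
                key = (score, ident, -si)
                if best_key is None or key > best_key:
                    best_key = key
                    best_val = (si, ident, cols)
            if best_val is not None:
                out[qi] = best_val
        return out


def fragment(seq: str, fragment_length: int) -> list[str]:
    """Consecutive non-overlapping windows; trailing remainder discarded."""
    n = len(seq) // fragment_length
    return [seq[i * fragment_length : (i + 1) * fragment_length] for i in range(n)]


def _concat(seqs: Sequence[GenomeSequence] | GenomeSequence | str) -> str:
    if isinstance(seqs, str):
        return seqs
    if isinstance(seqs, GenomeSequence):
        return seqs.sequence
    return "".join(s.sequence for s in seqs)


def _pick_aligner(config: AniConfig) -> FragmentAligner:
    if config.backend == "local":
        return LocalFragmentAligner()
    if config.backend == "blastn":
        return BlastnFragmentAligner()
    try:
        return BlastnFragmentAligner()
    except RuntimeError:
        return LocalFragmentAligner()


def orthoani(
    genome_a: Sequence[GenomeSequence] | GenomeSequence | str,
    genome_b: Sequence[GenomeSequence] | GenomeSequence | str,
    config: AniConfig | None = None,
    aligner: FragmentAligner | None = None,
) -> float:
    """Fragment-based reciprocal-best-hit average nucleotide identity (percent).

    Both genomes are cut into consecutive ``fragment_length`` windows
    (remainder discarded), each fragment is searched against the other
    genome's fragment set in both directions, and ANI is the mean percent
    identity over reciprocal best-hit fragment pairs (identity of the two
    directions averaged per pair).  Symmetric by construction.
    """
    config = config or AniConfig()
    seq_a, seq_b = _concat(genome_a), _concat(genome_b)
    frags_a = fragment(seq_a, config.fragment_length)
    frags_b = fragment(seq_b, config.fragment_length)
    if len(frags_a) < 2 or len(frags_b) < 2:
        raise ValueError("each genome must span at least 2 fragments")
    aligner = aligner or _pick_aligner(config)
    min_len = config.min_coverage * config.fragment_length
    fwd = aligner.best_hits(frags_a, frags_b)
    rev = aligner.best_hits(frags_b, frags_a)
    identities: list[float] = []
    for qi, (si, ident_f, len_f) in sorted(fwd.items()):
        hit_back = rev.get(si)
        if hit_back is None:
            continue
        bi, ident_r, len_r = hit_back
        if bi != qi:
            continue
        if len_f < min_len or len_r < min_len:
            continue
        identities.append((ident_f + ident_r) / 2.0)
    if not identities:
        raise ValueError("genomes too divergent for ANI (no reciprocal fragment pairs)")
    return sum(identities) / len(identities)


# ---------------------------------------------------------------------------
# 16S pairwise identity
# ---------------------------------------------------------------------------

def pairwise_identity_16S(
    seq_a: str | GenomeSequence,
    seq_b: str | GenomeSequence,
    match: float = 1.0,
    mismatch: float = -1.0,
    open_gap: float = -2.0,
    extend_gap: float = -0.5,
) -> float:
    """Global-alignment percent identity, terminal overhangs excluded.

    End gaps are free during alignment; identity = matches / aligned columns
    where terminal overhang columns are excluded but internal gap columns
    count in the denominator.
    """
    a = _concat(seq_a)
    b = _concat(seq_b)
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aligner.end_gap_score = 0.0  # free terminal overhangs
    aln = next(iter(aligner.align(a, b)))
    row_a, row_b = str(aln[0]), str(aln[1])
    # trim terminal overhangs (leading/trailing columns gapped in either row)
    start = 0
    end = len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    cols = end - start
    if cols == 0:
        return 0.0
    matches = sum(
        1 for x, y in zip(row_a[start:end], row_b[start:end]) if x == y and x != "-"
    )
    return 100.0 * matches / cols
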