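"""Per-gene functional role calling from raw domain hits.

CAZyme families are assigned by a consensus vote across search tools (a
family counts only when at least ``consensus_min_tools`` distinct tools
agree at the subfamily-stripped family level).  SusC/SusD transporter
components are called from TIGRFAM/Pfam marker accessions, and peptidases
and sulfatases from MEROPS/SulfAtlas hits, all under a strict e-value
cutoff (best hit must satisfy e < cutoff).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import DomainHit, VALID_TOOLS

logger = logging.getLogger(__name__)

__all__ = ["MarkerConfig", "GeneRoles", "GeneRoleTable", "consensus_cazymes",
           "call_susCD", "call_peptidases_sulfatases", "merge_roles",
           "strip_subfamily", "write_role_table", "read_role_table"]

_FAMILY_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)(\d+)")


def strip_subfamily(accession: str) -> str | None:
    """``GH16_3`` -> ``GH16``; returns None for non-CAZy accessions."""
    m = _FAMILY_RE.match(accession)
    if not m:
        return None
    return m.group(1) + m.group(2)


@dataclass(frozen=True)
class MarkerConfig:
    """Thresholds and marker accession sets for role calling."""

    susC_accessions: frozenset[str] = frozenset({"TIGR04056", "TIGR04057"})
    susD_accessions: frozenset[str] = frozenset({"PF07980", "PF12741", "PF12771"})
    evalue_cutoff: float = 1e-15
    consensus_min_tools: int = 2

    def __post_init__(self) -> None:
        if self.consensus_min_tools not in (1, 2, 3):
            raise ValueError("consensus_min_tools must be 1, 2 or 3")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")


@dataclass
class GeneRoles:
    """Roles held by a single gene; a gene may hold several."""

    cazyme_families: set[str] = field(default_factory=set)
    is_susC: bool = False
    is_susD: bool = False
    is_peptidase: bool = False
    is_sulfatase: bool = False

    @property
    def is_cazyme(self) -> bool:
        return bool(self.cazyme_families)

    def any_role(self) -> bool:
        return (self.is_cazyme or self.is_susC or self.is_susD
                or self.is_peptidase or self.is_sulfatase)


#: gene_id -> GeneRoles
GeneRoleTable = dict[str, GeneRoles]


def consensus_cazymes(hits: Sequence[DomainHit], config: MarkerConfig | None = None) -> GeneRoleTable:
    """Vote CAZyme families per gene across the dbCAN-style search tools.

    A tool's single vote for a gene is its best hit by e-value (ties broken
    lexicographically by accession), stripped to family level.  Family F is
    assigned to a gene iff at least ``consensus_min_tools`` distinct tools
    voted for F.
    """
    config = config or MarkerConfig()
    allowed = VALID_TOOLS["CAZy"]
    # A tool may legitimately report several distinct families for one gene
    # (multi-domain CAZymes, e.g. GH16+CBM32), so each tool casts one vote
    # per family it reports (best hit within that family).
    votes: dict[str, dict[str, set[str]]] = {}  # gene -> family -> tools
    for h in hits:
        if h.tool not in allowed:
            raise ValueError(f"tool {h.tool!r} is not a CAZyme search tool")
        fam = strip_subfamily(h.accession)
        if fam is None:
            continue
        votes.setdefault(h.gene_id, {}).setdefault(fam, set()).add(h.tool)
    table: GeneRoleTable = {}
    for gene in sorted(votes):
        fams = {
            fam for fam, tools in votes[gene].items()
            if len(tools) >= config.consensus_min_tools
        }
        if fams:
            table[gene] = GeneRoles(cazyme_families=fams)
    return table


def call_susCD(hits: Sequence[DomainHit], config: MarkerConfig | None = None) -> GeneRoleTable:
    """Call SusC/SusD from TIGRFAM/Pfam marker hits under the e-value cutoff.

    A gene hit by both SusC and SusD markers is resolved in favour of SusC
    (the TonB-dependent receptor markers are the more specific) with a
    logged warning.
    """
    config = config or MarkerConfig()
    table: GeneRoleTable = {}
    for h in hits:
        if h.evalue >= config.evalue_cutoff:
            continue
        if h.accession in config.susC_accessions:
            table.setdefault(h.gene_id, GeneRoles()).is_susC = True
        elif h.accession in config.susD_accessions:
            table.setdefault(h.gene_id, GeneRoles()).is_susD = True
    for gene, roles in table.items():
        if roles.is_susC and roles.is_susD:
            logger.warning("gene %s matched both SusC and SusD markers; keeping SusC", gene)
            roles.is_susD = False
    return {g: r for g, r in sorted(table.items())}


def call_peptidases_sulfatases(
    hits: Sequence[DomainHit], config: MarkerConfig | None = None
) -> GeneRoleTable:
    """Flag peptidases (MEROPS) / sulfatases (SulfAtlas) with best e < cutoff."""
    config = config or MarkerConfig()
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        key = (h.gene_id, h.source_db)
        if key not in best or h.evalue < best[key]:
            best[key] = h.evalue
    table: GeneRoleTable = {}
    for (gene, db), ev in sorted(best.items()):
        if ev < config.evalue_cutoff:
            roles = table.setdefault(gene, GeneRoles())
            if db == "MEROPS":
                roles.is_peptidase = True
            elif db == "SulfAtlas":
                roles.is_sulfatase = True
    return table


def merge_roles(*fragments: GeneRoleTable) -> GeneRoleTable:
    """Union role fragments per gene; SusC beats SusD on conflict."""
    merged: GeneRoleTable = {}
    for frag in fragments:
        for gene, roles in frag.items():
            tgt = merged.setdefault(gene, GeneRoles())
            tgt.cazyme_families |= roles.cazyme_families
            tgt.is_susC = tgt.is_susC or roles.is_susC
            tgt.is_susD = tgt.is_susD or roles.is_susD
            tgt.is_peptidase = tgt.is_peptidase or roles.is_peptidase
            tgt.is_sulfatase = tgt.is_sulfatase or roles.is_sulfatase
    for gene, roles in merged.items():
        if roles.is_susC and roles.is_susD:
            logger.warning("gene %s is both SusC and SusD after merge; keeping SusC", gene)
            roles.is_susD = False
    return dict(sorted(merged.items()))


def write_role_table(table: GeneRoleTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcazyme_families\tis_susC\tis_susD\tis_peptidase\tis_sulfatase\n")
        for gene in sorted(table):
            r = table[gene]
            fams = ",".join(sorted(r.cazyme_families))
            fh.write(
                f"{gene}\t{fams}\t{int(r.is_susC)}\t{int(r.is_susD)}"
                f"\t{int(r.is_peptidase)}\t{int(r.is_sulfatase)}\n"
            )


def read_role_table(path: str | Path) -> GeneRoleTable:
    table: GeneRoleTable = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            gene, fams, c, d, p, s = line.rstrip("\n").split("\t")
            table[gene] = GeneRoles(
                cazyme_families=set(fams.split(",")) if fams else set(),
                is_susC=bool(int(c)),
                is_susD=bool(int(d)),
                is_peptidase=bool(int(p)),
                is_sulfatase=bool(int(s)),
            )
    return table
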