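"""Rule-based polysaccharide utilization locus (PUL) prediction.

Two seed rules are applied to the ordered gene table:

* category 1 — a SusC/D pair with at least one GH or PL gene within
  ``window`` gene ranks of either pair member;
* category 2 — an unpaired SusC with at least ``min_gh_rule2`` distinct
  GH genes within ``window`` ranks.

Accepted seeds are expanded to the minimal rank interval covering the seed
genes plus all qualifying CAZyme/SusC/SusD genes in the window; overlapping
loci on one replicon are merged.  Substrates are labelled from the CAZyme
family profile; a locus is an alginate utilization locus (AUL) iff it
carries an alginate-lyase PL family and a SusC/D pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .annotation import GeneRoleTable
from .io_formats import GeneFeature

logger = logging.getLogger(__name__)

__all__ = [
    "PulRuleConfig",
    "SusCDPair",
    "Pul",
    "ALGINATE_PL_FAMILIES",
    "DEFAULT_SUBSTRATE_MAP",
    "find_susCD_pairs",
    "predict_puls",
    "classify_substrates",
    "summarize_puls",
    "write_pul_table",
]

#: the 15 polysaccharide lyase families with known alginate lyase activity
ALGINATE_PL_FAMILIES = frozenset(
    {"PL5", "PL6", "PL7", "PL8", "PL14", "PL15", "PL17", "PL18",
     "PL31", "PL32", "PL34", "PL36", "PL38", "PL39", "PL41"}
)

DEFAULT_SUBSTRATE_MAP: dict[str, frozenset[str]] = {
    "alginate": ALGINATE_PL_FAMILIES,
    "fucoidan": frozenset({"GH29", "GH95"}),
    "laminarin": frozenset({"GH16", "GH17", "GH30"}),
    "beta-mannan": frozenset({"GH130", "GH26"}),
    "xylan": frozenset({"GH43", "GH30", "GH10"}),
    "alpha-mannan": frozenset({"GH92"}),
    "rhamnose": frozenset({"GH78"}),
    "agar": frozenset({"GH117", "GH16", "GH50", "GH86"}),
    "ulvan": frozenset({"PL24", "PL25", "PL40"}),
}


def _family_to_substrates(substrate_map: Mapping[str, frozenset[str]]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for substrate, families in substrate_map.items():
        for fam in families:
            out.setdefault(fam, set()).add(substrate)
    return out


@dataclass(frozen=True)
class PulRuleConfig:
    window: int = 10
    min_gh_rule2: int = 5
    pair_max_gap: int = 2
    substrate_map: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTRATE_MAP)
    )
    alginate_pl_families: frozenset[str] = ALGINATE_PL_FAMILIES
    circular: bool = False

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_gh_rule2 < 1 or self.pair_max_gap < 1:
            raise ValueError("window, min_gh_rule2 and pair_max_gap must be >= 1")


@dataclass(frozen=True)
class SusCDPair:
    susC_gene: str
    susD_gene: str
    replicon_id: str
    rank_gap: int


@dataclass
class Pul:
    pul_id: str
    replicon_id: str
    rank_span: tuple[int, int]
    member_genes: list[str]
    pairs: list[SusCDPair]
    rule_category: int
    cazyme_families_present: list[str]  # one entry per (gene, family): a multiset
    substrates: set[str] = field(default_factory=set)
    is_AUL: bool = False


def _index_by_replicon(genes: Sequence[GeneFeature]) -> dict[str, list[GeneFeature]]:
    by_rep: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_rep.setdefault(g.replicon_id, []).append(g)
    for rep in by_rep:
        by_rep[rep].sort(key=lambda g: g.rank)
    return by_rep


def find_susCD_pairs(
    genes: Sequence[GeneFeature],
    roles: GeneRoleTable,
    config: PulRuleConfig | None = None,
) -> list[SusCDPair]:
    """Pair each SusD with its nearest SusC within ``pair_max_gap`` ranks.

    Each SusD is assigned to at most one SusC (the nearest; rank ties are
    broken in favour of the downstream gene, i.e. the higher rank).
    """
    config = config or PulRuleConfig()
    pairs: list[SusCDPair] = []
    for rep, rep_genes in sorted(_index_by_replicon(genes).items()):
        susC = [g for g in rep_genes if roles.get(g.gene_id) and roles[g.gene_id].is_susC]
        susD = [g for g in rep_genes if roles.get(g.gene_id) and roles[g.gene_id].is_susD]
        for d in susD:
            candidates = [c for c in susC if abs(c.rank - d.rank) <= config.pair_max_gap]
            if not candidates:
                continue
            # nearest; ties -> downstream (higher rank)
            best = min(candidates, key=lambda c: (abs(c.rank - d.rank), -c.rank))
            pairs.append(
                SusCDPair(best.gene_id, d.gene_id, rep, abs(best.rank - d.rank))
            )
    return pairs


def _window_ranks(rank: int, window: int, n: int, circular: bool) -> set[int]:
    if not circular:
        return set(range(max(0, rank - window), min(n, rank + window + 1)))
    return {(rank + d) % n for d in range(-window, window + 1)}


def predict_puls(
    genes: Sequence[GeneFeature],
    roles: GeneRoleTable,
    pairs: Sequence[SusCDPair] | None = None,
    config: PulRuleConfig | None = None,
) -> list[Pul]:
    """Apply the two PUL seed rules, expand and merge loci, and classify substrates."""
    config = config or PulRuleConfig()
    if pairs is None:
        pairs = find_susCD_pairs(genes, roles, config)
    by_rep = _index_by_replicon(genes)
    rank_of = {g.gene_id: g.rank for g in genes}
    paired_susC = {p.susC_gene for p in pairs}
    pairs_by_rep: dict[str, list[SusCDPair]] = {}
    for p in pairs:
        pairs_by_rep.setdefault(p.replicon_id, []).append(p)

    raw: list[tuple[str, int, int, int, list[SusCDPair]]] = []  # rep, lo, hi, cat, pairs
    for rep, rep_genes in sorted(by_rep.items()):
        n = len(rep_genes)

        def gene_roles(g: GeneFeature):
            return roles.get(g.gene_id)

        def fams(g: GeneFeature) -> set[str]:
            r = gene_roles(g)
            return r.cazyme_families if r else set()

        def is_ghpl(g: GeneFeature) -> bool:
            return any(f.startswith(("GH", "PL")) for f in fams(g))

        def is_gh(g: GeneFeature) -> bool:
            return any(f.startswith("GH") for f in fams(g))

        def is_marker(g: GeneFeature) -> bool:
            r = gene_roles(g)
            return bool(r and (r.is_susC or r.is_susD))

        # category 1: SusC/D pairs with >=1 GH/PL in the window of either member
        for p in pairs_by_rep.get(rep, []):
            c_rank, d_rank = rank_of[p.susC_gene], rank_of[p.susD_gene]
            win = _window_ranks(c_rank, config.window, n, config.circular) | _window_ranks(
                d_rank, config.window, n, config.circular
            )
            qual = [g for g in rep_genes if g.rank in win and (is_ghpl(g) or is_marker(g))]
            if any(is_ghpl(g) for g in qual):
                ranks = [c_rank, d_rank] + [g.rank for g in qual]
                raw.append((rep, min(ranks), max(ranks), 1, [p]))

        # category 2: unpaired SusC with >= min_gh_rule2 distinct GH genes in window
        for g in rep_genes:
            r = gene_roles(g)
            if not (r and r.is_susC) or g.gene_id in paired_susC:
                continue
            win = _window_ranks(g.rank, config.window, n, config.circular)
            gh_genes = [x for x in rep_genes if x.rank in win and is_gh(x)]
            if len(gh_genes) >= config.min_gh_rule2:
                qual = [x for x in rep_genes if x.rank in win and (is_ghpl(x) or is_marker(x))]
                ranks = [g.rank] + [x.rank for x in qual]
                raw.append((rep, min(ranks), max(ranks), 2, []))

    # merge overlapping intervals per replicon
    merged: list[tuple[str, int, int, int, list[SusCDPair]]] = []
    for rep in sorted({r[0] for r in raw}):
        intervals = sorted((r for r in raw if r[0] == rep), key=lambda r: (r[1], r[2]))
        for rec in intervals:
            if merged and merged[-1][0] == rep and rec[1] <= merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (
                    rep,
                    prev[1],
                    max(prev[2], rec[2]),
                    min(prev[3], rec[3]),
                    prev[4] + rec[4],
                )
            else:
                merged.append(rec)

    puls: list[Pul] = []
    for i, (rep, lo, hi, cat, span_pairs) in enumerate(merged, 1):
        members = [g.gene_id for g in by_rep[rep] if lo <= g.rank <= hi]
        fams_multiset: list[str] = []
        for gid in members:
            r = roles.get(gid)
            if r:
                fams_multiset.extend(sorted(r.cazyme_families))
        pul = Pul(
            pul_id=f"PUL{i:03d}",
            replicon_id=rep,
            rank_span=(lo, hi),
            member_genes=members,
            pairs=sorted(set(span_pairs), key=lambda p: p.susC_gene),
            rule_category=cat,
            cazyme_families_present=fams_multiset,
        )
        classify_substrates(pul, config)
        puls.append(pul)
    return puls


def classify_substrates(pul: Pul, config: PulRuleConfig | None = None) -> Pul:
    """Fill ``substrates`` and the AUL flag from the member family profile."""
    config = config or PulRuleConfig()
    fam2sub = _family_to_substrates(config.substrate_map)
    substrates: set[str] = set()
    for fam in set(pul.cazyme_families_present):
        subs = fam2sub.get(fam)
        if subs is None:
            if fam.startswith(("GH", "PL")):
                logger.debug("family %s has no substrate mapping", fam)
            continue
        substrates |= subs
    pul.substrates = substrates
    pul.is_AUL = bool(
        "alginate" in substrates
        and pul.pairs
        and set(pul.cazyme_families_present) & config.alginate_pl_families
    )
    return pul


def summarize_puls(
    puls_by_genome: Mapping[str, Sequence[Pul]],
    substrate_order: Sequence[str] | None = None,
) -> "pandas.DataFrame":
    """Genome x substrate PUL-count table, with a separate AUL column."""
    import pandas as pd

    substrates = substrate_order or sorted(DEFAULT_SUBSTRATE_MAP)
    rows = {}
    for genome, puls in sorted(puls_by_genome.items()):
        row = {s: 0 for s in substrates}
        row["AUL"] = 0
        row["total_puls"] = len(puls)
        for p in puls:
            for s in p.substrates:
                if s in row:
                    row[s] += 1
            if p.is_AUL:
                row["AUL"] += 1
        rows[genome] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def write_pul_table(puls: Sequence[Pul], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pul_id\treplicon_id\trank_span\trule_category\tn_pairs\t"
            "cazyme_families\tsubstrates\tis_AUL\tmember_genes\n"
        )
        for p in puls:
            fh.write(
                f"{p.pul_id}\t{p.replicon_id}\t{p.rank_span[0]}-{p.rank_span[1]}\t"
                f"{p.rule_category}\t{len(p.pairs)}\t"
                f"{','.join(sorted(set(p.cazyme_families_present)))}\t"
                f"{','.join(sorted(p.substrates))}\t{int(p.is_AUL)}\t"
                f"{','.join(p.member_genes)}\n"
            )
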