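"""Synthetic fixtures: annotated genomes with planted loci, mutated genome
pairs for ANI checks, and gene families evolved on a species tree with a
known duplication/transfer/loss history.

All generators are pure functions of (config, seed): the same inputs give
byte-identical outputs.  Decoy loci are enumerated, each violating exactly
one locus-rule condition, so that recovery tests can name what failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import DomainHit, GeneFeature, GenomeSequence
from .reconciliation import PhyloTree

__all__ = [
    "PlantedLocus",
    "GenomeSimConfig",
    "SimulatedGenome",
    "FamilySimConfig",
    "SimulatedFamily",
    "simulate_genome",
    "mutate_genome",
    "simulate_family",
    "DECOY_TYPES",
]

DECOY_TYPES = ("pair_too_far", "gh_count_4", "one_tool_cazyme", "no_window_cazyme")

_SUBSTRATE_FAMILIES = {
    "alginate": ("PL7", "PL17"),
    "fucoidan": ("GH29", "GH95"),
    "laminarin": ("GH16", "GH17"),
    "agar": ("GH117", "GH50"),
    "ulvan": ("PL40",),
}


@dataclass(frozen=True)
class PlantedLocus:
    rule_category: int = 1
    substrate: str = "alginate"
    susCD_gap: int = 1
    cazyme_families: tuple[str, ...] = ()

    def families(self) -> tuple[str, ...]:
        if self.cazyme_families:
            return self.cazyme_families
        if self.rule_category == 2:
            return ("GH16", "GH17", "GH29", "GH43", "GH92")
        return _SUBSTRATE_FAMILIES.get(self.substrate, ("GH16",))


@dataclass(frozen=True)
class GenomeSimConfig:
    n_genes: int = 200
    n_replicons: int = 1
    planted_loci: tuple[PlantedLocus, ...] = ()
    decoy_spec: tuple[str, ...] = ()
    seed: int = 0
    window: int = 10
    genome_id: str = "synthetic"


@dataclass
class SimulatedGenome:
    genome_id: str
    genes: list[GeneFeature]
    hits: dict[str, list[DomainHit]]  # source_db -> hits
    sequences: list[GenomeSequence]
    truth: list[dict]  # planted loci: category, substrate, replicon, span
    seed: int = 0


def simulate_genome(config: GenomeSimConfig) -> SimulatedGenome:
    """Generate a gene table, per-tool hit tables, sequence and planted truth.

    Planted loci emit SusC/SusD marker hits and CAZyme hits supported by two
    tools (so they pass the consensus vote); decoys violate exactly one rule
    condition.  Filler genes carry free-text products and no hits.
    """
    rng = np.random.default_rng(config.seed)
    for d in config.decoy_spec:
        if d not in DECOY_TYPES:
            raise ValueError(f"unknown decoy type {d!r}")

    # rank-level layout: interleave planted units separated by >2*window fillers
    sep = 2 * config.window + 5
    units: list[tuple[str, object]] = [("locus", p) for p in config.planted_loci]
    units += [("decoy", d) for d in config.decoy_spec]
    # unit width in genes (upper bound 12)
    needed = sep + sum(12 + sep for _ in units)
    if needed > config.n_genes * config.n_replicons:
        raise ValueError(
            f"planted loci need {needed} gene slots, have {config.n_genes * config.n_replicons}"
        )

    genes_per_rep = [config.n_genes // config.n_replicons] * config.n_replicons
    genes_per_rep[0] += config.n_genes % config.n_replicons

    # assign each unit a (replicon, start_rank)
    placements: list[tuple[int, int, str, object]] = []
    rep_cursor = [sep] * config.n_replicons
    rep_i = 0
    for kind, payload in units:
        tries = 0
        while rep_cursor[rep_i] + 12 + sep > genes_per_rep[rep_i]:
            rep_i = (rep_i + 1) % config.n_replicons
            tries += 1
            if tries > config.n_replicons:
                raise ValueError("planted loci do not fit; increase n_genes")
        placements.append((rep_i, rep_cursor[rep_i], kind, payload))
        rep_cursor[rep_i] += 12 + sep
        rep_i = (rep_i + 1) % config.n_replicons

    role_at: dict[tuple[int, int], tuple[str, str | None]] = {}  # (rep, rank) -> (kind, detail)
    truth: list[dict] = []
    for rep, start, kind, payload in placements:
        if kind == "locus":
            locus: PlantedLocus = payload
            fams = locus.families()
            if locus.rule_category == 1:
                role_at[(rep, start)] = ("susC", None)
                role_at[(rep, start + locus.susCD_gap)] = ("susD", None)
                pos = start + locus.susCD_gap + 1
            else:
                role_at[(rep, start)] = ("susC", None)
                pos = start + 1
            for fam in fams:
                role_at[(rep, pos)] = ("cazyme", fam)
                pos += 1
            truth.append(
                {
                    "category": locus.rule_category,
                    "substrate": locus.substrate,
                    "replicon_index": rep,
                    "span": (start, pos - 1),
                    "families": sorted(fams),
                }
            )
        else:
            decoy = payload
            if decoy == "pair_too_far":
                role_at[(rep, start)] = ("susC", None)
                role_at[(rep, start + 4)] = ("susD", None)  # gap 4 > pair_max_gap
                role_at[(rep, start + 5)] = ("cazyme", "GH16")
            elif decoy == "gh_count_4":
                role_at[(rep, start)] = ("susC", None)
                for i, fam in enumerate(("GH16", "GH17", "GH29", "GH43")):
                    role_at[(rep, start + 1 + i)] = ("cazyme", fam)
            elif decoy == "one_tool_cazyme":
                role_at[(rep, start)] = ("susC", None)
                role_at[(rep, start + 1)] = ("susD", None)
                role_at[(rep, start + 2)] = ("cazyme1tool", "GH16")
            elif decoy == "no_window_cazyme":
                role_at[(rep, start)] = ("susC", None)

    genes: list[GeneFeature] = []
    hits: dict[str, list[DomainHit]] = {
        "CAZy": [], "Pfam": [], "TIGRFAM": [], "MEROPS": [], "SulfAtlas": []
    }
    sequences: list[GenomeSequence] = []
    fillers = [
        "hypothetical protein", "MFS transporter", "ribosomal protein",
        "DNA polymerase subunit", "two-component sensor kinase",
    ]
    gidx = 0
    for rep in range(config.n_replicons):
        rep_id = f"{config.genome_id}_rep{rep + 1}"
        pos = 1
        for rank in range(genes_per_rep[rep]):
            length = int(rng.integers(300, 1500))
            gap = int(rng.integers(20, 200))
            start, end = pos, pos + length - 1
            pos = end + 1 + gap
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"{config.genome_id}_g{gidx:05d}"
            gidx += 1
            role = role_at.get((rep, rank))
            if role is None:
                product = fillers[int(rng.integers(0, len(fillers)))]
            else:
                kind, fam = role
                if kind == "susC":
                    product = "TonB-dependent receptor SusC"
                    hits["TIGRFAM"].append(DomainHit(gid, "TIGR04056", "BLASTP", 1e-40, "TIGRFAM"))
                elif kind == "susD":
                    product = "SusD family protein"
                    hits["Pfam"].append(DomainHit(gid, "PF07980", "BLASTP", 1e-20, "Pfam"))
                elif kind == "cazyme":
                    product = f"{fam} family protein"
                    # subfamily-suffixed HMMER accession exercises stripping
                    hits["CAZy"].append(DomainHit(gid, f"{fam}_1", "HMMER", 1e-30, "CAZy"))
                    hits["CAZy"].append(DomainHit(gid, fam, "DIAMOND", 1e-25, "CAZy"))
                else:  # cazyme1tool: fails the 2-of-3 consensus by construction
                    product = "glycoside hydrolase (single-tool)"
                    hits["CAZy"].append(DomainHit(gid, fam, "HMMER", 1e-30, "CAZy"))
            genes.append(GeneFeature(rep_id, rank, start, end, strand, gid, product))
        seq_len = pos + 100
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, seq_len)])
        sequences.append(GenomeSequence(rep_id, seq))

    return SimulatedGenome(
        genome_id=config.genome_id,
        genes=genes,
        hits=hits,
        sequences=sequences,
        truth=truth,
        seed=config.seed,
    )


def mutate_genome(
    seq: GenomeSequence | str, rate: float, seed: int
) -> GenomeSequence | str:
    """Independently substitute each base with probability ``rate``.

    Substitutions are uniform over the three other bases.  Non-ACGT bases
    are left untouched.
    """
    if not 0 <= rate < 0.25:
        raise ValueError("rate must be in [0, 0.25)")
    is_record = isinstance(seq, GenomeSequence)
    s = seq.sequence if is_record else seq
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(s.encode(), dtype="S1").copy()
    bases = np.array([b"A", b"C", b"G", b"T"])
    mask = rng.random(len(arr)) < rate
    idx = np.nonzero(mask)[0]
    base_idx = np.searchsorted(bases, arr[idx])
    valid = (base_idx < 4) & (bases[np.minimum(base_idx, 3)] == arr[idx])
    idx = idx[valid]
    base_idx = base_idx[valid]
    shift = rng.integers(1, 4, len(idx))
    arr[idx] = bases[(base_idx + shift) % 4]
    out = arr.tobytes().decode()
    if is_record:
        return GenomeSequence(seq.replicon_id + "_mut", out, seq.topology)
    return out


# ---------------------------------------------------------------------------
# gene-family evolution with known events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySimConfig:
    species_tree: PhyloTree = None  # required
    p_dup: float = 0.0
    p_transfer: float = 0.0
    p_loss: float = 0.0
    root_copies: int = 1
    seed: int = 0
    max_attempts: int = 100
    min_leaves: int = 2

    def __post_init__(self) -> None:
        for p in (self.p_dup, self.p_transfer, self.p_loss):
            if not 0 <= p < 1:
                raise ValueError("probabilities must be in [0, 1)")
        if self.p_dup + self.p_transfer + self.p_loss >= 1:
            raise ValueError("event probabilities must sum to < 1")


@dataclass
class SimulatedFamily:
    gene_tree: PhyloTree
    leaf_map: dict[str, str]
    events: list[dict]  # type, branch, donor, recipient
    seed: int


class _GNode:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []


def simulate_family(config: FamilySimConfig) -> SimulatedFamily:
    """Evolve one gene family top-down along the species tree.

    Each copy entering a species branch draws at most one event on that
    branch: loss (the copy dies), duplication (both daughters continue on
    the branch, event-free), or transfer (a daughter restarts on a uniformly
    chosen non-ancestral branch, with fresh event draws).  Copies surviving
    to species leaves become gene-tree leaves; unifurcations left by losses
    are suppressed.  Families ending with fewer than ``min_leaves`` leaves
    are resampled up to ``max_attempts`` times.
    """
    S = config.species_tree
    if S is None:
        raise ValueError("species_tree is required")
    incomp: dict[int, list[int]] = {}
    anc = [[False] * S.n for _ in range(S.n)]
    for y in range(S.n):
        x = y
        while x is not None:
            anc[x][y] = True
            x = S.parent[x]
    for x in range(S.n):
        incomp[x] = [y for y in range(S.n) if not anc[x][y] and not anc[y][x]]

    for attempt in range(config.max_attempts):
        rng = np.random.default_rng((config.seed, attempt))
        events: list[dict] = []
        counter = [0]

        def leaf_node(x: int) -> _GNode:
            counter[0] += 1
            return _GNode(label=f"{S.labels[x]}|{counter[0]}")

        def speciate(x: int, depth: int) -> _GNode | None:
            if not S.children[x]:
                return leaf_node(x)
            kids = [process_copy(k, depth) for k in S.children[x]]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return _GNode(children=kids)

        def process_copy(x: int, depth: int, allow_event: bool = True) -> _GNode | None:
            if depth > 50:
                return speciate(x, depth)
            if not allow_event:
                return speciate(x, depth + 1)
            r = rng.random()
            if r < config.p_loss:
                events.append({"type": "loss", "branch": S.node_name(x)})
                return None
            if r < config.p_loss + config.p_dup:
                events.append({"type": "duplication", "branch": S.node_name(x)})
                kids = [
                    process_copy(x, depth + 1, allow_event=False),
                    process_copy(x, depth + 1, allow_event=False),
                ]
                kids = [k for k in kids if k is not None]
                if not kids:
                    return None
                return kids[0] if len(kids) == 1 else _GNode(children=kids)
            if r < config.p_loss + config.p_dup + config.p_transfer and incomp[x]:
                y = incomp[x][int(rng.integers(0, len(incomp[x])))]
                events.append(
                    {
                        "type": "transfer",
                        "branch": S.node_name(x),
                        "donor": S.node_name(x),
                        "recipient": S.node_name(y),
                    }
                )
                stay = speciate(x, depth + 1)
                moved = process_copy(y, depth + 1)
                kids = [k for k in (stay, moved) if k is not None]
                if not kids:
                    return None
                return kids[0] if len(kids) == 1 else _GNode(children=kids)
            return speciate(x, depth + 1)

        roots = [process_copy(S.root, 0) for _ in range(config.root_copies)]
        roots = [r for r in roots if r is not None]
        if not roots:
            continue
        root = roots[0] if len(roots) == 1 else _GNode(children=roots)

        leaves: list[str] = []

        def collect(n: _GNode) -> None:
            if not n.children:
                leaves.append(n.label)
            for k in n.children:
                collect(k)

        collect(root)
        if len(leaves) < config.min_leaves:
            continue

        children: list[tuple[int, ...]] = []
        labels: list[str | None] = []

        def build(n: _GNode) -> int:
            idxs = tuple(build(k) for k in n.children)
            children.append(idxs)
            labels.append(n.label)
            return len(children) - 1

        build(root)
        gene_tree = PhyloTree(children, labels)
        leaf_map = {lbl: lbl.split("|")[0] for lbl in leaves}
        return SimulatedFamily(gene_tree, leaf_map, events, config.seed)

    raise RuntimeError(
        "all family simulations went extinct or were too small; lower p_loss"
    )
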