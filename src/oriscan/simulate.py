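"""Synthetic bacterial genomes evolved along a tree, with full truth logs.

The generator emulates the statistical structure the spatial-substitution
analysis assumes: a clock-like tree over a handful of taxa; a root replicon
of non-overlapping protein-coding genes (sense codons only) on a circular or
linear molecule; per-site substitution rates that vary with origin-relative
distance by a log-linear gradient, ``rate(d) = mu * exp(g * d)``, evaluated
in each *current* genome's coordinates so that rearranged blocks acquire the
rate of their new neighborhood; block translocations (optionally inverted)
along branches; and purifying selection as probabilistic rejection of
nonsynonymous changes.

Every accepted substitution is logged with its branch, root-site identity,
position in the parent genome (the true ancestral genomic position) and in
the child genome; every rearrangement is logged in application order, so the
whole history can be replayed deterministically (:func:`replay_truth`).  The
exact block decomposition induced by the rearrangement history is emitted as
gap-free aligned blocks, so no upstream aligner is needed.

No indels and no gene gain/loss are simulated: every block is present in
every taxon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ancestral import Phylogeny
from .blocks import AlignedBlock, AnnotationTable, BlockRow, Gene, write_xmfa
from .replicon import Replicon, Topology, assign_terminus, transform_distances

logger = logging.getLogger(__name__)

BASES = "ACGT"
_COMP = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G on the 0..3 code
_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.int8)  # A<->G, C<->T

_CODON_AA = {}


def _build_codon_aa():
    from .selection import _CODON_TABLE

    for codon, aa in _CODON_TABLE.items():
        idx = tuple("ACGT".index(b) for b in codon)
        _CODON_AA[idx] = aa


_build_codon_aa()
_SENSE_CODONS = [c for c, aa in _CODON_AA.items() if aa != "*"]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic data set.

    Defaults describe a desk-scale bacterial comparison: five moderately
    diverged strains (clock-like tree, root-to-tip height 0.02 expected
    substitutions per site), a 500-kb circular replicon about 85% coding
    with ~900-bp genes, no rate gradient unless asked for, mild purifying
    selection (one in five nonsynonymous proposals accepted), and an
    expectation of half a rearrangement per branch with a 30% chance of
    inversion.
    """

    seed: int = 0
    n_taxa: int = 5
    tree_newick: Optional[str] = None  # overrides the generated tree
    tree_height: float = 0.02  # root-to-tip, expected substitutions/site
    length: int = 500_000
    topology: str = "circular"
    origin: int = 1
    terminus: Optional[int] = None  # midpoint rule when None
    mean_gene_length: int = 900  # bp, rounded to codons
    mean_intergenic: int = 150  # bp between genes
    mu: float = 1.0  # rate multiplier per site per unit branch length
    gradient: float = 0.0  # g: log-rate change per bp of transformed distance
    kappa: float = 3.0  # transition/transversion proposal bias
    nonsyn_acceptance: float = 0.2  # f: probability a nonsynonymous change fixes
    #: expected rearrangements per average-length branch; per-branch counts are
    #: Poisson with mean proportional to branch length, so rearrangements
    #: accumulate over time like any other evolutionary event
    rearrangement_rate: float = 0.5
    inversion_prob: float = 0.3  # q: probability a rearranged block is inverted
    block_span: Tuple[int, int] = (5_000, 30_000)  # rearranged span length, bp

    def validate(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if not 0 < self.nonsyn_acceptance <= 1:
            raise ValueError("nonsyn_acceptance must be in (0, 1]")
        if min(self.mu, self.tree_height, self.rearrangement_rate) < 0:
            raise ValueError("rates must be nonnegative")
        if self.block_span[1] >= self.length:
            raise ValueError("rearranged spans must be shorter than the replicon")


@dataclass
class SimulationTruth:
    """Ledger of everything that happened, sufficient for exact replay."""

    substitutions: pd.DataFrame
    rearrangements: pd.DataFrame
    node_order: Dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SimulationResult:
    config: SimulationConfig
    replicon: Replicon
    tree: Phylogeny
    newick: str
    root_genome: "GenomeState"
    leaf_genomes: Dict[str, "GenomeState"]
    annotations: AnnotationTable
    blocks: List[AlignedBlock]
    truth: SimulationTruth

    def leaf_sequences(self) -> Dict[str, str]:
        return {t: g.sequence() for t, g in self.leaf_genomes.items()}


@dataclass
class GenomeState:
    """One genome: a permutation of root sites plus per-site bases.

    ``order[i]`` is the root-site id at (0-based) position ``i``;
    ``orient[rid]`` is ±1, the orientation of root site ``rid`` relative to
    the root genome; ``base[rid]`` is the current forward-strand base
    (0..3).  ``pos[rid]`` caches the inverse permutation.
    """

    order: np.ndarray
    orient: np.ndarray
    base: np.ndarray

    def __post_init__(self):
        self.pos = np.empty_like(self.order)
        self.pos[self.order] = np.arange(self.order.shape[0])

    def copy(self) -> "GenomeState":
        return GenomeState(self.order.copy(), self.orient.copy(), self.base.copy())

    def sequence(self) -> str:
        ascii_bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        return ascii_bases[self.base[self.order]].tobytes().decode()


# ---------------------------------------------------------------------------
# root genome and gene layout


@dataclass
class _GeneInfo:
    gene_id: str
    root_start: int  # 0-based first bp in root coordinates
    length: int  # bp, multiple of 3
    strand: int  # +1 forward, -1 reverse, relative to the root genome


def _layout_genes(cfg: SimulationConfig, rng: np.random.Generator) -> List[_GeneInfo]:
    genes: List[_GeneInfo] = []
    pos = int(rng.integers(0, cfg.mean_intergenic + 1))
    i = 0
    while True:
        codons = max(34, int(rng.normal(cfg.mean_gene_length / 3, cfg.mean_gene_length / 9)))
        length = 3 * codons
        if pos + length >= cfg.length:
            break
        strand = 1 if rng.random() < 0.5 else -1
        genes.append(_GeneInfo(f"g{i:04d}", pos, length, strand))
        i += 1
        pos += length + 1 + int(rng.geometric(1.0 / max(cfg.mean_intergenic, 1)))
    return genes


def _root_genome(
    cfg: SimulationConfig, genes: Sequence[_GeneInfo], rng: np.random.Generator
) -> Tuple[GenomeState, np.ndarray, np.ndarray, np.ndarray, Dict[int, np.ndarray]]:
    """Root state plus static site metadata.

    Returns (genome, gene_index per root site (-1 intergenic), codon_offset
    per root site (0-based offset on the coding strand), gene_strand per
    root site, codon_triples: codon ordinal -> the 3 root ids in coding
    order).  Site→codon membership never changes: rearrangements move
    sites, not their gene identity.
    """
    L = cfg.length
    base = rng.integers(0, 4, size=L).astype(np.int8)
    gene_index = np.full(L, -1, dtype=np.int32)
    codon_offset = np.full(L, -1, dtype=np.int32)
    gene_strand = np.zeros(L, dtype=np.int8)
    codon_of_site = np.full(L, -1, dtype=np.int64)
    triples: Dict[int, np.ndarray] = {}
    codon_ordinal = 0
    for gi, g in enumerate(genes):
        span = np.arange(g.root_start, g.root_start + g.length)
        coding = span if g.strand == 1 else span[::-1]
        gene_index[span] = gi
        gene_strand[span] = g.strand
        codon_offset[coding] = np.arange(g.length)
        codon_idxs = _SENSE_CODONS
        for c in range(g.length // 3):
            sites = coding[3 * c : 3 * c + 3]
            codon = codon_idxs[int(rng.integers(0, len(codon_idxs)))]
            for k, rid in enumerate(sites):
                # store the coding-strand base; flip to forward strand below
                base[rid] = codon[k]
            triples[codon_ordinal] = sites.copy()
            codon_of_site[sites] = codon_ordinal
            codon_ordinal += 1
        if g.strand == -1:
            base[span] = _COMP[base[span]]
    genome = GenomeState(
        order=np.arange(L, dtype=np.int64),
        orient=np.ones(L, dtype=np.int8),
        base=base,
    )
    return genome, gene_index, codon_offset, gene_strand, {"codon_of_site": codon_of_site, "triples": triples}


# ---------------------------------------------------------------------------
# evolution along branches


def _coding_codon(
    genome: GenomeState, sites: np.ndarray, gene_strand: np.ndarray
) -> Tuple[int, int, int]:
    """Codon (coding-strand base triple) at the given root sites."""
    out = []
    for rid in sites:
        b = genome.base[rid]
        if gene_strand[rid] * genome.orient[rid] < 0:
            b = _COMP[b]
        out.append(int(b))
    return tuple(out)


def _apply_rearrangement(
    genome: GenomeState, src: int, length: int, dest: int, inverted: bool
) -> None:
    """Excise ``length`` sites at 0-based ``src`` and reinsert at ``dest``.

    ``dest`` indexes the genome *after* excision.  Inversion reverses the
    span and complements its bases.
    """
    L = genome.order.shape[0]
    span = genome.order[src : src + length]
    rest = np.concatenate([genome.order[:src], genome.order[src + length :]])
    if inverted:
        span = span[::-1]
        genome.base[span] = _COMP[genome.base[span]]
        genome.orient[span] = -genome.orient[span]
    genome.order = np.concatenate([rest[:dest], span, rest[dest:]])
    genome.pos = np.empty_like(genome.order)
    genome.pos[genome.order] = np.arange(L)


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Generate one data set under the configured study conditions."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.length

    rep = Replicon(
        name="sim",
        length=L,
        topology=Topology(cfg.topology),
        origin=cfg.origin,
    )
    if rep.topology is Topology.CIRCULAR:
        rep = assign_terminus(rep, explicit=cfg.terminus) if cfg.terminus else assign_terminus(rep)
    distances, _ = transform_distances(np.arange(1, L + 1), rep)
    distances = distances.astype(float)

    newick = cfg.tree_newick or _yule_newick(cfg, rng)
    tree = Phylogeny.from_newick(newick)
    genes = _layout_genes(cfg, rng)
    root, gene_index, codon_offset, gene_strand, codons = _root_genome(cfg, genes, rng)
    codon_of_site = codons["codon_of_site"]
    triples = codons["triples"]

    sub_rows: List[dict] = []
    re_rows: List[dict] = []
    genomes: Dict[int, GenomeState] = {tree.root: root}
    node_name = {
        n.id: (n.taxon if n.taxon else f"n{n.id}") for n in tree.postorder()
    }

    branch_lengths = [tree.nodes[c].length for _, c in tree.branches()]
    mean_branch = max(float(np.mean(branch_lengths)), 1e-12)

    for node in tree.preorder():
        for child_id in node.children:
            child = tree.nodes[child_id]
            g = genomes[node.id].copy()
            parent_pos = genomes[node.id].pos  # before this branch's rearrangements
            # --- rearrangements first, then substitutions, along the branch;
            # counts scale with branch length (rate per average-length branch)
            n_re = int(rng.poisson(cfg.rearrangement_rate * child.length / mean_branch))
            for k in range(n_re):
                span_len = int(rng.integers(cfg.block_span[0], cfg.block_span[1] + 1))
                src = int(rng.integers(0, L - span_len + 1))
                dest = int(rng.integers(0, L - span_len + 1))
                inverted = bool(rng.random() < cfg.inversion_prob)
                _apply_rearrangement(g, src, span_len, dest, inverted)
                re_rows.append(
                    {
                        "branch": node_name[child_id],
                        "order": k,
                        "src_start": src + 1,
                        "length": span_len,
                        "dest_start": dest + 1,
                        "inverted": inverted,
                    }
                )
            # --- substitutions at rate mu * exp(g * d_current) * t
            t = max(child.length, 0.0)
            if cfg.mu > 0 and t > 0:
                rate = cfg.mu * t * np.exp(cfg.gradient * distances)
                counts = rng.poisson(rate)  # indexed by current position
                hit_positions = np.nonzero(counts)[0]
                for p in hit_positions:
                    rid = int(g.order[p])
                    for _ in range(int(counts[p])):
                        _attempt_substitution(
                            g, rid, p, cfg, rng,
                            gene_index, gene_strand, codon_of_site, triples,
                            parent_pos, node_name, node.id, child_id, sub_rows,
                        )
            genomes[child_id] = g

    leaf_genomes = {tree.nodes[i].taxon: genomes[i] for i in tree.leaves}
    blocks = _emit_blocks(leaf_genomes, root)
    annotations = _emit_annotations(leaf_genomes, genes, gene_index, codon_offset, gene_strand)
    truth = SimulationTruth(
        substitutions=pd.DataFrame(
            sub_rows,
            columns=[
                "branch", "parent", "root_site", "parent_position",
                "child_position", "from_base", "to_base", "kind",
            ],
        ),
        rearrangements=pd.DataFrame(
            re_rows,
            columns=["branch", "order", "src_start", "length", "dest_start", "inverted"],
        ),
        node_order={node_name[nid]: g.order.copy() for nid, g in genomes.items()},
    )
    return SimulationResult(
        config=cfg,
        replicon=rep,
        tree=tree,
        newick=newick,
        root_genome=root,
        leaf_genomes=leaf_genomes,
        annotations=annotations,
        blocks=blocks,
        truth=truth,
    )


def _attempt_substitution(
    g: GenomeState, rid: int, p: int, cfg, rng,
    gene_index, gene_strand, codon_of_site, triples,
    parent_pos, node_name, parent_id, child_id, sub_rows,
) -> None:
    old = int(g.base[rid])
    weights = np.ones(4)
    weights[_TS_PARTNER[old]] = cfg.kappa
    weights[old] = 0.0
    new = int(rng.choice(4, p=weights / weights.sum()))
    kind = "intergenic"
    if gene_index[rid] >= 0:
        sites = triples[int(codon_of_site[rid])]
        before = _coding_codon(g, sites, gene_strand)
        g.base[rid] = new
        after = _coding_codon(g, sites, gene_strand)
        g.base[rid] = old
        kind = "syn" if _CODON_AA[before] == _CODON_AA[after] else "nonsyn"
        if kind == "nonsyn" and rng.random() > cfg.nonsyn_acceptance:
            return  # purifying selection rejects the change
    g.base[rid] = new
    sub_rows.append(
        {
            "branch": node_name[child_id],
            "parent": node_name[parent_id],
            "root_site": rid,
            "parent_position": int(parent_pos[rid]) + 1,
            "child_position": p + 1,
            "from_base": BASES[old],
            "to_base": BASES[new],
            "kind": kind,
        }
    )


def _yule_newick(cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """A clock-like (ultrametric) random tree over t1..tn with the target height.

    Random sequential coalescence of uniformly chosen lineage pairs, with
    merge heights drawn as sorted uniforms rescaled so the root sits at
    ``tree_height`` — adequate as a neutral clock-like shape for desk-scale
    data sets.
    """
    n = cfg.n_taxa
    h = cfg.tree_height
    times = np.sort(rng.random(n - 1))
    times = times * (h / times[-1]) if times[-1] > 0 else np.full(n - 1, h)
    # each lineage: (newick subtree without trailing length, height of its root)
    lineages: List[Tuple[str, float]] = [(f"t{i+1}", 0.0) for i in range(n)]
    for tau in times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (sub_b, h_b) = lineages.pop(j)
        (sub_a, h_a) = lineages.pop(i)
        merged = f"({sub_a}:{tau - h_a:.10f},{sub_b}:{tau - h_b:.10f})"
        lineages.append((merged, float(tau)))
    return lineages[0][0] + ";"


# ---------------------------------------------------------------------------
# emitted outputs


def _emit_blocks(leaf_genomes: Dict[str, GenomeState], root: GenomeState) -> List[AlignedBlock]:
    """Exact block decomposition induced by the rearrangement history.

    A block is a maximal run of root sites that is contiguous, in a single
    orientation, in every leaf.  Rows are stored in root orientation
    (inverted blocks are reverse-complemented back), so every column is
    homologous; strand and a descending position map mark the inversion.
    """
    L = root.order.shape[0]
    ascii_bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    breaks = np.zeros(L, dtype=bool)  # break before root site r
    breaks[0] = True
    for g in leaf_genomes.values():
        pos = g.pos
        orient = g.orient
        adjacent = (pos[1:] == pos[:-1] + orient[:-1]) & (orient[1:] == orient[:-1])
        breaks[1:] |= ~adjacent
    starts = np.nonzero(breaks)[0]
    bounds = list(starts) + [L]
    blocks: List[AlignedBlock] = []
    for bi in range(len(starts)):
        a, b = bounds[bi], bounds[bi + 1]
        rows = []
        for taxon in sorted(leaf_genomes):
            g = leaf_genomes[taxon]
            span = np.arange(a, b)
            bases = g.base[span]
            inverted = g.orient[a] == -1
            if inverted:
                bases = _COMP[bases]  # back to root orientation
            seq = ascii_bases[bases].tobytes().decode()
            start = int(g.pos[a]) + 1
            rows.append(
                BlockRow(taxon=taxon, seq=seq, start=start, strand="-" if inverted else "+")
            )
        blocks.append(AlignedBlock(id=f"b{bi:04d}", rows=rows))
    return blocks


def _emit_annotations(
    leaf_genomes: Dict[str, GenomeState],
    genes: Sequence[_GeneInfo],
    gene_index: np.ndarray,
    codon_offset: np.ndarray,
    gene_strand: np.ndarray,
) -> AnnotationTable:
    """Per-leaf gene (segment) annotations in leaf coordinates.

    A rearrangement breakpoint inside a gene splits it into separately
    annotated runs; each run records the strand of the coding sequence in
    the leaf genome and the frame offset of its first in-frame base.
    """
    table: Dict[str, List[Gene]] = {}
    for taxon, g in leaf_genomes.items():
        entries: List[Gene] = []
        for gi, info in enumerate(genes):
            span = np.arange(info.root_start, info.root_start + info.length)
            pos = g.pos[span]  # leaf positions (0-based) of the gene's sites
            orient = g.orient[span]
            order_idx = np.argsort(pos)
            sorted_pos = pos[order_idx]
            run_break = np.nonzero(
                (np.diff(sorted_pos) != 1)
                | (np.diff(orient[order_idx].astype(int)) != 0)
            )[0]
            run_starts = np.concatenate([[0], run_break + 1])
            run_ends = np.concatenate([run_break, [len(span) - 1]])
            for ri, (s_i, e_i) in enumerate(zip(run_starts, run_ends)):
                first_rid = span[order_idx[s_i]]
                last_rid = span[order_idx[e_i]]
                start = int(sorted_pos[s_i]) + 1
                end = int(sorted_pos[e_i]) + 1
                strand = int(gene_strand[first_rid]) * int(g.orient[first_rid])
                if strand == 1:
                    c = int(codon_offset[first_rid]) % 3
                else:
                    c = int(codon_offset[last_rid]) % 3
                frame = (3 - c) % 3
                gid = info.gene_id if len(run_starts) == 1 else f"{info.gene_id}.p{ri}"
                entries.append(Gene(gid, start, end, "+" if strand == 1 else "-", frame))
        table[taxon] = entries
    return AnnotationTable(table)


# ---------------------------------------------------------------------------
# truth replay


def replay_truth(
    truth: SimulationTruth, root: GenomeState, tree: Phylogeny
) -> Dict[str, GenomeState]:
    """Reapply the logged history to the root genome; returns leaf genomes.

    Deterministic: rearrangements in logged order, then substitutions by
    child-genome position, per branch in preorder.  Byte-exact agreement
    with the emitted leaves is the generator's integrity contract.
    """
    node_name = {n.id: (n.taxon if n.taxon else f"n{n.id}") for n in tree.postorder()}
    re_by_branch = dict(tuple(truth.rearrangements.groupby("branch", sort=False)))
    sub_by_branch = dict(tuple(truth.substitutions.groupby("branch", sort=False)))
    genomes: Dict[int, GenomeState] = {tree.root: root.copy()}
    base_index = {b: i for i, b in enumerate(BASES)}
    for node in tree.preorder():
        for child_id in node.children:
            g = genomes[node.id].copy()
            name = node_name[child_id]
            if name in re_by_branch:
                for row in re_by_branch[name].sort_values("order").itertuples():
                    _apply_rearrangement(
                        g, row.src_start - 1, row.length, row.dest_start - 1, bool(row.inverted)
                    )
            if name in sub_by_branch:
                for row in sub_by_branch[name].itertuples():
                    rid = int(g.order[row.child_position - 1])
                    if rid != row.root_site or BASES[g.base[rid]] != row.from_base:
                        raise ValueError(
                            f"truth log inconsistent at branch {name}, "
                            f"position {row.child_position}"
                        )
                    g.base[rid] = base_index[row.to_base]
            genomes[child_id] = g
    return {tree.nodes[i].taxon: genomes[i] for i in tree.leaves}


def write_outputs(result: SimulationResult, outdir) -> Dict[str, Path]:
    """Write FASTA, annotations TSV, Newick, XMFA and truth TSVs to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = result.config.seed
    paths = {}

    fasta = outdir / "leaves.fasta"
    with open(fasta, "w") as fh:
        fh.write(f";seed={seed}\n")
        for taxon in sorted(result.leaf_genomes):
            seq = result.leaf_genomes[taxon].sequence()
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["fasta"] = fasta

    ann = outdir / "annotations.tsv"
    with open(ann, "w") as fh:
        fh.write(f"# seed={seed}\ntaxon\tgene_id\tstart\tend\tstrand\tframe\n")
        for taxon in sorted(result.annotations.taxa):
            for g in result.annotations.genes(taxon):
                fh.write(f"{taxon}\t{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.frame}\n")
    paths["annotations"] = ann

    tree_path = outdir / "tree.nwk"
    tree_path.write_text(f"[seed={seed}]\n{result.newick}\n")
    paths["tree"] = tree_path

    xmfa = outdir / "blocks.xmfa"
    write_xmfa(result.blocks, xmfa, comment=f"seed={seed}")
    paths["blocks"] = xmfa

    subs = outdir / "truth_substitutions.tsv"
    result.truth.substitutions.to_csv(subs, sep="\t", index=False)
    paths["truth_substitutions"] = subs
    rearr = outdir / "truth_rearrangements.tsv"
    result.truth.rearrangements.to_csv(rearr, sep="\t", index=False)
    paths["truth_rearrangements"] = rearr
    return paths
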