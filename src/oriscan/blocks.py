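"""Block-partitioned alignment I/O and alignment-hygiene filters.

Whole-genome aligners (progressiveMauve and kin) partition a set of replicons
into locally colinear blocks (LCBs): homologous stretches free of internal
rearrangement that may sit at different genomic positions, and on different
strands, in different taxa.  This module reads such block sets (XMFA or a
directory of per-block FASTA files), attaches per-column genomic position
maps, and applies the hygiene filters that turn raw blocks into
codon-consistent, gap-free gene segments:

* keep only blocks present in every required taxon,
* drop columns whose gap fraction exceeds a threshold (a simple stand-in for
  an alignment trimmer),
* keep only columns where every taxon is protein-coding with the identical
  codon position,
* split genes at gapped/ambiguous columns into segments, discard segments
  shorter than a minimum ungapped length (default 100 bp), and
* trim segments to complete codons.

Coordinates are 1-based inclusive externally; column indices are 0-based
internally.  The gap sentinel in position maps is ``-1``.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

GAP = -1
_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")
_UNAMBIGUOUS = frozenset("ACGT")


class BlockFormatError(ValueError):
    """Malformed block input (ragged rows, bad coordinates, ...)."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# aligned blocks


@dataclass
class BlockRow:
    """One taxon's aligned row of a block, stored in alignment orientation.

    ``start`` is the genomic (forward-strand) position of the row's first
    ungapped base *as stored*; for a ``-`` strand row the stored sequence is
    the reverse complement of the genome, so ``start`` is its highest
    coordinate and the position map descends.
    """

    taxon: str
    seq: str
    start: int
    strand: str = "+"

    def position_map(self) -> np.ndarray:
        """Genomic position per alignment column (``-1`` at gaps)."""
        step = 1 if self.strand == "+" else -1
        ungapped = np.frombuffer(self.seq.encode(), dtype=np.uint8) != ord("-")
        pm = np.full(len(self.seq), GAP, dtype=np.int64)
        pm[ungapped] = self.start + step * np.arange(int(ungapped.sum()))
        return pm


@dataclass
class AlignedBlock:
    id: str
    rows: List[BlockRow]
    #: per-taxon genomic position per column; derived lazily from rows
    _maps: Optional[Dict[str, np.ndarray]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        lengths = {len(r.seq) for r in self.rows}
        if len(lengths) > 1:
            raise BlockFormatError(f"block {self.id}: ragged rows {sorted(lengths)}")
        names = [r.taxon for r in self.rows]
        if len(set(names)) != len(names):
            raise BlockFormatError(f"block {self.id}: duplicate taxon row")

    @property
    def taxa(self) -> List[str]:
        return [r.taxon for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].seq) if self.rows else 0

    def row(self, taxon: str) -> BlockRow:
        for r in self.rows:
            if r.taxon == taxon:
                return r
        raise KeyError(f"block {self.id}: no row for taxon {taxon!r}")

    @property
    def position_maps(self) -> Dict[str, np.ndarray]:
        if self._maps is None:
            self._maps = {r.taxon: r.position_map() for r in self.rows}
        return self._maps

    def take_columns(self, columns: Sequence[int]) -> "AlignedBlock":
        """New block keeping the given columns; position maps are sliced, not re-derived."""
        cols = np.asarray(columns, dtype=np.int64)
        new_rows = []
        new_maps = {}
        for r in self.rows:
            arr = np.frombuffer(r.seq.encode(), dtype=np.uint8)[cols]
            seq = arr.tobytes().decode()
            pm = self.position_maps[r.taxon][cols]
            ungapped = pm[pm != GAP]
            start = int(ungapped[0]) if ungapped.size else r.start
            new_rows.append(BlockRow(taxon=r.taxon, seq=seq, start=start, strand=r.strand))
            new_maps[r.taxon] = pm
        blk = AlignedBlock(id=self.id, rows=new_rows)
        blk._maps = new_maps
        return blk

    def column_of(self, taxon: str, position: int) -> int:
        """Inverse of the position map for ungapped columns."""
        pm = self.position_maps[taxon]
        hits = np.nonzero(pm == position)[0]
        if hits.size != 1:
            raise KeyError(f"block {self.id}: position {position} not mapped for {taxon}")
        return int(hits[0])


_XMFA_HEADER = re.compile(
    r">\s*(?P<name>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)\s+(?P<strand>[+-])"
)


def read_blocks(
    path,
    fmt: str = "xmfa",
    replicon_lengths: Optional[Dict[str, int]] = None,
) -> List[AlignedBlock]:
    """Read aligned blocks from an XMFA file or a directory of per-block FASTAs.

    The XMFA dialect is Mauve's: per-sequence headers
    ``> taxon:start-end ± [comment]`` and blocks separated by ``=`` lines.
    A per-block FASTA directory uses the same header syntax, one file per
    block.  ``replicon_lengths`` enables bounds checking of the stated
    coordinates.
    """
    path = Path(path)
    if fmt == "xmfa":
        blocks = list(_parse_xmfa(path.read_text().splitlines(), source=path.name))
    elif fmt in ("multifasta-dir", "fasta-dir"):
        blocks = []
        for i, f in enumerate(sorted(path.glob("*.fa*"))):
            parsed = list(_parse_xmfa(f.read_text().splitlines(), source=f.stem))
            for b in parsed:
                b.id = f.stem if len(parsed) == 1 else f"{f.stem}.{b.id}"
            blocks.extend(parsed)
    else:
        raise ValueError(f"unknown block format {fmt!r}")
    if replicon_lengths:
        for b in blocks:
            for r in b.rows:
                L = replicon_lengths.get(r.taxon)
                if L is None:
                    continue
                pm = b.position_maps[r.taxon]
                mapped = pm[pm != GAP]
                if mapped.size and (mapped.min() < 1 or mapped.max() > L):
                    raise BlockFormatError(
                        f"block {b.id}, taxon {r.taxon}: positions exceed replicon length {L}"
                    )
    return blocks


def _parse_xmfa(lines: Iterable[str], source: str) -> Iterable[AlignedBlock]:
    rows: List[BlockRow] = []
    header: Optional[Tuple[str, int, int, str]] = None
    chunks: List[str] = []
    n_blocks = 0

    def flush_row():
        nonlocal header, chunks
        if header is None:
            return
        taxon, start, end, strand = header
        seq = "".join(chunks).upper()
        row_start = start if strand == "+" else end
        rows.append(BlockRow(taxon=taxon, seq=seq, start=row_start, strand=strand))
        header, chunks = None, []

    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("="):
            flush_row()
            if rows:
                n_blocks += 1
                yield AlignedBlock(id=f"{source}.block{n_blocks}", rows=rows)
            rows = []
        elif line.startswith(">"):
            flush_row()
            m = _XMFA_HEADER.match(line)
            if not m:
                raise BlockFormatError(f"{source}: unparseable header {line!r}")
            start, end = int(m["start"]), int(m["end"])
            if start < 1 or end < start:
                raise BlockFormatError(f"{source}: bad coordinates in {line!r}")
            header = (m["name"], start, end, m["strand"])
        else:
            if header is None:
                raise BlockFormatError(f"{source}: sequence data before any header")
            chunks.append(line)
    flush_row()
    if rows:
        n_blocks += 1
        yield AlignedBlock(id=f"{source}.block{n_blocks}", rows=rows)


def write_xmfa(blocks: Sequence[AlignedBlock], path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"#{comment}\n")
        for b in blocks:
            for r in b.rows:
                pm = b.position_maps[r.taxon]
                mapped = pm[pm != GAP]
                lo, hi = (int(mapped.min()), int(mapped.max())) if mapped.size else (r.start, r.start)
                fh.write(f"> {r.taxon}:{lo}-{hi} {r.strand} {b.id}\n")
                for i in range(0, len(r.seq), 80):
                    fh.write(r.seq[i : i + 80] + "\n")
            fh.write("=\n")


def select_universal_blocks(
    blocks: Sequence[AlignedBlock], required_taxa: Sequence[str]
) -> List[AlignedBlock]:
    """Keep only blocks that carry a row for every required taxon."""
    required = set(required_taxa)
    if not required:
        raise ValueError("required_taxa must be non-empty")
    kept = [b for b in blocks if required.issubset(b.taxa)]
    logger.info("universal-block filter: kept %d of %d blocks", len(kept), len(blocks))
    if not kept:
        logger.warning("no block is present in all required taxa")
    return kept


def gap_fraction_trim(block: AlignedBlock, max_gap_fraction: float = 0.2) -> AlignedBlock:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    A deliberately simple stand-in for heuristic alignment trimmers: the goal
    is removing excessively gapped columns, not modelling homology quality.
    """
    if block.n_columns == 0:
        return block
    mat = np.vstack(
        [np.frombuffer(r.seq.encode(), dtype=np.uint8) for r in block.rows]
    )
    gap_frac = (mat == ord("-")).mean(axis=0)
    keep = np.nonzero(gap_frac <= max_gap_fraction)[0]
    logger.debug("block %s: gap trim removed %d columns", block.id, block.n_columns - keep.size)
    return block.take_columns(keep)


# ---------------------------------------------------------------------------
# annotations


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    frame: int = 0  # offset of the first in-frame base, as in GFF3 phase

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


class AnnotationTable:
    """Per-taxon coding annotations with fast position → (gene, codon position) lookup."""

    def __init__(self, genes: Dict[str, Sequence[Gene]]):
        self._genes: Dict[str, List[Gene]] = {
            t: sorted(gs, key=lambda g: g.start) for t, gs in genes.items()
        }
        self._starts = {t: [g.start for g in gs] for t, gs in self._genes.items()}

    @property
    def taxa(self) -> List[str]:
        return list(self._genes)

    def genes(self, taxon: str) -> List[Gene]:
        return self._genes[taxon]

    def locate(self, taxon: str, position: int) -> Optional[Gene]:
        """The gene containing ``position`` in ``taxon``, or None if intergenic."""
        if taxon not in self._genes:
            raise KeyError(f"no annotations for taxon {taxon!r}")
        starts = self._starts[taxon]
        i = bisect_right(starts, position) - 1
        # walk left over genes that start before `position` but may overlap it
        while i >= 0:
            g = self._genes[taxon][i]
            if g.start <= position <= g.end:
                return g
            if g.end < position and i < len(starts) - 1:
                break
            i -= 1
        return None

    def codon_position(self, taxon: str, position: int) -> int:
        """Codon position (1, 2, 3) of a base, or 0 if intergenic.

        Computed on the coding strand: for a forward gene the offset is
        ``position - start - frame``, for a reverse gene ``end - position - frame``.
        """
        g = self.locate(taxon, position)
        if g is None:
            return 0
        off = (position - g.start - g.frame) if g.strand == "+" else (g.end - position - g.frame)
        if off < 0:
            return 0
        return off % 3 + 1

    @classmethod
    def read_tsv(cls, path) -> "AnnotationTable":
        """Read a 6-column TSV: taxon, gene_id, start, end, strand, frame."""
        genes: Dict[str, List[Gene]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("taxon\t"):
                    continue
                taxon, gid, start, end, strand, frame = line.split("\t")[:6]
                genes.setdefault(taxon, []).append(
                    Gene(gid, int(start), int(end), strand, int(frame))
                )
        return cls(genes)

    @classmethod
    def read_gff3(cls, paths: Dict[str, "str | Path"]) -> "AnnotationTable":
        """Read one GFF3 file per taxon, keeping CDS features."""
        genes: Dict[str, List[Gene]] = {}
        for taxon, path in paths.items():
            taxon_genes: List[Gene] = []
            with open(path) as fh:
                for line in fh:
                    if line.startswith("#") or not line.strip():
                        continue
                    fields = line.rstrip("\n").split("\t")
                    if len(fields) < 9 or fields[2] != "CDS":
                        continue
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    gid = attrs.get("ID") or attrs.get("locus_tag") or f"cds{len(taxon_genes)}"
                    frame = int(fields[7]) if fields[7] in "012" else 0
                    taxon_genes.append(
                        Gene(gid, int(fields[3]), int(fields[4]), fields[6], frame)
                    )
            genes[taxon] = taxon_genes
        return cls(genes)


# ---------------------------------------------------------------------------
# codon-consistency filtering and gene segments


def codon_consistency_filter(
    block: AlignedBlock, annotations: AnnotationTable
) -> List[int]:
    """Column indices where every taxon is coding with the identical codon position.

    Columns mapping to intergenic sequence (or a gap) in any taxon are
    dropped: the analysis is restricted to protein-coding positions whose
    reading frame agrees across the whole alignment column.
    """
    for t in block.taxa:
        if t not in annotations.taxa:
            raise KeyError(f"annotation missing for taxon {t!r}")
    kept: List[int] = []
    maps = block.position_maps
    for col in range(block.n_columns):
        cps = set()
        ok = True
        for t in block.taxa:
            pos = int(maps[t][col])
            if pos == GAP:
                ok = False
                break
            cp = annotations.codon_position(t, pos)
            if cp == 0:
                ok = False
                break
            cps.add(cp)
        if ok and len(cps) == 1:
            kept.append(col)
    return kept


@dataclass
class GeneSegment:
    """A codon-consistent, gap-free slice of a coding alignment.

    Sequences are stored in coding orientation (reverse-strand genes are
    reverse-complemented), while ``position_maps`` keep genomic
    forward-strand coordinates, so column ``j`` of every taxon is homologous
    and mappable back to each genome.  ``codon_pos[j]`` is the shared codon
    position (1/2/3) of column ``j``.
    """

    id: str
    seqs: Dict[str, str]
    position_maps: Dict[str, np.ndarray]
    strands: Dict[str, str]
    codon_pos: np.ndarray

    @property
    def taxa(self) -> List[str]:
        return list(self.seqs)

    @property
    def length(self) -> int:
        return len(self.codon_pos)

    def take_columns(self, cols: np.ndarray) -> "GeneSegment":
        return GeneSegment(
            id=self.id,
            seqs={t: "".join(s[c] for c in cols) for t, s in self.seqs.items()},
            position_maps={t: pm[cols] for t, pm in self.position_maps.items()},
            strands=dict(self.strands),
            codon_pos=self.codon_pos[cols],
        )


MIN_SEGMENT_LENGTH = 100


def split_into_segments(
    block: AlignedBlock,
    annotations: AnnotationTable,
    kept_columns: Optional[Sequence[int]] = None,
    min_len: int = MIN_SEGMENT_LENGTH,
    reference: Optional[str] = None,
) -> List[GeneSegment]:
    """Cut codon-consistent columns into per-gene, gap-free segments.

    Columns are grouped by the reference taxon's gene, then split into
    maximal runs of consecutive, unambiguous columns.  A gap or ambiguous
    base therefore severs a gene into separate segments, each analyzed as a
    distinct "gene"; runs shorter than ``min_len`` ungapped bp are discarded
    as too short to compare reliably.
    """
    if kept_columns is None:
        kept_columns = codon_consistency_filter(block, annotations)
    if not kept_columns:
        return []
    reference = reference or block.taxa[0]
    maps = block.position_maps
    seqs = {r.taxon: r.seq for r in block.rows}

    # group kept columns by the reference taxon's gene
    by_gene: Dict[str, List[int]] = {}
    gene_strand: Dict[str, str] = {}
    for col in kept_columns:
        g = annotations.locate(reference, int(maps[reference][col]))
        if g is None:  # cannot happen after the codon filter, defensive
            continue
        by_gene.setdefault(g.gene_id, []).append(col)
        gene_strand[g.gene_id] = g.strand

    segments: List[GeneSegment] = []
    for gid, cols in by_gene.items():
        cols = sorted(cols)
        runs: List[List[int]] = [[]]
        for c in cols:
            clean = all(seqs[t][c] in _UNAMBIGUOUS for t in block.taxa)
            if not clean:
                if runs[-1]:
                    runs.append([])
                continue
            if runs[-1] and c != runs[-1][-1] + 1:
                runs.append([])
            runs[-1].append(c)
        idx = 0
        for run in runs:
            if len(run) < min_len:
                continue
            idx += 1
            segments.append(
                _make_segment(block, annotations, gid, idx, run, reference, gene_strand[gid])
            )
    return segments


def _make_segment(
    block: AlignedBlock,
    annotations: AnnotationTable,
    gene_id: str,
    index: int,
    cols: List[int],
    reference: str,
    ref_strand: str,
) -> GeneSegment:
    maps = block.position_maps
    labels = np.array(
        [annotations.codon_position(reference, int(maps[reference][c])) for c in cols]
    )
    # coding direction: codon positions ascend along the alignment for a
    # forward-reading gene; if they descend, flip to coding orientation.
    descending = labels.size >= 2 and (
        (labels[1] - labels[0]) % 3 == 2 if labels[0] != labels[1] else False
    )
    order = cols[::-1] if descending else cols
    seg_seqs: Dict[str, str] = {}
    seg_maps: Dict[str, np.ndarray] = {}
    strands: Dict[str, str] = {}
    for r in block.rows:
        bases = [r.seq[c] for c in order]
        seq = "".join(bases)
        if descending:
            seq = seq.translate(_COMPLEMENT)
        seg_seqs[r.taxon] = seq
        seg_maps[r.taxon] = maps[r.taxon][np.asarray(order)]
        strands[r.taxon] = r.strand
    seg_labels = labels[::-1] if descending else labels
    return GeneSegment(
        # block id is part of the key: a gene crossing a block boundary is
        # processed per block, as separate "genes"
        id=f"{block.id}.{gene_id}.seg{index}",
        seqs=seg_seqs,
        position_maps=seg_maps,
        strands=strands,
        codon_pos=np.asarray(seg_labels, dtype=np.int8),
    )


def trim_to_codons(segment: GeneSegment) -> Optional[GeneSegment]:
    """Trim a segment so it starts at codon position 1 and ends at position 3.

    Returns None (and logs) when no complete codon survives.
    """
    labels = segment.codon_pos
    firsts = np.nonzero(labels == 1)[0]
    lasts = np.nonzero(labels == 3)[0]
    if firsts.size == 0 or lasts.size == 0 or lasts[-1] < firsts[0]:
        logger.debug("segment %s: no complete codon after trimming", segment.id)
        return None
    lo, hi = int(firsts[0]), int(lasts[-1])
    trimmed = segment.take_columns(np.arange(lo, hi + 1))
    if trimmed.length % 3 != 0:
        # interior frame break (should not occur on codon-filtered input)
        logger.warning("segment %s: length %d not a codon multiple", segment.id, trimmed.length)
        return None
    return trimmed


def write_segments(segments: Sequence[GeneSegment], fasta_path, sidecar_path) -> None:
    """Write per-segment FASTA plus a TSV sidecar of per-taxon coordinates."""
    with open(fasta_path, "w") as fa, open(sidecar_path, "w") as tsv:
        tsv.write("segment\ttaxon\tstart\tend\tstrand\tlength\n")
        for seg in segments:
            for t in seg.taxa:
                fa.write(f">{seg.id}|{t}\n{seg.seqs[t]}\n")
                pm = seg.position_maps[t]
                tsv.write(
                    f"{seg.id}\t{t}\t{int(pm.min())}\t{int(pm.max())}\t"
                    f"{seg.strands[t]}\t{seg.length}\n"
                )
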