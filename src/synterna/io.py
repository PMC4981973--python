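"""Readers and writers: MAF, BED6, UCSC chain, tRNAscan-SE tabular, TSV artifacts.

Everything is normalized to 0-based half-open forward-strand coordinates
at parse time — MAF and chain records on the minus strand are flipped via
the source sequence length, and tRNAscan-SE rows (1-based inclusive,
strand encoded by coordinate order) are swapped and shifted.  Keeping a
single convention internally avoids the classic off-by-one class of
synteny errors.
"""

from __future__ import annotations

import csv
import logging
from typing import Iterable, Sequence, TextIO

from .genes import THREE_TO_ONE, TRNAGene
from .graph import OrthologyGraph
from .intervals import Anchor, ChainBlock, GenomicInterval

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# MAF

def parse_maf(stream: TextIO) -> list[list[GenomicInterval]]:
    """Alignment blocks as per-species interval lists.

    Source fields of the form ``species.chrom`` are split on the first
    dot; minus-strand records are converted to forward-strand
    coordinates (start' = srcSize - start - size).
    """
    blocks: list[list[GenomicInterval]] = []
    current: list[GenomicInterval] | None = None
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if line.startswith("a"):
            if current:
                blocks.append(current)
            current = []
        elif line.startswith("s"):
            if current is None:
                raise ValueError(f"line {lineno}: 's' record outside a block")
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"line {lineno}: truncated 's' record")
            src, start_s, size_s, strand, src_size_s = parts[1:6]
            try:
                start, size, src_size = int(start_s), int(size_s), int(src_size_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed coordinate field: {exc}") from None
            if size <= 0 or start < 0 or start + size > src_size:
                raise ValueError(f"line {lineno}: inconsistent start/size/srcSize")
            if strand not in "+-":
                raise ValueError(f"line {lineno}: bad strand {strand!r}")
            species, _, chrom = src.partition(".")
            fstart = start if strand == "+" else src_size - start - size
            current.append(GenomicInterval(species, chrom or "chr", fstart, fstart + size, strand))
    if current:
        blocks.append(current)
    return blocks


# --------------------------------------------------------------------------
# BED

def read_bed(stream: TextIO, species: str) -> list[GenomicInterval]:
    out = []
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        strand = f[5] if len(f) > 5 else "+"
        out.append(GenomicInterval(species, f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(stream: TextIO, intervals: Sequence[GenomicInterval], names: Sequence[str] | None = None) -> None:
    for i, iv in enumerate(intervals):
        name = names[i] if names else f"iv{i}"
        stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# --------------------------------------------------------------------------
# UCSC chain (header lines only; each chain is one aligned interval pair)

def parse_chains(stream: TextIO, species_a: str, species_b: str) -> list[ChainBlock]:
    out = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line.startswith("chain"):
            continue
        f = line.split()
        if len(f) < 12:
            raise ValueError(f"line {lineno}: truncated chain header")
        t_name, t_size, t_strand, t_start, t_end = f[2], int(f[3]), f[4], int(f[5]), int(f[6])
        q_name, q_size, q_strand, q_start, q_end = f[7], int(f[8]), f[9], int(f[10]), int(f[11])
        if t_strand == "-":
            t_start, t_end = t_size - t_end, t_size - t_start
        if q_strand == "-":
            q_start, q_end = q_size - q_end, q_size - q_start
        out.append(
            ChainBlock(
                GenomicInterval(species_a, t_name, t_start, t_end, "+"),
                GenomicInterval(species_b, q_name, q_start, q_end, "+"),
            )
        )
    return out


# --------------------------------------------------------------------------
# tRNAscan-SE tabular output

def parse_trnascan(stream: TextIO, species: str, sequences: dict[str, str] | None = None) -> list[TRNAGene]:
    """Parse the common tRNAscan-SE tabular layout.

    Columns: name, tRNA#, begin, end, isotype, anticodon, intron begin,
    intron end, score[, ...note].  Coordinates are 1-based inclusive with
    minus-strand genes written begin > end.  Unknown isotype tokens keep
    the gene with isoacceptor "Undet".  ``sequences`` optionally attaches
    gene sequences keyed by the generated gene id.
    """
    genes: list[TRNAGene] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        low = line.lower()
        if low.startswith(("sequence", "name", "----")):
            continue  # header block
        f = [x.strip() for x in line.split("\t")]
        if len(f) < 9:
            f = line.split()
        if len(f) < 9:
            raise ValueError(f"line {lineno}: expected >=9 columns")
        chrom, num = f[0], f[1]
        begin, end = int(f[2]), int(f[3])
        isotype, anticodon = f[4], f[5].upper()
        ib, ie = int(f[6]), int(f[7])
        note = " ".join(f[9:]).lower() if len(f) > 9 else ""

        strand = "+" if begin <= end else "-"
        lo, hi = (begin, end) if strand == "+" else (end, begin)
        locus = GenomicInterval(species, chrom, lo - 1, hi, strand)

        introns: list[tuple[int, int]] = []
        if ib and ie:
            if lo <= min(ib, ie) and max(ib, ie) <= hi:  # genomic coordinates
                b, e = sorted((ib, ie))
                if strand == "+":
                    introns.append((b - lo, e - lo + 1))
                else:
                    introns.append((hi - e, hi - b + 1))
            else:  # already relative to the gene's 5' end, 1-based inclusive
                b, e = sorted((ib, ie))
                introns.append((b - 1, e))

        iso = isotype if isotype in THREE_TO_ONE else "Undet"
        if iso == "Undet" and isotype not in ("Undet", "Pseudo", "Sup"):
            log.warning("line %d: unknown isotype token %r; kept as Undet", lineno, isotype)
        gid = f"{species}.{chrom}.trna{num}"
        seq = (sequences or {}).get(gid, "")
        pseudo = "pseudo" in note or isotype == "Pseudo"
        try:
            gene = TRNAGene(id=gid, locus=locus, sequence=seq, anticodon=anticodon,
                            pseudogene=pseudo, introns=introns)
        except Exception:
            gene = TRNAGene(id=gid, locus=locus, sequence=seq, anticodon="NNN",
                            isoacceptor="Undet", pseudogene=pseudo, introns=introns)
        if gene.isoacceptor == "Undet" and iso != "Undet":
            gene.isoacceptor = iso
        genes.append(gene)
    return genes


# --------------------------------------------------------------------------
# TSV artifacts

def write_anchors_tsv(stream: TextIO, anchors: Iterable[Anchor]) -> None:
    w = csv.writer(stream, delimiter="\t", lineterminator="\n")
    w.writerow(["anchor_id", "species", "chrom", "start", "end", "strand"])
    for a in anchors:
        for sp in sorted(a.placements):
            iv = a.placements[sp]
            w.writerow([a.id, sp, iv.chrom, iv.start, iv.end, iv.strand])


def read_anchors_tsv(stream: TextIO) -> list[Anchor]:
    r = csv.reader(stream, delimiter="\t")
    header = next(r)
    assert header[0] == "anchor_id"
    by_id: dict[str, dict[str, GenomicInterval]] = {}
    order: list[str] = []
    for aid, sp, chrom, start, end, strand in r:
        if aid not in by_id:
            by_id[aid] = {}
            order.append(aid)
        by_id[aid][sp] = GenomicInterval(sp, chrom, int(start), int(end), strand)
    return [Anchor(id=aid, placements=by_id[aid]) for aid in order]


def write_graph_tsv(stream: TextIO, G: OrthologyGraph) -> None:
    stream.write(f"#stage\t{G.stage}\n")
    w = csv.writer(stream, delimiter="\t", lineterminator="\n")
    w.writerow(["gene_a", "gene_b"])
    for e in sorted(tuple(sorted(edge)) for edge in G.edges):
        w.writerow(e)


def read_graph_tsv(stream: TextIO, genes: dict[str, TRNAGene]) -> OrthologyGraph:
    first = stream.readline().strip()
    stage = first.split("\t")[1] if first.startswith("#stage") else "candidate"
    G = OrthologyGraph(genes, stage)
    r = csv.reader(stream, delimiter="\t")
    header = next(r, None)
    if header and header[0] != "gene_a":
        G.add_edge(*header)
    for u, v in r:
        G.add_edge(u, v)
    return G


def write_clusters_tsv(stream: TextIO, G: OrthologyGraph) -> None:
    w = csv.writer(stream, delimiter="\t", lineterminator="\n")
    w.writerow(["cluster_id", "gene_id", "species", "order_index"])
    for cid in sorted(G.clusters):
        for sp in sorted(G.cluster_species(cid)):
            for i, gid in enumerate(G.gene_list(cid, sp)):
                w.writerow([cid, gid, sp, i])


def write_genes_tsv(stream: TextIO, genes: Iterable[TRNAGene]) -> None:
    w = csv.writer(stream, delimiter="\t", lineterminator="\n")
    w.writerow(["gene_id", "species", "chrom", "start", "end", "strand",
                "anticodon", "isoacceptor", "pseudogene", "introns", "sequence"])
    for g in sorted(genes, key=lambda g: g.id):
        introns = ";".join(f"{s}-{e}" for s, e in g.introns)
        w.writerow([g.id, g.species, g.locus.chrom, g.locus.start, g.locus.end,
                    g.locus.strand, g.anticodon, g.isoacceptor, int(g.pseudogene),
                    introns, g.sequence])


def read_genes_tsv(stream: TextIO) -> list[TRNAGene]:
    r = csv.reader(stream, delimiter="\t")
    next(r)
    out = []
    for gid, sp, chrom, start, end, strand, ac, iso, pseudo, introns, seq in r:
        ivs = [tuple(map(int, p.split("-"))) for p in introns.split(";") if p]
        out.append(
            TRNAGene(
                id=gid,
                locus=GenomicInterval(sp, chrom, int(start), int(end), strand),
                sequence=seq, anticodon=ac, isoacceptor=iso,
                pseudogene=bool(int(pseudo)), introns=ivs,
            )
        )
    return out
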