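"""I/O for the formats a reference-backbone pangenome pipeline touches.

The central container is :class:`PangenomeGraph`: a sequence graph whose
nodes are genomic segments and whose rank-0 nodes, ordered by their origin
offset, form the linear reference backbone of each chromosome.  Per-sample
graph traversals (:class:`SamplePath`) are stored as BED-like records of
oriented node lists.  Structural-variant records are exported as VCF 4.2
with the conventional shared anchor base.

Internal coordinates are 0-based half-open throughout; conversion to the
1-based anchored VCF convention happens only at emission time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pangraphsv")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GFAParseError(ValueError):
    """Malformed rGFA/GFA1 input."""


class ReferentialIntegrityError(KeyError):
    """A record references a node absent from the graph."""


class ConsistencyError(ValueError):
    """Emitted data disagrees with the reference sequence."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """A graph segment: uppercase DNA plus rGFA provenance.

    ``rank`` 0 marks reference-backbone segments; ``origin`` is the
    (contig, offset) pair from the SN/SO tags when present.
    """

    sequence: str
    rank: int = 0
    origin: tuple[str, int] | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PangenomeGraph:
    """Node/edge sequence graph anchored on a rank-0 reference backbone."""

    nodes: dict[str, Node] = field(default_factory=dict)
    edges: set[tuple[str, str, str, str]] = field(default_factory=set)
    #: chromosome -> ordered rank-0 node ids
    backbone: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._backbone_set: set[str] = {
            n for chain in self.backbone.values() for n in chain
        }

    def rebuild_backbone_index(self) -> None:
        self.__post_init__()

    def is_backbone(self, node_id: str) -> bool:
        return node_id in self._backbone_set

    def backbone_offsets(self, chromosome: str) -> list[int]:
        """Cumulative 0-based start offset of each backbone node (prefix sums)."""
        offsets, pos = [], 0
        for nid in self.backbone[chromosome]:
            offsets.append(pos)
            pos += self.nodes[nid].length
        return offsets

    def reference_length(self, chromosome: str) -> int:
        return sum(self.nodes[n].length for n in self.backbone[chromosome])

    def reference_sequence(self, chromosome: str) -> str:
        return "".join(self.nodes[n].sequence for n in self.backbone[chromosome])

    def total_bases(self) -> int:
        return sum(n.length for n in self.nodes.values())

    def has_edge(self, u: str, uo: str, v: str, vo: str) -> bool:
        """True if the step u(uo) -> v(vo) is realized, in either writing."""
        flip = {"+": "-", "-": "+"}
        return (u, uo, v, vo) in self.edges or (v, flip[vo], u, flip[uo]) in self.edges

    def validate(self) -> None:
        for nid, node in self.nodes.items():
            if node.length != len(node.sequence):
                raise ValueError(f"node {nid}: length/sequence mismatch")
            if (node.rank == 0) != self.is_backbone(nid):
                raise ValueError(f"node {nid}: rank-0 iff on backbone violated")
        for u, _, v, _ in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ReferentialIntegrityError(f"edge endpoint missing: {u}->{v}")
        for chrom in self.backbone:
            off = self.backbone_offsets(chrom)
            if any(b <= a for a, b in zip(off, off[1:])):
                raise ValueError(f"{chrom}: backbone offsets not strictly increasing")


@dataclass
class SamplePath:
    """One assembly's oriented node traversal along a chromosome."""

    sample_id: str
    chromosome: str
    steps: list[tuple[str, str]]
    breed: str | None = None
    #: reference intervals (0-based half-open) the path anchors to
    covered_intervals: list[tuple[int, int]] = field(default_factory=list)

    def node_ids(self) -> list[str]:
        return [n for n, _ in self.steps]


# ---------------------------------------------------------------------------
# rGFA / GFA1
# ---------------------------------------------------------------------------

def _parse_tags(fields: Sequence[str], lineno: int) -> dict[str, str | int]:
    tags: dict[str, str | int] = {}
    for f in fields:
        parts = f.split(":", 2)
        if len(parts) != 3:
            raise GFAParseError(f"line {lineno}: malformed tag {f!r}")
        name, typ, value = parts
        tags[name] = int(value) if typ == "i" else value
    return tags


def read_gfa(path: str | Path, backbone: Mapping[str, Sequence[str]] | None = None
             ) -> PangenomeGraph:
    """Read an rGFA/GFA1 graph.

    rGFA SN/SO/SR tags are required on rank-0 (backbone) segments; a plain
    GFA1 file without tags is accepted when an explicit ``backbone``
    (chromosome -> ordered node ids) is supplied instead.
    """
    nodes: dict[str, Node] = {}
    edges: set[tuple[str, str, str, str]] = set()
    ref_nodes: list[tuple[str, int, str]] = []  # (chrom, offset, node_id)
    file_order: list[str] = []
    any_tagged = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "S":
                if len(fields) < 3:
                    raise GFAParseError(f"line {lineno}: S-line needs id and sequence")
                sid, seq = fields[1], fields[2]
                tags = _parse_tags(fields[3:], lineno)
                if seq == "*":
                    if "LN" not in tags:
                        raise GFAParseError(
                            f"line {lineno}: S-line carries neither sequence nor LN")
                    seq = "N" * int(tags["LN"])
                seq = seq.upper()
                if "LN" in tags and int(tags["LN"]) != len(seq):
                    raise GFAParseError(f"line {lineno}: LN disagrees with sequence")
                if sid in nodes:
                    raise GFAParseError(f"line {lineno}: duplicate node id {sid!r}")
                origin = None
                if "SN" in tags and "SO" in tags:
                    origin = (str(tags["SN"]), int(tags["SO"]))
                if "SR" in tags:
                    any_tagged = True
                    rank = int(tags["SR"])
                else:
                    rank = 1  # untagged GFA1 segment: off-backbone unless listed
                nodes[sid] = Node(sequence=seq, rank=rank, origin=origin)
                file_order.append(sid)
                if rank == 0:
                    if origin is None:
                        raise GFAParseError(
                            f"line {lineno}: rank-0 segment lacks SN/SO origin tags")
                    ref_nodes.append((origin[0], origin[1], sid))
            elif kind == "L":
                if len(fields) < 5:
                    raise GFAParseError(f"line {lineno}: truncated L-line")
                u, uo, v, vo = fields[1:5]
                if uo not in "+-" or vo not in "+-":
                    raise GFAParseError(f"line {lineno}: bad orientation")
                edges.add((u, uo, v, vo))
            # other record types (H, P, ...) are ignored

    if backbone is not None:
        chains = {c: list(ids) for c, ids in backbone.items()}
        for chain in chains.values():
            for nid in chain:
                if nid not in nodes:
                    raise ReferentialIntegrityError(f"backbone node {nid} not in graph")
                nodes[nid].rank = 0
    elif not any_tagged:
        # plain GFA1 with no rGFA tags and no explicit backbone: treat the
        # segments, in file order, as the linear reference chain
        chains = {"ref": file_order}
        for nid in file_order:
            nodes[nid].rank = 0
    else:
        chains = {}
        for chrom, offset, nid in sorted(ref_nodes):
            chains.setdefault(chrom, []).append(nid)
        # overlapping rank-0 offsets are a construction error
        for chrom, chain in chains.items():
            pos = None
            for nid in chain:
                so = nodes[nid].origin[1]  # type: ignore[index]
                if pos is not None and so < pos:
                    raise GFAParseError(
                        f"{chrom}: rank-0 nodes with overlapping offsets at {nid}")
                pos = so + nodes[nid].length

    graph = PangenomeGraph(nodes=nodes, edges=edges, backbone=chains)
    for u, _, v, _ in edges:
        if u not in nodes or v not in nodes:
            raise ReferentialIntegrityError(f"L-line references unknown segment {u}/{v}")
    return graph


def write_gfa(graph: PangenomeGraph, path: str | Path) -> None:
    """Write rGFA; re-reading yields an equal graph (ids, sequences, ranks, edges)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for nid in sorted(graph.nodes):
            node = graph.nodes[nid]
            tags = [f"LN:i:{node.length}"]
            if node.origin is not None:
                tags += [f"SN:Z:{node.origin[0]}", f"SO:i:{node.origin[1]}"]
            tags.append(f"SR:i:{node.rank}")
            fh.write("\t".join(["S", nid, node.sequence, *tags]) + "\n")
        for u, uo, v, vo in sorted(graph.edges):
            fh.write(f"L\t{u}\t{uo}\t{v}\t{vo}\t0M\n")


# ---------------------------------------------------------------------------
# Sample path BED
# ---------------------------------------------------------------------------

def write_path_bed(paths: Iterable[SamplePath], path: str | Path) -> None:
    """One record per (sample, chromosome): chrom, start, end, sample, steps."""
    with open(path, "w") as fh:
        for p in paths:
            if p.covered_intervals:
                start = min(s for s, _ in p.covered_intervals)
                end = max(e for _, e in p.covered_intervals)
            else:
                start, end = 0, 0
            steps = ",".join(f"{n}{o}" for n, o in p.steps)
            fh.write(f"{p.chromosome}\t{start}\t{end}\t{p.sample_id}\t{steps}\n")


def read_path_bed(path: str | Path, graph: PangenomeGraph) -> list[SamplePath]:
    """Read BED-like path records, enforcing referential integrity.

    Every referenced node must exist in ``graph`` and every consecutive
    step pair must correspond to a graph edge.  An empty file is a valid
    empty path set.
    """
    out: list[SamplePath] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise GFAParseError(f"line {lineno}: truncated path record")
            chrom, start, end, sample, steplist = fields[:5]
            steps: list[tuple[str, str]] = []
            if steplist:
                for token in steplist.split(","):
                    nid, orient = token[:-1], token[-1]
                    if orient not in "+-":
                        raise GFAParseError(f"line {lineno}: bad step {token!r}")
                    if nid not in graph.nodes:
                        raise ReferentialIntegrityError(
                            f"line {lineno}: node {nid!r} absent from graph")
                    steps.append((nid, orient))
            for (u, uo), (v, vo) in zip(steps, steps[1:]):
                if not graph.has_edge(u, uo, v, vo):
                    raise ReferentialIntegrityError(
                        f"line {lineno}: step {u}{uo}->{v}{vo} has no graph edge")
            out.append(SamplePath(
                sample_id=sample, chromosome=chrom, steps=steps,
                covered_intervals=[(int(start), int(end))]))
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        records[name] = "".join(chunks)
    return records


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant class (INS/DEL/SUB)">
##INFO=<ID=SVLEN,Number=A,Type=Integer,Description="Alt minus ref allele length">
##INFO=<ID=ALLELICITY,Number=1,Type=String,Description="biallelic or multiallelic">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(svs: Sequence, reference: Mapping[str, str] | str | Path,
              path: str | Path, samples: Sequence[str] | None = None) -> None:
    """Write classified SV records as VCF 4.2.

    Records are duck-typed: each needs ``chromosome``, ``start`` (0-based
    start of the reference allele), ``sv_id``, ``ref_seq``, ``alt_seqs``,
    ``sv_type``, ``allelicity`` and ``genotypes`` (sample -> allele index,
    0 = reference, ``None`` = missing).  POS is the base before the event
    and REF/ALT share that anchor base, per VCF convention.
    """
    if not isinstance(reference, Mapping):
        reference = read_fasta(reference)
    if samples is None:
        seen: dict[str, None] = {}
        for sv in svs:
            for s in sv.genotypes:
                seen.setdefault(s)
        samples = sorted(seen)

    lines = [_VCF_HEADER]
    for chrom, seq in reference.items():
        lines.append(f"##contig=<ID={chrom},length={len(seq)}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")

    for sv in sorted(svs, key=lambda r: (r.chromosome, r.start)):
        chrom_seq = reference[sv.chromosome]
        if sv.start < 1:
            raise ConsistencyError(f"{sv.sv_id}: no anchor base before offset 0")
        anchor = chrom_seq[sv.start - 1]
        if chrom_seq[sv.start:sv.start + len(sv.ref_seq)] != sv.ref_seq:
            raise ConsistencyError(
                f"{sv.sv_id}: REF allele disagrees with reference at "
                f"{sv.chromosome}:{sv.start}")
        ref = anchor + sv.ref_seq
        alts = [anchor + a for a in sv.alt_seqs]
        svlen = ",".join(str(len(a) - len(ref)) for a in alts)
        info = f"SVTYPE={sv.sv_type};SVLEN={svlen};ALLELICITY={sv.allelicity}"
        gts = []
        for s in samples:
            a = sv.genotypes.get(s)
            gts.append("./." if a is None else str(a))
        lines.append("\t".join([
            sv.chromosome, str(sv.start), sv.sv_id, ref, ",".join(alts),
            ".", "PASS", info, "GT", *gts]) + "\n")

    with open(path, "w") as fh:
        fh.writelines(lines)


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a (possibly SV) VCF into a tidy frame, one row per record.

    Columns: chrom, pos (1-based), id, ref, alts (tuple), svtype, svlen
    (tuple), allelicity, plus one genotype column per sample holding the
    allele index (NaN = missing).
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        sample_names = list(vf.header.samples)
        for rec in vf:
            row = {
                "chrom": rec.chrom, "pos": rec.pos, "id": rec.id,
                "ref": rec.ref, "alts": tuple(rec.alts or ()),
                "svtype": rec.info.get("SVTYPE"),
                "svlen": tuple(np.atleast_1d(rec.info.get("SVLEN", ()))),
                "allelicity": rec.info.get("ALLELICITY"),
            }
            for s in sample_names:
                alleles = rec.samples[s]["GT"]
                allele = alleles[0] if alleles else None
                row[s] = np.nan if allele is None else float(allele)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tabular inputs: genotypes, phenotypes, breed metadata
# ---------------------------------------------------------------------------

def _dosage_from_gt(gt: tuple) -> float:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return np.nan
    return float(sum(1 for a in alleles if a > 0))


def read_tables(genotypes: str | Path, phenotypes: str | Path,
                metadata: str | Path
                ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Read the GWAS inputs.

    ``genotypes``: TSV with sample rows and marker columns (dosages coded
    0/1/2, NA for missing), or a VCF whose GT fields are converted to
    dosages.  ``phenotypes``: TSV with columns animal, trait, dyd, weight.
    ``metadata``: TSV with columns sample, breed.

    Samples present in the phenotype table but absent from the genotypes
    are excluded with a logged warning.
    """
    genotypes = Path(genotypes)
    if genotypes.suffix == ".vcf" or genotypes.name.endswith(".vcf.gz"):
        import pysam

        with pysam.VariantFile(str(genotypes)) as vf:
            sample_names = list(vf.header.samples)
            data: dict[str, list[float]] = {}
            for rec in vf:
                mid = rec.id or f"{rec.chrom}:{rec.pos}"
                data[mid] = [_dosage_from_gt(rec.samples[s]["GT"]) for s in sample_names]
        dosages = pd.DataFrame(data, index=sample_names)
    else:
        dosages = pd.read_csv(genotypes, sep="\t", index_col=0, na_values=["NA", "."])
        dosages = dosages.astype(float)

    pheno = pd.read_csv(phenotypes, sep="\t")
    pheno.columns = [c.lower() for c in pheno.columns]
    required = {"animal", "trait", "dyd", "weight"}
    if not required.issubset(pheno.columns):
        raise ValueError(f"phenotype table must carry columns {sorted(required)}")
    missing = sorted(set(pheno["animal"]) - set(dosages.index))
    if missing:
        logger.warning("excluding %d phenotyped animals without genotypes: %s",
                       len(missing), ", ".join(missing[:5]))
        pheno = pheno[~pheno["animal"].isin(missing)].reset_index(drop=True)

    meta = pd.read_csv(metadata, sep="\t")
    meta.columns = [c.lower() for c in meta.columns]
    breed_map = dict(zip(meta["sample"], meta["breed"]))
    return dosages, pheno, breed_map


def write_tables(dosages: pd.DataFrame, pheno: pd.DataFrame,
                 breed_map: Mapping[str, str], genotypes: str | Path,
                 phenotypes: str | Path, metadata: str | Path) -> None:
    dosages.to_csv(genotypes, sep="\t", na_rep="NA")
    pheno.to_csv(phenotypes, sep="\t", index=False)
    pd.DataFrame({"sample": list(breed_map), "breed": list(breed_map.values())}
                 ).to_csv(metadata, sep="\t", index=False)
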