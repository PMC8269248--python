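"""Readers and writers for every on-disk representation.

Formats: FASTA (genome), GFF3 (CDS features; 1-based closed, converted on
read), TSV (TSS table, per-feature attribute tables), per-strand BedGraph
(0-based half-open; track lines ignored; floats accepted) and BED6/TSV
outputs. All in-memory coordinates are 0-based half-open.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    FormatError,
    GeneModel,
    Genome,
    StemLoop,
    Tep,
    Track,
    Tss,
    Tu,
    Tuc,
)

# ---------------------------------------------------------------------------
# coordinate conventions


def gff_to_internal(start: int, end: int) -> Tuple[int, int]:
    """GFF3 1-based closed interval -> 0-based half-open."""
    if start < 1 or end < start:
        raise FormatError(f"invalid GFF interval {start}..{end}")
    return start - 1, end


def internal_to_gff(start: int, end: int) -> Tuple[int, int]:
    """0-based half-open interval -> GFF3 1-based closed."""
    if start < 0 or end <= start:
        raise FormatError(f"invalid half-open interval [{start}, {end})")
    return start + 1, end


# ---------------------------------------------------------------------------
# genome / annotation / TSS


def read_genome(path: str) -> Genome:
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(contigs)


def write_genome(genome: Genome, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_genes(gff_path: str, attrs_path: Optional[str] = None) -> List[GeneModel]:
    """Load CDS features from GFF3; optional TSV adds COG/smBGC categories."""
    db = gffutils.create_db(
        gff_path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    extra: Dict[str, Dict[str, str]] = {}
    if attrs_path is not None:
        tab = pd.read_csv(attrs_path, sep="\t", dtype=str).fillna("")
        for _, row in tab.iterrows():
            extra[row["gene_id"]] = dict(row)

    genes: List[GeneModel] = []
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        start, end = gff_to_internal(feat.start, feat.end)
        cog = (feat.attributes.get("cog") or [None])[0]
        smbgc = (feat.attributes.get("smbgc") or [None])[0]
        if gene_id in extra:
            cog = extra[gene_id].get("cog") or cog
            smbgc = extra[gene_id].get("smbgc") or smbgc
        genes.append(
            GeneModel(gene_id, feat.seqid, feat.strand, start, end,
                      cog=cog or None, smbgc=smbgc or None)
        )
    return genes


def write_genes_gff3(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = internal_to_gff(g.cds_start, g.cds_end)
            attrs = [f"ID={g.gene_id}"]
            if g.cog:
                attrs.append(f"cog={g.cog}")
            if g.smbgc:
                attrs.append(f"smbgc={g.smbgc}")
            fh.write(
                f"{g.contig}\ttermscape\tCDS\t{start}\t{end}\t.\t{g.strand}\t0\t"
                + ";".join(attrs) + "\n"
            )


TSS_COLUMNS = ["contig", "position", "strand", "category", "gene_id"]


def read_tss_table(path: str) -> List[Tss]:
    tab = pd.read_csv(path, sep="\t", dtype={"contig": str, "gene_id": str})
    missing = set(TSS_COLUMNS[:4]) - set(tab.columns)
    if missing:
        raise FormatError(f"TSS table {path} lacks columns: {sorted(missing)}")
    out = []
    for _, row in tab.iterrows():
        if row["strand"] not in "+-":
            raise FormatError(f"TSS table {path}: unknown strand {row['strand']!r}")
        gene = row.get("gene_id")
        if pd.isna(gene):
            gene = None
        out.append(Tss(row["contig"], int(row["position"]), row["strand"],
                       str(row["category"]), gene))
    return out


def write_tss_table(tss_set: Sequence[Tss], path: str) -> None:
    pd.DataFrame(
        [
            {"contig": t.contig, "position": t.position, "strand": t.strand,
             "category": t.category, "gene_id": t.gene_id or ""}
            for t in tss_set
        ],
        columns=TSS_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BedGraph tracks


def _fill_bedgraph(path: str, arr_by_contig, lengths) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 BedGraph fields")
            contig, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if contig not in lengths:
                raise FormatError(f"{path}:{lineno}: unknown contig {contig!r}")
            if start < 0 or end > lengths[contig] or end <= start:
                raise FormatError(
                    f"{path}:{lineno}: interval {start}..{end} outside contig "
                    f"{contig} (length {lengths[contig]})"
                )
            arr_by_contig[contig][start:end] += value


def read_track(lengths: Dict[str, int], plus_path: str, minus_path: str) -> Track:
    """Read a per-strand BedGraph pair into a dense track (gaps filled with 0)."""
    track = Track(lengths)
    _fill_bedgraph(plus_path, {c: track[(c, "+")] for c in lengths}, lengths)
    _fill_bedgraph(minus_path, {c: track[(c, "-")] for c in lengths}, lengths)
    return track


def write_track(track: Track, plus_path: str, minus_path: str) -> None:
    """Write a dense track as a per-strand BedGraph pair (zero runs omitted)."""
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w") as fh:
            for contig in track.lengths:
                arr = track[(contig, strand)]
                start = None
                value = None
                for i, v in enumerate(arr):
                    if v != 0 and v == value:
                        continue
                    if start is not None and value != 0:
                        fh.write(f"{contig}\t{start}\t{i}\t{value:g}\n")
                    start, value = i, v
                if start is not None and value != 0:
                    fh.write(f"{contig}\t{start}\t{len(arr)}\t{value:g}\n")


# ---------------------------------------------------------------------------
# feature tables (mirrors the per-feature supplementary-sheet layout)

TEP_TSV_COLUMNS = [
    "contig", "position", "strand", "count", "category", "gene_id", "class",
    "delta_g", "stem_length", "loop_length", "stem_end_offset", "u_count",
    "readthrough", "zscore", "terminality",
]


def _fmt(value) -> str:
    return "" if value is None else str(value)


def write_features(teps: Sequence[Tep], tus: Sequence[Tu], tucs: Sequence[Tuc],
                   out_dir: str) -> Dict[str, str]:
    """Write TEP/TU/TUC BED and TSV files; returns the path set."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, name) for name in (
        "teps.bed", "teps.tsv", "tus.bed", "tus.tsv", "tucs.bed", "tucs.tsv")}

    with open(paths["teps.bed"], "w") as fh:
        fh.write("# BED6: transcript 3'-end positions; name = category:class\n")
        for t in teps:
            name = f"{_fmt(t.category) or 'NA'}:{_fmt(t.tep_class) or 'NA'}"
            fh.write(f"{t.contig}\t{t.position}\t{t.position + 1}\t{name}\t"
                     f"{t.count:g}\t{t.strand}\n")
    rows = []
    for t in teps:
        rows.append({
            "contig": t.contig, "position": t.position, "strand": t.strand,
            "count": t.count, "category": _fmt(t.category),
            "gene_id": _fmt(t.gene_id), "class": _fmt(t.tep_class),
            "delta_g": _fmt(t.delta_g),
            "stem_length": _fmt(t.stem.stem_length if t.stem else None),
            "loop_length": _fmt(t.stem.loop_length if t.stem else None),
            "stem_end_offset": _fmt(t.stem.stem_end_offset if t.stem else None),
            "u_count": _fmt(t.u_count), "readthrough": _fmt(t.readthrough),
            "zscore": _fmt(t.zscore), "terminality": _fmt(t.terminality),
        })
    pd.DataFrame(rows, columns=TEP_TSV_COLUMNS).to_csv(
        paths["teps.tsv"], sep="\t", index=False)

    with open(paths["tus.bed"], "w") as fh:
        fh.write("# BED6: transcription units (TSS..TEP span)\n")
        for i, tu in enumerate(tus):
            fh.write(f"{tu.contig}\t{tu.start}\t{tu.end}\tTU{i}:{_fmt(tu.category)}\t"
                     f"0\t{tu.strand}\n")
    pd.DataFrame(
        [{"contig": tu.contig, "start": tu.start, "end": tu.end,
          "length": tu.length, "strand": tu.strand,
          "tss_position": tu.tss.position, "tss_category": tu.tss.category,
          "tep_position": tu.tep.position, "tep_category": _fmt(tu.tep.category),
          "category": _fmt(tu.category), "terminality": _fmt(tu.terminality),
          "gene_ids": ",".join(tu.gene_ids),
          "passing_phases": ",".join(tu.passing_phases)}
         for tu in tus]
    ).to_csv(paths["tus.tsv"], sep="\t", index=False)

    with open(paths["tucs.bed"], "w") as fh:
        fh.write("# BED6: transcription unit clusters\n")
        for i, tuc in enumerate(tucs):
            fh.write(f"{tuc.contig}\t{tuc.start}\t{tuc.end}\tTUC{i}\t"
                     f"{len(tuc.members)}\t{tuc.strand}\n")
    pd.DataFrame(
        [{"contig": tuc.contig, "start": tuc.start, "end": tuc.end,
          "strand": tuc.strand, "n_members": len(tuc.members),
          "gene_ids": ",".join(tuc.gene_ids)}
         for tuc in tucs]
    ).to_csv(paths["tucs.tsv"], sep="\t", index=False)
    return paths


def read_teps_tsv(path: str) -> List[Tep]:
    tab = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    teps = []
    for _, row in tab.iterrows():
        stem = None
        if row["stem_length"]:
            stem = StemLoop(int(row["stem_length"]), int(row["loop_length"]),
                            int(row["stem_end_offset"]), dot_bracket="")
        teps.append(Tep(
            contig=row["contig"], position=int(row["position"]),
            strand=row["strand"], count=float(row["count"]),
            category=row["category"] or None, gene_id=row["gene_id"] or None,
            tep_class=row["class"] or None,
            delta_g=float(row["delta_g"]) if row["delta_g"] else None,
            stem=stem, u_count=int(row["u_count"]) if row["u_count"] else None,
            readthrough=float(row["readthrough"]) if row["readthrough"] else None,
            zscore=float(row["zscore"]) if row["zscore"] else None,
            terminality=row["terminality"] or None,
        ))
    return teps


# ---------------------------------------------------------------------------
# aligned FASTA (consumed by the Poisson-distance analysis)


def read_alignment(path: str) -> Dict[str, str]:
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    if not records:
        raise FormatError(f"no aligned FASTA records in {path}")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise FormatError(f"aligned FASTA {path}: unequal sequence lengths")
    return records


def read_inputs(genome_path: str, annotation_path: str, tss_path: str,
                termseq_paths: Sequence[Tuple[str, str]],
                rnaseq_paths: Dict[str, Tuple[str, str]],
                attrs_path: Optional[str] = None):
    """Load the full input set for a pipeline run.

    ``termseq_paths`` is a list of (plus, minus) BedGraph pairs, one per
    replicate; ``rnaseq_paths`` maps growth-phase name -> (plus, minus) pair.
    """
    genome = read_genome(genome_path)
    genes = read_genes(annotation_path, attrs_path)
    tss_set = read_tss_table(tss_path)
    lengths = genome.lengths
    termseq = [read_track(lengths, p, m) for p, m in termseq_paths]
    rnaseq = {phase: read_track(lengths, p, m)
              for phase, (p, m) in rnaseq_paths.items()}
    return genome, genes, tss_set, termseq, rnaseq
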