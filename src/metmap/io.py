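"""File format adapters: FASTA, SAM/BAM, BED, TSV outputs."""

from __future__ import annotations

import sys
from pathlib import Path

from .counts import AlignmentRecord, revcomp
from .genome import CGSite, GGIsland
from .sumi import SUMI

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_alignments",
    "read_bed_intervals",
    "write_bed_sites",
    "write_bed_islands",
    "write_sumi_bed",
    "write_sumi_tsv",
    "write_site_scores",
    "write_alignments_sam",
]


def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines) into {name: sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignments(path) -> list[AlignmentRecord]:
    """Alignments from SAM/BAM (via pysam) or BED6.

    For SAM/BAM the sequenced 5' prefix is recovered from the stored
    sequence (reverse-complemented for reverse-strand alignments). BED
    records may carry the prefix in the name column; otherwise they are
    treated as prefix-unknown and will be dropped by read filtering.
    """
    path = Path(path)
    if path.suffix.lower() in {".sam", ".bam", ".cram"}:
        return _read_sam(path)
    return _read_bed_alignments(path)


def _read_sam(path: Path) -> list[AlignmentRecord]:
    import pysam

    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    out = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            seq = rec.query_sequence or ""
            if rec.is_reverse:
                prefix = revcomp(seq[-3:]) if len(seq) >= 3 else None
            else:
                prefix = seq[:3] if len(seq) >= 3 else None
            out.append(
                AlignmentRecord(
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    prefix,
                )
            )
    return out


def _read_bed_alignments(path: Path) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "+"
            prefix = name if len(name) == 3 and set(name) <= set("ACGT") else None
            out.append(AlignmentRecord(chrom, start, end, strand, prefix))
    return out


def read_bed_intervals(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    for ivs in out.values():
        ivs.sort()
    return out


def write_bed_sites(path, sites: list[CGSite]) -> None:
    with open(path, "w") as fh:
        for s in sites:
            name = "CCGG" if s.is_hpaii else "CG"
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 2}\t{name}\t0\t+\n")


def write_bed_islands(path, islands: list[GGIsland]) -> None:
    with open(path, "w") as fh:
        for k, isl in enumerate(islands):
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\tCpG_{k}\t"
                f"{int(round(1000 * min(isl.obs_exp_cg, 1.0)))}\t+\n"
            )


def write_sumi_bed(path, sumis: list[SUMI]) -> None:
    with open(path, "w") as fh:
        for k, s in enumerate(sumis):
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\tSUMI_{k}\t"
                f"{int(round(1000 * s.score))}\t+\n"
            )


def write_sumi_tsv(path, sumis: list[SUMI], header_lines: list[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "chrom\tstart\tend\tscore\tprovenance\tn_sites\tn_supported_fragments\n"
        )
        for s in sumis:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.score:.6f}\t{s.provenance}\t"
                f"{s.n_sites}\t{s.n_supported_fragments}\n"
            )


def write_site_scores(path, posteriors, header_lines: list[str] = ()) -> None:
    """BED-like TSV of per-site posteriors (HpaII sites in scope)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("chrom\tstart\tend\tmetmap_score\tp_U\tp_P\tp_M\tp_island\n")
        for r in posteriors:
            fh.write(
                f"{r.site.chrom}\t{r.site.pos}\t{r.site.pos + 2}\t"
                f"{r.score:.6f}\t{r.p_u:.6f}\t{r.p_p:.6f}\t{r.p_m:.6f}\t"
                f"{r.p_island:.6f}\n"
            )


def write_alignments_sam(path, alignments, chrom_lengths: dict[str, int]) -> None:
    """Minimal SAM with fixed-quality placeholder sequences (the positions
    and strands carry all the information the pipeline consumes)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for k, rec in enumerate(alignments):
            flag = 16 if rec.strand == "-" else 0
            seq = (rec.prefix or "NNN") + "N" * max(0, rec.end - rec.start - 3)
            if rec.strand == "-":
                seq = revcomp(seq)
            fh.write(
                f"read{k}\t{flag}\t{rec.chrom}\t{rec.start + 1}\t60\t"
                f"{rec.end - rec.start}M\t*\t0\t0\t{seq}\t*\n"
            )
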