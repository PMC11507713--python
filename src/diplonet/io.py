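"""File formats and run manifests.

Text dialects only: FASTA (indexed reads via pyfaidx), minimal VCF with
unphased GT genotypes (reads via pysam, restricted to biallelic SNPs),
4-column bedGraph with one file per strand, BED6 peaks, and TSV tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vcf_snps",
    "write_vcf",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
    "read_tsv",
    "write_tsv",
    "RunManifest",
    "file_checksum",
    "write_panel",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    with pyfaidx.Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_vcf_snps(path: str | Path) -> tuple[list[str], pd.DataFrame, np.ndarray]:
    """Biallelic SNPs from a VCF.

    Returns (sample names, SNP table with 0-based positions, dosage matrix
    of shape (n_samples, n_snps)). Non-SNP and multi-allelic records are
    skipped with a logged count.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, dosage_cols = [], []
    n_skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        rows.append({"chrom": rec.chrom, "pos": rec.pos - 1, "ref": rec.ref,
                     "alt": alts[0], "snp_id": rec.id or f"{rec.chrom}:{rec.pos}"})
        dosage_cols.append([sum(1 for a in rec.samples[s]["GT"] if a == 1)
                            for s in samples])
    vf.close()
    if n_skipped:
        logger.info("skipped %d non-SNP/multi-allelic records", n_skipped)
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dosages = np.array(dosage_cols, dtype=np.int8).T if dosage_cols else \
        np.zeros((len(samples), 0), np.int8)
    return samples, snps, dosages


def write_vcf(path: str | Path, snps: pd.DataFrame, genotypes: np.ndarray,
              samples: list[str], chrom_lengths: dict[str, int]) -> None:
    """Minimal unphased-GT VCF ('0/0', '0/1', '1/1')."""
    gt_repr = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = snps.sort_values(["chrom", "pos"]).index
        for i in order:
            row = snps.loc[i]
            gts = "\t".join(gt_repr[int(genotypes[s, snps.index.get_loc(i)])]
                            for s in range(len(samples)))
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_bedgraph(path: str | Path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Dense per-base coverage from a 4-column bedGraph."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str, "start": np.int64, "end": np.int64,
                                "value": np.float64})
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed bedGraph: {exc}") from exc
    out = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_lengths.items()}
    for line, row in enumerate(df.itertuples(), start=1):
        if row.chrom not in out:
            raise ValueError(f"{path}:{line}: unknown chromosome {row.chrom!r}")
        if not 0 <= row.start < row.end <= chrom_lengths[row.chrom]:
            raise ValueError(f"{path}:{line}: invalid interval [{row.start}, {row.end})")
        out[row.chrom][row.start:row.end] += row.value
    return out


def write_bedgraph(path: str | Path, coverage: dict[str, np.ndarray]) -> None:
    """Run-length encoded bedGraph of nonzero coverage."""
    with open(path, "w") as fh:
        for chrom in coverage:
            values = np.asarray(coverage[chrom])
            if values.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [values.size]])
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    v_out = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{chrom}\t{s}\t{e}\t{v_out}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "name", "score", "strand"],
                         dtype={"chrom": str, "start": np.int64, "end": np.int64})
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed BED: {exc}") from exc
    for line, row in enumerate(df.itertuples(), start=1):
        if row.start < 0 or row.end <= row.start:
            raise ValueError(f"{path}:{line}: invalid interval [{row.start}, {row.end})")
        if row.strand not in ("+", "-", "."):
            raise ValueError(f"{path}:{line}: invalid strand {row.strand!r}")
    return df


def write_bed(path: str | Path, intervals: pd.DataFrame) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seeds: dict[str, int]
    input_checksums: dict[str, str] = field(default_factory=dict)
    fold_assignment: dict[str, int] = field(default_factory=dict)
    version: str = "0.1.0"

    @classmethod
    def create(cls, command: str, config: dict, seeds: dict[str, int],
               inputs: dict[str, str | Path] | None = None,
               fold_assignment: dict[str, int] | None = None) -> "RunManifest":
        cfg_hash = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
        checksums = {k: file_checksum(v) for k, v in (inputs or {}).items()}
        return cls(command=command, config_hash=cfg_hash, seeds=seeds,
                   input_checksums=checksums, fold_assignment=fold_assignment or {})

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def write_panel(panel, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated panel as FASTA + VCF + per-library bedGraphs +
    BED6 peaks + truth TSV. Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["reference"] = outdir / "reference.fa"
    write_fasta(paths["reference"], panel.reference)
    paths["vcf"] = outdir / "genotypes.vcf"
    write_vcf(paths["vcf"], panel.snps, panel.genotypes, panel.libraries,
              panel.chrom_lengths)
    for lib in panel.libraries:
        for si, strand in enumerate(["plus", "minus"]):
            p = outdir / f"coverage_{lib}_{strand}.bedGraph"
            write_bedgraph(p, {c: panel.coverage[lib][c][si] for c in panel.reference})
            paths[f"coverage_{lib}_{strand}"] = p
    paths["peaks"] = outdir / "peaks.bed"
    write_bed(paths["peaks"], panel.peaks)
    paths["truth"] = outdir / "truth.tsv"
    write_tsv(paths["truth"], panel.truth)
    return paths
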