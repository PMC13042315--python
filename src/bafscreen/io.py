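"""Readers and writers for the package's on-disk formats.

VCF is restricted to a minimal single-sample dialect: biallelic records with
FORMAT ``DP:AD`` (AD holds ref,alt read counts). Multiallelic records are
skipped with a count returned alongside. FASTA is 60-column wrapped; FASTQ is
plain or gzipped 4-line records; trees travel as newick with bootstrap
supports as internal node labels.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import ReferenceGenome, SiteRecord

logger = logging.getLogger("bafscreen")

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_newick",
    "read_newick",
    "records_to_frame",
    "frame_to_records",
    "write_records_tsv",
    "read_records_tsv",
    "child_seeds",
    "config_hash",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(
    records: list[SiteRecord],
    path,
    contigs: dict[str, int] | None = None,
    sample: str = "SAMPLE",
) -> None:
    """Write site records as minimal VCF 4.2 with DP and AD per sample."""
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bafscreen\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Read depth per allele">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for r in sorted(records, key=lambda x: (x.chrom, x.pos)):
            ad = f"{r.depth - r.alt_depth},{r.alt_depth}"
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"DP:AD\t{r.depth}:{ad}\n"
            )


def read_vcf(path, min_depth: int = 0) -> list[SiteRecord]:
    """Read the DP:AD dialect back (first sample; first alt allele only).

    Multiallelic records are skipped with a logged count. A missing AD (or
    DP) FORMAT key raises a ValueError naming the key.
    """
    import pysam

    records: list[SiteRecord] = []
    skipped_multi = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None:
                continue
            if len(rec.alts) > 1:
                skipped_multi += 1
                continue
            sample = rec.samples[0]
            if "AD" not in sample or sample["AD"] is None or sample["AD"][0] is None:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} lacks the AD FORMAT key"
                )
            if "DP" not in sample or sample["DP"] is None:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} lacks the DP FORMAT key"
                )
            ad = sample["AD"]
            depth = int(sample["DP"])
            alt_depth = int(ad[1]) if len(ad) > 1 else 0
            if depth < min_depth:
                continue
            records.append(
                SiteRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    depth=depth,
                    alt_depth=alt_depth,
                )
            )
    if skipped_multi:
        logger.info("skipped %d multiallelic records", skipped_multi)
    return records


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path) -> None:
    """60-column wrapped FASTA."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def reference_from_fasta(path) -> ReferenceGenome:
    return ReferenceGenome.from_strings(list(read_fasta(path).items()))


def _open_auto(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(reads: list[tuple[str, str, str]], path) -> None:
    """Write (name, sequence, quality-string) triples; gzip by extension."""
    with _open_auto(path, "wt") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read plain or gzipped FASTQ transparently."""
    out = []
    with _open_auto(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            out.append((rec.id, str(rec.seq), qual))
    return out


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# tabular site records
# ---------------------------------------------------------------------------


def records_to_frame(records: list[SiteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            "depth": [r.depth for r in records],
            "alt_depth": [r.alt_depth for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[SiteRecord]:
    return [
        SiteRecord(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            depth=int(r.depth),
            alt_depth=int(r.alt_depth),
        )
        for r in df.itertuples()
    ]


def write_records_tsv(records: list[SiteRecord], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        records_to_frame(records).to_csv(fh, sep="\t", index=False)


def read_records_tsv(path) -> list[SiteRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return frame_to_records(df)


# ---------------------------------------------------------------------------
# seeding and config identity
# ---------------------------------------------------------------------------


def child_seeds(seed: int, n: int) -> list[int]:
    """Expand a global seed into n stable per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
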