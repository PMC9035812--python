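"""Readers and writers for the plain-text formats the pipeline exchanges:
FASTA genomes, BED SSR loci, VCF genotype matrices (GT:AD:DP), and TSV
tables (depths, phenotypes, metadata)."""

from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotype_qc import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix
from .ssr_scan import SSRLocus


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_bed(loci: Iterable[SSRLocus], path: str) -> None:
    """BED6-ish output: chrom, start, end, motif_class, repeat_count, '+'."""
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t"
                f"{locus.motif_class}\t{locus.repeat_count}\t+\n"
            )


def read_bed(path: str) -> List[SSRLocus]:
    out: List[SSRLocus] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score = line.split("\t")[:5]
            out.append(
                SSRLocus(
                    chrom=chrom, start=int(start), end=int(end),
                    motif_class=name, repeat_count=int(score), motif=name,
                )
            )
    return out


_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_GT_CODES = {
    "0/0": HOM_REF, "0|0": HOM_REF,
    "0/1": HET, "1/0": HET, "0|1": HET, "1|0": HET,
    "1/1": HOM_ALT, "1|1": HOM_ALT,
    "./.": MISSING, ".|.": MISSING, ".": MISSING,
}


def write_vcf(m: GenotypeMatrix, path: str,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Minimal VCF 4.2 writer with GT:AD:DP genotype fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=migkit\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(m.chrom.tolist()):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.samples) + "\n")
        for i in range(m.n_sites):
            qual = m.qual[i]
            qual_str = "." if not np.isfinite(qual) else f"{qual:g}"
            cells = []
            for j in range(m.n_samples):
                gt = _GT_STRINGS[int(m.gt[i, j])]
                ad = f"{m.ad[i, j, 0]},{m.ad[i, j, 1]}"
                cells.append(f"{gt}:{ad}:{m.dp[i, j]}")
            fh.write(
                f"{m.chrom[i]}\t{m.pos[i]}\t.\t{m.ref[i]}\t{m.alt[i]}\t"
                f"{qual_str}\t.\t.\tGT:AD:DP\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read an uncompressed VCF with GT (and optional AD/DP) fields, tolerant
    of any FORMAT key ordering."""
    chroms: List[str] = []
    poss: List[int] = []
    refs: List[str] = []
    alts: List[str] = []
    quals: List[float] = []
    gts: List[List[int]] = []
    dps: List[List[int]] = []
    ads: List[List[Tuple[int, int]]] = []
    samples: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, _, ref, alt, qual, _, _, fmt = parts[:9]
            keys = fmt.split(":")
            row_gt: List[int] = []
            row_dp: List[int] = []
            row_ad: List[Tuple[int, int]] = []
            for cell in parts[9:]:
                vals = dict(zip(keys, cell.split(":")))
                gt = _GT_CODES.get(vals.get("GT", "."), MISSING)
                ad_field = vals.get("AD", ".")
                if ad_field in (".", ""):
                    ad = (0, 0)
                else:
                    ad_parts = [0 if x == "." else int(x) for x in ad_field.split(",")]
                    ad = (ad_parts[0], ad_parts[1] if len(ad_parts) > 1 else 0)
                dp_field = vals.get("DP", ".")
                dp = sum(ad) if dp_field in (".", "") else int(dp_field)
                row_gt.append(gt)
                row_dp.append(dp)
                row_ad.append(ad)
            chroms.append(chrom)
            poss.append(int(pos))
            refs.append(ref)
            alts.append(alt)
            quals.append(float("nan") if qual == "." else float(qual))
            gts.append(row_gt)
            dps.append(row_dp)
            ads.append(row_ad)
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        qual=np.array(quals, dtype=float),
        samples=samples,
        gt=np.array(gts, dtype=np.int8),
        dp=np.array(dps, dtype=np.int32),
        ad=np.array(ads, dtype=np.int32),
    )
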