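"""Readers and writers for the pipeline's on-disk formats.

Tables travel as TSV; DHS intervals additionally as BED6 + extra columns
(0-based, half-open); variants as a minimal VCF 4.2 with annotations as
INFO key=value pairs (positions 1-based); position weight matrices in
JASPAR text format (parsed with Biopython).
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs

from .dhs_mapping import DhsRegion, SnvRecord
from .errors import InvalidInputError


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(regions: list[DhsRegion], path) -> None:
    """BED6 + gene, r, p_perm extra columns. Score column carries 1000*|r|
    rounded, the conventional 0-1000 scaling."""
    with open(path, "w") as fh:
        for reg in regions:
            score = 0 if reg.r is None else int(round(1000 * abs(reg.r)))
            strand = "."
            r = "." if reg.r is None else f"{reg.r:.6g}"
            p = "." if reg.p_perm is None else f"{reg.p_perm:.6g}"
            name = f"{reg.gene}_dhs"
            fh.write(f"{reg.chrom}\t{reg.start}\t{reg.end}\t{name}\t"
                     f"{score}\t{strand}\t{reg.gene}\t{r}\t{p}\n")


def read_bed(path) -> list[DhsRegion]:
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise InvalidInputError(f"malformed BED line: {line!r}")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        gene = parts[6] if len(parts) > 6 else (parts[3] if len(parts) > 3
                                                else "")
        r = None
        p = None
        if len(parts) > 8:
            r = None if parts[7] == "." else float(parts[7])
            p = None if parts[8] == "." else float(parts[8])
        regions.append(DhsRegion(chrom=chrom, start=start, end=end,
                                 gene=gene, r=r, p_perm=p))
    return regions


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Target gene">
##INFO=<ID=ANN,Number=1,Type=String,Description="JSON-encoded annotations">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(snvs: pd.DataFrame, path) -> None:
    """Minimal VCF; nested annotation columns are packed into INFO/ANN."""
    info_cols = [c for c in snvs.columns
                 if c not in ("rsid", "chrom", "pos", "ref", "alt", "gene")]
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for _, row in snvs.iterrows():
            ann = {c: row[c] for c in info_cols}
            blob = json.dumps(ann, default=str).replace(";", ",")
            info = f"GENE={row.gene};ANN={blob}" if "gene" in snvs.columns \
                else f"ANN={blob}"
            fh.write(f"{row.chrom}\t{row.pos}\t{row.rsid}\t{row.ref}\t"
                     f"{row.alt}\t.\t.\t{info}\n")


def read_vcf_records(path) -> list[SnvRecord]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, pos, rsid, ref, alt = line.split("\t")[:5]
        out.append(SnvRecord(rsid=rsid, chrom=chrom, pos=int(pos),
                             ref=ref, alt=alt))
    return out


def read_jaspar(path_or_text) -> dict[str, np.ndarray]:
    """Parse JASPAR-format PWMs into (L, 4) probability matrices (ACGT)."""
    if isinstance(path_or_text, (str, Path)) and Path(path_or_text).exists():
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    out = {}
    with io.StringIO(text) as fh:
        for motif in motifs.parse(fh, "jaspar"):
            counts = np.array([motif.counts[b] for b in "ACGT"],
                              dtype=float).T  # (L, 4)
            sums = counts.sum(axis=1, keepdims=True)
            if np.any(sums == 0):
                raise InvalidInputError(
                    f"motif {motif.matrix_id or motif.name} has an empty "
                    "column")
            out[motif.matrix_id or motif.name] = counts / sums
    return out
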