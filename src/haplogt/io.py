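"""Format plumbing: FASTA panels, FASTQ reads, BED weight tracks, TSV output."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .genotyper import GenotypeResult
from .panel import Haplotype, LocusPanel
from .pipeline import ReadInput


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_fasta(path: str | Path) -> list[Haplotype]:
    with _open_text(path) as fh:
        return [Haplotype(rec.id, str(rec.seq)) for rec in
                SeqIO.parse(fh, "fasta")]


def load_panels(path: str | Path, window_size: int = 100,
                delimiter: str = "*") -> list[LocusPanel]:
    """Load locus panels from multi-FASTA.

    The locus id is parsed from the record id using the ``locus*hap``
    convention; records without the delimiter form a single panel named
    after the file stem.
    """
    haps = load_fasta(path)
    groups: dict[str, list[Haplotype]] = {}
    default = Path(path).name.split(".")[0]
    for hap in haps:
        locus = hap.id.split(delimiter)[0] if delimiter in hap.id else default
        hap.locus_id = locus
        groups.setdefault(locus, []).append(hap)
    return [LocusPanel(locus, hs, window_size)
            for locus, hs in groups.items()]


def load_weights_bed(path: str | Path, panel: LocusPanel) -> None:
    """Attach a BED weight track (chrom = haplotype id, score = weight).

    Uncovered bases default to weight 1.0.
    """
    tracks = {h.id: np.ones(len(h.seq)) for h in panel.haplotypes}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}:{ln}: need 5 BED columns "
                                 "(chrom start end name score)")
            hap_id, start, end, score = f[0], int(f[1]), int(f[2]), float(f[4])
            if hap_id not in tracks:
                continue
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{path}:{ln}: weight {score} outside [0, 1]")
            tracks[hap_id][start:end] = score
    panel.explicit_weights = tracks
    panel.__post_init__()


def load_reads(path1: str | Path, path2: str | Path | None = None
               ) -> list[ReadInput]:
    """Load FASTQ reads: two-file paired, /1-/2 tagged single file, or
    single-end."""
    def parse(path):
        with _open_text(path) as fh:
            return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fastq")]

    first = parse(path1)
    if path2 is not None:
        second = dict(parse(path2))
        return [ReadInput(rid, seq, second.get(rid)) for rid, seq in first]
    if all(rid.endswith(("/1", "/2")) for rid, _ in first):
        pairs: dict[str, dict[str, str]] = {}
        order: list[str] = []
        for rid, seq in first:
            base, end = rid[:-2], rid[-1]
            if base not in pairs:
                pairs[base] = {}
                order.append(base)
            pairs[base][end] = seq
        return [ReadInput(base, pairs[base]["1"], pairs[base].get("2"))
                for base in order]
    return [ReadInput(rid, seq) for rid, seq in first]


def write_results_tsv(path: str | Path, locus_id: str,
                      results: Sequence[GenotypeResult],
                      max_rows: int | None = None) -> None:
    rows = results if max_rows is None else results[:max_rows]
    with open(path, "w") as fh:
        fh.write("locus\tgenotype\tquality\tprobability\tmean_loglik\t"
                 "sd_loglik\tunexplained_reads\tweighted_jaccard\n")
        for r in rows:
            fh.write(f"{locus_id}\t{r.genotype}\t{r.quality:.2f}\t"
                     f"{r.probability:.6g}\t{r.mean:.4f}\t{r.sd:.4f}\t"
                     f"{r.unexplained_reads}\t{r.weighted_jaccard:.4f}\n")
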