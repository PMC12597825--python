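"""Synthetic data generation: haplotype panels, diploid truth, WGS reads.

The simulator produces inputs with the statistical structure the genotyping
model assumes: a panel of haplotypes derived from a common ancestor by
SNVs, short indels, optional structural variants and VNTR copy-number
changes; paired-end fragments with negative-binomial insert sizes (or long
reads with heavier error); and context-free per-base sequencing errors at
configured mismatch / insertion / deletion rates.  Truth tables record the
originating haplotype and position of every read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .panel import Genotype, Haplotype, LocusPanel

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Study conditions of a simulated locus and WGS dataset."""

    seed: int = 0
    # panel
    n_haplotypes: int = 8
    locus_length: int = 10_000
    snv_rate: float = 0.002
    indel_rate: float = 2e-4
    max_indel_len: int = 10
    sv_count: int = 1
    sv_len: int = 300
    vntr_unit: int = 50
    vntr_copies: tuple[int, int] = (3, 8)
    lineage: str = "star"  # star: all from the ancestor; tree: genealogy
    gc_range: tuple[float, float] = (0.5, 0.5)  # GC gradient along the locus
    # reads
    coverage: float = 30.0
    read_len: int = 150
    paired: bool = True
    insert_mean: float = 500.0
    insert_nb_n: float = 400.0
    mismatch_rate: float = 0.002
    ins_rate: float = 2e-4
    del_rate: float = 2e-4
    # long reads
    long_read: bool = False
    long_read_mean_len: float = 8000.0
    long_read_mismatch: float = 0.006
    long_read_indel: float = 0.002

    def __post_init__(self) -> None:
        for name in ("snv_rate", "indel_rate", "mismatch_rate", "ins_rate",
                     "del_rate"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name} must be in [0, 1), got {r}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def insert_psi(self) -> float:
        return self.insert_nb_n / (self.insert_nb_n + self.insert_mean)


def random_seq(rng: np.random.Generator, length: int,
               gc_range: tuple[float, float] = (0.5, 0.5)) -> str:
    """i.i.d. random sequence, optionally with a linear GC gradient."""
    gc = np.linspace(gc_range[0], gc_range[1], length)
    p = np.stack([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2], axis=1)
    u = rng.random(length)
    idx = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    return "".join(_BASES[idx])


def _mutate(rng: np.random.Generator, seq: str, cfg: SimConfig) -> str:
    """Apply SNVs and short indels at the configured rates."""
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        r = rng.random()
        if r < cfg.snv_rate:
            old = seq[i]
            choices = [b for b in "ACGT" if b != old]
            out.append(choices[rng.integers(3)])
            i += 1
        elif r < cfg.snv_rate + cfg.indel_rate:
            ln = int(rng.integers(1, cfg.max_indel_len + 1))
            if rng.random() < 0.5:
                out.append(random_seq(rng, ln))
                out.append(seq[i])
                i += 1
            else:
                i += ln
        else:
            out.append(seq[i])
            i += 1
    return "".join(out)


def simulate_panel(cfg: SimConfig,
                   rng: np.random.Generator | None = None,
                   locus_id: str = "locus") -> tuple[LocusPanel, dict]:
    """Derive a QV-diverse haplotype panel from a random ancestor.

    The ancestor carries one VNTR region whose copy number is resampled per
    haplotype; each haplotype additionally receives SNVs, short indels and
    optional SV insertions/deletions.

    With ``lineage="star"`` every haplotype mutates the ancestor directly,
    which makes all haplotypes roughly equidistant.  With ``lineage="tree"``
    each haplotype after the first mutates a uniformly chosen earlier
    haplotype, producing the nested relatedness of real panels — some
    haplotypes have close relatives and others do not, which matters for
    leave-one-out evaluations where accuracy is bounded by the closest
    remaining haplotype.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    unit = random_seq(rng, cfg.vntr_unit)
    base_copies = int(np.mean(cfg.vntr_copies))
    flank = cfg.locus_length - cfg.vntr_unit * base_copies
    if flank < 2 * cfg.read_len:
        raise ValueError("locus too short for the configured VNTR")
    left = random_seq(rng, flank // 2, cfg.gc_range)
    right = random_seq(rng, flank - flank // 2, cfg.gc_range)
    ancestry: dict = {"vntr_unit": unit, "haplotypes": {}}
    haps: list[Haplotype] = []
    if cfg.lineage not in ("star", "tree"):
        raise ValueError(f"unknown lineage {cfg.lineage!r}")
    for i in range(cfg.n_haplotypes):
        parent = None
        if cfg.lineage == "tree" and i > 0:
            parent = haps[int(rng.integers(i))]
        if parent is None:
            copies = int(rng.integers(cfg.vntr_copies[0],
                                      cfg.vntr_copies[1] + 1))
            seq = left + unit * copies + right
        else:
            copies = ancestry["haplotypes"][parent.id]["vntr_copies"]
            seq = parent.seq
        seq = _mutate(rng, seq, cfg)
        svs: list[tuple[str, int]] = []
        for _ in range(cfg.sv_count):
            if rng.random() < 0.5 and len(seq) > 4 * cfg.sv_len:
                pos = int(rng.integers(cfg.read_len, len(seq) - cfg.sv_len
                                       - cfg.read_len))
                seq = seq[:pos] + seq[pos + cfg.sv_len:]
                svs.append(("del", pos))
            else:
                pos = int(rng.integers(cfg.read_len, len(seq) - cfg.read_len))
                seq = seq[:pos] + random_seq(rng, cfg.sv_len) + seq[pos:]
                svs.append(("ins", pos))
        if not seq:
            raise ValueError("mutation rates produced an empty haplotype")
        hid = f"{locus_id}*h{i + 1:02d}"
        haps.append(Haplotype(hid, seq, locus_id))
        ancestry["haplotypes"][hid] = {
            "vntr_copies": copies, "svs": svs,
            "parent": parent.id if parent is not None else None}
    return LocusPanel(locus_id, haps), ancestry


def sample_genotype(panel: LocusPanel, rng: np.random.Generator,
                    heterozygous: bool = True) -> Genotype:
    ids = panel.haplotype_ids
    if heterozygous and len(ids) > 1:
        i, j = rng.choice(len(ids), size=2, replace=False)
    else:
        i = j = rng.integers(len(ids))
    return Genotype(ids[int(i)], ids[int(j)])


@dataclass
class SimRead:
    """One simulated read (pair) with its truth annotation."""

    read_id: str
    seq1: str
    seq2: str | None
    hap_id: str
    start: int
    insert: int


def _apply_errors(rng: np.random.Generator, seq: str,
                  p_x: float, p_i: float, p_d: float) -> str:
    out: list[str] = []
    for base in seq:
        r = rng.random()
        if r < p_d:
            continue
        if r < p_d + p_i:
            out.append(str(_BASES[rng.integers(4)]))
            out.append(base)
            continue
        if r < p_d + p_i + p_x:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(3)])
            continue
        out.append(base)
    return "".join(out)


def simulate_reads(haplotypes: Sequence[Haplotype], cfg: SimConfig,
                   rng: np.random.Generator | None = None,
                   prefix: str = "rd") -> list[SimRead]:
    """Sample reads at the configured coverage, equally from each haplotype.

    Paired mode draws NB insert sizes (resampling inserts shorter than the
    read length) and emits forward/reverse 150 bp ends; long-read mode
    draws gamma-distributed lengths around the configured mean.  Per-base
    errors are context-free at the configured rates.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    mean_len = float(np.mean([len(h.seq) for h in haplotypes]))
    reads: list[SimRead] = []
    if cfg.long_read:
        n_reads = max(1, round(cfg.coverage * mean_len
                               / cfg.long_read_mean_len))
        for i in range(n_reads):
            hap = haplotypes[int(rng.integers(len(haplotypes)))]
            ln = int(rng.gamma(4.0, cfg.long_read_mean_len / 4.0))
            ln = min(max(ln, 500), len(hap.seq))
            start = int(rng.integers(0, len(hap.seq) - ln + 1))
            frag = hap.seq[start:start + ln]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            frag = _apply_errors(rng, frag, cfg.long_read_mismatch,
                                 cfg.long_read_indel / 2,
                                 cfg.long_read_indel / 2)
            reads.append(SimRead(f"{prefix}{i:06d}", frag, None,
                                 hap.id, start, ln))
        return reads

    n_frags = max(1, round(cfg.coverage * mean_len / (2 * cfg.read_len)))
    psi = cfg.insert_psi
    for i in range(n_frags):
        hap = haplotypes[int(rng.integers(len(haplotypes)))]
        hap_len = len(hap.seq)
        insert = 0
        for _ in range(100):
            insert = int(rng.negative_binomial(cfg.insert_nb_n, psi))
            if cfg.read_len <= insert <= hap_len:
                break
        else:
            insert = min(cfg.read_len, hap_len)
        start = int(rng.integers(0, hap_len - insert + 1))
        frag = hap.seq[start:start + insert]
        r1 = frag[:cfg.read_len]
        r2 = revcomp(frag[-cfg.read_len:])
        r1 = _apply_errors(rng, r1, cfg.mismatch_rate, cfg.ins_rate,
                           cfg.del_rate)
        r2 = _apply_errors(rng, r2, cfg.mismatch_rate, cfg.ins_rate,
                           cfg.del_rate)
        reads.append(SimRead(f"{prefix}{i:06d}", r1, r2, hap.id,
                             start, insert))
    return reads


def simulate_background(length: int, cfg: SimConfig,
                        rng: np.random.Generator | None = None,
                        gc_range: tuple[float, float] = (0.35, 0.65),
                        ) -> tuple[Haplotype, list[SimRead]]:
    """A background region plus reads, for fitting the WGS profiles.

    The GC gradient gives the depth model signal across GC bins.  Reads are
    drawn at the same total coverage as the locus sample, so after the
    diploid-to-haploid correction the depth model matches the per-haplotype
    locus depth.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    seq = random_seq(rng, length, gc_range)
    bg = Haplotype("background", seq, "background")
    reads = simulate_reads([bg], cfg, rng, prefix="bg")
    return bg, reads


# -- text output --------------------------------------------------------------

def write_fasta(path: str | Path, haplotypes: Iterable[Haplotype]) -> None:
    with open(path, "w") as fh:
        for hap in haplotypes:
            fh.write(f">{hap.id}\n")
            for i in range(0, len(hap.seq), 80):
                fh.write(hap.seq[i:i + 80] + "\n")


def write_fastq(path1: str | Path, reads: Sequence[SimRead],
                path2: str | Path | None = None) -> None:
    """Write reads as FASTQ; paired reads go to two files when both paths
    are given, otherwise ends are tagged /1 and /2 in one file."""
    def rec(fh, rid, seq):
        fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    if path2 is not None:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for r in reads:
                rec(f1, r.read_id, r.seq1)
                if r.seq2 is not None:
                    rec(f2, r.read_id, r.seq2)
    else:
        with open(path1, "w") as f1:
            for r in reads:
                if r.seq2 is None:
                    rec(f1, r.read_id, r.seq1)
                else:
                    rec(f1, r.read_id + "/1", r.seq1)
                    rec(f1, r.read_id + "/2", r.seq2)


def write_truth(path: str | Path, reads: Sequence[SimRead],
                genotype: Genotype | None = None) -> None:
    with open(path, "w") as fh:
        if genotype is not None:
            fh.write(f"#genotype\t{genotype.h1}\t{genotype.h2}\n")
        fh.write("read_id\thap_id\tstart\tinsert\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.hap_id}\t{r.start}\t{r.insert}\n")
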