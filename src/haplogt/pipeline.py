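"""High-level pipeline: profile fitting, recruitment, alignment, genotyping.

These functions connect the stage modules into the tool's standard flow:

1. ``fit_profiles`` maps reads to a background region with the internal
   aligner and fits the insert-size, error and depth models.
2. ``recruit_reads`` assigns reads to target loci by minimizer matching.
3. ``align_reads_to_panel`` produces scored candidate alignments of the
   recruited reads against every panel haplotype.
4. ``genotype_sample`` runs the genotyper and returns ranked results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import kmers
from .align import AlignmentRecord, HaplotypeIndex, ReadAlignments, align_read
from .genotyper import Genotyper, GenotypeResult, NoiseConfig
from .likelihood import OMEGA_D, OMEGA_R
from .panel import (DEFAULT_WINDOW_SIZE, Haplotype, LocusPanel, build_windows,
                    window_features)
from .profiles import (DepthModel, ErrorProfile, InsertSizeModel, WgsProfile,
                       fit_depth_model, fit_error_profile, fit_insert_size)
from .recruit import MinimizerIndex, RecruitParams, recruit_long, recruit_short
from .solvers import SolverConfig

MAX_CLIP_FRAC = 0.02
MIN_MAPQ = 20


@dataclass
class ReadInput:
    """One input read: single-end (seq2 None) or a pair."""

    read_id: str
    seq1: str
    seq2: str | None = None

    @property
    def paired(self) -> bool:
        return self.seq2 is not None


def _best(records: Sequence[AlignmentRecord]) -> AlignmentRecord | None:
    return min(records, key=lambda r: r.edit_distance) if records else None


def fit_profiles(background: Haplotype, reads: Sequence[ReadInput],
                 window_size: int = DEFAULT_WINDOW_SIZE,
                 kmer_size: int = 25,
                 minimizer_w: int = 10, minimizer_k: int = 15,
                 ) -> WgsProfile:
    """Fit the three WGS profiles from reads of a background region.

    Reads are mapped to the background with the internal aligner; the best
    alignment per end is the primary one.  Insert sizes come from pairs
    with both ends aligned; the error and depth fits use only pairs whose
    insert falls inside the 99.9% interval of the fitted insert NB.  Window
    depth counts first-mate primary alignments only.
    """
    index = HaplotypeIndex(background, minimizer_w, minimizer_k)
    primaries: list[tuple[AlignmentRecord | None, AlignmentRecord | None]] = []
    paired_any = False
    for read in reads:
        b1 = _best(align_read(read.seq1, index))
        b2 = _best(align_read(read.seq2, index)) if read.paired else None
        paired_any = paired_any or read.paired
        primaries.append((b1, b2))

    insert_model: InsertSizeModel | None = None
    if paired_any:
        inserts = []
        for b1, b2 in primaries:
            if b1 is not None and b2 is not None:
                lo = min(b1.start, b2.start)
                hi = max(b1.end_pos, b2.end_pos)
                inserts.append(hi - lo)
        insert_model = fit_insert_size(inserts)

    error_recs = []
    depth_pairs = []
    for b1, b2 in primaries:
        if paired_any:
            if b1 is None or b2 is None:
                continue
            insert = max(b1.end_pos, b2.end_pos) - min(b1.start, b2.start)
            if insert_model is not None and not insert_model.in_ci(insert):
                continue
            recs = (b1, b2)
        else:
            if b1 is None:
                continue
            recs = (b1,)
        for rec in recs:
            if rec.clip_frac > MAX_CLIP_FRAC:
                continue
            error_recs.append((rec.read_len, rec.matches, rec.mismatches,
                               rec.ins, rec.dels))
        depth_pairs.append(recs[0])
    error_profile = fit_error_profile(error_recs)

    # window depth over the background region
    n_win = len(background.seq) // window_size
    depth = np.zeros(n_win, dtype=int)
    for rec in depth_pairs:
        w = min(int(rec.midpoint // window_size), n_win - 1)
        depth[w] += 1
    counts = kmers.kmer_counts(background.seq, kmer_size)
    window_records = []
    for i in range(n_win):
        start, end = i * window_size, (i + 1) * window_size
        a = max(0, start - window_size // 2)
        b = min(len(background.seq), end + window_size // 2)
        gc, _, _ = window_features(background.seq, start, end, window_size,
                                   None)
        hashes = kmers.canonical_kmer_hashes(background.seq[a:b], kmer_size)
        if hashes.size:
            uniq = float(np.mean([counts.get(int(h), 0) == 1
                                  for h in hashes]))
        else:
            uniq = 0.0
        window_records.append((int(depth[i]), gc, uniq))
    depth_model = fit_depth_model(window_records, window_size)
    if not paired_any:
        # single-end data: one counted end per read at genotyping time
        depth_model = depth_model.at_rate(0.5)
    return WgsProfile(insert=insert_model, error=error_profile,
                      depth=depth_model)


def recruit_reads(reads: Sequence[ReadInput], index: MinimizerIndex,
                  params: RecruitParams | None = None,
                  long_reads: bool = False,
                  ) -> dict[str, list[ReadInput]]:
    """Partition reads by recruiting locus (a read may recruit to several)."""
    params = params or RecruitParams()
    out: dict[str, list[ReadInput]] = {locus: []
                                       for locus in index.locus_minimizers}
    for read in reads:
        if long_reads:
            hashes = kmers.minimizer_hashes(read.seq1, index.w, index.k)
            loci = recruit_long(hashes, index, params)
        else:
            ends = [kmers.minimizer_hashes(read.seq1, index.w, index.k)]
            if read.paired:
                ends.append(kmers.minimizer_hashes(read.seq2, index.w,
                                                   index.k))
            loci = recruit_short(ends, index, params, paired=read.paired)
        for locus in loci:
            out[locus].append(read)
    return out


def align_reads_to_panel(reads: Sequence[ReadInput], panel: LocusPanel,
                         error_profile: ErrorProfile,
                         minimizer_w: int = 10, minimizer_k: int = 15,
                         index: MinimizerIndex | None = None,
                         ) -> list[ReadAlignments]:
    """Scored candidate alignments of each read against every haplotype.

    When a minimizer index is supplied, the per-read count of locus-
    specific minimizers is recorded so that reads from homologous regions
    can be neutralized downstream.
    """
    hap_indexes = [HaplotypeIndex(h, minimizer_w, minimizer_k)
                   for h in panel.haplotypes]
    out: list[ReadAlignments] = []
    for read in reads:
        holder = ReadAlignments(read.read_id)
        ends = {1: read.seq1, 2: read.seq2} if read.paired else {0: read.seq1}
        for end, seq in ends.items():
            recs: list[AlignmentRecord] = []
            for hi in hap_indexes:
                recs.extend(align_read(seq, hi, read.read_id, end,
                                       profile=error_profile))
            holder.ends[end] = recs
        if index is not None:
            hashes: list[int] = []
            for seq in ends.values():
                hashes.extend(kmers.minimizer_hashes(seq, index.w, index.k))
            holder.target_specific_kmers = index.target_specific_count(
                panel.locus_id, hashes)
        out.append(holder)
    return out


def genotype_sample(panel: LocusPanel, reads: Sequence[ReadInput],
                    profile: WgsProfile,
                    kmer_counts: Mapping[int, int] | None = None,
                    solver_config: SolverConfig | None = None,
                    noise_config: NoiseConfig | None = None,
                    omega_r: float = OMEGA_R, omega_d: float = OMEGA_D,
                    recruit_index: MinimizerIndex | None = None,
                    noise: bool = True) -> list[GenotypeResult]:
    """Full per-locus genotyping of pre-recruited reads."""
    windows = build_windows(panel, kmer_counts)
    aligned = align_reads_to_panel(reads, panel, profile.error,
                                   index=recruit_index)
    gt = Genotyper(panel, windows, profile, solver_config, noise_config,
                   omega_r, omega_d, kmer_counts)
    return gt.run(aligned, noise=noise)
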