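"""Read-to-haplotype alignment: internal seed-and-extend plus SAM import.

The internal aligner seeds candidate placements from shared minimizers,
clusters seeds by diagonal and runs a banded unit-cost infix alignment
(global in the read, free ends on the haplotype) for each cluster.  It
reports per-operation counts (match / mismatch / insertion / deletion),
the alignment log-probability under the fitted error profile and the
beta-binomial tail probability of the edit distance.

Precomputed alignments can also be imported from a minimal SAM subset
(CIGAR operations M/=/X/I/D/S; NM tag used to split M into matches and
mismatches when present) or from the internal TSV dialect.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

from . import kmers
from .panel import Haplotype
from .profiles import ErrorProfile

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class AlignmentRecord:
    """One candidate alignment of a read end to a haplotype."""

    read_id: str
    end: int  # 1 or 2 for pairs, 0 for single-end / long reads
    hap_id: str
    start: int
    end_pos: int
    matches: int
    mismatches: int
    ins: int
    dels: int
    clip_frac: float = 0.0
    log_prob: float = 0.0
    bb_p: float = 1.0

    @property
    def edit_distance(self) -> int:
        return self.mismatches + self.ins + self.dels

    @property
    def read_len(self) -> int:
        return self.matches + self.mismatches + self.ins

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end_pos)

    def score_with(self, profile: ErrorProfile) -> None:
        self.log_prob = profile.alignment_log_prob(
            self.matches, self.mismatches, self.ins, self.dels)
        self.bb_p = profile.bb_pvalue(
            min(self.edit_distance, self.read_len), self.read_len)


def default_band(read_len: int) -> int:
    return max(16, -(-12 * read_len // 100))


def _parse_extended_cigar(cigar: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, ins, dels) from an =/X/I/D CIGAR string."""
    m = x = i = d = 0
    for length, op in _CIGAR_RE.findall(cigar):
        n = int(length)
        if op == "=":
            m += n
        elif op == "X":
            x += n
        elif op == "I":
            i += n
        elif op == "D":
            d += n
        else:
            raise ValueError(f"unexpected CIGAR op {op}")
    return m, x, i, d


class HaplotypeIndex:
    """Minimizer position index of one haplotype, for alignment seeding."""

    def __init__(self, hap: Haplotype, w: int = 10, k: int = 15) -> None:
        self.hap = hap
        self.w = w
        self.k = k
        self.positions: dict[int, list[int]] = defaultdict(list)
        for pos, h in kmers.extract_minimizers(hap.seq, w, k):
            self.positions[h].append(pos)


_RC = str.maketrans("ACGTN", "TGCAN")


def align_read(read_seq: str, hap_index: HaplotypeIndex,
               read_id: str = "", end: int = 0,
               profile: ErrorProfile | None = None,
               band: int | None = None,
               max_candidates: int = 8) -> list[AlignmentRecord]:
    """Candidate alignments of a read to one haplotype, both strands.

    Each strand is seeded and extended independently; records from both
    orientations are pooled, deduplicated by start position (best edit
    distance wins) and sorted.  Reads sharing no minimizer with the
    haplotype produce no alignments (they may still attach to the null
    window downstream).
    """
    read_seq = read_seq.upper()
    fwd = _align_oriented(read_seq, hap_index, read_id, end, band)
    rev = _align_oriented(read_seq.translate(_RC)[::-1], hap_index,
                          read_id, end, band)
    by_start: dict[int, AlignmentRecord] = {}
    for rec in fwd + rev:
        cur = by_start.get(rec.start)
        if cur is None or rec.edit_distance < cur.edit_distance:
            by_start[rec.start] = rec
    records = sorted(by_start.values(),
                     key=lambda r: (r.edit_distance, r.start))
    records = records[:max_candidates]
    if profile is not None:
        for rec in records:
            rec.score_with(profile)
    return records


def _align_oriented(read_seq: str, hap_index: HaplotypeIndex,
                    read_id: str, end: int,
                    band: int | None) -> list[AlignmentRecord]:
    """Seed-and-extend alignment of one read orientation.

    Shared minimizers between the read and the haplotype propose diagonals;
    diagonals within one band width are clustered and each cluster is
    resolved by a banded infix alignment of the whole read against the
    implied haplotype segment.
    """
    hap = hap_index.hap
    if band is None:
        band = default_band(len(read_seq))
    read_mins = kmers.extract_minimizers(read_seq, hap_index.w, hap_index.k)
    diagonals: list[int] = []
    for rpos, h in read_mins:
        for hpos in hap_index.positions.get(h, ()):
            diagonals.append(hpos - rpos)
    if not diagonals:
        return []
    diagonals.sort()
    clusters: list[tuple[int, int]] = []
    lo = hi = diagonals[0]
    for dg in diagonals[1:]:
        if dg - hi <= band:
            hi = dg
        else:
            clusters.append((lo, hi))
            lo = hi = dg
    clusters.append((lo, hi))

    records: list[AlignmentRecord] = []
    seen_starts: set[int] = set()
    for lo, hi in clusters[:16]:
        seg_start = max(0, lo - band)
        seg_end = min(len(hap.seq), hi + len(read_seq) + band)
        segment = hap.seq[seg_start:seg_end]
        res = edlib.align(read_seq, segment, mode="HW", task="path", k=band)
        if res["editDistance"] < 0:
            continue
        loc = res["locations"][0]
        m, x, i, d = _parse_extended_cigar(res["cigar"])
        start = seg_start + loc[0]
        if start in seen_starts:
            continue
        seen_starts.add(start)
        rec = AlignmentRecord(
            read_id=read_id, end=end, hap_id=hap.id,
            start=start, end_pos=seg_start + loc[1] + 1,
            matches=m, mismatches=x, ins=i, dels=d)
        records.append(rec)
    return records


# -- pair-level filtering -----------------------------------------------------

PAIR_KEEP_P = 0.01
ALIGNMENT_KEEP_P = 0.001


@dataclass
class ReadAlignments:
    """All retained alignments of one read (pair), grouped per end."""

    read_id: str
    ends: dict[int, list[AlignmentRecord]] = field(default_factory=dict)
    weight: float = 1.0
    target_specific_kmers: int | None = None

    @property
    def end_ids(self) -> list[int]:
        return sorted(self.ends)

    def by_hap(self, end: int) -> dict[str, list[AlignmentRecord]]:
        grouped: dict[str, list[AlignmentRecord]] = defaultdict(list)
        for rec in self.ends.get(end, []):
            grouped[rec.hap_id].append(rec)
        return grouped

    def best_log_prob(self, end: int) -> float:
        recs = self.ends.get(end, [])
        if not recs:
            raise ValueError(f"read {self.read_id}: end {end} has no alignments")
        return max(r.log_prob for r in recs)


def filter_alignments(reads: Iterable[ReadAlignments],
                      keep_p: float = PAIR_KEEP_P,
                      drop_p: float = ALIGNMENT_KEEP_P,
                      ) -> tuple[list[ReadAlignments], int]:
    """Apply the beta-binomial retention thresholds.

    A read (pair) is kept iff every end has at least one alignment with
    tail probability >= 0.01 on some haplotype; within kept reads,
    individual alignments with tail probability < 0.001 are dropped.
    Returns the retained reads and the number of discarded ones.
    """
    kept: list[ReadAlignments] = []
    discarded = 0
    for read in reads:
        if not read.ends or any(not recs for recs in read.ends.values()):
            discarded += 1
            continue
        if all(max(r.bb_p for r in recs) >= keep_p
               for recs in read.ends.values()):
            filtered = {
                e: [r for r in recs if r.bb_p >= drop_p]
                for e, recs in read.ends.items()}
            kept.append(ReadAlignments(read.read_id, filtered, read.weight,
                                       read.target_specific_kmers))
        else:
            discarded += 1
    return kept, discarded


# -- SAM / TSV import ---------------------------------------------------------

def _counts_from_sam(cigartuples, nm: int | None) -> tuple[int, int, int, int, int]:
    """(matches, mismatches, ins, dels, clipped) from pysam cigartuples."""
    M = X = EQ = I = D = S = 0
    for op, n in cigartuples:
        if op == 0:
            M += n
        elif op == 1:
            I += n
        elif op == 2:
            D += n
        elif op == 4:
            S += n
        elif op == 7:
            EQ += n
        elif op == 8:
            X += n
        elif op in (3, 5, 6):
            continue
        else:
            raise ValueError(f"unsupported CIGAR op code {op}")
    if M and nm is not None:
        # NM = X + I + D over the M run; recover mismatches
        x_in_m = max(nm - I - D - X, 0)
        return M - x_in_m + EQ, X + x_in_m, I, D, S
    return M + EQ, X, I, D, S


def read_sam_alignments(path: str | Path,
                        profile: ErrorProfile | None = None,
                        ) -> list[ReadAlignments]:
    """Import alignments from a minimal SAM file via pysam.

    Unmapped and secondary-flag-free multi-alignments are all retained; the
    caller applies BB filtering afterwards.
    """
    import pysam

    reads: dict[str, ReadAlignments] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else None
            m, x, i, d, s = _counts_from_sam(rec.cigartuples, nm)
            end = 0
            if rec.is_paired:
                end = 1 if rec.is_read1 else 2
            read_len = m + x + i + s
            ar = AlignmentRecord(
                read_id=rec.query_name, end=end, hap_id=rec.reference_name,
                start=rec.reference_start,
                end_pos=rec.reference_start + m + x + d,
                matches=m, mismatches=x, ins=i, dels=d,
                clip_frac=s / read_len if read_len else 0.0)
            if profile is not None:
                ar.score_with(profile)
            holder = reads.setdefault(rec.query_name,
                                      ReadAlignments(rec.query_name))
            holder.ends.setdefault(end, []).append(ar)
    return list(reads.values())


TSV_COLUMNS = ["read_id", "end", "hap_id", "start", "matches", "mismatches",
               "ins", "dels", "mapq", "clip_frac"]


def read_tsv_alignments(path: str | Path,
                        profile: ErrorProfile | None = None,
                        ) -> list[ReadAlignments]:
    """Import alignments from the internal TSV dialect."""
    reads: dict[str, ReadAlignments] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: idx for idx, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            m = int(f[col["matches"]])
            x = int(f[col["mismatches"]])
            i = int(f[col["ins"]])
            d = int(f[col["dels"]])
            start = int(f[col["start"]])
            ar = AlignmentRecord(
                read_id=f[col["read_id"]], end=int(f[col["end"]]),
                hap_id=f[col["hap_id"]], start=start,
                end_pos=start + m + x + d, matches=m, mismatches=x,
                ins=i, dels=d, clip_frac=float(f[col.get("clip_frac", -1)])
                if "clip_frac" in col else 0.0)
            if profile is not None:
                ar.score_with(profile)
            holder = reads.setdefault(ar.read_id, ReadAlignments(ar.read_id))
            holder.ends.setdefault(ar.end, []).append(ar)
    return list(reads.values())
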