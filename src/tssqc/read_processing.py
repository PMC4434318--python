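"""From raw tagged reads to deduplicated strand-specific 5'-end count tracks.

The ligated oligonucleotide leaves a 12-nt tag at the start of every read:
4 random nt (UMI part 1), the fixed block CGCG, the fixed ribo-CG, and 2
random (ribo) nt (UMI part 2).  The two random blocks together form a 6-nt
unique molecular identifier used to remove PCR duplicates; the remainder of
the read is the transcript 5' sequence, whose first base marks the TSS.

Duplicate removal keys on (chromosome, position, strand, UMI): fragmentation
happens after ligation, so the 5' identity plus the UMI defines the molecule
regardless of read length.  A read whose first base mismatches the genome is
still counted at its mapped position; those mismatches are analysed
separately by :func:`mismatch_slippage_profile` because a specific genomic
context (A(N)6PyAAA, a "slippery" run of As after a pyrimidine) produces
transcripts carrying a non-templated extra A.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import PYRIMIDINES, base_at, downstream, revcomp, sense_slice

#: tag motifs: N = random base, fixed letters must match exactly.
TAG_MOTIFS = {
    "tap": "NNNNCGCGCGNN",         # oligo ligated to TAP-treated (capped) RNA
    "fragmented": "NNNNGCCGCGNN",  # oligo ligated to fragmented RNA libraries
}


@dataclass
class TaggedRead:
    read_id: str
    umi: str       # 6 nt: the 4 leading + 2 trailing random tag positions
    rna_seq: str


@dataclass
class MappedFivePrime:
    """One mapped read reduced to its transcript 5' end.

    ``pos`` is the 1-based genomic coordinate of the transcript's 5'-most
    base; on the minus strand this is the rightmost aligned genomic base.
    """

    chrom: str
    pos: int
    strand: str
    umi: str
    aligned_seq: str = ""
    first_base_genomic: str = ""
    first_base_read: str = ""


@dataclass
class TSSCountTrack:
    """Sparse per-(chromosome, strand, position) unique-read counts."""

    sample_id: str
    counts: dict[tuple[str, str], Counter] = field(default_factory=dict)

    def add(self, chrom: str, strand: str, pos: int, n: int = 1) -> None:
        self.counts.setdefault((chrom, strand), Counter())[pos] += n

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self.counts.get((chrom, strand), Counter()).get(pos, 0)

    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def items(self):
        for (chrom, strand), c in sorted(self.counts.items()):
            for pos in sorted(c):
                yield chrom, strand, pos, c[pos]


# ---------------------------------------------------------------------------
# tag extraction


def extract_ligation_tag(read_id: str, seq: str, motif: str = TAG_MOTIFS["tap"]):
    """Split a raw read into UMI and RNA remainder according to the tag motif.

    Returns ``(TaggedRead, None)`` on success or ``(None, reason)`` where
    reason is ``"too_short"``, ``"tag_mismatch"`` or ``"empty_insert"``.
    """
    if len(seq) < len(motif):
        return None, "too_short"
    umi = []
    for base, m in zip(seq, motif):
        if m == "N":
            umi.append(base)
        elif base != m:
            return None, "tag_mismatch"
    rna = seq[len(motif):]
    if not rna:
        return None, "empty_insert"
    return TaggedRead(read_id, "".join(umi), rna), None


def extract_tags(reads, motif: str = TAG_MOTIFS["tap"]):
    """Batch tag extraction: ``(tagged_reads, Counter of rejection reasons)``.

    ``reads`` yields ``(read_id, sequence)`` pairs.
    """
    out, reasons = [], Counter()
    for read_id, seq in reads:
        tr, why = extract_ligation_tag(read_id, seq, motif)
        if tr is None:
            reasons[why] += 1
        else:
            out.append(tr)
    return out, reasons


# ---------------------------------------------------------------------------
# deduplication and counting

_KEY_COLS = ["chrom", "pos", "strand", "umi"]


def deduplicate(records):
    """Keep the first record per (chrom, pos, strand, UMI) key.

    Accepts a list of :class:`MappedFivePrime` (returns a list) or a
    DataFrame with columns chrom/pos/strand/umi (returns a DataFrame).
    Returns ``(unique_records, n_removed)``; input order decides retention.
    """
    if isinstance(records, pd.DataFrame):
        unique = records.drop_duplicates(subset=_KEY_COLS, keep="first")
        return unique, len(records) - len(unique)
    seen = set()
    unique = []
    for r in records:
        key = (r.chrom, r.pos, r.strand, r.umi)
        if key not in seen:
            seen.add(key)
            unique.append(r)
    return unique, len(records) - len(unique)


def fiveprime_counts(records, sample_id: str) -> TSSCountTrack:
    """Count unique 5' ends per (chrom, strand, position).

    Callers are expected to deduplicate first; counts are of the records
    given.  Accepts the same inputs as :func:`deduplicate`.
    """
    track = TSSCountTrack(sample_id)
    if isinstance(records, pd.DataFrame):
        grouped = records.groupby(["chrom", "strand", "pos"], observed=True).size()
        for (chrom, strand, pos), n in grouped.items():
            track.add(chrom, strand, int(pos), int(n))
        return track
    for r in records:
        track.add(r.chrom, r.strand, r.pos)
    return track


def alignments_to_records(df: pd.DataFrame) -> pd.DataFrame:
    """BED-like alignment frame (chrom, start0, end0, strand, umi, seq[, read_id])
    to a mapped-5'-end frame with a 1-based ``pos`` column.

    Plus-strand reads start at start0 + 1; minus-strand reads start at end0
    (rightmost aligned base, 1-based).
    """
    pos = np.where(df["strand"].to_numpy() == "+",
                   df["start0"].to_numpy() + 1,
                   df["end0"].to_numpy())
    out = df.copy()
    out["pos"] = pos.astype(int)
    return out


# ---------------------------------------------------------------------------
# first-base mismatch / slippage diagnostics


@dataclass
class MismatchProfile:
    """Per-cDNA-position mismatch rates and PyAAA slippage classification."""

    n_positions: int
    mismatch_rate: np.ndarray          # rate per read position (index 0 = pos 1)
    pos1_rate_by_base: dict            # genomic base at pos 1 -> mismatch rate
    candidate_sites: set               # (chrom, strand, pos) flagged PyAAA TSSs
    site_stats: dict                   # site -> {"reads": n, "py_to_a": m}
    skipped: int = 0                   # records overrunning a contig end

    @property
    def flagged_py_to_a_fraction(self) -> float:
        reads = sum(s["reads"] for s in self.site_stats.values())
        hits = sum(s["py_to_a"] for s in self.site_stats.values())
        return hits / reads if reads else 0.0


def is_slippage_context(genome: dict[str, str], chrom: str, strand: str, pos: int) -> bool:
    """True when the genomic context of a mapped position matches A(N)6PyAAA
    with the mapped base being the pyrimidine (transcription-sense)."""
    b0 = base_at(genome, chrom, strand, pos)
    b1 = base_at(genome, chrom, strand, downstream(pos, strand, 1))
    b2 = base_at(genome, chrom, strand, downstream(pos, strand, 2))
    a7 = base_at(genome, chrom, strand, downstream(pos, strand, -7))
    return b0 in PYRIMIDINES and b1 == "A" and b2 == "A" and a7 == "A"


def mismatch_slippage_profile(records, genome: dict[str, str], max_len: int = 50) -> MismatchProfile:
    """Mismatch rates along the cDNA and slippage-candidate classification.

    ``records`` may be a list of :class:`MappedFivePrime` (with aligned_seq)
    or an alignment-style DataFrame with chrom/strand/pos/seq columns.
    """
    if isinstance(records, pd.DataFrame):
        rows = records[["chrom", "strand", "pos", "seq"]].itertuples(index=False)
    else:
        rows = ((r.chrom, r.strand, r.pos, r.aligned_seq) for r in records)

    mm = np.zeros(max_len)
    tot = np.zeros(max_len)
    pos1 = {b: [0, 0] for b in "ACGT"}  # base -> [mismatches, total]
    sites: dict[tuple, dict] = defaultdict(lambda: {"reads": 0, "py_to_a": 0})
    candidates: set[tuple] = set()
    skipped = 0

    for chrom, strand, pos, seq in rows:
        k = min(len(seq), max_len)
        ref = sense_slice(genome, chrom, strand, pos, k)
        if len(ref) < k:
            skipped += 1
            continue
        for i in range(k):
            tot[i] += 1
            if seq[i] != ref[i]:
                mm[i] += 1
        g1 = ref[0]
        if g1 in pos1:
            pos1[g1][0] += int(seq[0] != g1)
            pos1[g1][1] += 1
        if g1 in PYRIMIDINES:
            if is_slippage_context(genome, chrom, strand, pos):
                site = (chrom, strand, pos)
                candidates.add(site)
                sites[site]["reads"] += 1
                if seq[0] == "A":
                    sites[site]["py_to_a"] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(tot > 0, mm / np.maximum(tot, 1), 0.0)
    by_base = {b: (v[0] / v[1] if v[1] else 0.0) for b, v in pos1.items()}
    return MismatchProfile(max_len, rate, by_base, candidates, dict(sites), skipped)


# ---------------------------------------------------------------------------
# exact-match placer for synthetic reads

_INDEX_K = 24


def build_exact_index(genome: dict[str, str], k: int = _INDEX_K):
    """k-mer index of both strands: kmer -> list of (chrom, strand, 5' pos)."""
    index: dict[str, list] = defaultdict(list)
    for chrom, seq in genome.items():
        for i in range(len(seq) - k + 1):
            index[seq[i:i + k]].append((chrom, "+", i + 1))
        rc = revcomp(seq)
        n = len(seq)
        for i in range(n - k + 1):
            # rc[i:i+k] starts (in transcript sense) at genomic 1-based n - i
            index[rc[i:i + k]].append((chrom, "-", n - i))
    return dict(index)


def map_reads_exact(tagged_reads, genome: dict[str, str], k: int = _INDEX_K):
    """Place synthetic reads by exact match, requiring a unique hit.

    A read whose suffix (all but the first base) matches uniquely one base
    downstream of a candidate is placed with a first-base mismatch, which is
    how slippage reads map.  Returns ``(records, Counter of drop reasons)``.
    """
    index = build_exact_index(genome, k)
    records: list[MappedFivePrime] = []
    reasons = Counter()
    for tr in tagged_reads:
        seq = tr.rna_seq
        if len(seq) < k + 1:
            reasons["too_short"] += 1
            continue
        hits = [h for h in index.get(seq[:k], ())
                if sense_slice(genome, h[0], h[1], h[2], len(seq)) == seq]
        if not hits:
            # tolerate one mismatch at the first base: anchor on seq[1:]
            sub = [h for h in index.get(seq[1:k + 1], ())
                   if sense_slice(genome, h[0], h[1], h[2], len(seq) - 1) == seq[1:]]
            hits = [(c, s, downstream(p, s, -1)) for c, s, p in sub
                    if base_at(genome, c, s, downstream(p, s, -1)) not in ("", seq[0])]
        if len(hits) == 1:
            c, s, p = hits[0]
            records.append(MappedFivePrime(c, p, s, tr.umi, seq,
                                           base_at(genome, c, s, p), seq[0]))
        elif not hits:
            reasons["unmapped"] += 1
        else:
            reasons["multi_hit"] += 1
    return records, reasons
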