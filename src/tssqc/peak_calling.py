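"""Group individual TSS positions into TSS clusters (TSSCs).

Closely spaced 5' ends of a transcription unit are treated as one cluster:
positions observed in any sample are single-linkage chained per
(chromosome, strand), joining two adjacent positions when they are at most
``max_gap`` nucleotides apart, and a candidate cluster is retained when its
summed read count reaches ``min_reads`` in at least one sample.  The default
parameters (gap 50 nt, threshold 4 reads, cluster-level in at least one
sample) are the ones that maximise one-cluster-per-ORF assignment on real
yeast data.

The threshold is applied to the cluster-level per-sample total by default;
``min_reads_scope="position"`` applies it per member position instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .read_processing import TSSCountTrack


@dataclass
class TSSC:
    """A TSS cluster across a set of samples."""

    id: str
    chrom: str
    strand: str
    start: int                 # 1-based inclusive bounds of member positions
    end: int
    positions: list[int]       # sorted ascending
    count_matrix: dict[str, dict[int, int]]   # sample -> pos -> count
    totals: dict[str, int] = field(default_factory=dict)
    summit: int = 0
    category: str = ""
    feature_id: str | None = None
    snr: float | None = None
    accuracy: float | None = None
    passed: bool | None = None

    def pooled_counts(self) -> dict[int, int]:
        pooled: dict[int, int] = {p: 0 for p in self.positions}
        for per_pos in self.count_matrix.values():
            for p, n in per_pos.items():
                pooled[p] += n
        return pooled

    def total(self, sample: str) -> int:
        return self.totals.get(sample, 0)


def summit(tssc: TSSC) -> int:
    """Position maximising the across-sample summed count; ties break toward
    the transcription-upstream end (smallest coordinate on +, largest on -)."""
    pooled = tssc.pooled_counts()
    best = max(pooled.values())
    tied = [p for p in tssc.positions if pooled[p] == best]
    return min(tied) if tssc.strand == "+" else max(tied)


def call_clusters(tracks: list[TSSCountTrack], max_gap: int = 50,
                  min_reads: int = 4, min_reads_scope: str = "cluster") -> list[TSSC]:
    """Cluster TSS positions from a set of count tracks.

    Clusters never span chromosomes or strands; IDs are deterministic in
    (chrom, strand, start) order and independent of sample ordering.
    """
    if max_gap < 0 or min_reads < 1:
        raise ValueError("max_gap must be >= 0 and min_reads >= 1")
    if min_reads_scope not in ("cluster", "position"):
        raise ValueError("min_reads_scope must be 'cluster' or 'position'")

    chrom_sets = [{c for c, _ in t.counts} for t in tracks if t.counts]
    for i in range(1, len(chrom_sets)):
        if not chrom_sets[i] & chrom_sets[0]:
            raise ValueError("tracks reference disjoint chromosome sets; "
                             "are they from the same genome?")

    keys = sorted({k for t in tracks for k in t.counts})
    clusters: list[TSSC] = []
    for chrom, strand in keys:
        per_sample = {t.sample_id: t.counts.get((chrom, strand), {}) for t in tracks}
        positions = sorted({p for c in per_sample.values() for p in c})
        if not positions:
            continue
        run: list[int] = []
        for p in positions + [None]:
            if run and (p is None or p - run[-1] > max_gap):
                cm = {s: {q: c[q] for q in run if q in c} for s, c in per_sample.items()}
                cm = {s: d for s, d in cm.items() if d}
                if min_reads_scope == "cluster":
                    keep = any(sum(d.values()) >= min_reads for d in cm.values())
                    members = run
                else:
                    members = [q for q in run
                               if any(d.get(q, 0) >= min_reads for d in cm.values())]
                    keep = bool(members)
                    cm = {s: {q: n for q, n in d.items() if q in set(members)}
                          for s, d in cm.items()}
                    cm = {s: d for s, d in cm.items() if d}
                if keep:
                    t = TSSC(id="", chrom=chrom, strand=strand,
                             start=members[0], end=members[-1],
                             positions=list(members), count_matrix=cm)
                    t.totals = {s: sum(d.values()) for s, d in cm.items()}
                    t.summit = summit(t)
                    clusters.append(t)
                run = []
            if p is not None:
                run.append(p)

    clusters.sort(key=lambda t: (t.chrom, t.strand, t.start))
    for i, t in enumerate(clusters, start=1):
        t.id = f"TSSC{i:05d}"
    return clusters
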