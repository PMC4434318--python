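"""Sequence and chromatin context of TSSs.

Yeast TSSs follow a loose pyrimidine-purine initiator consensus with an
additional A eight nucleotides upstream: A(N)6PyPu, with the purine being
the first transcribed base.  This module builds position frequency matrices
around observed TSSs (offsets relative to the TSS, which is +1; there is no
offset 0), scans a genome for consensus occurrences to ask what fraction of
conforming sites is actually used, and aggregates nucleosome-occupancy
signal around TSSs, where gene promoters show a nucleosome-free region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import PURINES, PYRIMIDINES, pos_at_offset, revcomp, sense_slice

BASES = "ACGT"
DEFAULT_WINDOW = (-10, 5)


@dataclass
class PositionMatrix:
    """Per-offset base frequencies around a set of anchor positions."""

    offsets: list[int]          # e.g. -10..-1, +1..+5 (no 0)
    counts: np.ndarray          # 4 x n_offsets, rows in BASES order
    n_sites: int                # sites contributing (weighting applied)
    skipped_edge: int           # anchors whose window left the contig

    @property
    def freq(self) -> np.ndarray:
        tot = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.counts / np.maximum(tot, 1), np.nan)

    def information_content(self) -> np.ndarray:
        """Per-offset information content 2 + sum(f log2 f), in bits."""
        f = self.freq
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + np.nansum(term, axis=0)

    def base_freq(self, base: str, offset: int) -> float:
        return float(self.freq[BASES.index(base), self.offsets.index(offset)])

    def summary(self) -> dict[str, float]:
        """Fractions diagnostic for the A(N)6PyPu initiator consensus."""
        f = self.freq
        j1 = self.offsets.index(1)
        jm1 = self.offsets.index(-1)
        out = {
            "purine_plus1": float(sum(f[BASES.index(b), j1] for b in PURINES)),
            "pyrimidine_minus1": float(sum(f[BASES.index(b), jm1] for b in PYRIMIDINES)),
        }
        if -8 in self.offsets:
            out["a_minus8"] = self.base_freq("A", -8)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=list(BASES),
                            columns=pd.Index(self.offsets, name="offset"))


def pfm_around(sites, genome: dict[str, str],
               window: tuple[int, int] = DEFAULT_WINDOW,
               weight: str = "tss") -> PositionMatrix:
    """Position frequency matrix around TSS anchors.

    ``sites`` yields ``(chrom, strand, pos)`` or ``(chrom, strand, pos, n)``
    tuples; with ``weight="tss"`` every site counts once, with
    ``weight="reads"`` it counts ``n`` times.  Anchors whose window exceeds
    the contig are skipped and counted in ``skipped_edge``.
    """
    if weight not in ("tss", "reads"):
        raise ValueError("weight must be 'tss' or 'reads'")
    lo, hi = window
    offsets = [o for o in range(lo, hi + 1) if o != 0]
    counts = np.zeros((4, len(offsets)))
    n_sites = 0
    skipped = 0
    base_idx = {b: i for i, b in enumerate(BASES)}
    for site in sites:
        chrom, strand, pos = site[0], site[1], site[2]
        w = int(site[3]) if (weight == "reads" and len(site) > 3) else 1
        pa = pos_at_offset(pos, strand, lo)
        pb = pos_at_offset(pos, strand, hi)
        if min(pa, pb) < 1 or max(pa, pb) > len(genome.get(chrom, "")):
            skipped += 1
            continue
        # pa is the window's most-upstream position in transcription sense,
        # which is the higher genomic coordinate on the minus strand
        seq = sense_slice(genome, chrom, strand, pa, len(offsets))
        ok = True
        for j, b in enumerate(seq):
            if b not in base_idx:
                ok = False
                break
        if not ok:
            skipped += 1
            continue
        for j, b in enumerate(seq):
            counts[base_idx[b], j] += w
        n_sites += w
    return PositionMatrix(offsets, counts, n_sites, skipped)


# ---------------------------------------------------------------------------
# consensus scanning


@dataclass
class ConsensusScan:
    n_sites: int         # consensus occurrences in the genome (both strands)
    n_used: int          # occurrences coinciding with an observed TSS
    sites: set           # (chrom, strand, pos of the purine = putative +1)

    @property
    def pct_used(self) -> float:
        return 100.0 * self.n_used / self.n_sites if self.n_sites else 0.0


def _scan_strand(seq: str) -> np.ndarray:
    """0-based indices i (in ``seq``) where i is the purine of A(N)6PyPu:
    seq[i] purine, seq[i-1] pyrimidine, seq[i-8] == 'A'."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_pur = (arr == ord("A")) | (arr == ord("G"))
    is_pyr = (arr == ord("C")) | (arr == ord("T"))
    is_a = arr == ord("A")
    n = len(arr)
    if n < 9:
        return np.empty(0, dtype=int)
    ok = is_pur[8:] & is_pyr[7:-1] & is_a[:-8]
    return np.nonzero(ok)[0] + 8


def consensus_scan(genome: dict[str, str], used_positions=None,
                   chroms: list[str] | None = None) -> ConsensusScan:
    """Scan both strands for A(N)6PyPu and intersect with observed TSSs.

    ``used_positions`` is a set of ``(chrom, strand, pos)`` observed TSSs
    (1-based, pos = the purine / first transcribed base).
    """
    used_positions = used_positions or set()
    sites: set = set()
    for chrom, seq in genome.items():
        if chroms is not None and chrom not in chroms:
            continue
        for i in _scan_strand(seq):
            sites.add((chrom, "+", int(i) + 1))
        n = len(seq)
        for i in _scan_strand(revcomp(seq)):
            sites.add((chrom, "-", n - int(i)))
    n_used = sum(1 for s in sites if s in used_positions)
    return ConsensusScan(len(sites), n_used, sites)


# ---------------------------------------------------------------------------
# nucleosome occupancy


def nucleosome_profile(anchors, occupancy: dict[tuple[str, int], float],
                       window: tuple[int, int] = (-1000, 1000)) -> pd.DataFrame:
    """Average occupancy around anchors, oriented by transcription direction.

    ``anchors`` yields ``(chrom, strand, pos)``; ``occupancy`` maps
    ``(chrom, 1-based pos)`` to a signal value.  Positions with no signal
    value are excluded from the average (not treated as zero).  Returns a
    frame indexed by signed distance (no 0 is fine here: distance 0 is the
    anchor itself) with columns ``mean`` and ``n``.
    """
    lo, hi = window
    dists = np.arange(lo, hi + 1)
    total = np.zeros(len(dists))
    n = np.zeros(len(dists))
    for chrom, strand, pos in anchors:
        sign = 1 if strand == "+" else -1
        for j, d in enumerate(dists):
            v = occupancy.get((chrom, pos + sign * int(d)))
            if v is not None:
                total[j] += v
                n[j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"mean": mean, "n": n.astype(int)},
                        index=pd.Index(dists, name="distance"))
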