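"""Small shared sequence/coordinate helpers.

Internal convention: genomic coordinates are 1-based inclusive in all public
data structures (matching wig/GFF3); readers of 0-based formats convert on
input, writers convert on output.  "Downstream" always means the direction of
transcription of the strand under consideration.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def base_at(genome: dict[str, str], chrom: str, strand: str, pos: int) -> str:
    """Transcription-sense base at 1-based position ``pos`` (or ``""`` off-contig)."""
    seq = genome[chrom]
    if pos < 1 or pos > len(seq):
        return ""
    b = seq[pos - 1]
    return b.translate(COMPLEMENT) if strand == "-" else b


def downstream(pos: int, strand: str, k: int) -> int:
    """Genomic 1-based position ``k`` nt downstream (in transcription sense) of ``pos``."""
    return pos + k if strand == "+" else pos - k


def sense_slice(genome: dict[str, str], chrom: str, strand: str, pos: int, length: int) -> str:
    """Transcription-sense sequence of ``length`` nt starting at 1-based ``pos``.

    Returns a shorter string when the window overruns the contig.
    """
    seq = genome[chrom]
    if strand == "+":
        return seq[max(pos - 1, 0): pos - 1 + length]
    stop = pos
    start = max(pos - length, 0)
    return revcomp(seq[start:stop])


def offset_from_anchor(pos: int, anchor: int, strand: str) -> int:
    """Offset of ``pos`` relative to an anchor base with anchor = +1 and no offset 0.

    The base immediately 5' (upstream in transcription direction) of the anchor
    is -1.
    """
    d = pos - anchor if strand == "+" else anchor - pos
    return d + 1 if d >= 0 else d


def pos_at_offset(anchor: int, strand: str, offset: int) -> int:
    """Inverse of :func:`offset_from_anchor`."""
    if offset == 0:
        raise ValueError("offset 0 does not exist in this convention")
    d = offset - 1 if offset > 0 else offset
    return anchor + d if strand == "+" else anchor - d


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; entries whose window is incomplete are returned
    unsmoothed (callers flag them)."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    v = np.asarray(values, dtype=float)
    half = window // 2
    out = v.copy()
    if len(v) >= window:
        kernel = np.ones(window) / window
        core = np.convolve(v, kernel, mode="valid")
        out[half: half + len(core)] = core
    return out
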