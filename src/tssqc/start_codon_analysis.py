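"""Relate individual TSSs to annotated start codons.

Offsets use the convention A of the annotated ATG = +1 and the base
immediately 5' of it = -1; there is no offset 0.  TSSs within -200..+100 of
an ORF's ATG are analysed: for each, the two next downstream ATGs (the scan
includes the TSS base itself) and their reading frames decide the isoform
class:

* ``ANNOTATED_FIRST`` — TSS upstream of the ATG and the annotated ATG is
  the first one encountered (a canonical mRNA 5' end);
* ``UORF`` — TSS upstream but another ATG precedes the annotated one (the
  transcript carries an upstream ORF, a canonical NMD trigger);
* ``ITSS_INFRAME`` / ``ITSS_OUTFRAME`` — TSS at or downstream of the ATG
  (an internal TSS); the first downstream ATG is in / out of the annotated
  reading frame.  Out-of-frame first ATGs give a short spurious ORF and a
  long 3'-UTR, i.e. an NMD substrate; in-frame ones would make N-terminally
  truncated protein.

The module also provides ATG-anchored metagene profiles, per-offset group
comparisons, the in-frame codon-bias profile along gene bodies (the
statistic showing depletion of +1-frame ATGs at the start of iTSS-carrying
genes), per-residue methionine frequencies, and first-ORF/3'-UTR sizes for
pervasive transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import moving_average, offset_from_anchor, pos_at_offset, sense_slice

DEFAULT_WINDOW = (-200, 100)

ICLASSES = ("ANNOTATED_FIRST", "UORF", "ITSS_INFRAME", "ITSS_OUTFRAME", "NO_ATG_FOUND")


@dataclass
class IsoformCall:
    chrom: str
    pos: int
    strand: str
    gene_id: str
    offset: int
    atg1_offset: int | None
    atg2_offset: int | None
    atg1_inframe: bool | None
    iclass: str


def _shift(off: int, delta: int) -> int:
    """Advance an ATG-anchored offset ``delta`` nt downstream, skipping 0."""
    if off > 0:
        return off + delta
    return off + delta if off + delta < 0 else off + delta + 1


def default_search_limit(gene, tss_pos: int) -> int:
    """Scan length: to 1000 nt past the CDS stop or the transcript 3' end,
    whichever comes first."""
    if gene.strand == "+":
        stop_end = gene.cds_end
        limit_end = min(stop_end + 1000, gene.tx_end)
        return max(limit_end - tss_pos + 1, 3)
    stop_end = gene.cds_start
    limit_end = max(stop_end - 1000, gene.tx_start)
    return max(tss_pos - limit_end + 1, 3)


def call_isoform(tss: tuple[str, int, str], gene, genome: dict[str, str],
                 search_limit: int | None = None,
                 window: tuple[int, int] = DEFAULT_WINDOW) -> IsoformCall | None:
    """Classify one TSS against its gene's ATG; None if outside the window."""
    chrom, pos, strand = tss
    off = offset_from_anchor(pos, gene.atg_pos, strand)
    lo, hi = window
    if not lo <= off <= hi:
        return None
    limit = search_limit if search_limit is not None else default_search_limit(gene, pos)
    seq = sense_slice(genome, chrom, strand, pos, limit)
    hits = []
    i = seq.find("ATG")
    while i >= 0 and len(hits) < 2:
        hits.append(_shift(off, i))
        i = seq.find("ATG", i + 1)
    atg1 = hits[0] if hits else None
    atg2 = hits[1] if len(hits) > 1 else None
    inframe = None if atg1 is None else (atg1 - 1) % 3 == 0
    if atg1 is None:
        iclass = "NO_ATG_FOUND"
    elif off < 1:
        iclass = "ANNOTATED_FIRST" if atg1 == 1 else "UORF"
    else:
        iclass = "ITSS_INFRAME" if inframe else "ITSS_OUTFRAME"
    return IsoformCall(chrom, pos, strand, gene.id, off, atg1, atg2, inframe, iclass)


def isoform_calls(tracks, genes, genome: dict[str, str],
                  window: tuple[int, int] = DEFAULT_WINDOW) -> pd.DataFrame:
    """Classify every observed TSS in the ATG window of every gene.

    Returns one row per (gene, TSS position) with the call fields plus one
    read-count column per sample.
    """
    sample_ids = [t.sample_id for t in tracks]
    rows = []
    for g in genes:
        if g.fclass != "ORF" or g.dubious:
            continue
        atg = g.atg_pos
        for off in range(window[0], window[1] + 1):
            if off == 0:
                continue
            pos = pos_at_offset(atg, g.strand, off)
            counts = [t.get(g.chrom, g.strand, pos) for t in tracks]
            if not any(counts):
                continue
            call = call_isoform((g.chrom, pos, g.strand), g, genome, window=window)
            if call is None:
                continue
            rows.append([g.id, g.chrom, g.strand, pos, call.offset, call.atg1_offset,
                         call.atg2_offset, call.atg1_inframe, call.iclass] + counts)
    cols = ["gene_id", "chrom", "strand", "pos", "offset", "atg1_offset",
            "atg2_offset", "atg1_inframe", "iclass"] + sample_ids
    return pd.DataFrame(rows, columns=cols)


def gene_itss_status(calls: pd.DataFrame, sample_ids: list[str],
                     min_itss_reads: int = 4, itss_max_offset: int = 100,
                     diffres: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene iTSS status and class read summaries.

    A gene has iTSSs when its summed read count at offsets >= +1 (up to
    ``itss_max_offset``) reaches ``min_itss_reads``.  When ``diffres`` (a
    differential-test table indexed by (chrom, strand, pos) with a
    ``significant`` column) is given, per-gene flags report whether any
    uORF-class or out-of-frame-iTSS-class TSS is significantly stabilised.
    """
    df = calls.copy()
    df["reads"] = df[sample_ids].sum(axis=1)
    is_itss = (df["offset"] >= 1) & (df["offset"] <= itss_max_offset)
    sig = None
    if diffres is not None:
        keys = list(zip(df["chrom"], df["strand"], df["pos"]))
        sig = pd.Series(
            [bool(diffres["significant"].get(k, False)) for k in keys], index=df.index)

    out = []
    for gene_id, sub in df.groupby("gene_id", sort=True):
        m_itss = is_itss.loc[sub.index]
        itss_reads = int(sub.loc[m_itss, "reads"].sum())
        uorf_mask = sub["iclass"] == "UORF"
        outframe_mask = sub["iclass"] == "ITSS_OUTFRAME"
        row = {
            "gene_id": gene_id,
            "itss_reads": itss_reads,
            "has_itss": itss_reads >= min_itss_reads,
            "uorf_reads": int(sub.loc[uorf_mask, "reads"].sum()),
            "itss_outframe_reads": int(sub.loc[outframe_mask & m_itss, "reads"].sum()),
        }
        if sig is not None:
            s = sig.loc[sub.index]
            row["uorf_significant"] = bool((s & uorf_mask).any())
            row["itss_outframe_significant"] = bool((s & outframe_mask & m_itss).any())
        out.append(row)
    return pd.DataFrame(out).set_index("gene_id")


# ---------------------------------------------------------------------------
# metagene profiles


def metagene_profile(tracks, genes, genome: dict[str, str],
                     window: tuple[int, int] = (-200, 200), smooth: int = 11,
                     mode: str = "reads"):
    """ATG-anchored cumulative per-offset series, one column per sample.

    ``mode="reads"`` sums read counts, ``mode="tss_count"`` counts distinct
    TSS positions.  The series is smoothed with a centred ``smooth``-nt
    moving average; offsets whose smoothing window is incomplete are emitted
    unsmoothed and flagged.  Genes whose window leaves the contig are
    skipped (and counted).
    """
    if mode not in ("reads", "tss_count"):
        raise ValueError("mode must be 'reads' or 'tss_count'")
    lo, hi = window
    offsets = [o for o in range(lo, hi + 1) if o != 0]
    idx = {o: i for i, o in enumerate(offsets)}
    raw = {t.sample_id: np.zeros(len(offsets)) for t in tracks}
    skipped = 0
    for g in genes:
        if g.fclass != "ORF" or g.dubious:
            continue
        atg = g.atg_pos
        pa = pos_at_offset(atg, g.strand, lo)
        pb = pos_at_offset(atg, g.strand, hi)
        if min(pa, pb) < 1 or max(pa, pb) > len(genome[g.chrom]):
            skipped += 1
            continue
        for t in tracks:
            counter = t.counts.get((g.chrom, g.strand))
            if not counter:
                continue
            arr = raw[t.sample_id]
            for o in offsets:
                n = counter.get(pos_at_offset(atg, g.strand, o), 0)
                if n:
                    arr[idx[o]] += n if mode == "reads" else 1
    half = smooth // 2
    flags = np.zeros(len(offsets), dtype=bool)
    if smooth > 1:
        flags[:half] = True
        flags[len(offsets) - half:] = True
    data = {s: moving_average(v, smooth) for s, v in raw.items()}
    df = pd.DataFrame(data, index=pd.Index(offsets, name="offset"))
    df.attrs["skipped_genes"] = skipped
    df.attrs["unsmoothed"] = flags.tolist()
    raw_df = pd.DataFrame(raw, index=df.index)
    return df, raw_df


def positionwise_ratio_test(values_a: pd.DataFrame, values_b: pd.DataFrame,
                            pooled_interval: tuple[int, int] | None = None):
    """Per-offset one-way ANOVA between two groups of per-gene values.

    ``values_a`` / ``values_b``: genes x offsets.  With two groups the F
    test equals a pooled-variance two-sample t test.  Returns (Series of p
    per offset, pooled p over ``pooled_interval`` or None).
    """
    offsets = values_a.columns.intersection(values_b.columns)
    ps = {}
    for o in offsets:
        a = values_a[o].dropna().to_numpy()
        b = values_b[o].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            ps[o] = np.nan
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            ps[o] = 1.0
            continue
        ps[o] = stats.f_oneway(a, b).pvalue
    series = pd.Series(ps).sort_index()
    pooled = None
    if pooled_interval is not None:
        lo, hi = pooled_interval
        sel = [o for o in offsets if lo <= o <= hi]
        a = values_a[sel].to_numpy().ravel()
        b = values_b[sel].to_numpy().ravel()
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) > 1 and len(b) > 1 and np.ptp(np.concatenate([a, b])) > 0:
            pooled = float(stats.f_oneway(a, b).pvalue)
    return series, pooled


# ---------------------------------------------------------------------------
# codon and methionine bias


@dataclass
class CodonBiasProfile:
    gene_set_id: str
    codon: str
    bin_width: int
    bin_starts: np.ndarray          # first offset of each bin (+1-based, no 0 issue: all > 3)
    inframe: np.ndarray             # in-frame occurrence count per bin
    total: np.ndarray               # all occurrences per bin
    series: np.ndarray              # proportion in-frame per bin (nan if empty)
    normalized_series: np.ndarray   # log2(series / mean over the reference region)


def inframe_codon_bias(genes, genome: dict[str, str], codon: str = "ATG",
                       bin_width: int = 9, span: int = 1000,
                       ref_region: tuple[int, int] = (500, 1000),
                       gene_set_id: str = "genes") -> CodonBiasProfile:
    """Proportion of in-frame occurrences of a codon along gene bodies.

    Occurrences are counted at every offset o in [+4, +span] (the start
    codon itself is excluded); an occurrence is in frame when (o-1) % 3 == 0.
    The normalised series divides by the mean proportion over the reference
    region, where codon use is assumed frame-biased only by the genetic
    code, not by start-proximal selection.
    """
    bin_starts = np.arange(4, span + 1, bin_width)
    nb = len(bin_starts)
    inframe = np.zeros(nb)
    total = np.zeros(nb)
    for g in genes:
        cds_len = g.cds_end - g.cds_start + 1
        seq = sense_slice(genome, g.chrom, g.strand, g.atg_pos, min(cds_len, span + len(codon) - 1))
        i = seq.find(codon)
        while i >= 0:
            o = i + 1  # offset of the occurrence start, A of ATG = +1
            if 4 <= o <= span:
                b = (o - 4) // bin_width
                total[b] += 1
                if (o - 1) % 3 == 0:
                    inframe[b] += 1
            i = seq.find(codon, i + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        series = np.where(total > 0, inframe / np.maximum(total, 1), np.nan)
    lo, hi = ref_region
    ref_mask = (bin_starts >= lo) & (bin_starts <= hi)
    ref_mean = np.nanmean(series[ref_mask]) if ref_mask.any() else np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.log2(series / ref_mean)
    return CodonBiasProfile(gene_set_id, codon, bin_width, bin_starts,
                            inframe, total, series, norm)


def codon_bias_anova(profile_a: CodonBiasProfile, profile_b: CodonBiasProfile,
                     region: tuple[int, int] = (4, 100)) -> float:
    """One-way ANOVA on per-bin in-frame proportions between two gene sets
    over a start-proximal region (default: the first 100 nt)."""
    lo, hi = region
    mask_a = (profile_a.bin_starts >= lo) & (profile_a.bin_starts <= hi)
    mask_b = (profile_b.bin_starts >= lo) & (profile_b.bin_starts <= hi)
    a = profile_a.series[mask_a]
    b = profile_b.series[mask_b]
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    return float(stats.f_oneway(a, b).pvalue)


def codon_bias_gene_anova(genes_a, genes_b, genome: dict[str, str],
                          codon: str = "ATG",
                          region: tuple[int, int] = (4, 100)) -> float:
    """One-way ANOVA between gene sets on per-gene in-frame codon counts.

    Each gene contributes its count of in-frame occurrences of ``codon``
    (offsets o in the region with (o-1) % 3 == 0; the start codon itself is
    excluded by the region default).  Genes are the observations, so the
    comparison keeps its power at moderate set sizes where the per-bin
    proportions of :func:`inframe_codon_bias` are binomial-noise limited.
    """
    lo, hi = region

    def counts(genes):
        out = []
        for g in genes:
            cds_len = g.cds_end - g.cds_start + 1
            seq = sense_slice(genome, g.chrom, g.strand, g.atg_pos,
                              min(cds_len, hi + len(codon) - 1))
            n = 0
            i = seq.find(codon)
            while i >= 0:
                o = i + 1
                if lo <= o <= hi and (o - 1) % 3 == 0:
                    n += 1
                i = seq.find(codon, i + 1)
            out.append(n)
        return np.asarray(out, dtype=float)

    a, b = counts(genes_a), counts(genes_b)
    if len(a) < 2 or len(b) < 2 or np.ptp(np.concatenate([a, b])) == 0:
        return float("nan")
    return float(stats.f_oneway(a, b).pvalue)


def proteins_from_genes(genes, genome: dict[str, str]) -> list[str]:
    """Translate CDS sequences (stop codon dropped)."""
    from Bio.Seq import Seq

    prots = []
    for g in genes:
        cds = sense_slice(genome, g.chrom, g.strand, g.atg_pos,
                          g.cds_end - g.cds_start + 1)
        prots.append(str(Seq(cds).translate()).rstrip("*"))
    return prots


def met_frequency(proteins: list[str], max_pos: int = 334) -> np.ndarray:
    """Frequency of methionine at residue positions 2..max_pos.

    The initiator methionine (residue 1) is omitted.  Entry i of the result
    is the frequency at residue i + 2 among proteins long enough to have
    that residue.
    """
    if not proteins:
        raise ValueError("empty protein set")
    freq = np.full(max_pos - 1, np.nan)
    for i, residue in enumerate(range(2, max_pos + 1)):
        have = [p for p in proteins if len(p) >= residue]
        if have:
            freq[i] = sum(p[residue - 1] == "M" for p in have) / len(have)
    return freq


def met_frequency_anova(freq_a: np.ndarray, freq_b: np.ndarray,
                        residues: tuple[int, int] = (2, 34)) -> float:
    """ANOVA on per-residue Met frequencies between two sets over a residue
    range (default residues 2..34, i.e. the first ~100 nt of coding sequence)."""
    lo, hi = residues
    sl = slice(lo - 2, hi - 1)
    a, b = freq_a[sl], freq_b[sl]
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    return float(stats.f_oneway(a, b).pvalue)


# ---------------------------------------------------------------------------
# spurious ORFs of pervasive transcripts


@dataclass
class SpuriousOrf:
    orf_length_aa: int
    utr3_length_nt: int
    no_atg: bool = False
    truncated: bool = False


def spurious_orf_metrics(feature, genome: dict[str, str]) -> SpuriousOrf:
    """First-ORF length and 3'-UTR length of a transcript.

    The first ATG at or after the transcript 5' end opens the ORF; the first
    in-frame stop closes it (length in aa excludes the stop).  Without an
    ATG the result is (0, transcript length), flagged; without an in-frame
    stop the ORF is truncated at the transcript end, flagged.
    """
    tx_len = feature.tx_end - feature.tx_start + 1
    seq = sense_slice(genome, feature.chrom, feature.strand, feature.five_prime, tx_len)
    i = seq.find("ATG")
    if i < 0:
        return SpuriousOrf(0, tx_len, no_atg=True)
    stops = {"TAA", "TAG", "TGA"}
    j = i
    while j + 3 <= len(seq):
        if seq[j:j + 3] in stops:
            return SpuriousOrf((j - i) // 3, len(seq) - (j + 3))
        j += 3
    return SpuriousOrf((len(seq) - i) // 3, 0, truncated=True)


def expressed_genes(tsscs) -> set[str]:
    """Genes with at least one passing O-category cluster."""
    return {t.feature_id for t in tsscs
            if t.category == "O" and t.passed and t.feature_id}
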