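"""Cluster quality filters, size-factor normalisation, a simplified
negative-binomial differential test, and the TAP/no-TAP false-discovery bound.

Two filters remove false-positive clusters:

* **SNR** — log2 of the (normalised) TAP over no-TAP read count of the
  cluster; capped 5' ends require TAP treatment for ligation, so genuine
  TSSs are strongly TAP-enriched.  The default limit is 0.55 (inclusive),
  with a pseudocount of 1 on both totals so zero-background clusters pass.
* **TSS accuracy** — the proportion of member positions (unique TSSs, not
  reads) that sit on a purine preceded by a pyrimidine, the invariant core
  of the initiation consensus; default minimum 0.80.

Size factors use the median-of-ratios estimator on a set of standard units:
either the per-ORF read counts in the window 50 to 10 nt upstream of each
non-dubious ATG (internal mode) or per-unit spike-in counts (spike-in mode).

The differential test is a deliberately simplified negative-binomial Wald
test: per-unit dispersions are estimated by method of moments, shrunk in
log space toward a fitted mean-dispersion trend a0 + a1/mu, and the Wald
statistic on the log2 fold change of normalised means is referred to a t
distribution with the within-condition degrees of freedom.  p-values are
Benjamini-Hochberg adjusted.  Full DESeq2 machinery (Cox-Reid dispersions,
shrunken fold changes, outlier handling) is intentionally out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import PURINES, PYRIMIDINES, base_at, downstream


@dataclass
class FilterVerdict:
    tssc_id: str
    snr: float
    accuracy: float
    passed: bool


SNR_MIN_DEFAULT = 0.55
ACC_MIN_DEFAULT = 0.80


# ---------------------------------------------------------------------------
# filters


def snr_filter(tap_total: float, notap_total: float, snr_min: float = SNR_MIN_DEFAULT,
               pseudocount: float = 1.0) -> tuple[float, bool]:
    """Signal-to-noise ratio of a cluster and whether it passes.

    ``snr = log2((tap + pc) / (notap + pc))`` on size-factor-normalised
    totals; the limit is inclusive.
    """
    if tap_total < 0 or notap_total < 0:
        raise ValueError("totals must be non-negative")
    snr = math.log2((tap_total + pseudocount) / (notap_total + pseudocount))
    return snr, snr >= snr_min


def position_conforms(genome: dict[str, str], chrom: str, strand: str, pos: int) -> bool:
    """Purine at the position, pyrimidine immediately 5' (transcription sense).

    Positions at a contig edge count as non-conforming.
    """
    b = base_at(genome, chrom, strand, pos)
    prev = base_at(genome, chrom, strand, downstream(pos, strand, -1))
    return b in PURINES and prev in PYRIMIDINES


def accuracy_filter(tssc, genome: dict[str, str], acc_min: float = ACC_MIN_DEFAULT,
                    read_weighted: bool = False) -> tuple[float, bool]:
    """TSS accuracy of a cluster and whether it passes.

    Default counts unique member positions, unweighted by reads; with
    ``read_weighted=True`` each position is weighted by its pooled count.
    """
    pooled = tssc.pooled_counts()
    num = den = 0.0
    for p in tssc.positions:
        w = pooled[p] if read_weighted else 1
        den += w
        if position_conforms(genome, tssc.chrom, tssc.strand, p):
            num += w
    acc = num / den if den else 0.0
    return acc, acc >= acc_min


def apply_filters(tsscs, genome, tap_totals: dict[str, float], notap_totals: dict[str, float],
                  snr_min: float = SNR_MIN_DEFAULT, acc_min: float = ACC_MIN_DEFAULT,
                  pseudocount: float = 1.0, read_weighted: bool = False) -> list[FilterVerdict]:
    """Run both filters over a cluster list; records verdicts on the clusters.

    ``tap_totals`` / ``notap_totals`` map cluster id -> normalised total.
    The filters are independent, order-free and idempotent.
    """
    verdicts = []
    for t in tsscs:
        snr, ok_snr = snr_filter(tap_totals.get(t.id, 0.0), notap_totals.get(t.id, 0.0),
                                 snr_min, pseudocount)
        acc, ok_acc = accuracy_filter(t, genome, acc_min, read_weighted)
        t.snr, t.accuracy, t.passed = snr, acc, ok_snr and ok_acc
        verdicts.append(FilterVerdict(t.id, snr, acc, t.passed))
    return verdicts


# ---------------------------------------------------------------------------
# normalisation


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from a (standard units x samples) matrix.

    factor_j = median over units u of count[u, j] / geometric_mean_s(count[u, s]);
    units whose geometric mean is zero are excluded.  Normalised counts are
    raw / factor.
    """
    m = count_matrix.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(m)
    usable = np.all(np.isfinite(logs), axis=1)
    if not usable.any():
        raise ValueError("no usable standard: every unit has a zero count")
    geo = np.exp(logs[usable].mean(axis=1))
    ratios = m[usable] / geo[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=count_matrix.columns, name="size_factor")


def internal_standard_counts(tracks, features, window: tuple[int, int] = (-50, -10)) -> pd.DataFrame:
    """Per-ORF TSS read counts in a window upstream of the ATG, per sample.

    The window is in ATG-anchored offsets (A of ATG = +1, no offset 0);
    default -50..-10.  Dubious ORFs are excluded.  Rows: ORF ids, columns:
    sample ids.
    """
    from ._util import pos_at_offset

    lo, hi = window
    orfs = [f for f in features if f.fclass == "ORF" and not f.dubious]
    data = {}
    for tr in tracks:
        col = []
        for f in orfs:
            atg = f.atg_pos
            s = 0
            for off in range(lo, hi + 1):
                if off == 0:
                    continue
                s += tr.get(f.chrom, f.strand, pos_at_offset(atg, f.strand, off))
            col.append(s)
        data[tr.sample_id] = col
    return pd.DataFrame(data, index=[f.id for f in orfs])


def spikein_counts(tracks, spike_prefix: str = "spombe") -> pd.DataFrame:
    """Per-position spike-in counts (rows: spike positions, columns: samples).

    Any position on a spike-in chromosome observed in any sample is a
    standard unit; median-of-ratios then ignores units with zero geometric
    mean, so sample-specific dropouts are harmless.
    """
    rows: dict[tuple, dict[str, int]] = {}
    for tr in tracks:
        for (chrom, strand), counter in tr.counts.items():
            if not chrom.startswith(spike_prefix):
                continue
            for pos, n in counter.items():
                rows.setdefault((chrom, strand, pos), {})[tr.sample_id] = n
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
    return df.reindex(columns=[t.sample_id for t in tracks], fill_value=0)


def masked_total(track, mask: list[tuple[str, int, int]] | None = None,
                 exclude_prefix: str | None = None) -> int:
    """Total track count excluding masked intervals (1-based inclusive,
    both strands) and, optionally, chromosomes with a given prefix
    (e.g. the spike-in species)."""
    mask = mask or []
    total = 0
    for (chrom, _strand), counter in track.counts.items():
        if exclude_prefix and chrom.startswith(exclude_prefix):
            continue
        ivals = [(a, b) for c, a, b in mask if c == chrom]
        for pos, n in counter.items():
            if any(a <= pos <= b for a, b in ivals):
                continue
            total += n
    return total


# ---------------------------------------------------------------------------
# differential expression


def _trend_fit(mean: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mean over informative units."""
    ok = (mean > 0) & (alpha > 1e-8) & np.isfinite(alpha)
    if ok.sum() < 10:
        a0 = float(np.median(alpha[alpha > 0])) if (alpha > 0).any() else 0.1
        return max(a0, 1e-4), 0.0
    x = 1.0 / mean[ok]
    y = alpha[ok]
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a0 = max(float(coef[0]), 1e-4)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def diff_expression(count_matrix: pd.DataFrame, factors: pd.Series,
                    conditions: dict[str, str], contrast: tuple[str, str],
                    alpha: float = 0.05, dispersion_mode: str = "trended",
                    prior_dispersion: float = 0.1) -> pd.DataFrame:
    """Negative-binomial Wald test of ``contrast[1]`` vs ``contrast[0]``.

    ``count_matrix`` holds raw counts (units x samples), ``factors`` the
    size factors, ``conditions`` maps sample -> condition.  Returns a frame
    with baseMean, log2fc, pvalue, padj and ``significant`` (padj < alpha
    and log2fc > 0, i.e. "significantly stabilised").

    ``dispersion_mode``: "trended" (moment estimates shrunk toward the
    fitted trend; default), "per_unit" (raw moment estimates) or "fixed"
    (use ``prior_dispersion``).  With single-replicate conditions the prior
    dispersion is used regardless.
    """
    ref, alt = contrast
    s_ref = [s for s in count_matrix.columns if conditions.get(s) == ref]
    s_alt = [s for s in count_matrix.columns if conditions.get(s) == alt]
    if not s_ref or not s_alt:
        raise ValueError(f"degenerate design: need samples for both {ref!r} and {alt!r}")
    if dispersion_mode not in ("trended", "per_unit", "fixed"):
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")

    q = count_matrix / factors
    q1 = q[s_ref].to_numpy(dtype=float)
    q2 = q[s_alt].to_numpy(dtype=float)
    n1, n2 = q1.shape[1], q2.shape[1]
    m1, m2 = q1.mean(axis=1), q2.mean(axis=1)
    base_mean = np.concatenate([q1, q2], axis=1).mean(axis=1)

    if n1 < 2 or n2 < 2 or dispersion_mode == "fixed":
        disp = np.full(len(q), prior_dispersion)
    else:
        ss = q1.var(axis=1, ddof=1) * (n1 - 1) + q2.var(axis=1, ddof=1) * (n2 - 1)
        pooled_var = ss / (n1 + n2 - 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            mom = (pooled_var - base_mean) / np.square(base_mean)
        mom = np.where(np.isfinite(mom), mom, 0.0)
        mom = np.clip(mom, 1e-8, 10.0)
        if dispersion_mode == "per_unit":
            disp = mom
        else:
            a0, a1 = _trend_fit(base_mean, mom)
            trend = a0 + a1 / np.maximum(base_mean, 1e-8)
            # geometric shrinkage toward the trend; moment estimates are
            # clamped within 8x of the trend first so that units whose sample
            # variance fell below Poisson do not collapse the estimate
            clamped = np.clip(mom, trend / 8.0, trend * 8.0)
            disp = np.exp(0.5 * np.log(clamped) + 0.5 * np.log(trend))

    eps = 0.5  # moderates fold changes and Wald SEs for zero means
    log2fc = np.log2((m2 + eps) / (m1 + eps))
    var_ln = ((1.0 / (m1 + eps) + disp) / n1) + ((1.0 / (m2 + eps) + disp) / n2)
    se_lfc = np.sqrt(var_ln) / math.log(2)
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = np.where(se_lfc > 0, log2fc / se_lfc, 0.0)
    df = max(n1 + n2 - 2, 1)
    pvalue = 2.0 * stats.t.sf(np.abs(wald), df)
    tested = (base_mean > 0)
    pvalue = np.where(tested, pvalue, 1.0)
    padj = np.ones_like(pvalue)
    if tested.any():
        padj[tested] = stats.false_discovery_control(pvalue[tested], method="bh")

    out = pd.DataFrame({
        "baseMean": base_mean,
        "log2fc": log2fc,
        "pvalue": pvalue,
        "padj": padj,
        "significant": (padj < alpha) & (log2fc > 0),
    }, index=count_matrix.index)
    out.index.name = "unit_id"
    return out


# ---------------------------------------------------------------------------
# method false-discovery bound


def fdr_upper_bound(tap_reads: float, notap_reads: float) -> float:
    """Upper bound (percent) on the TSS false-discovery rate.

    The ratio of no-TAP to TAP read totals (post-normalisation,
    rDNA-excluded): reads obtained without the cap-dependent ligation step
    bound the fraction of TAP-library reads not marking genuine capped ends.
    """
    if tap_reads <= 0:
        raise ValueError("tap_reads must be positive")
    if notap_reads < 0:
        raise ValueError("notap_reads must be non-negative")
    return 100.0 * notap_reads / tap_reads


def percent(part: float, whole: float) -> float:
    """Plain percentage part/whole * 100 (whole must be positive)."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return 100.0 * part / whole
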