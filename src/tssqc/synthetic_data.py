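"""Two-species synthetic TSS-seq dataset with full ground truth.

The generator emulates the statistical structure a 5'-cap-selective TSS
sequencing experiment on budding-yeast RNA-quality-control mutants assumes:

* a genome in which every planned TSS sits on the yeast initiation consensus
  (A at -8, pyrimidine at -1, purine at +1: A(N)6PyPu);
* protein-coding genes with a major TSS ~30 nt upstream of the ATG plus minor
  upstream (uORF-generating) and internal (iTSS) isoforms;
* pervasive transcripts (CUT/XUT/SUT-like) whose first ORF is a fixed 14
  codons followed by a long 3' remainder, i.e. canonical NMD-substrate shape;
* condition-specific multiplicative stabilisation of transcript classes
  (rrp6-delta-like acting on CUTs, upf1-delta-like on XUT/SUT and on
  uORF/iTSS isoforms);
* tagged raw reads (4-nt UMI + CGCG + CG + 2 random nt), TAP vs no-TAP
  libraries, PCR duplicates, a second-species spike-in at fixed proportion,
  "slippery" PyAAA starts emitting a non-templated A, and nucleosome-free
  regions at promoters.

Every emitted read is attributed to exactly one ground-truth source so the
analysis modules can be scored against the simulation.

Each planned TSS is emitted as a compact block of closely spaced consensus
positions (8 for major TSSs, 4 for minor isoforms) rather than a single
genomic base: real TSS clusters consist of several closely spaced 5' ends,
and the unweighted TSS-accuracy filter downstream presupposes that structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import revcomp

# ---------------------------------------------------------------------------
# configuration

BASES = "ACGT"
#: effect-matrix column names: annotated feature classes plus the two minor
#: mRNA isoform classes that respond to NMD inactivation.
EFFECT_CLASSES = ("ORF", "CUT", "XUT", "SUT", "NCRNA", "UORF", "ITSS")

TAG_UMI5 = 4          # leading random nt of the ligated oligo
TAG_FIXED = "CGCGCG"  # fixed block: CGCG + rCrG of the tag
TAG_UMI3 = 2          # trailing random (ribo) nt
TAG_LEN = TAG_UMI5 + len(TAG_FIXED) + TAG_UMI3


def default_effect_matrix() -> dict[str, dict[str, float]]:
    """Stabilisation fold-changes per condition and transcript class.

    Wild type is the reference (all ones).  The rrp6-delta-like condition
    stabilises CUTs strongly; the upf1-delta-like condition stabilises
    XUT/SUT pervasive transcripts and the uORF/iTSS minor mRNA isoforms;
    the double mutant combines both.  Annotated-first mRNA isoforms and
    stable ncRNAs are unaffected everywhere.
    """
    base = {c: 1.0 for c in EFFECT_CLASSES}
    wt = dict(base)
    upf1 = dict(base, XUT=8.0, SUT=8.0, CUT=1.5, UORF=4.0, ITSS=4.0)
    rrp6 = dict(base, CUT=8.0, XUT=1.5, SUT=1.5)
    upf1_rrp6 = dict(base, CUT=8.0, XUT=8.0, SUT=8.0, UORF=4.0, ITSS=4.0)
    return {"wt": wt, "upf1": upf1, "rrp6": rrp6, "upf1_rrp6": upf1_rrp6}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the default study conditions: four genotypes in three
    replicates, ~40 expected unique reads per major TSS block, mild PCR
    duplication, a 20% second-species spike-in and a 2% residual capped
    ligation rate in no-TAP libraries.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 140_000
    n_orfs: int = 200
    n_cuts: int = 40
    n_xuts: int = 40
    n_suts: int = 40
    n_ncrna: int = 20
    mean_expression: float = 40.0
    effect_matrix: dict[str, dict[str, float]] = field(default_factory=default_effect_matrix)
    n_replicates: int = 3
    uorf_isoform_frac: float = 0.10
    itss_isoform_frac: float = 0.10
    slippage_isoform_frac: float = 0.05
    slippage_gene_frac: float = 0.30
    capped_frac: float = 0.9975
    notap_residual: float = 0.02
    notap_condition: str = "upf1_rrp6"
    n_notap_replicates: int = 2
    pcr_dup_rate: float = 0.10
    slippage_prob: float = 0.5
    spikein_frac: float = 0.20
    nb_dispersion: float = 0.05
    inframe_atg_bias: float = 0.5
    biased_gene_frac: float = 0.5
    read_length: int = 40
    depth_range: tuple[float, float] = (0.7, 1.5)
    n_spike_transcripts: int = 160
    spike_chrom_length: int = 45_000

    def validate(self) -> None:
        fracs = {
            "uorf_isoform_frac": self.uorf_isoform_frac,
            "itss_isoform_frac": self.itss_isoform_frac,
            "slippage_isoform_frac": self.slippage_isoform_frac,
            "slippage_gene_frac": self.slippage_gene_frac,
            "capped_frac": self.capped_frac,
            "notap_residual": self.notap_residual,
            "pcr_dup_rate": self.pcr_dup_rate,
            "slippage_prob": self.slippage_prob,
            "spikein_frac": self.spikein_frac,
            "inframe_atg_bias": self.inframe_atg_bias,
            "biased_gene_frac": self.biased_gene_frac,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.chrom_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.mean_expression <= 0 or self.nb_dispersion <= 0:
            raise ValueError("mean_expression and nb_dispersion must be positive")
        if self.pcr_dup_rate >= 0.5:
            raise ValueError("pcr_dup_rate must be < 0.5")
        if self.uorf_isoform_frac + self.itss_isoform_frac + self.slippage_isoform_frac >= 1:
            raise ValueError("isoform fractions must sum to < 1")
        for cond, row in self.effect_matrix.items():
            for cls, v in row.items():
                if cls not in EFFECT_CLASSES:
                    raise ValueError(f"unknown effect class {cls!r} in condition {cond!r}")
                if v <= 0:
                    raise ValueError(f"effect_matrix[{cond}][{cls}] must be > 0")

    @property
    def conditions(self) -> list[str]:
        return list(self.effect_matrix)


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class TrueTSS:
    """One planned TSS position and everything a read from it inherits."""

    tss_id: str
    feature_id: str
    chrom: str
    strand: str
    pos: int                      # 1-based initiation site (real start base)
    isoform_role: str             # major | uorf | itss | slippage
    basal_share: float            # share of the feature's wild-type expression
    effect_class: str             # column of the effect matrix
    slippage: bool = False        # PyAAA site: reads may map 1 nt upstream
    condition_means: dict[str, float] = field(default_factory=dict)
    iclass_truth: str = ""        # scan-derived isoform class (ORF genes only)
    atg_offset: int = 0           # offset of the TSS from the gene ATG (ORF genes)


@dataclass
class GroundTruth:
    true_tss: list[TrueTSS] = field(default_factory=list)
    true_fold_changes: dict[tuple[str, str], float] = field(default_factory=dict)
    slippage_sites: list[tuple[str, str, int]] = field(default_factory=list)
    biased_gene_ids: list[str] = field(default_factory=list)
    spike_tss: list[TrueTSS] = field(default_factory=list)


@dataclass
class SimRead:
    read_id: str
    chrom: str
    strand: str
    pos: int          # 1-based genomic coordinate of the transcript 5'-most base
    umi: str
    seq: str          # transcription-sense RNA sequence after the tag
    source: str       # tss_id | "background" | "spike:<id>"
    duplicate: bool = False


@dataclass
class Sample:
    sample_id: str
    condition: str
    replicate: int
    tap: bool
    depth: float
    reads: list[SimRead] = field(default_factory=list)
    ledger: dict[str, int] = field(default_factory=dict)


@dataclass
class Simulation:
    config: SimConfig
    genome: dict[str, str]
    spike_genome: dict[str, str]
    features: list  # list[annotate_classify.Feature]; late import avoids a cycle
    truth: GroundTruth
    samples: list[Sample] = field(default_factory=list)
    nucleosome: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence building blocks

# Promoter template letters: offsets -8..(2*n_pos-2) relative to the first TSS
# of the block.  TSS positions are the even offsets 0, 2, ... 2*(n_pos-1); each
# has A at its -8, a pyrimidine (C) at its -1 and a purine (A) at +1.


def _tss_block_template(n_pos: int, fill: str = "C") -> tuple[str, list[int]]:
    """Return (template, tss_local_offsets) for a block of conforming TSSs.

    ``tss_local_offsets`` are 0-based offsets into the template string.
    """
    length = 8 + 2 * n_pos - 1
    letters = [fill] * length
    # A at -8 of each TSS: template index (tss_idx - 8) where tss_idx = 8 + 2k
    for k in range(n_pos):
        letters[2 * k] = "A"          # -8 of TSS k
        letters[8 + 2 * k] = "A"      # the TSS base itself (purine)
        if 8 + 2 * k - 1 >= 0:
            letters[8 + 2 * k - 1] = "C"  # -1 pyrimidine
    return "".join(letters), [8 + 2 * k for k in range(n_pos)]


MAJOR_BLOCK_N = 8
MINOR_BLOCK_N = 4
MAJOR_WEIGHTS = np.array([0.30, 0.20, 0.13, 0.10, 0.08, 0.07, 0.06, 0.06])
MINOR_WEIGHTS = np.array([0.40, 0.30, 0.20, 0.10])

_ACT_CODONS = [a + b + c for a in "ACT" for b in "ACT" for c in "ACT" if a + b + c != "TAA"]
_STOPS = {"TAA", "TAG", "TGA"}
_ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
_SENSE_CODONS = [c for c in _ALL_CODONS if c not in _STOPS]


def _rand_noatg(rng: np.random.Generator, n: int) -> str:
    """Random filler over {A,C,T}: cannot contain ATG (or any G)."""
    return "".join(np.array(list("ACT"))[rng.integers(0, 3, n)])


def _codon_probs(met_prob: float) -> np.ndarray:
    p = np.full(len(_SENSE_CODONS), (1.0 - met_prob) / (len(_SENSE_CODONS) - 1))
    p[_SENSE_CODONS.index("ATG")] = met_prob
    return p


_MET_PROB = 0.03  # baseline Met codon frequency in simulated gene bodies


def _sample_codons(rng: np.random.Generator, n: int, met_prob: float) -> list[str]:
    idx = rng.choice(len(_SENSE_CODONS), size=n, p=_codon_probs(met_prob))
    return [_SENSE_CODONS[i] for i in idx]


# ---------------------------------------------------------------------------
# genome and annotation generation


class PlacementError(RuntimeError):
    """Requested features cannot be placed on the configured genome."""


@dataclass
class _Slot:
    """A feature laid out in local transcription-sense coordinates."""

    feature_id: str
    fclass: str
    seq: str
    tx_local: tuple[int, int]              # 1-based inclusive local transcript bounds
    cds_local: tuple[int, int] | None      # ORFs: local A-of-ATG .. last stop base
    tss_blocks: list[tuple[str, list[int], np.ndarray, str]]
    # (role, local 1-based TSS positions, weights, effect_class)
    slippage_local: int | None = None      # local 1-based mapped-Py position


def _build_orf_slot(rng: np.random.Generator, fid: str, biased: bool,
                    slippage_gene: bool, cfg: SimConfig) -> _Slot:
    """Lay out one protein-coding gene in local coordinates.

    Local layout (1-based; L denotes template/segment lengths)::

        [pad 8][uORF TSS block][5'UTR filler + uORF + major TSS block][ATG..stop][3'UTR]

    Offsets relative to the A of the ATG (A = +1, no 0): uORF TSS block at
    -160..-154, optional slippage site at -120, uORF ATG at -100, major TSS
    block at -33..-19, internal TSS block at +52..+58.
    """
    n_codons = int(rng.integers(350, 421))     # body codons incl. none for stop
    utr5_len = 160                             # ATG offset -160 is the first TSS
    utr3_len = 100
    # local coordinate of the A of ATG: 8 nt pad upstream of the first TSS so
    # its -8 consensus base fits inside the slot.
    atg_local = 8 + utr5_len + 1
    total = 8 + utr5_len + 3 * (n_codons + 2) + utr3_len  # ATG + body + stop
    letters = list(_rand_noatg(rng, total))

    def put(local_start1: int, s: str) -> None:
        letters[local_start1 - 1: local_start1 - 1 + len(s)] = list(s)

    def off2loc(off: int) -> int:
        # offset +1 = atg_local, -1 = atg_local - 1 (no 0)
        return atg_local + off - 1 if off > 0 else atg_local + off

    # CDS: start ATG, body codons, stop
    met = _MET_PROB
    head = _sample_codons(rng, 33, met * (1.0 - cfg.inframe_atg_bias) if biased else met)
    tail = _sample_codons(rng, n_codons - 33, met)
    put(atg_local, "ATG" + "".join(head + tail) + "TAA")
    tx_end_local = atg_local + 3 * (n_codons + 2) - 1 + utr3_len

    blocks: list[tuple[str, list[int], np.ndarray, str]] = []
    # major TSS block at offsets -33..-19
    tpl, offs = _tss_block_template(MAJOR_BLOCK_N)
    start = off2loc(-33) - 8
    put(start, tpl)
    blocks.append(("major", [start + o for o in offs], MAJOR_WEIGHTS, "ORF"))
    # uORF isoform TSS block at offsets -160..-154
    tpl, offs = _tss_block_template(MINOR_BLOCK_N)
    start = off2loc(-160) - 8
    put(start, tpl)
    blocks.append(("uorf", [start + o for o in offs], MINOR_WEIGHTS, "UORF"))
    # the uORF itself: ATG at -100, 8 ACT-codons, TAA
    uorf_codons = [_ACT_CODONS[i] for i in rng.integers(0, len(_ACT_CODONS), 8)]
    put(off2loc(-100), "ATG" + "".join(uorf_codons) + "TAA")
    # internal TSS block at offsets +52..+58 (A/C letters: no stops, no ATG)
    tpl, offs = _tss_block_template(MINOR_BLOCK_N)
    start = off2loc(52) - 8
    put(start, tpl)
    blocks.append(("itss", [start + o for o in offs], MINOR_WEIGHTS, "ITSS"))

    slip_local = None
    if slippage_gene:
        # PyAAA site at offset -120: mapped pyrimidine, real start on the A at
        # -119, consensus A at -127 (i.e. -8 of the real start).
        q = off2loc(-120)
        put(q - 7, "A")
        put(q, "TAA")
        slip_local = q
        blocks.append(("slippage", [q + 1], np.array([1.0]), "UORF"))

    return _Slot(fid, "ORF", "".join(letters), (9, tx_end_local),
                 (atg_local, atg_local + 3 * (n_codons + 2) - 1), blocks, slip_local)


def _build_pervasive_slot(rng: np.random.Generator, fid: str, fclass: str) -> _Slot:
    """CUT/XUT/SUT/ncRNA slot: TSS block at the 5' end; for the unstable
    classes a fixed 14-codon first ORF followed by a long 3' remainder."""
    tpl, offs = _tss_block_template(MAJOR_BLOCK_N)
    head_pad = 8
    body: list[str] = []
    if fclass == "NCRNA":
        body.append(_rand_noatg(rng, 200))
    else:
        body.append(_rand_noatg(rng, 15))
        orf_codons = [_ACT_CODONS[i] for i in rng.integers(0, len(_ACT_CODONS), 13)]
        body.append("ATG" + "".join(orf_codons) + "TAA")   # 14 aa incl. Met
        body.append(_rand_noatg(rng, 250))
    seq = _rand_noatg(rng, head_pad) + tpl + "".join(body)
    # tpl[0] sits at local 1-based position head_pad+1; TSS k at tpl index offs[k]
    local_tss = [head_pad + o + 1 for o in offs]
    tx_start_local = local_tss[0]
    blocks = [("major", local_tss, MAJOR_WEIGHTS, fclass)]
    return _Slot(fid, fclass, seq, (tx_start_local, len(seq)), None, blocks, None)


def generate_genome_and_annotations(config: SimConfig):
    """Build the two genomes, the feature annotation and the truth skeleton.

    Returns ``(genome, spike_genome, features, truth)`` where ``features`` is a
    list of :class:`tssqc.annotate_classify.Feature` and ``truth`` carries one
    :class:`TrueTSS` per planned TSS position (condition means unfilled; see
    :func:`simulate_condition_expression`).
    """
    from .annotate_classify import Feature  # local import: avoids module cycle

    config.validate()
    rng = np.random.default_rng(config.seed)

    plan: list[tuple[str, str]] = []
    plan += [("ORF", f"ORF{i:04d}") for i in range(config.n_orfs)]
    plan += [("CUT", f"CUT{i:04d}") for i in range(config.n_cuts)]
    plan += [("XUT", f"XUT{i:04d}") for i in range(config.n_xuts)]
    plan += [("SUT", f"SUT{i:04d}") for i in range(config.n_suts)]
    plan += [("NCRNA", f"NCR{i:04d}") for i in range(config.n_ncrna)]
    rng.shuffle(plan)

    n_biased = int(round(config.n_orfs * config.biased_gene_frac))
    orf_ids = sorted(fid for cls, fid in plan if cls == "ORF")
    biased_ids = set(orf_ids[:n_biased])       # deterministic: first ids by name
    slip_ids = {fid for fid in orf_ids if rng.random() < config.slippage_gene_frac}

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_seqs = {c: list("".join(np.array(list(BASES))[rng.integers(0, 4, config.chrom_length)]))
                  for c in chrom_names}
    cursor = {c: 0 for c in chrom_names}

    features: list[Feature] = []
    truth = GroundTruth(biased_gene_ids=sorted(biased_ids))

    chrom_idx = 0
    for fclass, fid in plan:
        if fclass == "ORF":
            slot = _build_orf_slot(rng, fid, fid in biased_ids, fid in slip_ids, config)
        else:
            slot = _build_pervasive_slot(rng, fid, fclass)
        strand = "+" if rng.random() < 0.5 else "-"
        spacer = int(rng.integers(60, 200))
        L = len(slot.seq)
        placed = False
        for _ in range(len(chrom_names)):
            c = chrom_names[chrom_idx % len(chrom_names)]
            if cursor[c] + spacer + L + 10 <= config.chrom_length:
                g0 = cursor[c] + spacer          # 0-based slot start
                cursor[c] = g0 + L
                placed = True
                break
            chrom_idx += 1
        if not placed:
            raise PlacementError(
                f"cannot place {fid}: genome too small for the requested features")
        chrom_idx += 1

        local_seq = slot.seq if strand == "+" else revcomp(slot.seq)
        chrom_seqs[c][g0: g0 + L] = list(local_seq)

        def loc2gen(local1: int) -> int:
            return g0 + local1 if strand == "+" else g0 + L - local1 + 1

        lo, hi = slot.tx_local
        tx_a, tx_b = sorted((loc2gen(lo), loc2gen(hi)))
        cds_a = cds_b = None
        if slot.cds_local is not None:
            ca, cb = slot.cds_local
            cds_a, cds_b = sorted((loc2gen(ca), loc2gen(cb)))
        features.append(Feature(id=fid, fclass=fclass, chrom=c, strand=strand,
                                tx_start=tx_a, tx_end=tx_b,
                                cds_start=cds_a, cds_end=cds_b))
        if slot.slippage_local is not None:
            truth.slippage_sites.append((c, strand, loc2gen(slot.slippage_local)))

        for role, local_pos, weights, eclass in slot.tss_blocks:
            share = {"major": 1.0 - config.uorf_isoform_frac - config.itss_isoform_frac
                             - (config.slippage_isoform_frac if fid in slip_ids else 0.0),
                     "uorf": config.uorf_isoform_frac,
                     "itss": config.itss_isoform_frac,
                     "slippage": config.slippage_isoform_frac}[role]
            if fclass != "ORF":
                share = 1.0
            for k, (lp, w) in enumerate(zip(local_pos, weights)):
                truth.true_tss.append(TrueTSS(
                    tss_id=f"{fid}:{role}:{k}", feature_id=fid, chrom=c,
                    strand=strand, pos=loc2gen(lp), isoform_role=role,
                    basal_share=share * float(w), effect_class=eclass,
                    slippage=(role == "slippage")))

    genome = {c: "".join(s) for c, s in chrom_seqs.items()}

    # spike-in species: an independent genome with its own promoter blocks
    sp_rng = np.random.default_rng(config.seed + 7919)
    sp_seq = list("".join(np.array(list(BASES))[sp_rng.integers(0, 4, config.spike_chrom_length)]))
    spike_tss: list[TrueTSS] = []
    tpl, offs = _tss_block_template(MINOR_BLOCK_N)
    gap = max(1, (config.spike_chrom_length - 400) // max(config.n_spike_transcripts, 1))
    for i in range(config.n_spike_transcripts):
        g0 = 100 + i * gap
        if g0 + len(tpl) + 60 > config.spike_chrom_length:
            raise PlacementError("spike-in genome too small for requested transcripts")
        sp_seq[g0: g0 + len(tpl)] = list(tpl)
        for k, o in enumerate(offs):
            spike_tss.append(TrueTSS(
                tss_id=f"SPIKE{i:03d}:{k}", feature_id=f"SPIKE{i:03d}",
                chrom="spombe_1", strand="+", pos=g0 + o + 1, isoform_role="major",
                basal_share=float(MINOR_WEIGHTS[k]), effect_class="NCRNA"))
    truth.spike_tss = spike_tss
    spike_genome = {"spombe_1": "".join(sp_seq)}

    _annotate_truth_iclasses(genome, features, truth)
    return genome, spike_genome, features, truth


def _annotate_truth_iclasses(genome, features, truth) -> None:
    """Scan-derive the isoform class of each ORF-gene TSS from the final genome.

    Independent of the analysis modules: a direct string scan for the first
    downstream ATG and its frame relative to the annotated ORF.
    """
    from ._util import offset_from_anchor, sense_slice

    fmap = {f.id: f for f in features}
    for t in truth.true_tss:
        f = fmap[t.feature_id]
        if f.fclass != "ORF":
            continue
        atg = f.cds_start if f.strand == "+" else f.cds_end
        t.atg_offset = offset_from_anchor(t.pos, atg, f.strand)
        window = sense_slice(genome, f.chrom, f.strand, t.pos, 2500)
        i = window.find("ATG")
        if i < 0:
            t.iclass_truth = "NO_ATG_FOUND"
            continue
        off = t.atg_offset
        if off > 0:
            atg1_off = off + i
        else:
            atg1_off = off + i if off + i < 0 else off + i + 1  # skip missing 0
        if t.atg_offset < 1:
            t.iclass_truth = "ANNOTATED_FIRST" if atg1_off == 1 else "UORF"
        else:
            t.iclass_truth = "ITSS_INFRAME" if (atg1_off - 1) % 3 == 0 else "ITSS_OUTFRAME"


# ---------------------------------------------------------------------------
# expression and libraries


def simulate_condition_expression(config: SimConfig, features, truth: GroundTruth) -> GroundTruth:
    """Fill per-condition expected unique-read means for every true TSS.

    mean(condition, tss) = mean_expression x basal share x effect, with the
    effect looked up by the TSS's effect class (uORF/iTSS minor isoforms use
    the NMD-sensitive columns, annotated-first isoforms the feature class).
    """
    config.validate()
    for t in truth.true_tss + truth.spike_tss:
        t.condition_means = {}
        for cond, row in config.effect_matrix.items():
            if cond not in config.effect_matrix:
                raise KeyError(f"unknown condition {cond!r}")
            eff = 1.0 if t.feature_id.startswith("SPIKE") else row[t.effect_class]
            t.condition_means[cond] = config.mean_expression * t.basal_share * eff
    for f in features:
        for cond, row in config.effect_matrix.items():
            truth.true_fold_changes[(f.id, cond)] = row[f.fclass]
    return truth


def _random_umis(rng: np.random.Generator, n: int) -> list[str]:
    arr = np.array(list(BASES))[rng.integers(0, 4, (n, TAG_UMI5 + TAG_UMI3))]
    return ["".join(row) for row in arr]


def _read_seq(genome: dict[str, str], chrom: str, strand: str, pos: int, length: int) -> str:
    from ._util import sense_slice
    return sense_slice(genome, chrom, strand, pos, length)


def simulate_libraries(config: SimConfig, genome: dict[str, str],
                       spike_genome: dict[str, str], features,
                       truth: GroundTruth) -> list[Sample]:
    """Draw reads for every sample (TAP per condition x replicate, plus no-TAP
    libraries for ``notap_condition``), spike-in mixed in.

    Unique molecule counts per TSS are negative binomial with the configured
    dispersion; capped molecules require TAP (rate ``notap_residual`` without
    it) while the uncapped background pool and the TAP-treated spike-in ligate
    in both library types.  PCR duplicates replicate full reads so that the
    expected duplicate fraction equals ``pcr_dup_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    both = dict(genome)
    both.update(spike_genome)

    plan: list[tuple[str, str, int, bool]] = []
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            plan.append((f"{cond}_r{rep}", cond, rep, True))
    for rep in range(1, config.n_notap_replicates + 1):
        plan.append((f"{config.notap_condition}_notap_r{rep}",
                     config.notap_condition, rep, False))

    # transcribed intervals for the uncapped background pool
    spans = [(f.chrom, f.strand, f.tx_start, f.tx_end) for f in features]
    span_len = np.array([b - a + 1 for (_, _, a, b) in spans], dtype=float)
    span_p = span_len / span_len.sum() if len(spans) else None

    capped_total_wt = sum(t.condition_means.get("wt", config.mean_expression * t.basal_share)
                          for t in truth.true_tss)
    bg_mean_total = capped_total_wt * (1.0 - config.capped_frac) / config.capped_frac
    spike_block_mean = sum(t.basal_share for t in truth.spike_tss) * config.mean_expression
    # scale spike transcript means so spike reads are ~spikein_frac of a TAP library
    spike_target = (capped_total_wt + bg_mean_total) * config.spikein_frac / max(1e-9, 1 - config.spikein_frac)
    spike_scale = spike_target / spike_block_mean if spike_block_mean > 0 else 0.0

    samples: list[Sample] = []
    disp = config.nb_dispersion
    for sample_id, cond, rep, tap in plan:
        depth = float(rng.uniform(*config.depth_range))
        s = Sample(sample_id, cond, rep, tap, depth)
        molecules: list[tuple[str, str, int, str, bool]] = []
        # (chrom, strand, mapped pos, source, first_base_is_extra_A)

        for t in truth.true_tss:
            mean = t.condition_means[cond] * depth * (1.0 if tap else config.notap_residual)
            n = _nb_draw(rng, mean, disp)
            if n == 0:
                continue
            if t.slippage:
                n_slip = rng.binomial(n, config.slippage_prob)
                q = t.pos - 1 if t.strand == "+" else t.pos + 1  # mapped Py position
                molecules += [(t.chrom, t.strand, q, t.tss_id, True)] * int(n_slip)
                molecules += [(t.chrom, t.strand, t.pos, t.tss_id, False)] * int(n - n_slip)
            else:
                molecules += [(t.chrom, t.strand, t.pos, t.tss_id, False)] * int(n)
        n_true = len(molecules)

        n_bg = int(rng.poisson(bg_mean_total * depth)) if span_p is not None else 0
        if n_bg:
            which = rng.choice(len(spans), size=n_bg, p=span_p)
            offs = rng.random(n_bg)
            for w, u in zip(which, offs):
                c, st, a, b = spans[w]
                p = a + int(u * (b - a + 1))
                molecules.append((c, st, p, "background", False))

        n_spike = 0
        for t in truth.spike_tss:
            n = _nb_draw(rng, config.mean_expression * t.basal_share * spike_scale * depth, disp)
            molecules += [(t.chrom, t.strand, t.pos, f"spike:{t.tss_id}", False)] * int(n)
            n_spike += int(n)

        umis = _random_umis(rng, len(molecules))
        reads: list[SimRead] = []
        for i, ((c, st, p, src, extra_a), umi) in enumerate(zip(molecules, umis)):
            if extra_a:
                body = "A" + _read_seq(both, c, st, p + (1 if st == "+" else -1),
                                       config.read_length - 1)
            else:
                body = _read_seq(both, c, st, p, config.read_length)
            reads.append(SimRead(f"{sample_id}:r{i:07d}", c, st, p, umi, body, src))

        n_dup = rng.binomial(len(reads), config.pcr_dup_rate / (1 - config.pcr_dup_rate)) \
            if reads and config.pcr_dup_rate > 0 else 0
        for j in range(int(n_dup)):
            src_read = reads[int(rng.integers(0, len(reads)))]
            reads.append(dataclasses.replace(
                src_read, read_id=f"{src_read.read_id}.dup{j}", duplicate=True))
        order = rng.permutation(len(reads))
        s.reads = [reads[i] for i in order]
        s.ledger = {"unique_true": n_true, "background": n_bg, "spike": n_spike,
                    "duplicates": int(n_dup), "total": len(reads)}
        samples.append(s)
    return samples


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with mean ``mean`` and Var = mean + dispersion*mean^2."""
    if mean <= 0:
        return 0
    size = 1.0 / dispersion
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def simulate(config: SimConfig) -> Simulation:
    """Full generation pass: genome, annotation, expression, libraries, NFR track."""
    genome, spike_genome, features, truth = generate_genome_and_annotations(config)
    simulate_condition_expression(config, features, truth)
    samples = simulate_libraries(config, genome, spike_genome, features, truth)
    nuc = nucleosome_track(genome, features)
    return Simulation(config, genome, spike_genome, features, truth, samples, nuc)


def nucleosome_track(genome: dict[str, str], features) -> dict[str, np.ndarray]:
    """Occupancy with an NFR dip at each feature 5' end flanked by two
    positioned nucleosomes (+1/-1), on a baseline of 1.0."""
    tracks = {c: np.ones(len(s)) for c, s in genome.items()}
    x = np.arange(-400, 401)
    dip = -0.8 * np.exp(-x ** 2 / (2 * 60.0 ** 2))
    bumps = 0.35 * (np.exp(-(x - 150.0) ** 2 / (2 * 50.0 ** 2))
                    + np.exp(-(x + 150.0) ** 2 / (2 * 50.0 ** 2)))
    shape = dip + bumps
    for f in features:
        tss = f.tx_start if f.strand == "+" else f.tx_end
        arr = tracks[f.chrom]
        a = max(0, tss - 1 - 400)
        b = min(len(arr), tss + 400)
        sl = shape[a - (tss - 1 - 400): len(shape) - (tss - 1 + 401 - b)]
        arr[a:b] += sl
    return tracks


# ---------------------------------------------------------------------------
# fixture writing


def write_fixtures(sim: Simulation, directory: str | Path, include_fastq: bool = True) -> dict[str, Path]:
    """Write the simulation to disk in standard formats.

    genome FASTA (both species), features GFF3 + TSV, per-sample FASTQ and
    BED-like alignment TSV, nucleosome bedGraph, ground-truth and sample
    manifests.  Files round-trip through the :mod:`tssqc.cli_io` readers.
    """
    from . import cli_io

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out / "genome.fa"
    cli_io.write_fasta(sim.genome, paths["genome"])
    paths["spike_genome"] = out / "spike_genome.fa"
    cli_io.write_fasta(sim.spike_genome, paths["spike_genome"])

    paths["features_gff3"] = out / "features.gff3"
    cli_io.write_features_gff3(sim.features, paths["features_gff3"])
    paths["features_tsv"] = out / "features.tsv"
    cli_io.write_features_tsv(sim.features, paths["features_tsv"])

    paths["nucleosome"] = out / "nucleosome.bedGraph"
    cli_io.write_bedgraph(sim.nucleosome, paths["nucleosome"], step=10)

    man_rows = []
    for s in sim.samples:
        aln = out / f"alignments_{s.sample_id}.tsv"
        with open(aln, "w") as fh:
            fh.write("chrom\tstart0\tend0\tstrand\tumi\tseq\tread_id\n")
            for r in s.reads:
                L = len(r.seq)
                if r.strand == "+":
                    a0, b0 = r.pos - 1, r.pos - 1 + L
                else:
                    a0, b0 = r.pos - L, r.pos
                fh.write(f"{r.chrom}\t{a0}\t{b0}\t{r.strand}\t{r.umi}\t{r.seq}\t{r.read_id}\n")
        paths[f"alignments_{s.sample_id}"] = aln
        if include_fastq:
            fq = out / f"reads_{s.sample_id}.fastq"
            with open(fq, "w") as fh:
                for r in s.reads:
                    full = r.umi[:TAG_UMI5] + TAG_FIXED + r.umi[TAG_UMI5:] + r.seq
                    fh.write(f"@{r.read_id}\n{full}\n+\n{'I' * len(full)}\n")
            paths[f"reads_{s.sample_id}"] = fq
        man_rows.append((s.sample_id, s.condition, s.replicate, int(s.tap),
                         f"{s.depth:.6g}", s.ledger["total"], s.ledger["unique_true"],
                         s.ledger["background"], s.ledger["spike"], s.ledger["duplicates"]))

    paths["samples"] = out / "samples.tsv"
    with open(paths["samples"], "w") as fh:
        fh.write("sample_id\tcondition\treplicate\ttap\tdepth\ttotal_reads\t"
                 "unique_true\tbackground\tspike\tduplicates\n")
        for row in man_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    paths["truth_tss"] = out / "truth_tss.tsv"
    conds = sim.config.conditions
    with open(paths["truth_tss"], "w") as fh:
        fh.write("tss_id\tfeature_id\tchrom\tstrand\tpos\tisoform_role\tbasal_share\t"
                 "effect_class\tslippage\ticlass_truth\tatg_offset\t"
                 + "\t".join(f"mean_{c}" for c in conds) + "\n")
        for t in sim.truth.true_tss:
            means = "\t".join(f"{t.condition_means.get(c, float('nan')):.6g}" for c in conds)
            fh.write(f"{t.tss_id}\t{t.feature_id}\t{t.chrom}\t{t.strand}\t{t.pos}\t"
                     f"{t.isoform_role}\t{t.basal_share:.6g}\t{t.effect_class}\t"
                     f"{int(t.slippage)}\t{t.iclass_truth}\t{t.atg_offset}\t{means}\n")

    paths["biased_genes"] = out / "biased_genes.txt"
    paths["biased_genes"].write_text("\n".join(sim.truth.biased_gene_ids) + "\n")
    return paths
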