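"""Assign TSS clusters to annotation categories.

Every cluster gets exactly one of eight category letters, decided at its
summit position (anchor configurable) against the feature annotation:

* ``O`` — sense overlap with an mRNA 5'-UTR (the cluster is a gene's TSS);
* ``F`` — sense overlap with a stable ncRNA or transposable element;
* ``C`` / ``X`` / ``S`` — sense overlap with a CUT, XUT or SUT, in that
  priority order (the three pervasive-transcript annotations overlap);
* ``B`` — sense position within an ORF's CDS or 3'-UTR (internal sense
  initiation);
* ``A`` — antisense within an mRNA;
* ``I`` — intergenic (none of the above).

The 5'-UTR is the half-open interval [transcript 5' end, A of ATG) in the
direction of transcription: a summit exactly on the A of the start codon is
downstream (category B), consistent with the observation that the A and G of
the start codon themselves serve as internal TSSs.  ORFs flagged dubious are
excluded from O/B/A matching.
"""

from __future__ import annotations

from dataclasses import dataclass

FEATURE_CLASSES = ("ORF", "CUT", "XUT", "SUT", "NCRNA", "TE")


@dataclass
class Feature:
    """Annotated transcript unit with genomic (1-based inclusive) bounds.

    ``tx_start <= tx_end`` regardless of strand; for ORFs ``cds_start`` /
    ``cds_end`` are the genomic bounds of the CDS and the A of the ATG is
    ``cds_start`` on + and ``cds_end`` on -.
    """

    id: str
    fclass: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int | None = None
    cds_end: int | None = None
    dubious: bool = False

    def validate(self) -> None:
        if self.fclass not in FEATURE_CLASSES:
            raise ValueError(f"{self.id}: unknown feature class {self.fclass!r}")
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.id}: tx_start > tx_end")
        if self.fclass == "ORF":
            if self.cds_start is None or self.cds_end is None:
                raise ValueError(f"{self.id}: ORF without CDS bounds")
            if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
                raise ValueError(f"{self.id}: CDS outside transcript bounds")
            if (self.cds_end - self.cds_start + 1) % 3:
                raise ValueError(f"{self.id}: CDS length not divisible by 3")

    @property
    def atg_pos(self) -> int:
        """1-based genomic coordinate of the A of the start codon."""
        if self.cds_start is None:
            raise ValueError(f"{self.id}: not an ORF")
        return self.cds_start if self.strand == "+" else self.cds_end

    @property
    def five_prime(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos <= self.tx_end

    def in_utr5(self, pos: int) -> bool:
        """Sense-strand position within [tx 5' end, A of ATG)."""
        if self.fclass != "ORF":
            return False
        if self.strand == "+":
            return self.tx_start <= pos < self.cds_start
        return self.cds_end < pos <= self.tx_end

    def in_cds_or_utr3(self, pos: int) -> bool:
        if self.fclass != "ORF":
            return False
        if self.strand == "+":
            return self.cds_start <= pos <= self.tx_end
        return self.tx_start <= pos <= self.cds_end


@dataclass
class CategoryCall:
    tssc_id: str
    category: str
    feature_id: str | None


def _nearest_downstream_atg(pos: int, cands: list[Feature]) -> Feature:
    def key(f: Feature) -> tuple:
        d = f.atg_pos - pos if f.strand == "+" else pos - f.atg_pos
        return (d < 0, abs(d), f.id)  # prefer downstream ATG, then closest
    return min(cands, key=key)


def _nearest_five_prime(pos: int, cands: list[Feature]) -> Feature:
    return min(cands, key=lambda f: (abs(f.five_prime - pos), f.id))


def assign_category(tssc, features: list[Feature], anchor: str = "summit") -> CategoryCall:
    """Category call for one cluster; see the module docstring for the rules.

    ``anchor="summit"`` decides overlap at the summit position;
    ``anchor="any"`` lets any member position of the cluster satisfy a rule
    (the first rule satisfied by any position wins).
    """
    if anchor not in ("summit", "any"):
        raise ValueError("anchor must be 'summit' or 'any'")
    positions = [tssc.summit] if anchor == "summit" else list(tssc.positions)
    here = [f for f in features if f.chrom == tssc.chrom]
    for f in here:
        f.validate()
    sense = [f for f in here if f.strand == tssc.strand]
    anti = [f for f in here if f.strand != tssc.strand]

    def pick(rule, cands, tie) -> Feature | None:
        for pos in positions:
            hit = [f for f in cands if rule(f, pos)]
            if hit:
                chosen = tie(pos, hit) if len(hit) > 1 else hit[0]
                return chosen
        return None

    orfs = [f for f in sense if f.fclass == "ORF" and not f.dubious]
    f = pick(lambda f, p: f.in_utr5(p), orfs, _nearest_downstream_atg)
    if f:
        return CategoryCall(tssc.id, "O", f.id)
    stable = [f for f in sense if f.fclass in ("NCRNA", "TE")]
    f = pick(lambda f, p: f.contains(p), stable, _nearest_five_prime)
    if f:
        return CategoryCall(tssc.id, "F", f.id)
    for fclass, letter in (("CUT", "C"), ("XUT", "X"), ("SUT", "S")):
        cands = [f for f in sense if f.fclass == fclass]
        f = pick(lambda f, p: f.contains(p), cands, _nearest_five_prime)
        if f:
            return CategoryCall(tssc.id, letter, f.id)
    f = pick(lambda f, p: f.in_cds_or_utr3(p), orfs, _nearest_downstream_atg)
    if f:
        return CategoryCall(tssc.id, "B", f.id)
    anti_orfs = [f for f in anti if f.fclass == "ORF" and not f.dubious]
    f = pick(lambda f, p: f.contains(p), anti_orfs, _nearest_five_prime)
    if f:
        return CategoryCall(tssc.id, "A", f.id)
    return CategoryCall(tssc.id, "I", None)


def assign_categories(tsscs, features: list[Feature], anchor: str = "summit") -> list[CategoryCall]:
    """Batch version; also records category/feature_id on each cluster."""
    by_chrom: dict[str, list[Feature]] = {}
    for f in features:
        f.validate()
        by_chrom.setdefault(f.chrom, []).append(f)
    calls = []
    for t in tsscs:
        call = assign_category(t, by_chrom.get(t.chrom, []), anchor=anchor)
        t.category, t.feature_id = call.category, call.feature_id
        calls.append(call)
    return calls


def apply_atg_corrections(features: list[Feature], corrections) -> list[Feature]:
    """Replace misannotated start-codon coordinates.

    ``corrections`` yields ``(orf_id, new_atg_pos)`` pairs where the new
    position is the 1-based genomic coordinate of the A of the ATG.  Returns
    a new feature list; unknown ids or corrections that break the CDS frame
    raise with the offending ORF named.
    """
    by_id = {f.id: f for f in features}
    out = {f.id: f for f in features}
    for orf_id, new_atg in corrections:
        f = by_id.get(orf_id)
        if f is None or f.fclass != "ORF":
            raise KeyError(f"ATG correction for unknown ORF {orf_id!r}")
        new_atg = int(new_atg)
        if f.strand == "+":
            g = Feature(f.id, f.fclass, f.chrom, f.strand, f.tx_start, f.tx_end,
                        new_atg, f.cds_end, f.dubious)
        else:
            g = Feature(f.id, f.fclass, f.chrom, f.strand, f.tx_start, f.tx_end,
                        f.cds_start, new_atg, f.dubious)
        try:
            g.validate()
        except ValueError as e:
            raise ValueError(f"ATG correction breaks {orf_id}: {e}") from e
        out[orf_id] = g
    return [out[f.id] for f in features]
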