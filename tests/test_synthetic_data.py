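import numpy as np
import pytest

from tssqc.synthetic_data import (SimConfig, TAG_FIXED, TAG_UMI5,
                                  generate_genome_and_annotations,
                                  simulate, simulate_condition_expression,
                                  simulate_libraries)
from tssqc._util import PURINES, PYRIMIDINES, base_at, downstream


def tiny_cfg(**kw):
    base = dict(seed=0, n_chromosomes=1, chrom_length=40_000, n_orfs=8,
                n_cuts=3, n_xuts=3, n_suts=3, n_ncrna=2, n_spike_transcripts=10,
                spike_chrom_length=8_000)
    base.update(kw)
    return SimConfig(**base)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(capped_frac=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(mean_expression=-1).validate()
    with pytest.raises(ValueError):
        SimConfig(pcr_dup_rate=0.6).validate()
    with pytest.raises(ValueError):
        SimConfig(uorf_isoform_frac=0.5, itss_isoform_frac=0.5).validate()
    bad = SimConfig()
    bad.effect_matrix["wt"]["CUT"] = -1
    with pytest.raises(ValueError):
        bad.validate()


def test_empty_config_empty_features():
    cfg = tiny_cfg(n_orfs=0, n_cuts=0, n_xuts=0, n_suts=0, n_ncrna=0)
    genome, _sg, feats, truth = generate_genome_and_annotations(cfg)
    assert feats == []
    assert truth.true_tss == []
    assert len(genome) == 1 and len(genome["chr1"]) == cfg.chrom_length


def test_planted_tss_on_consensus():
    # for every planned TSS: A at -8, pyrimidine at -1, purine at +1 (sense)
    genome, _sg, _feats, truth = generate_genome_and_annotations(tiny_cfg())
    assert truth.true_tss
    for t in truth.true_tss:
        assert base_at(genome, t.chrom, t.strand, t.pos) in PURINES
        assert base_at(genome, t.chrom, t.strand, downstream(t.pos, t.strand, -1)) in PYRIMIDINES
        assert base_at(genome, t.chrom, t.strand, downstream(t.pos, t.strand, -8)) == "A"


def test_orf_structure():
    from tssqc._util import sense_slice

    genome, _sg, feats, _truth = generate_genome_and_annotations(tiny_cfg())
    stops = {"TAA", "TAG", "TGA"}
    for f in feats:
        if f.fclass != "ORF":
            continue
        cds = sense_slice(genome, f.chrom, f.strand, f.atg_pos,
                          f.cds_end - f.cds_start + 1)
        assert cds.startswith("ATG")
        assert cds[-3:] in stops
        internal = [cds[i:i + 3] for i in range(3, len(cds) - 3, 3)]
        assert not any(c in stops for c in internal)


def test_inframe_atg_bias_realised():
    # biased genes have ~bias-fold fewer +1-frame ATGs in the first 100 nt
    from tssqc._util import sense_slice

    ratios = []
    for seed in range(3):
        cfg = tiny_cfg(seed=seed, n_orfs=60, chrom_length=140_000, inframe_atg_bias=0.5)
        genome, _sg, feats, truth = generate_genome_and_annotations(cfg)
        bset = set(truth.biased_gene_ids)

        def count(fs):
            n = 0
            for f in fs:
                seq = sense_slice(genome, f.chrom, f.strand, f.atg_pos, 102)
                n += sum(seq[i:i + 3] == "ATG" for i in range(3, 99, 3))
            return n

        orfs = [f for f in feats if f.fclass == "ORF"]
        nb = count([f for f in orfs if f.id in bset])
        nu = count([f for f in orfs if f.id not in bset])
        ratios.append(nb / nu)
    assert 0.2 < np.mean(ratios) < 0.8


def test_condition_means_multiplicative():
    cfg = tiny_cfg()
    _g, _s, feats, truth = generate_genome_and_annotations(cfg)
    simulate_condition_expression(cfg, feats, truth)
    for t in truth.true_tss:
        for cond, row in cfg.effect_matrix.items():
            expect = cfg.mean_expression * t.basal_share * row[t.effect_class]
            assert t.condition_means[cond] == pytest.approx(expect)
    # wild type is the all-ones reference
    assert all(v == 1.0 for v in cfg.effect_matrix["wt"].values())


def test_identity_effects_equal_wt():
    cfg = tiny_cfg()
    for cond in cfg.effect_matrix:
        cfg.effect_matrix[cond] = {c: 1.0 for c in cfg.effect_matrix[cond]}
    _g, _s, feats, truth = generate_genome_and_annotations(cfg)
    simulate_condition_expression(cfg, feats, truth)
    for t in truth.true_tss:
        assert len(set(t.condition_means.values())) == 1


def test_nb_counts_match_means():
    # realized per-TSS unique counts across seeds: mean within 3 SE of target
    cfg = tiny_cfg(pcr_dup_rate=0.0, capped_frac=0.999)
    genome, sg, feats, truth = generate_genome_and_annotations(cfg)
    simulate_condition_expression(cfg, feats, truth)
    t0 = max(truth.true_tss, key=lambda t: t.basal_share)
    totals, means = [], []
    for seed in range(50):
        cfg.seed = seed
        samples = simulate_libraries(cfg, genome, sg, feats, truth)
        s = samples[0]  # wt replicate 1
        n = sum(1 for r in s.reads if r.source == t0.tss_id)
        totals.append(n)
        means.append(t0.condition_means["wt"] * s.depth)
    mu = np.mean(means)
    se = np.std(totals, ddof=1) / np.sqrt(len(totals))
    assert abs(np.mean(totals) - mu) < 3 * se + 1e-9


def test_duplicate_fraction_and_zero_rates():
    cfg = tiny_cfg(pcr_dup_rate=0.0, notap_residual=0.0)
    sim = simulate(cfg)
    notap = [s for s in sim.samples if not s.tap]
    assert notap
    for s in sim.samples:
        ids = [r.read_id for r in s.reads]
        assert len(ids) == len(set(ids))
        assert s.ledger["duplicates"] == 0
    for s in notap:
        assert all(r.source == "background" or r.source.startswith("spike:")
                   for r in s.reads)

    cfg2 = tiny_cfg(pcr_dup_rate=0.2)
    fracs = []
    for seed in range(5):
        cfg2.seed = seed
        sim2 = simulate(cfg2)
        tot = sum(s.ledger["total"] for s in sim2.samples)
        dup = sum(s.ledger["duplicates"] for s in sim2.samples)
        fracs.append(dup / tot)
    assert abs(np.mean(fracs) - 0.2) < 0.02


def test_slippage_prob_one_forces_extra_a():
    cfg = tiny_cfg(slippage_prob=1.0, slippage_gene_frac=1.0)
    sim = simulate(cfg)
    genome = sim.genome
    slip_ids = {t.tss_id for t in sim.truth.true_tss if t.slippage}
    assert slip_ids
    seen = 0
    for s in sim.samples:
        for r in s.reads:
            if r.source in slip_ids and not r.duplicate:
                seen += 1
                assert r.seq[0] == "A"
                # mapped over the genomic pyrimidine one nt 5' of the real start
                assert base_at(genome, r.chrom, r.strand, r.pos) in PYRIMIDINES
    assert seen > 0


def test_read_sequences_match_genome():
    sim = simulate(tiny_cfg())
    both = dict(sim.genome)
    both.update(sim.spike_genome)
    from tssqc._util import sense_slice

    s = sim.samples[0]
    checked = 0
    for r in s.reads[:500]:
        if r.source == "background" or r.source.startswith("spike:"):
            assert r.seq == sense_slice(both, r.chrom, r.strand, r.pos, len(r.seq))
            checked += 1
    assert checked > 0


def test_write_fixtures_roundtrip(small_sim, small_fixture_dir):
    from tssqc import cli_io

    genome = cli_io.read_fasta(small_fixture_dir / "genome.fa")
    assert genome == small_sim.genome
    feats = cli_io.load_features(small_fixture_dir / "features.tsv")
    assert feats == small_sim.features
    feats_g = cli_io.load_features(small_fixture_dir / "features.gff3")
    assert feats_g == small_sim.features
    # FASTQ carries the full tag: UMI parts flanking the fixed block
    s = small_sim.samples[0]
    reads = dict(cli_io.read_fastq(small_fixture_dir / f"reads_{s.sample_id}.fastq"))
    r = s.reads[0]
    assert reads[r.read_id] == r.umi[:TAG_UMI5] + TAG_FIXED + r.umi[TAG_UMI5:] + r.seq


def test_placement_error():
    from tssqc.synthetic_data import PlacementError

    with pytest.raises(PlacementError):
        generate_genome_and_annotations(tiny_cfg(n_orfs=100, chrom_length=5_000))


def test_nucleosome_track_dip(small_sim):
    # occupancy at a feature 5' end is depressed relative to baseline
    f = small_sim.features[0]
    tss = f.tx_start if f.strand == "+" else f.tx_end
    arr = small_sim.nucleosome[f.chrom]
    assert arr[tss - 1] < 0.6
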